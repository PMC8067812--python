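# Methods

## Scope and conventions

`exactsim` predicts the spectrum of repair products at a single CRISPR
double-strand break from sequence alone.  All coordinates are 0-based,
half-open on the gene-sense top strand; a cut junction at index `j` is the
backbone break between positions `j−1` and `j`.  Sequences are unambiguous
ACGT strings: lower case is folded, IUPAC ambiguity codes are rejected
outright because every downstream operation (microhomology search, arm
validation, dimer scanning) is exact string matching.

## Cleavage model

Cas9 recognizes NGG and cuts bluntly 3 nt 5' of the PAM.  Cas12a
recognizes TTTN and cuts staggered, after protospacer positions 18 (on the
protospacer strand) and 23 (opposite strand), leaving a 5-nt 5' overhang
for either guide orientation.  The 18/23 offsets are conventional
enzymology and configurable (`cas12a_cut_top`, `cas12a_cut_bottom`); the
quantity the repair model relies on is the 5-nt overhang, which is
invariant under those choices' difference.  Downstream repair operations
consume a single coordinate — the top-strand break — because deletion
bookkeeping in sequencing data is single-coordinate; the overhang interval
is carried on the `CutSite` for the dimer pathway.

## MMEJ enumeration

A deletion `[u, v)` is MMEJ-attributable iff `locus[u:u+m] == locus[v:v+m]`
for some `m ≥ min_mh`, with `u ≤ junction−1`, `v ≥ junction` and
`v−u ≤ max_del`.  Enumeration is exhaustive over forward-maximal matches
within a ±`window` of the cut; repeat occurrences may overlap (tandem
repeats).  Pairs producing the same product string are merged, keeping the
largest `mh_len` (ties: smallest `u_start`); output is sorted by `mh_len`
desc, `del_len` asc, `u_start` asc, so results are deterministic.  A
brute-force oracle over all spanning deletion intervals of small loci backs
the enumeration in the tests.

MMEJ propensity is the heuristic `w = mh_len · exp(−del_len / L_decay)`
(`L_decay` = 20 nt): increasing in repeat length (greater annealing
stabilization), decreasing in deletion length (more resection needed).
Only the order relations of these weights are meaningful.

Defaults: `min_mh` = 3 (3-nt repeats demonstrably drive deletions),
`max_del` = 30, `window` = 30.  NHEJ indels are modeled as small
(≤ 30 nt, truncated geometric with p = 0.5), deletion:insertion 3:1,
uniform insert bases, uniform left/right split of deletions about the
junction — a seeded, bit-reproducible sampler producing the characteristic
plurality of minor products.  A stated upper bound of ">30 bp" for small
NHEJ indels in the source description is treated as a typo for ≤30 bp,
since "typically small" contradicts a lower bound; the bound is
configurable.

## ssODN-templated repair

An oligo is `left_arm + payload + right_arm` in gene-sense orientation
(`orientation` records which strand the physical molecule matches; the
`NS` molecule is the reverse complement).  Arms must match the reference
flanks exactly (tolerance 0): modeling mismatch-tolerant annealing would
require an annealing energy model with no constraining data, and a failed
arm match returns no product, signalling fallback to error-prone repair.

One-step gap bridging and the two-step SDSA-style route produce the same
perfect product by construction; they differ only in side products and
weighting (`pathway_split` = 0.5, a placeholder — the two routes are not
experimentally distinguishable).  The two-step route's duplication side
product arises by mispriming: if the upstream flank's 3'-terminal
`sdsa_min_anneal` (= 5) bases occur a second time within the upstream arm,
ending at reference coordinate `m < junction`, the template walk re-copies
the bases between the alternative anneal site and the cut:

    product = locus[:junction] + locus[m:junction] + payload + downstream

i.e. a tandem duplication of `locus[m:junction]` flanking the edit.  Only
the upstream-arm route is implemented; because assembly is done in
gene-sense coordinates, flipping the oligo's delivery strand leaves the
product set unchanged.  Extension is treated as full-length and
deterministic; partial-extension stochasticity is out of scope.

Strand bias: the ssODN matching the guide RNA's polarity repairs more
efficiently.  No mechanism is established (cut-end structure and residual
Cas binding are ruled out), so the bias is a single multiplicative factor
`bias_ratio` (= 2.0) on the precise-product weight when oligo orientation
equals guide strand — keyed to the guide, not the gene.

## ssODN self-dimers

Two copies of one oligo annealed antiparallel are parameterized by the
pairing `i + j = c`; every contiguous complementary run ≥ `min_overlap`
(= 4) is reported once.  A run covering the complete 3'-terminal overlap
region of its alignment pairs both 3' termini (recessed ends, protruding
5' tails — `three_prime_recessed`, or `blunt` for the full-length
alignment); every other run leaves an unpaired 3' terminus and is
classified `three_prime_overhang`.  Only recessed/blunt ("productive")
geometries can engage the free ends of a staggered cut; the filter also
drops geometries weaker than `dimer_dg_threshold` (= −9 kcal/mol, a common
primer-dimer heuristic).

Duplex ΔG°₃₇ is the SantaLucia 1998 unified nearest-neighbor sum plus one
initiation term per end.  Dangling-end, salt and duplex-symmetry
corrections are omitted: the model uses ΔG only to rank geometries and
gate activation, and the published increments are exactly reproduced by a
hand-summation oracle in the tests.  Vendor-tool ΔG outputs are not
reproduction targets.

The insertion reconstruction is deterministic assembly: one oligo copy is
incorporated into the top strand as written (against its normal templating
orientation); its 5' end is flap-trimmed by `dimer_trim` (= 2) unmatched
bases; the next `dimer_min_mh` (= 5) bases must match the upstream flank
exactly (rightmost occurrence, minimizing resection, match ending at `m`);
upstream bases `[m, junction)` are resected and the microhomology is
counted once, from the reference side:

    product = locus[:m] + copy[trim+mh:] + fill + locus[junction:]
    net     = (L − trim − mh) + len(fill) − (junction − m)

`fill` (default empty) covers the open question of whether the second
stage involves fill-in synthesis or pure ligation.  On the packaged
`F_DIMER` construct (70-nt oligo, 15-nt resection span) this yields
net +48.

## Spectrum combination

Weights are combined analytically — no Monte-Carlo over pathway choice —
so spectra are exactly reproducible; the seed only instantiates the
concrete NHEJ events that share the fixed NHEJ aggregate.  With a template
present: precise products get `hdr_base_weight × bias`, split between the
one- and two-step routes; duplication side products take
`sdsa_duplication_rate` (= 0.1) of the two-step share when a misprime site
exists; error-prone totals are multiplied by `suppression` (= 0.5 < 1); a
productive dimer switches on the insertion product at
`dimer_base_weight`; and a hybrid molecule (the programmed edit plus a
1-bp flanking deletion) is pinned at normalized frequency `hybrid_rate`
(= 5×10⁻⁴ ≤ 1:1000).  Products are merged into sequence classes within a
pathway label (not across pathways, so per-pathway aggregates stay
well-defined) and normalized to frequencies summing to 1.

`nhej_total_weight` = 2.0 is the one calibrated constant: with the MMEJ
weight formula above and a single engineered repeat pair 10 nt apart,
3-bp repeats fall below it (3·e^−0.5 ≈ 1.82) and 4-bp repeats exceed it
(4·e^−0.5 ≈ 2.43), reproducing the observed ~4-bp threshold at which
microhomology overtakes NHEJ.  `hdr_base_weight` = 5.0 makes the perfect
product dominate a templated reaction, matching the observation that the
programmed edit is the only HDR-class product seen.  None of these encode
absolute editing efficiencies; fitting them to measured product
percentages is a non-goal.

## Synthetic data

The generator owns testability: loci are built with engineered repeat
copies and pads drawn from disjoint alphabets ({A,C} upstream of the cut,
{G,T} downstream), so flanks cannot share sequence except where designed.
Every construct passes an executable audit before being returned: the
engineered copies are present verbatim; any substring ≥ k (= 3) occurring
both at an upstream start and a downstream start — the exact condition for
an MMEJ alignment to span the cut, junction-crossing windows included — is
a substring of the engineered repeat and occurs only inside the engineered
copies; and no engineered-offset alignment extends past the copies
(boundary bases differ).  Randomized generation is seeded with bounded
retries; packaged fixtures use fixed constant pads so every downstream
number is exact.

What the generator does not emulate: real genomic base composition,
chromatin, repeat families, sequencing noise, or cell-type-dependent
pathway prevalence.  Passing tests therefore demonstrate the correctness
of the sequence-level model, not predictions of in-cell editing rates.

The packaged fixtures encode the documented repeat geometries ("X bp
upstream / Y bp downstream" is read as repeat-start separation X + Y, the
only reading consistent with an 11-bp deletion from repeats 6 bp upstream
and 5 bp downstream).  The 28/27/30-nt microhomology loci are too short to
host a full guide, so they carry an explicit junction instead of a `Guide`;
the 100-nt NotI and 80-nt dimer constructs carry real Cas9/Cas12a guides.
The dimer construct additionally fixes trim = 2, microhomology = 5,
fill = 0 and a 15-nt resection span so the assembly identity yields
net +48, and its audit re-verifies the 8-nt 3'-terminal palindrome, the
probe match and the +48 reconstruction on every load.

## Numerical and degenerate-input choices

Ties in dimer ranking break by larger overlap, then smaller
|alignment offset|; MMEJ product merging keeps the longest-microhomology
representative.  Empty spectra normalize to all-zero frequencies rather
than dividing by zero.  Junctions must be strictly interior; guides whose
cut would fall on a locus boundary are rejected.  Frequencies are exact
ratios of float weights; normalization is checked to 1e−9 in the tests.

## Known limitations

* Pathway weights are order-relation calibrations, not probabilities fit
  to data; absolute fractions in a predicted spectrum should not be read
  as editing efficiencies.
* A secondary −10 bp product reported alongside the −11 bp deletion at the
  CTGG repeat site is not produced by clean enumeration (a 1-nt slippage
  variant is unspecified) and is deliberately not modeled.
* Mismatch-tolerant arm annealing, nick-templated repair, hairpin
  (intramolecular) oligo structure, off-target scoring and learned indel
  predictors are out of scope.
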