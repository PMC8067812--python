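"""Attribute observed deletions to flanking microhomology.

Enumerates every MMEJ-capable repeat alignment around the cut on two
packaged repeat-geometry loci.  The 6-nt CGTCGT repeat pair (copies at the
cut site and 10 nt downstream) explains both a 10-bp and a 13-bp deletion;
the 4-nt CTGG pair (6 bp upstream / 5 bp downstream) collapses to a single
11-bp deletion class.
"""

from exactsim import apply_mmej, enumerate_mmej, mmej_weight
from exactsim.synthetic import fixtures

for name in ("F1364", "F1344"):
    fix = fixtures(name)
    print(f"{name}: locus {fix.locus} cut at {fix.junction}")
    for pair in enumerate_mmej(fix.locus, fix.junction):
        product = apply_mmej(fix.locus, pair)
        print(
            f"  repeat {fix.locus[pair.u_start : pair.u_start + pair.mh_len]:<7}"
            f" mh={pair.mh_len}  deletion={pair.del_len:>2} bp"
            f"  weight={mmej_weight(pair):.2f}  product={product.seq}"
        )
    print()

print("Longer microhomology and shorter deletions rank higher: the top line")
print("is the deletion class expected to dominate error-prone repair.")
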