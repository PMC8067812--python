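"""Synthetic loci, oligos, and packaged fixtures with guaranteed
microhomology geometry.

Every stage of the repair model is testable without external data because
the generator constructs loci whose cross-junction sequence sharing is fully
controlled: apart from deliberately engineered repeat copies, the upstream
flank is drawn from the {A, C} alphabet and the downstream flank from
{G, T}, so the two flanks cannot share any k-mer at all.  An exhaustive
shared-substring audit (plus a boundary non-extension check on the
engineered copies) verifies each construction before it is returned —
the audits are executable guarantees, not documentation.

The packaged fixtures use fixed constant pads (not randomized) so that
every downstream quantity is exact:

* ``F1364`` — 28-nt locus with a 6-nt CGTCGT repeat at the cut site and
  10 nt downstream; MMEJ yields deletions of 7, 10 and 13 bp.
* ``F1344`` — 27-nt locus with 4-nt CTGG repeats 6 bp upstream and 5 bp
  downstream of the cut; a single merged 11-bp MMEJ deletion.
* ``F1228`` — 30-nt locus with a 5-nt GAATG repeat 1 bp upstream and 7 bp
  downstream of the cut (no printed deletion size; used for
  suppression-direction properties).
* ``F_NOTI`` — 100-nt locus with a Cas9 guide and a 36+8+36 ssODN carrying
  a central NotI site (GCGGCCGC) insertion.
* ``F_DIMER`` — 80-nt locus with an NS Cas12a guide and a 70-nt
  (40 + 1 + 29) single-base-repair ssODN whose 3' terminus carries an 8-nt
  palindrome: its only productive self-dimer has an 8-nt overlap and the
  dimer-mediated insertion reconstructs a +48 bp product (5' trim 2,
  5-nt upstream microhomology, 15-nt upstream resection).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .cleavage import Guide, cut_geometry
from .dimer import best_productive_dimer, dimer_insertion_repair
from .hdr import Edit, Oligo
from .seqcore import SequenceError, as_seq, check_junction, revcomp, write_fasta

__all__ = [
    "AuditError",
    "LocusSpec",
    "OligoSpec",
    "Fixture",
    "audit_mmej_locus",
    "make_mmej_locus",
    "make_single_repeat_locus",
    "make_oligo",
    "fixtures",
    "FIXTURE_NAMES",
    "write_fixture",
]

_UPSTREAM_ALPHA = "AC"
_DOWNSTREAM_ALPHA = "GT"


class AuditError(SequenceError):
    """A generated construct failed its executable audit."""


@dataclass(frozen=True)
class LocusSpec:
    """Recipe for a locus with engineered flanking-repeat geometry.

    ``copy_starts`` are the 0-based starts of the engineered repeat copies;
    everything else is pad.  The audit window covers the full flanks with
    shared-k-mer floor ``k``.
    """

    repeat_unit: str
    copy_starts: tuple[int, ...]
    junction: int
    total_len: int
    k: int = 3

    def __post_init__(self) -> None:
        if self.repeat_unit:
            object.__setattr__(self, "repeat_unit", as_seq(self.repeat_unit))
        L = len(self.repeat_unit)
        for s in self.copy_starts:
            if not 0 <= s <= self.total_len - L:
                raise SequenceError(f"repeat copy at {s} does not fit in total_len")
        if not 0 < self.junction < self.total_len:
            raise SequenceError("junction must be interior to the locus")
        if self.k < 2:
            raise SequenceError("audit k-mer floor must be >= 2")


def _substrings(s: str, length: int) -> set[str]:
    return {s[i : i + length] for i in range(len(s) - length + 1)}


def audit_mmej_locus(locus: str, spec: LocusSpec) -> None:
    """Exhaustive audit of the engineered-geometry invariants.

    1. every engineered repeat copy is present verbatim;
    2. shared-substring exclusion: any substring of length >= k occurring
       both at a start upstream of the junction and at a start at/after it
       (the exact condition for an MMEJ alignment to span the cut, windows
       crossing the junction included) is a substring of the repeat;
    3. boundary non-extension: no engineered-offset alignment extends past
       the engineered copies.
    """
    locus = as_seq(locus)
    if len(locus) != spec.total_len:
        raise AuditError("locus length differs from spec")
    R, L = spec.repeat_unit, len(spec.repeat_unit)
    for s in spec.copy_starts:
        if locus[s : s + L] != R:
            raise AuditError(f"engineered repeat missing at {s}")
    repeat_subs = {R[i:j] for i in range(L) for j in range(i + spec.k, L + 1)}
    for length in range(spec.k, len(locus) + 1):
        upstream_start = {
            locus[i : i + length]
            for i in range(0, min(spec.junction, len(locus) - length + 1))
        }
        downstream_start = {
            locus[i : i + length] for i in range(spec.junction, len(locus) - length + 1)
        }
        shared = upstream_start & downstream_start
        rogue = shared - repeat_subs
        if rogue:
            raise AuditError(f"flanks share non-engineered {length}-mers: {sorted(rogue)}")
        # every occurrence of a shared substring must sit inside an
        # engineered copy, or a non-engineered alignment could span the cut
        for w in shared:
            start = locus.find(w)
            while start != -1:
                if not any(s <= start and start + length <= s + L for s in spec.copy_starts):
                    raise AuditError(
                        f"shared {length}-mer {w} occurs outside the engineered copies at {start}"
                    )
                start = locus.find(w, start + 1)
        if not shared:
            break
    for a in spec.copy_starts:
        for b in spec.copy_starts:
            if a >= b:
                continue
            if a - 1 >= 0 and b - 1 >= 0 and locus[a - 1] == locus[b - 1]:
                raise AuditError(f"repeat alignment ({a},{b}) extends left")
            if b + L < len(locus) and locus[a + L] == locus[b + L]:
                raise AuditError(f"repeat alignment ({a},{b}) extends right")


def make_mmej_locus(
    spec: LocusSpec,
    seed: Optional[int] = None,
    pads: Optional[str] = None,
) -> str:
    """Construct a locus satisfying ``spec``; audited before return.

    Pad positions upstream of the junction are drawn from {A, C} and
    downstream from {G, T} (deterministically from ``seed``, or taken
    left-to-right from the explicit ``pads`` string for packaged constants);
    bounded retries, then explicit failure.
    """
    R, L = spec.repeat_unit, len(spec.repeat_unit)
    pad_positions = [
        i
        for i in range(spec.total_len)
        if not any(s <= i < s + L for s in spec.copy_starts)
    ]
    if pads is not None:
        if len(pads) != len(pad_positions):
            raise SequenceError(
                f"explicit pads length {len(pads)} != number of pad positions {len(pad_positions)}"
            )
        attempts = [list(as_seq(pads))] if pads else [[]]
    else:
        if seed is None:
            raise SequenceError("a seed is required for randomized pad generation")
        rng = np.random.default_rng(seed)
        attempts = [
            [
                str(
                    rng.choice(
                        list(_UPSTREAM_ALPHA if i < spec.junction else _DOWNSTREAM_ALPHA)
                    )
                )
                for i in pad_positions
            ]
            for _ in range(200)
        ]
    last_err: Optional[AuditError] = None
    for pad_chars in attempts:
        chars = ["N"] * spec.total_len
        for s in spec.copy_starts:
            for k, ch in enumerate(R):
                chars[s + k] = ch
        for pos, ch in zip(pad_positions, pad_chars):
            chars[pos] = ch
        locus = "".join(chars)
        try:
            audit_mmej_locus(locus, spec)
            return locus
        except AuditError as err:
            last_err = err
    raise AuditError(f"unsatisfiable locus spec after bounded retries: {last_err}")


def make_single_repeat_locus(repeat_len: int, seed: int, offset: int = 10) -> tuple[str, int]:
    """One engineered repeat pair at a fixed start offset (default 10 nt).

    Returns ``(locus, junction)``; the repeat is a prefix of ACGTACGT, the
    copies start at 12 and ``12 + offset``, and the junction sits mid-spacer.
    Used for the MMEJ-vs-NHEJ dominance sweep.
    """
    if not 2 <= repeat_len <= 8:
        raise SequenceError("repeat_len must be in [2, 8]")
    if repeat_len >= offset:
        raise SequenceError("repeat must be shorter than the start offset")
    repeat = "ACGTACGT"[:repeat_len]
    start = 12
    junction = start + repeat_len + (offset - repeat_len + 1) // 2
    spec = LocusSpec(
        repeat_unit=repeat,
        copy_starts=(start, start + offset),
        junction=junction,
        total_len=start + offset + repeat_len + 12,
    )
    return make_mmej_locus(spec, seed=seed), junction


@dataclass(frozen=True)
class OligoSpec:
    """Declared oligo layout plus optional engineered-feature contracts."""

    left_arm_len: int
    right_arm_len: int
    edit: Edit
    orientation: str = "S"
    engineered_3prime_palindrome: Optional[int] = None      # palindrome length at the 3' end
    engineered_upstream_mh: Optional[tuple[int, int, int]] = None  # (mh_len, ref_end, trim)


def make_oligo(locus: str, junction: int, spec: OligoSpec) -> Oligo:
    """Build an ssODN from the locus flanks and audit its declared features."""
    locus = as_seq(locus)
    junction = check_junction(junction, locus)
    lo = junction - spec.left_arm_len
    hi = junction + spec.edit.ref_span + spec.right_arm_len
    if lo < 0 or hi > len(locus):
        raise SequenceError("oligo arms do not fit within the locus")
    if spec.edit.kind == "substitution":
        ref = locus[junction : junction + spec.edit.ref_span]
        if ref == spec.edit.payload:
            raise AuditError("substitution payload equals the reference bases")
    gene_sense = (
        locus[lo:junction]
        + spec.edit.payload
        + locus[junction + spec.edit.ref_span : hi]
    )
    seq = gene_sense if spec.orientation == "S" else revcomp(gene_sense)
    oligo = Oligo(
        seq=seq,
        left_arm_len=spec.left_arm_len,
        right_arm_len=spec.right_arm_len,
        edit=spec.edit,
        orientation=spec.orientation,  # type: ignore[arg-type]
    )
    # audits: arm complementarity is by construction, engineered extras by string check
    if oligo.left_arm != locus[lo:junction] or oligo.right_arm != locus[
        junction + spec.edit.ref_span : hi
    ]:
        raise AuditError("arm audit failed")
    if spec.engineered_3prime_palindrome is not None:
        n = spec.engineered_3prime_palindrome
        tail = oligo.seq[-n:]
        if tail != revcomp(tail):
            raise AuditError(f"3'-terminal {n}-mer {tail} is not self-complementary")
    if spec.engineered_upstream_mh is not None:
        mh_len, ref_end, trim = spec.engineered_upstream_mh
        if oligo.seq[trim : trim + mh_len] != locus[ref_end - mh_len : ref_end]:
            raise AuditError("engineered upstream microhomology audit failed")
    return oligo


@dataclass(frozen=True)
class Fixture:
    """A packaged (locus, junction, guide?, oligo?) bundle."""

    name: str
    locus: str
    junction: int
    guide: Optional[Guide] = None
    oligo: Optional[Oligo] = None
    notes: str = ""
    locus_spec: Optional[LocusSpec] = field(default=None, compare=False)


_F1364_LOCUS = "TTGGAGCGTCGTAACACGTCGTTATTAT"
_F1344_LOCUS = "AAGCAACTGGTAACCATCTGGCTCCTC"
_F1228_LOCUS = "CCAACACAACCGAATGTTGGAATGGTTGGT"
_NOTI = "GCGGCCGC"
_F_NOTI_LOCUS = (
    "CACACACAACCCACAAACCACAAACAAACCACAACCCCACCAACCAAAAA"
    "TTGGGGGGGGGGGGGGTGGGTTTGTTGGTGTTGTTTGTTTGTTTTGTTTT"
)
_F_DIMER_LOCUS = (
    "GCGGCCGCACAAACAAAAAAGTTTCACAAAAACAACCCAAATTTGTGGGTGGGGGTTTTGGGGGAAACTGTGGTTGGGGG"
)

FIXTURE_NAMES = ("F1364", "F1344", "F1228", "F_DIMER", "F_NOTI")


def _mmej_fixture(name: str, locus: str, junction: int, spec: LocusSpec) -> Fixture:
    audit_mmej_locus(locus, spec)
    oligo = make_oligo(
        locus,
        junction,
        OligoSpec(
            left_arm_len=junction,
            right_arm_len=len(locus) - junction,
            edit=Edit(kind="insertion", payload=_NOTI),
            orientation="S",
        ),
    )
    return Fixture(
        name=name,
        locus=locus,
        junction=junction,
        oligo=oligo,
        notes="microhomology-attribution fixture; full-flank arms + NotI insert",
        locus_spec=spec,
    )


def fixtures(name: str) -> Fixture:
    """Return a packaged fixture by name; every contract is re-audited."""
    if name == "F1364":
        # 6-nt CGTCGT repeat at the cut site and 10 nt downstream
        return _mmej_fixture(
            name,
            _F1364_LOCUS,
            14,
            LocusSpec(repeat_unit="CGTCGT", copy_starts=(6, 16), junction=14, total_len=28),
        )
    if name == "F1344":
        # 4-nt CTGG repeats 6 bp upstream and 5 bp downstream of the cut
        return _mmej_fixture(
            name,
            _F1344_LOCUS,
            12,
            LocusSpec(repeat_unit="CTGG", copy_starts=(6, 17), junction=12, total_len=27),
        )
    if name == "F1228":
        # 5-nt GAATG repeat 1 bp upstream and 7 bp downstream of the cut
        return _mmej_fixture(
            name,
            _F1228_LOCUS,
            12,
            LocusSpec(repeat_unit="GAATG", copy_starts=(11, 19), junction=12, total_len=30),
        )
    if name == "F_NOTI":
        locus = _F_NOTI_LOCUS
        guide = Guide(cas="cas9", protospacer=locus[33:53], pam_start=53, strand="S")
        cut = cut_geometry(guide, locus)
        oligo = make_oligo(
            locus,
            cut.junction,
            OligoSpec(
                left_arm_len=36,
                right_arm_len=36,
                edit=Edit(kind="insertion", payload=_NOTI),
                orientation="S",
            ),
        )
        return Fixture(
            name=name,
            locus=locus,
            junction=cut.junction,
            guide=guide,
            oligo=oligo,
            notes="36+8+36 NotI-insertion design with an S-strand Cas9 guide",
        )
    if name == "F_DIMER":
        locus = _F_DIMER_LOCUS
        guide = Guide(
            cas="cas12a", protospacer=revcomp(locus)[17:40], pam_start=13, strand="NS"
        )
        cut = cut_geometry(guide, locus)
        if cut.junction != 40 or cut.overhang_len != 5:
            raise AuditError("F_DIMER cut-geometry contract violated")
        oligo = make_oligo(
            locus,
            cut.junction,
            OligoSpec(
                left_arm_len=40,
                right_arm_len=29,
                edit=Edit(kind="substitution", payload="C", ref_span=1),
                orientation="NS",
                engineered_3prime_palindrome=8,
                engineered_upstream_mh=(5, 25, 2),  # probe matches locus[20:25]
            ),
        )
        geom = best_productive_dimer(oligo)
        if geom is None or geom.overlap_len != 8:
            raise AuditError("F_DIMER productive-dimer contract violated")
        product = dimer_insertion_repair(locus, cut.junction, oligo, geom)
        if product is None or product.net_indel != 48:
            raise AuditError("F_DIMER +48 insertion contract violated")
        return Fixture(
            name=name,
            locus=locus,
            junction=cut.junction,
            guide=guide,
            oligo=oligo,
            notes=(
                "40+1+29 single-base-repair ssODN with an 8-nt 3'-terminal "
                "palindrome; dimer-mediated insertion reconstructs +48 bp"
            ),
        )
    raise SequenceError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def write_fixture(fix: Fixture, out_prefix: str | Path) -> list[Path]:
    """Write locus FASTA, oligo FASTA (if any), and a JSON manifest."""
    out_prefix = Path(out_prefix)
    written: list[Path] = []
    locus_path = out_prefix.with_name(out_prefix.name + "_locus.fa")
    write_fasta([(fix.name, fix.locus)], locus_path)
    written.append(locus_path)
    if fix.oligo is not None:
        oligo_path = out_prefix.with_name(out_prefix.name + "_oligo.fa")
        write_fasta([(fix.name + "_oligo", fix.oligo.seq)], oligo_path)
        written.append(oligo_path)
    manifest = {
        "name": fix.name,
        "junction": fix.junction,
        "locus_len": len(fix.locus),
        "notes": fix.notes,
        "guide": None
        if fix.guide is None
        else {
            "cas": fix.guide.cas,
            "pam_start": fix.guide.pam_start,
            "strand": fix.guide.strand,
            "protospacer": fix.guide.protospacer,
        },
        "oligo": None
        if fix.oligo is None
        else {
            "left_arm_len": fix.oligo.left_arm_len,
            "right_arm_len": fix.oligo.right_arm_len,
            "orientation": fix.oligo.orientation,
            "edit_kind": fix.oligo.edit.kind,
            "edit_payload": fix.oligo.edit.payload,
            "edit_ref_span": fix.oligo.edit.ref_span,
        },
    }
    manifest_path = out_prefix.with_name(out_prefix.name + "_manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    written.append(manifest_path)
    return written
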