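"""Cas9/Cas12a target recognition and cut-end geometry.

The model implements the canonical PAM rules — SpCas9 cleaves 3 nt 5' of an
NGG PAM leaving blunt ends; AsCas12a cleaves distal to a TTTN PAM in a
staggered fashion leaving 5-nt 5' overhangs regardless of guide orientation.
Guides may sit on either the gene-sense top strand (``S``) or its reverse
complement (``NS``); all cut coordinates are reported on the top strand.

The staggered Cas12a cut offsets (after protospacer positions 18 and 23) are
conventional enzymology and configurable; the invariant that matters to the
downstream repair model is the 5-nt 5' overhang.  Repair operations consume a
single top-strand junction: the position where the *top* strand backbone is
broken (midpoint convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

from .seqcore import SequenceError, as_seq, revcomp

__all__ = [
    "CAS9",
    "CAS12A",
    "PROTOSPACER_LEN",
    "Guide",
    "CutSite",
    "find_guide_sites",
    "cut_geometry",
]

CAS9 = "cas9"
CAS12A = "cas12a"

PROTOSPACER_LEN = {CAS9: 20, CAS12A: 23}
_PAM_LEN = {CAS9: 3, CAS12A: 4}
_PAM_RE = {CAS9: re.compile(r"(?=[ACGT]GG)"), CAS12A: re.compile(r"(?=TTT[ACGT])")}

Strand = Literal["S", "NS"]


@dataclass(frozen=True)
class Guide:
    """A positioned guide RNA.

    ``pam_start`` is the 0-based start of the PAM on the *declared* strand
    (``S``: identical to the gene top strand, ``NS``: its reverse complement).
    For Cas9 the protospacer lies immediately 5' of the PAM; for Cas12a
    immediately 3' of it.
    """

    cas: str
    protospacer: str
    pam_start: int
    strand: Strand

    def __post_init__(self) -> None:
        if self.cas not in PROTOSPACER_LEN:
            raise SequenceError(f"unknown Cas type {self.cas!r}")
        if self.strand not in ("S", "NS"):
            raise SequenceError(f"guide strand must be 'S' or 'NS', got {self.strand!r}")
        object.__setattr__(self, "protospacer", as_seq(self.protospacer))

    @property
    def protospacer_len(self) -> int:
        return PROTOSPACER_LEN[self.cas]


@dataclass(frozen=True)
class CutSite:
    """Double-strand break geometry in top-strand coordinates.

    ``top_junction``/``bottom_junction`` are the break positions of the top
    and bottom strand backbones.  ``junction`` (the coordinate consumed by
    repair operations) is the top-strand break.
    """

    top_junction: int
    bottom_junction: int
    overhang_kind: Literal["blunt", "five_prime"]

    @property
    def overhang_len(self) -> int:
        return abs(self.top_junction - self.bottom_junction)

    @property
    def junction(self) -> int:
        return self.top_junction


def _strand_view(locus: str, strand: Strand) -> str:
    return locus if strand == "S" else revcomp(locus)


def find_guide_sites(locus: str, cas: str) -> list[Guide]:
    """Exhaustively enumerate valid guide placements on both strands.

    Returns every position where the PAM rule is satisfied and a full-length
    protospacer fits on the locus; S-strand guides first (ascending
    ``pam_start``), then NS.
    """
    locus = as_seq(locus)
    if cas not in PROTOSPACER_LEN:
        raise SequenceError(f"unknown Cas type {cas!r}")
    spacer_len = PROTOSPACER_LEN[cas]
    pam_len = _PAM_LEN[cas]
    guides: list[Guide] = []
    for strand in ("S", "NS"):
        s = _strand_view(locus, strand)
        for m in _PAM_RE[cas].finditer(s):
            p = m.start()
            if cas == CAS9:
                if p < spacer_len:
                    continue
                proto = s[p - spacer_len : p]
            else:
                if p + pam_len + spacer_len > len(s):
                    continue
                proto = s[p + pam_len : p + pam_len + spacer_len]
            guides.append(Guide(cas=cas, protospacer=proto, pam_start=p, strand=strand))
    return guides


def _validate_placement(guide: Guide, s: str) -> None:
    p = guide.pam_start
    pam_len = _PAM_LEN[guide.cas]
    if guide.cas == CAS9:
        lo, hi = p - guide.protospacer_len, p + pam_len
        pam_ok = 0 <= p and p + pam_len <= len(s) and s[p + 1 : p + 3] == "GG"
        proto = s[p - guide.protospacer_len : p] if p >= guide.protospacer_len else ""
    else:
        lo, hi = p, p + pam_len + guide.protospacer_len
        pam_ok = 0 <= p and p + pam_len <= len(s) and s[p : p + 3] == "TTT"
        proto = s[p + pam_len : p + pam_len + guide.protospacer_len]
    if lo < 0 or hi > len(s):
        raise SequenceError("guide overhangs locus boundary")
    if not pam_ok:
        raise SequenceError(f"PAM rule violated at pam_start={p} on strand {guide.strand}")
    if proto != guide.protospacer:
        raise SequenceError("declared protospacer does not match the locus")


def cut_geometry(
    guide: Guide,
    locus: str,
    *,
    cas12a_cut_top: int = 18,
    cas12a_cut_bottom: int = 23,
) -> CutSite:
    """Compute break positions, reported in top-strand coordinates.

    Cas9: blunt cut 3 nt 5' of the PAM (between protospacer positions 17|18).
    Cas12a: protospacer-strand cut after position ``cas12a_cut_top``,
    opposite-strand cut after ``cas12a_cut_bottom`` (PAM-distal), giving a
    ``cut_bottom - cut_top`` nt 5' overhang (5 by default) for either guide
    orientation.
    """
    locus = as_seq(locus)
    s = _strand_view(locus, guide.strand)
    _validate_placement(guide, s)
    p = guide.pam_start
    if guide.cas == CAS9:
        j_decl = j_opp_decl = p - 3
        kind: Literal["blunt", "five_prime"] = "blunt"
    else:
        j_decl = p + _PAM_LEN[CAS12A] + cas12a_cut_top
        j_opp_decl = p + _PAM_LEN[CAS12A] + cas12a_cut_bottom
        kind = "five_prime"
    if guide.strand == "S":
        top_j, bottom_j = j_decl, j_opp_decl
    else:
        # Declared strand is the gene bottom strand: the gene top strand is
        # cut where the declared *opposite* strand is cut, mirrored.
        top_j, bottom_j = len(locus) - j_opp_decl, len(locus) - j_decl
    for j in (top_j, bottom_j):
        if not 0 < j < len(locus):
            raise SequenceError("cut position falls outside the locus interior")
    return CutSite(top_junction=top_j, bottom_junction=bottom_j, overhang_kind=kind)
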