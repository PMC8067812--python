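"""ssODN self-dimer detection, thermodynamic scoring, and dimer-mediated
insertion reconstruction.

Two copies of the same ssODN can anneal antiparallel through self-
complementary stretches.  A dimer whose 3'-terminal overlap region is fully
paired presents recessed (or blunt) 3' ends and protruding 5' tails — such a
"productive" dimer can engage the free DNA ends of a staggered Cas cut and
template an atypical insertion in which one full oligo copy is incorporated
in-line, against its normal templating orientation.  Dimers pairing only
internal stretches leave unpaired 3' termini (3' overhangs) and cannot
associate with the cut ends; they are detected and rejected.

Duplex stability is scored with SantaLucia (1998) unified nearest-neighbor
free-energy increments at 37 degC plus terminal initiation terms; dangling
ends, salt and symmetry corrections are deliberately omitted (only ranking
and a coarse activation threshold matter to the model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Union

from .hdr import Oligo
from .products import RepairProduct
from .seqcore import SequenceError, as_seq, check_junction, complement_base

__all__ = [
    "NN_DG37",
    "NN_INIT_GC",
    "NN_INIT_AT",
    "DimerGeometry",
    "nn_delta_g",
    "scan_self_dimers",
    "filter_productive_dimers",
    "best_productive_dimer",
    "dimer_insertion_repair",
]

# SantaLucia 1998 unified nearest-neighbor delta-G(37) increments, kcal/mol,
# keyed by the top-strand dinucleotide of a Watson-Crick duplex step.
NN_DG37 = {
    "AA": -1.00, "TT": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45, "TG": -1.45,
    "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28,
    "GA": -1.30, "TC": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84, "CC": -1.84,
}
NN_INIT_GC = 0.98  # initiation with a terminal G.C pair
NN_INIT_AT = 1.03  # initiation with a terminal A.T pair


def nn_delta_g(duplex_top: str) -> float:
    """Delta-G(37) of a fully paired duplex given its top strand, kcal/mol.

    Sum of nearest-neighbor increments over all dinucleotide steps plus one
    initiation term per duplex end.
    """
    s = as_seq(duplex_top)
    if len(s) < 2:
        raise SequenceError("duplex must be at least 2 bp for nearest-neighbor scoring")
    dg = sum(NN_DG37[s[i : i + 2]] for i in range(len(s) - 1))
    for terminal in (s[0], s[-1]):
        dg += NN_INIT_GC if terminal in "GC" else NN_INIT_AT
    return round(dg, 10)


@dataclass(frozen=True)
class DimerGeometry:
    """One antiparallel self-alignment of two oligo copies.

    The alignment is parameterized so that position ``i`` of copy 1 pairs
    with position ``c - i`` of copy 2 (``c = alignment_offset + n - 1``).
    ``overlap_len`` is the length of the contiguous complementary run;
    ``span`` is its copy-1 interval.  ``three_prime_recessed``/``blunt``
    geometries have both 3' termini paired (the run covers the whole
    3'-terminal overlap region); anything else leaves a 3' overhang.
    """

    overlap_len: int
    end_state: Literal["three_prime_recessed", "blunt", "three_prime_overhang"]
    delta_g: float
    alignment_offset: int
    span: tuple[int, int]

    @property
    def productive(self) -> bool:
        return self.end_state != "three_prime_overhang"


def _runs(mask: list[bool]) -> list[tuple[int, int]]:
    runs, start = [], None
    for idx, flag in enumerate(mask):
        if flag and start is None:
            start = idx
        elif not flag and start is not None:
            runs.append((start, idx))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def scan_self_dimers(
    oligo: Union[Oligo, str],
    min_overlap: int = 4,
) -> list[DimerGeometry]:
    """Enumerate self-dimer geometries of an oligo (as-written 5'->3').

    Exhaustive over all antiparallel self-alignments: every contiguous
    complementary run of ``>= min_overlap`` bases is reported once.  Runs
    that pair the complete 3'-terminal overlap region of the alignment are
    classified ``three_prime_recessed`` (``blunt`` for the full-length
    alignment); all other runs leave unpaired 3' termini and are
    ``three_prime_overhang``.  Sorted by delta-G ascending, then larger
    overlap, then smaller |alignment_offset|.
    """
    s = oligo.seq if isinstance(oligo, Oligo) else as_seq(oligo)
    n = len(s)
    if min_overlap < 2:
        raise SequenceError("min_overlap must be >= 2")
    if n < min_overlap:
        raise SequenceError("oligo shorter than min_overlap")
    comp = [complement_base(b) for b in s]
    geoms: list[DimerGeometry] = []
    for c in range(min_overlap - 1, 2 * n - 1):
        i_lo, i_hi = max(0, c - n + 1), min(n - 1, c)
        mask = [s[i] == comp[c - i] for i in range(i_lo, i_hi + 1)]
        region_len = i_hi - i_lo + 1
        for r0, r1 in _runs(mask):
            length = r1 - r0
            if length < min_overlap:
                continue
            i0, i1 = i_lo + r0, i_lo + r1 - 1
            # symmetric twin run within the same alignment: report one copy
            if i0 > c - i1:
                continue
            full_overlap = c >= n - 1 and length == region_len
            if full_overlap:
                state: Literal[
                    "three_prime_recessed", "blunt", "three_prime_overhang"
                ] = "blunt" if c == n - 1 else "three_prime_recessed"
            else:
                state = "three_prime_overhang"
            geoms.append(
                DimerGeometry(
                    overlap_len=length,
                    end_state=state,
                    delta_g=nn_delta_g(s[i0 : i1 + 1]),
                    alignment_offset=c - (n - 1),
                    span=(i0, i1 + 1),
                )
            )
    geoms.sort(key=lambda g: (g.delta_g, -g.overlap_len, abs(g.alignment_offset)))
    return geoms


def filter_productive_dimers(
    geoms: list[DimerGeometry],
    dg_threshold: float = -9.0,
) -> list[DimerGeometry]:
    """Keep geometries able to engage free DNA ends.

    Removes every 3'-overhang geometry and every geometry whose delta-G lies
    above the activation threshold (too weak to persist at 37 degC).
    """
    return [g for g in geoms if g.productive and g.delta_g <= dg_threshold]


def best_productive_dimer(
    oligo: Union[Oligo, str],
    min_overlap: int = 4,
    dg_threshold: float = -9.0,
) -> Optional[DimerGeometry]:
    """Lowest-delta-G productive geometry, or None."""
    kept = filter_productive_dimers(scan_self_dimers(oligo, min_overlap), dg_threshold)
    return kept[0] if kept else None


def dimer_insertion_repair(
    locus: str,
    junction: int,
    oligo: Oligo,
    geometry: Optional[DimerGeometry] = None,
    *,
    trim: int = 2,
    min_mh: int = 5,
    fill: str = "",
) -> Optional[RepairProduct]:
    """Reconstruct the dimer-mediated in-line oligo insertion.

    A productive dimer bridges the staggered cut and one oligo copy is
    ligated into the top strand as written (opposite to its normal
    templating orientation).  The copy's 5' end is flap-trimmed by ``trim``
    unmatched bases; the next ``min_mh`` bases must find an exact match in
    the upstream flank (the rightmost occurrence is used, minimizing
    resection).  For a match ending at reference coordinate ``m`` the
    upstream bases ``[m, junction)`` are resected and the product top strand
    is ``locus[:m] + copy[trim + min_mh:] + fill + locus[junction:]`` — the
    microhomology is counted once, supplied by the reference side.  Net
    length change = ``(L - trim - min_mh) + len(fill) - (junction - m)``.
    """
    locus = as_seq(locus)
    junction = check_junction(junction, locus)
    fill = as_seq(fill, allow_empty=True)
    if geometry is not None and not geometry.productive:
        raise SequenceError("a 3'-overhang dimer cannot associate with the cut ends")
    copy = oligo.seq
    if trim < 0 or trim + min_mh > len(copy):
        raise SequenceError("trim/microhomology exceed the oligo length")
    probe = copy[trim : trim + min_mh]
    m_start = locus.rfind(probe, 0, junction)
    if m_start < 0:
        return None
    m = m_start + min_mh
    seq = locus[:m] + copy[trim + min_mh :] + fill + locus[junction:]
    net = (len(copy) - trim - min_mh) + len(fill) - (junction - m)
    return RepairProduct(
        seq=seq,
        pathway="dimer-ExACT",
        net_indel=net,
        detail={
            "trim": trim,
            "mh_interval": (m_start, m),
            "resected_interval": (m, junction),
            "incorporated": copy[trim:],
            "geometry": geometry,
        },
    )
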