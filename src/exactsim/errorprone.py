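"""Error-prone repair: MMEJ deletion enumeration and NHEJ indel sampling.

MMEJ (microhomology-mediated end joining) resolves a double-strand break by
annealing short exact repeats that flank the cut; the sequence between the two
repeat copies is lost, so the deletion length equals the repeat-start offset.
``enumerate_mmej`` finds every such flanking-repeat alignment near the
junction deterministically.

NHEJ produces small, diverse indels with no strong sequence preference; it is
modeled as a seeded sampler over a truncated geometric size distribution with
a 3:1 deletion:insertion ratio, giving the characteristic plurality of minor
products rather than a few dominant ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .products import RepairProduct
from .seqcore import SequenceError, as_seq, check_junction

__all__ = [
    "MicrohomologyPair",
    "NhejEvent",
    "enumerate_mmej",
    "apply_mmej",
    "mmej_weight",
    "sample_nhej",
    "apply_nhej",
]


@dataclass(frozen=True)
class MicrohomologyPair:
    """One flanking-repeat alignment.

    The repeat occurs at ``u_start`` (left copy) and ``v_start`` (right copy)
    with ``mh_len`` exactly matching bases; annealing the two copies deletes
    the interval ``[u_start, v_start)``, i.e. ``del_len = v_start - u_start``
    bases.  The two occurrences may overlap (tandem repeats).
    """

    u_start: int
    v_start: int
    mh_len: int

    @property
    def del_len(self) -> int:
        return self.v_start - self.u_start

    @property
    def del_interval(self) -> tuple[int, int]:
        return (self.u_start, self.v_start)


@dataclass(frozen=True)
class NhejEvent:
    kind: Literal["deletion", "insertion"]
    size: int
    position: int  # junction
    inserted: str = ""
    left: int = 0  # for deletions: bases removed 5' of the junction

    def __post_init__(self) -> None:
        if self.size < 1:
            raise SequenceError("NHEJ event size must be >= 1")
        if self.kind == "insertion" and len(self.inserted) != self.size:
            raise SequenceError("inserted sequence length must equal event size")


def enumerate_mmej(
    locus: str,
    junction: int,
    min_mh: int = 3,
    max_del: int = 30,
    window: int = 30,
) -> list[MicrohomologyPair]:
    """Enumerate MMEJ deletion alignments spanning the cut.

    Exhaustive over maximal exact-match repeat pairs with ``mh_len >=
    min_mh`` whose implied deletion spans the junction (``u_start <=
    junction - 1``, ``v_start >= junction``) and has length ``<= max_del``;
    both repeat occurrences must start within ``window`` nt of the junction.
    Pairs whose deletion yields an identical product sequence are merged,
    keeping the representative with the largest ``mh_len`` (then smallest
    ``u_start``).  Sorted by ``mh_len`` desc, ``del_len`` asc, ``u_start``
    asc.
    """
    locus = as_seq(locus)
    junction = check_junction(junction, locus)
    if min_mh < 2:
        raise SequenceError("min_mh below 2 is rejected: matches that short are not microhomology")
    n = len(locus)
    lo = max(0, junction - window)
    hi = min(n, junction + window)
    best: dict[str, MicrohomologyPair] = {}
    for u in range(lo, junction):
        for v in range(junction, hi):
            if v - u > max_del:
                break
            # forward-maximal exact match starting at (u, v)
            m = 0
            while u + m < n and v + m < n and locus[u + m] == locus[v + m]:
                m += 1
            if m < min_mh:
                continue
            pair = MicrohomologyPair(u_start=u, v_start=v, mh_len=m)
            product = locus[:u] + locus[v:]
            prev = best.get(product)
            if prev is None or (pair.mh_len, -pair.u_start) > (prev.mh_len, -prev.u_start):
                best[product] = pair
    return sorted(best.values(), key=lambda p: (-p.mh_len, p.del_len, p.u_start))


def apply_mmej(locus: str, pair: MicrohomologyPair) -> RepairProduct:
    """Delete ``[u_start, v_start)`` and label the product MMEJ."""
    locus = as_seq(locus)
    u, v = pair.del_interval
    if not (0 <= u < v <= len(locus)):
        raise SequenceError(f"pair interval [{u}, {v}) invalid for locus of length {len(locus)}")
    if locus[u : u + pair.mh_len] != locus[v : v + pair.mh_len]:
        raise SequenceError("pair microhomology does not match the locus")
    product = locus[:u] + locus[v:]
    return RepairProduct(
        seq=product,
        pathway="MMEJ",
        net_indel=-pair.del_len,
        detail={"mh_len": pair.mh_len, "del_interval": pair.del_interval},
    )


def mmej_weight(pair: MicrohomologyPair, l_decay: float = 20.0) -> float:
    """Heuristic MMEJ propensity: ``mh_len * exp(-del_len / l_decay)``.

    Monotone increasing in microhomology length (longer repeats stabilize
    the annealed intermediate more) and decreasing in deletion length
    (longer resection is required).  Only order relations are meaningful.
    """
    if pair.mh_len <= 0:
        return 0.0
    return pair.mh_len * math.exp(-pair.del_len / l_decay)


def sample_nhej(
    junction: int,
    n: int,
    seed: int,
    *,
    p_geom: float = 0.5,
    max_size: int = 30,
    deletion_fraction: float = 0.75,
) -> list[NhejEvent]:
    """Draw ``n`` NHEJ indel events (seeded, bit-reproducible).

    Sizes follow a geometric distribution (success probability ``p_geom``)
    truncated to ``[1, max_size]``; deletions and insertions occur 3:1 by
    default; inserted bases are uniform over ACGT; a deletion of size ``s``
    removes ``left`` bases 5' of the junction and ``s - left`` 3' of it with
    ``left`` uniform on ``[0, s]``.
    """
    if n < 0:
        raise SequenceError("number of NHEJ events must be nonnegative")
    if seed is None:
        raise SequenceError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    events: list[NhejEvent] = []
    for _ in range(n):
        size = int(rng.geometric(p_geom))
        while size > max_size:
            size = int(rng.geometric(p_geom))
        if rng.random() < deletion_fraction:
            left = int(rng.integers(0, size + 1))
            events.append(NhejEvent(kind="deletion", size=size, position=junction, left=left))
        else:
            bases = "".join(rng.choice(list("ACGT"), size=size))
            events.append(
                NhejEvent(kind="insertion", size=size, position=junction, inserted=bases)
            )
    return events


def apply_nhej(locus: str, event: NhejEvent) -> RepairProduct:
    """Materialize an NHEJ event into a product sequence."""
    locus = as_seq(locus)
    j = check_junction(event.position, locus)
    if event.kind == "insertion":
        seq = locus[:j] + event.inserted + locus[j:]
        net = event.size
        detail = {"inserted": event.inserted}
    else:
        u = max(0, j - event.left)
        v = min(len(locus), j + (event.size - event.left))
        seq = locus[:u] + locus[v:]
        net = -(v - u)
        detail = {"del_interval": (u, v)}
    return RepairProduct(seq=seq, pathway="NHEJ", net_indel=net, detail=detail)
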