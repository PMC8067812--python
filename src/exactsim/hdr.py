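"""ssODN-templated precise repair: one-step gap bridging and two-step SDSA.

An ssODN (single-stranded oligodeoxynucleotide) repair template carries two
homology arms flanking a central programmed edit.  Two routes yield the same
perfect product:

* one-step gap bridging (ExACT): the oligo anneals across the break to the
  perfect-match flanks on one strand and the gap is filled and ligated; the
  template itself is never incorporated;
* two-step SDSA-style repair (SDSA-ExACT): one broken 3' end is first
  extended using the oligo as template, dissociates, and then bridges the
  break by annealing to the other end.

The two-step route additionally admits a characteristic side product: if the
cut-proximal 3' terminus misprimes at a second occurrence of its terminal
bases inside the upstream homology arm, the bases between that alternative
anneal site and the cut are copied twice, producing a tandem duplication
alongside the programmed edit.

Homology arms must match the reference flanks exactly (tolerance 0): an
annealing model for mismatched arms is deliberately out of scope, and a
failed arm match returns no product, signalling fallback to the error-prone
pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .products import RepairProduct
from .seqcore import SequenceError, as_seq, check_junction, revcomp

__all__ = [
    "Edit",
    "Oligo",
    "exact_bridge_repair",
    "sdsa_two_step_repair",
    "strand_bias_weight",
]


@dataclass(frozen=True)
class Edit:
    """The programmed change between the two homology arms.

    ``payload`` replaces ``ref_span`` reference bases starting at the cut
    junction: substitutions have ``len(payload) == ref_span``, insertions
    ``ref_span == 0``, deletions an empty payload.
    """

    kind: Literal["substitution", "insertion", "deletion"]
    payload: str = ""
    ref_span: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "payload", as_seq(self.payload, allow_empty=True))
        if self.kind == "insertion" and (self.ref_span != 0 or not self.payload):
            raise SequenceError("insertion edit needs ref_span 0 and a nonempty payload")
        if self.kind == "deletion" and (self.ref_span < 1 or self.payload):
            raise SequenceError("deletion edit needs ref_span >= 1 and empty payload")
        if self.kind == "substitution" and (
            self.ref_span < 1 or len(self.payload) != self.ref_span
        ):
            raise SequenceError("substitution edit needs len(payload) == ref_span >= 1")

    @property
    def net(self) -> int:
        return len(self.payload) - self.ref_span


@dataclass(frozen=True)
class Oligo:
    """An ssODN given 5'->3' with its declared layout.

    ``left_arm_len``/``right_arm_len`` are the upstream/downstream homology
    arm lengths *in gene (top-strand) orientation*; ``orientation`` states
    whether ``seq`` as written equals the gene-sense layout (``S``) or its
    reverse complement (``NS``).  The gene-sense layout is always
    ``left_arm + edit.payload + right_arm``.
    """

    seq: str
    left_arm_len: int
    right_arm_len: int
    edit: Edit
    orientation: Literal["S", "NS"] = "S"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", as_seq(self.seq))
        expect = self.left_arm_len + self.right_arm_len + len(self.edit.payload)
        if len(self.seq) != expect:
            raise SequenceError(
                f"oligo length {len(self.seq)} != left_arm + payload + right_arm = {expect}"
            )
        if self.left_arm_len < 1 or self.right_arm_len < 1:
            raise SequenceError("both homology arms must be nonempty")
        if self.orientation not in ("S", "NS"):
            raise SequenceError("oligo orientation must be 'S' or 'NS'")

    @property
    def gene_sense(self) -> str:
        """The oligo sequence read in top-strand orientation."""
        return self.seq if self.orientation == "S" else revcomp(self.seq)

    @property
    def left_arm(self) -> str:
        return self.gene_sense[: self.left_arm_len]

    @property
    def right_arm(self) -> str:
        return self.gene_sense[self.left_arm_len + len(self.edit.payload) :]

    def flipped(self) -> "Oligo":
        """The same physical design delivered on the opposite strand."""
        return Oligo(
            seq=revcomp(self.seq),
            left_arm_len=self.left_arm_len,
            right_arm_len=self.right_arm_len,
            edit=self.edit,
            orientation="NS" if self.orientation == "S" else "S",
        )


def _arms_match(locus: str, junction: int, oligo: Oligo) -> bool:
    left_ref = locus[junction - oligo.left_arm_len : junction]
    right_start = junction + oligo.edit.ref_span
    right_ref = locus[right_start : right_start + oligo.right_arm_len]
    if junction - oligo.left_arm_len < 0 or right_start + oligo.right_arm_len > len(locus):
        raise SequenceError("oligo arms extend beyond the locus")
    return left_ref == oligo.left_arm and right_ref == oligo.right_arm


def exact_bridge_repair(locus: str, junction: int, oligo: Oligo) -> Optional[RepairProduct]:
    """One-step gap-bridging repair (perfect product or no product).

    Both arms must match the reference flanks exactly; on success the
    product is the reference with the programmed edit swapped in at the
    junction.  The template is purely instructive — no arm sequence is ever
    incorporated as an extra copy.
    """
    locus = as_seq(locus)
    junction = check_junction(junction, locus)
    if not _arms_match(locus, junction, oligo):
        return None
    edit = oligo.edit
    seq = locus[:junction] + edit.payload + locus[junction + edit.ref_span :]
    return RepairProduct(
        seq=seq,
        pathway="ExACT",
        net_indel=edit.net,
        detail={"edit": edit.kind, "payload": edit.payload, "ref_span": edit.ref_span},
    )


def sdsa_two_step_repair(
    locus: str,
    junction: int,
    oligo: Oligo,
    *,
    min_anneal: int = 5,
) -> list[RepairProduct]:
    """Two-step SDSA-style repair: perfect product plus duplication products.

    The perfect product equals the one-step bridging output.  Duplications
    arise when the upstream flank's 3'-terminal ``min_anneal`` bases occur a
    second time within the oligo's upstream arm: mispriming there makes the
    template walk re-copy the bases between the alternative anneal site and
    the cut.  For an alternative match ending at reference coordinate ``m``
    (< junction) the product is
    ``locus[:junction] + locus[m:junction] + payload + downstream``, i.e. a
    tandem duplication of ``locus[m:junction]`` flanking the edit.
    """
    locus = as_seq(locus)
    junction = check_junction(junction, locus)
    perfect = exact_bridge_repair(locus, junction, oligo)
    if perfect is None:
        return []
    products = [
        RepairProduct(
            seq=perfect.seq,
            pathway="SDSA-ExACT",
            net_indel=perfect.net_indel,
            detail=dict(perfect.detail),
        )
    ]
    edit = oligo.edit
    k = int(min_anneal)
    if k < 1:
        raise SequenceError("min_anneal must be >= 1")
    terminal = locus[junction - k : junction]
    arm_start = junction - oligo.left_arm_len
    if len(terminal) == k:
        # alternative anneal sites: matches of the terminal k-mer inside the
        # upstream arm, ending strictly before the junction
        for m in range(arm_start + k, junction):
            if locus[m - k : m] == terminal:
                dup = locus[m:junction]
                seq = locus[:junction] + dup + edit.payload + locus[junction + edit.ref_span :]
                products.append(
                    RepairProduct(
                        seq=seq,
                        pathway="SDSA-ExACT",
                        net_indel=edit.net + len(dup),
                        detail={
                            "edit": edit.kind,
                            "payload": edit.payload,
                            "ref_span": edit.ref_span,
                            "duplication_span": (m, junction),
                            "duplicated": dup,
                            "anneal_site": (m - k, m),
                        },
                    )
                )
    return products


def strand_bias_weight(
    guide_strand: str,
    oligo: Oligo,
    *,
    bias_ratio: float = 2.0,
) -> float:
    """HDR weight multiplier for guide/oligo polarity matching.

    Empirically, the ssODN whose polarity matches the gRNA strand shows the
    higher HDR efficiency; the bias is keyed to the *guide* orientation, not
    the gene orientation, and is modeled as a single multiplicative factor
    (``bias_ratio`` when matched, 1.0 otherwise) because no molecular
    mechanism is established.
    """
    if guide_strand not in ("S", "NS"):
        raise SequenceError("guide strand must be 'S' or 'NS'")
    if bias_ratio < 1.0:
        raise SequenceError("bias_ratio below 1 would invert the observed bias")
    return float(bias_ratio) if oligo.orientation == guide_strand else 1.0
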