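"""Shared repair-product container used by every pathway module."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

__all__ = ["PATHWAYS", "RepairProduct"]

PATHWAYS = ("NHEJ", "MMEJ", "ExACT", "SDSA-ExACT", "dimer-ExACT", "hybrid")


@dataclass
class RepairProduct:
    """One reconstructed repair outcome.

    ``net_indel`` is the signed length change relative to the reference locus
    (``len(seq) - len(reference)``); ``detail`` carries pathway-specific
    bookkeeping (microhomology length, deleted interval, inserted segment,
    duplication span, ...).  ``weight`` is the unnormalized pathway weight
    assigned by the spectrum combiner.
    """

    seq: str
    pathway: str
    net_indel: int
    detail: dict[str, Any] = field(default_factory=dict)
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ValueError(f"unknown pathway label {self.pathway!r}")
        if self.weight < 0:
            raise ValueError("product weight must be nonnegative")

    def check_against(self, reference: str) -> None:
        """Assert the net-indel bookkeeping against a reference sequence."""
        if self.net_indel != len(self.seq) - len(reference):
            raise ValueError(
                f"net_indel {self.net_indel} inconsistent with product/reference "
                f"lengths {len(self.seq)}/{len(reference)}"
            )
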