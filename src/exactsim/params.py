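"""Tunable model parameters, loadable from a flat YAML config.

Only order relations among pathway weights are empirically constrained (the
underlying experiments measure wet-lab product fractions that no sequence
model can recompute); the defaults here encode those order relations:

* ``nhej_total_weight`` is calibrated against the MMEJ propensity
  ``mh_len * exp(-del_len / l_decay)`` so that, for a single flanking repeat
  10 nt apart, a 4-bp repeat is the smallest that lets MMEJ match NHEJ —
  the observed dominance threshold.
* ``bias_ratio`` (matched guide/oligo polarity) and ``suppression`` (the
  damping of error-prone repair when a template is present) encode observed
  directions, not magnitudes.
* ``hybrid_rate`` keeps precise+error-prone hybrid molecules at or below the
  observed < 1:1000 ceiling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["SimParams"]


@dataclass
class SimParams:
    # MMEJ enumeration / weighting
    min_mh: int = 3            # nt; shortest repeat treated as microhomology
    max_del: int = 30          # nt; largest MMEJ deletion enumerated
    window: int = 30           # nt; search window either side of the cut
    l_decay: float = 20.0      # nt; deletion-length decay scale of MMEJ weight
    # NHEJ sampling
    nhej_total_weight: float = 2.0   # aggregate NHEJ weight (calibrated, see module docstring)
    nhej_events: int = 12            # sampled indel events instantiated per run
    nhej_p: float = 0.5              # geometric size distribution parameter
    nhej_max_size: int = 30          # nt; indel size truncation
    nhej_deletion_fraction: float = 0.75  # deletion:insertion = 3:1
    # ssODN-templated repair
    hdr_base_weight: float = 5.0     # weight of the precise product before bias
    pathway_split: float = 0.5       # one-step bridging vs two-step SDSA share
    sdsa_duplication_rate: float = 0.1   # share of the SDSA branch diverted to duplications
    sdsa_min_anneal: int = 5         # nt; re-anneal minimum match
    bias_ratio: float = 2.0          # matched-polarity HDR multiplier
    suppression: float = 0.5         # error-prone damping when an oligo is present
    hybrid_rate: float = 5e-4        # normalized frequency of hybrid molecules
    # ssODN self-dimer pathway
    dimer_min_overlap: int = 4       # nt; shortest reported self-complementary run
    dimer_dg_threshold: float = -9.0  # kcal/mol; activation threshold
    dimer_base_weight: float = 1.0   # weight of the dimer insertion product when gated on
    dimer_trim: int = 2              # nt; 5' flap trim of the incorporated copy
    dimer_min_mh: int = 5            # nt; upstream microhomology requirement
    # cleavage geometry
    cas12a_cut_top: int = 18         # protospacer-strand cut offset
    cas12a_cut_bottom: int = 23      # opposite-strand cut offset (5-nt 5' overhang)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimParams":
        """Load parameters from a flat YAML mapping; unknown keys are errors."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown parameters in config: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
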