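"""Consensus-model orchestration: combine all repair pathways into a
weighted, classified product spectrum.

All pathway weights are combined analytically (no Monte-Carlo over pathway
choice), so a spectrum is reproducible by construction; the seed only
instantiates the concrete NHEJ indel events that share the fixed aggregate
NHEJ weight.  With a repair template present, precise products enter with a
polarity-bias-adjusted weight, error-prone totals are damped by the
suppression factor, a productive self-dimer (if any) switches on the
dimer-insertion product, and rare precise+error-prone hybrid molecules are
pinned at a configurable normalized frequency.

Products are reported as sequence classes: identical product sequences from
the same pathway are merged and their weights summed, mirroring how repair
outcomes are tabulated from sequencing reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .cleavage import Guide, cut_geometry
from .dimer import best_productive_dimer, dimer_insertion_repair
from .errorprone import apply_mmej, apply_nhej, enumerate_mmej, mmej_weight, sample_nhej
from .hdr import Oligo, exact_bridge_repair, sdsa_two_step_repair, strand_bias_weight
from .params import SimParams
from .products import RepairProduct
from .seqcore import SequenceError, as_seq, check_junction

__all__ = [
    "Spectrum",
    "simulate_spectrum",
    "classify_product",
    "write_spectrum",
    "read_spectrum",
    "compare_spectra",
]

CLASSES = ("precise", "error_prone", "hybrid", "dimer_insertion")


def classify_product(p: RepairProduct) -> str:
    """Map a pathway-labeled product onto the reporting classes.

    Perfect template-driven products are ``precise``; NHEJ/MMEJ are
    ``error_prone``; the dimer-mediated insertion is its own class; anything
    mixing precise and unprogrammed change on one molecule (explicit hybrid
    products, SDSA duplications carrying the edit plus extra sequence) is
    ``hybrid``.
    """
    if p.pathway in ("NHEJ", "MMEJ"):
        return "error_prone"
    if p.pathway == "dimer-ExACT":
        return "dimer_insertion"
    if p.pathway == "hybrid":
        return "hybrid"
    if p.pathway == "SDSA-ExACT" and "duplication_span" in p.detail:
        return "hybrid"
    return "precise"


@dataclass
class Spectrum:
    """A normalized collection of repair products for one locus/guide."""

    reference: str
    junction: int
    products: list[RepairProduct]

    @property
    def frequencies(self) -> list[float]:
        total = sum(p.weight for p in self.products)
        if total <= 0:
            return [0.0 for _ in self.products]
        return [p.weight / total for p in self.products]

    def normalized(self) -> "Spectrum":
        freqs = self.frequencies
        prods = [
            RepairProduct(p.seq, p.pathway, p.net_indel, dict(p.detail), f)
            for p, f in zip(self.products, freqs)
        ]
        prods.sort(key=lambda p: (-p.weight, p.pathway, p.seq))
        return Spectrum(self.reference, self.junction, prods)

    def class_frequencies(self) -> dict[str, float]:
        out = {c: 0.0 for c in CLASSES}
        for p, f in zip(self.products, self.frequencies):
            out[classify_product(p)] += f
        return out

    def pathway_frequencies(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for p, f in zip(self.products, self.frequencies):
            out[p.pathway] = out.get(p.pathway, 0.0) + f
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (p, f) in enumerate(zip(self.products, self.frequencies)):
            rows.append(
                {
                    "product_id": f"p{i:03d}",
                    "pathway": p.pathway,
                    "class": classify_product(p),
                    "net_indel": p.net_indel,
                    "mh_len": p.detail.get("mh_len", ""),
                    "frequency": f,
                    "sequence": p.seq,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "product_id", "pathway", "class", "net_indel",
                "mh_len", "frequency", "sequence",
            ],
        )


def _merge_classes(products: list[RepairProduct]) -> list[RepairProduct]:
    merged: dict[tuple[str, str], RepairProduct] = {}
    for p in products:
        key = (p.pathway, p.seq)
        if key in merged:
            merged[key].weight += p.weight
        else:
            merged[key] = RepairProduct(p.seq, p.pathway, p.net_indel, dict(p.detail), p.weight)
    return list(merged.values())


def simulate_spectrum(
    locus: str,
    guide: Optional[Guide] = None,
    oligo: Optional[Oligo] = None,
    params: Optional[SimParams] = None,
    seed: int = 0,
    *,
    junction: Optional[int] = None,
    guide_strand: Optional[str] = None,
) -> Spectrum:
    """Predict the weighted repair-product spectrum for one break.

    The break is specified either by a positioned ``guide`` (the cut
    geometry model supplies the top-strand junction) or by an explicit
    ``junction``.  ``guide_strand`` feeds the HDR polarity bias when no
    guide object is given; without it the bias is neutral.
    """
    locus = as_seq(locus)
    params = params or SimParams()
    if junction is None:
        if guide is None:
            raise SequenceError("either a guide or an explicit junction is required")
        cut = cut_geometry(
            guide,
            locus,
            cas12a_cut_top=params.cas12a_cut_top,
            cas12a_cut_bottom=params.cas12a_cut_bottom,
        )
        junction = cut.junction
    junction = check_junction(junction, locus)
    if guide is not None:
        guide_strand = guide.strand

    products: list[RepairProduct] = []

    # error-prone pathways
    ep_scale = params.suppression if oligo is not None else 1.0
    for pair in enumerate_mmej(locus, junction, params.min_mh, params.max_del, params.window):
        p = apply_mmej(locus, pair)
        p.weight = mmej_weight(pair, params.l_decay) * ep_scale
        products.append(p)
    if params.nhej_events > 0 and params.nhej_total_weight > 0:
        events = sample_nhej(
            junction,
            params.nhej_events,
            seed,
            p_geom=params.nhej_p,
            max_size=params.nhej_max_size,
            deletion_fraction=params.nhej_deletion_fraction,
        )
        w = params.nhej_total_weight / len(events) * ep_scale
        for ev in events:
            p = apply_nhej(locus, ev)
            p.weight = w
            products.append(p)

    # template-driven pathways
    if oligo is not None:
        bias = 1.0
        if guide_strand is not None:
            bias = strand_bias_weight(guide_strand, oligo, bias_ratio=params.bias_ratio)
        hdr_w = params.hdr_base_weight * bias
        bridged = exact_bridge_repair(locus, junction, oligo)
        if bridged is not None:
            bridged.weight = hdr_w * params.pathway_split
            products.append(bridged)
            sdsa = sdsa_two_step_repair(
                locus, junction, oligo, min_anneal=params.sdsa_min_anneal
            )
            sdsa_w = hdr_w * (1.0 - params.pathway_split)
            dups = [p for p in sdsa if "duplication_span" in p.detail]
            perfect = [p for p in sdsa if "duplication_span" not in p.detail]
            dup_share = params.sdsa_duplication_rate if dups else 0.0
            for p in perfect:
                p.weight = sdsa_w * (1.0 - dup_share)
                products.append(p)
            for p in dups:
                p.weight = sdsa_w * dup_share / len(dups)
                products.append(p)
        geom = best_productive_dimer(
            oligo, params.dimer_min_overlap, params.dimer_dg_threshold
        )
        if geom is not None:
            dp = dimer_insertion_repair(
                locus, junction, oligo, geom,
                trim=params.dimer_trim, min_mh=params.dimer_min_mh,
            )
            if dp is not None:
                dp.weight = params.dimer_base_weight
                products.append(dp)
        # rare precise + error-prone hybrid molecules
        has_precise = bridged is not None
        has_ep = any(p.pathway in ("NHEJ", "MMEJ") for p in products)
        if has_precise and has_ep and params.hybrid_rate > 0:
            edit = oligo.edit
            after = junction + edit.ref_span
            if after + 1 <= len(locus):
                seq = locus[:junction] + edit.payload + locus[after + 1 :]
                total = sum(p.weight for p in products)
                products.append(
                    RepairProduct(
                        seq=seq,
                        pathway="hybrid",
                        net_indel=edit.net - 1,
                        detail={"edit": edit.kind, "extra_deletion": (after, after + 1)},
                        weight=params.hybrid_rate / (1.0 - params.hybrid_rate) * total,
                    )
                )

    merged = _merge_classes(products)
    for p in merged:
        p.check_against(locus)
    return Spectrum(reference=locus, junction=junction, products=merged).normalized()


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write the spectrum as a TSV product table (header always present)."""
    spectrum.to_frame().to_csv(path, sep="\t", index=False)


def read_spectrum(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def compare_spectra(a: Spectrum, b: Spectrum) -> dict[str, float]:
    """Per-class frequency deltas (``a`` minus ``b``)."""
    fa, fb = a.class_frequencies(), b.class_frequencies()
    return {c: fa[c] - fb[c] for c in CLASSES}
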