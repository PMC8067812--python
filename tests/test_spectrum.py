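"""Spectrum orchestration: weighting, classification, suppression, I/O."""

import math

import pytest

from exactsim.errorprone import MicrohomologyPair, apply_mmej
from exactsim.products import RepairProduct
from exactsim.seqcore import SequenceError
from exactsim.spectrum import (
    classify_product,
    compare_spectra,
    read_spectrum,
    simulate_spectrum,
    write_spectrum,
)
from exactsim.synthetic import make_single_repeat_locus


def test_frequencies_always_sum_to_one(f1364, f_dimer):
    for sp in (
        simulate_spectrum(f1364.locus, junction=f1364.junction, seed=1),
        simulate_spectrum(
            f1364.locus, junction=f1364.junction, oligo=f1364.oligo, seed=1
        ),
        simulate_spectrum(f_dimer.locus, guide=f_dimer.guide, oligo=f_dimer.oligo, seed=1),
    ):
        assert math.isclose(sum(sp.frequencies), 1.0, abs_tol=1e-9)
        assert all(f >= 0 for f in sp.frequencies)


def test_no_oligo_spectrum_contains_the_attributed_deletions(f1364):
    sp = simulate_spectrum(f1364.locus, junction=f1364.junction, seed=1)
    mmej = {p.net_indel: f for p, f in zip(sp.products, sp.frequencies) if p.pathway == "MMEJ"}
    assert mmej[-10] > 0
    assert mmej[-13] > 0


def test_removing_the_oligo_removes_precise_and_dimer_products(f_dimer):
    with_oligo = simulate_spectrum(
        f_dimer.locus, guide=f_dimer.guide, oligo=f_dimer.oligo, seed=1
    )
    without = simulate_spectrum(f_dimer.locus, guide=f_dimer.guide, seed=1)
    cf = with_oligo.class_frequencies()
    assert cf["precise"] > 0 and cf["dimer_insertion"] > 0
    cf0 = without.class_frequencies()
    assert cf0["precise"] == 0 and cf0["dimer_insertion"] == 0 and cf0["hybrid"] == 0
    assert {p.pathway for p in without.products} <= {"MMEJ", "NHEJ"}


@pytest.mark.parametrize("name", ["f1364", "f1344", "f1228"])
def test_oligo_presence_suppresses_error_prone_repair(name, request):
    fix = request.getfixturevalue(name)
    without = simulate_spectrum(fix.locus, junction=fix.junction, seed=1)
    with_oligo = simulate_spectrum(fix.locus, junction=fix.junction, oligo=fix.oligo, seed=1)
    assert (
        with_oligo.class_frequencies()["error_prone"]
        < without.class_frequencies()["error_prone"]
    )


def test_matched_polarity_oligo_has_strictly_higher_precise_fraction(f_noti, f_dimer):
    for fix in (f_noti, f_dimer):
        matched_oligo = (
            fix.oligo if fix.oligo.orientation == fix.guide.strand else fix.oligo.flipped()
        )
        matched = simulate_spectrum(
            fix.locus, guide=fix.guide, oligo=matched_oligo, seed=1
        ).class_frequencies()["precise"]
        mismatched = simulate_spectrum(
            fix.locus, guide=fix.guide, oligo=matched_oligo.flipped(), seed=1
        ).class_frequencies()["precise"]
        assert matched > mismatched


def test_hybrid_frequency_is_at_most_one_in_a_thousand(f1364, f1344, f1228, f_noti, f_dimer):
    for fix in (f1364, f1344, f1228, f_noti, f_dimer):
        sp = simulate_spectrum(
            fix.locus, junction=fix.junction, guide=fix.guide, oligo=fix.oligo, seed=1
        )
        assert sp.class_frequencies()["hybrid"] <= 1.0 / 1000 + 1e-12


def test_mmej_outweighs_nhej_from_4bp_repeats(f1364):
    # the dominance sweep: 3-bp repeat below NHEJ, 4-bp at or above
    for L, expect in ((3, False), (4, True)):
        locus, junction = make_single_repeat_locus(L, seed=50 + L)
        pf = simulate_spectrum(locus, junction=junction, seed=1).pathway_frequencies()
        assert (pf.get("MMEJ", 0.0) >= pf.get("NHEJ", 0.0)) is expect


def test_spectrum_is_deterministic_for_fixed_seed(f1364):
    a = simulate_spectrum(f1364.locus, junction=f1364.junction, oligo=f1364.oligo, seed=7)
    b = simulate_spectrum(f1364.locus, junction=f1364.junction, oligo=f1364.oligo, seed=7)
    assert [(p.seq, p.pathway, p.weight) for p in a.products] == [
        (p.seq, p.pathway, p.weight) for p in b.products
    ]


def test_classification_of_each_pathway(f1364):
    mmej = apply_mmej(f1364.locus, MicrohomologyPair(6, 16, 6))
    assert classify_product(mmej) == "error_prone"
    assert classify_product(RepairProduct("ACGT", "ExACT", 0)) == "precise"
    assert classify_product(RepairProduct("ACGT", "SDSA-ExACT", 0)) == "precise"
    assert (
        classify_product(
            RepairProduct("ACGT", "SDSA-ExACT", 4, {"duplication_span": (0, 4)})
        )
        == "hybrid"
    )
    assert classify_product(RepairProduct("ACGT", "dimer-ExACT", 0)) == "dimer_insertion"
    assert classify_product(RepairProduct("ACGT", "NHEJ", -1)) == "error_prone"


def test_write_read_roundtrip_preserves_frequencies(tmp_path, f1364):
    sp = simulate_spectrum(f1364.locus, junction=f1364.junction, oligo=f1364.oligo, seed=1)
    path = tmp_path / "spectrum.tsv"
    write_spectrum(sp, path)
    frame = read_spectrum(path)
    assert list(frame["frequency"]) == pytest.approx(sp.frequencies)
    assert list(frame.columns) == [
        "product_id", "pathway", "class", "net_indel", "mh_len", "frequency", "sequence",
    ]


def test_empty_spectrum_writes_header_only(tmp_path):
    from exactsim.spectrum import Spectrum

    path = tmp_path / "empty.tsv"
    write_spectrum(Spectrum("ACGTACGT", 4, []), path)
    lines = path.read_text().splitlines()
    assert len(lines) == 1 and lines[0].startswith("product_id")


def test_compare_spectra_reports_positive_precise_delta_for_matched(f_noti):
    matched = simulate_spectrum(f_noti.locus, guide=f_noti.guide, oligo=f_noti.oligo, seed=1)
    mismatched = simulate_spectrum(
        f_noti.locus, guide=f_noti.guide, oligo=f_noti.oligo.flipped(), seed=1
    )
    delta = compare_spectra(matched, mismatched)
    assert delta["precise"] > 0
    assert set(delta) == {"precise", "error_prone", "hybrid", "dimer_insertion"}


def test_guide_or_junction_is_required(f1364):
    with pytest.raises(SequenceError):
        simulate_spectrum(f1364.locus, seed=1)
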