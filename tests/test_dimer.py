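"""Self-dimer scanning, nearest-neighbor thermodynamics, dimer insertion."""

import itertools

import numpy as np
import pytest

from exactsim.dimer import (
    NN_DG37,
    NN_INIT_AT,
    NN_INIT_GC,
    DimerGeometry,
    best_productive_dimer,
    dimer_insertion_repair,
    filter_productive_dimers,
    nn_delta_g,
    scan_self_dimers,
)
from exactsim.seqcore import SequenceError, complement_base, revcomp


def brute_delta_g(duplex_top):
    """Independent hand summation over the published increment table."""
    steps = {
        "AA": -1.00, "AT": -0.88, "TA": -0.58, "CA": -1.45, "GT": -1.44,
        "CT": -1.28, "GA": -1.30, "CG": -2.17, "GC": -2.24, "GG": -1.84,
    }
    total = 0.0
    for i in range(len(duplex_top) - 1):
        di = duplex_top[i : i + 2]
        total += steps[di] if di in steps else steps[revcomp(di)]
    for terminal in (duplex_top[0], duplex_top[-1]):
        total += 0.98 if terminal in "GC" else 1.03
    return total


def test_two_nt_duplex_is_one_increment_plus_initiation():
    assert nn_delta_g("GC") == pytest.approx(NN_DG37["GC"] + 2 * NN_INIT_GC)
    assert nn_delta_g("AT") == pytest.approx(NN_DG37["AT"] + 2 * NN_INIT_AT)


def test_noti_self_duplex_equals_hand_summed_increments():
    # GC + CG + GG + GC + CC + CG + GC steps, two G.C initiations
    expected = (
        -2.24 - 2.17 - 1.84 - 2.24 - 1.84 - 2.17 - 2.24 + 2 * 0.98
    )
    assert nn_delta_g("GCGGCCGC") == pytest.approx(expected)
    assert expected == pytest.approx(-12.78)


def test_nn_delta_g_matches_exhaustive_table_summation_up_to_12nt():
    rng = np.random.default_rng(19)
    # all duplexes of length 2-4 exhaustively, longer ones sampled
    for n in (2, 3, 4):
        for tup in itertools.product("ACGT", repeat=n):
            s = "".join(tup)
            assert nn_delta_g(s) == pytest.approx(brute_delta_g(s))
    for n in range(5, 13):
        for _ in range(50):
            s = "".join(rng.choice(list("ACGT"), size=n))
            assert nn_delta_g(s) == pytest.approx(brute_delta_g(s))


def test_longer_gc_overlap_is_more_stable_than_its_prefix():
    assert nn_delta_g("GCGCGC") < nn_delta_g("GCGC") < nn_delta_g("GC")


def test_nn_delta_g_rejects_degenerate_input():
    with pytest.raises(SequenceError):
        nn_delta_g("G")
    with pytest.raises(SequenceError):
        nn_delta_g("GN")


def test_oligo_without_self_complement_run_has_no_dimers():
    assert scan_self_dimers("ACACACACACAC") == []


def test_terminal_aatt_gives_a_productive_overlap_4_geometry():
    oligo = "GAGGAGGAGGAGGAGGAATT"  # 20-mer ending in the palindrome AATT
    productive = [g for g in scan_self_dimers(oligo) if g.productive]
    assert any(g.overlap_len == 4 for g in productive)


def test_scan_classifies_internal_runs_as_three_prime_overhangs():
    # GGGGCCCC in the middle pairs with itself without involving 3' ends
    oligo = "ATATAGGGGCCCCTATAT" + "AA"
    geoms = scan_self_dimers(oligo)
    assert any(g.end_state == "three_prime_overhang" for g in geoms)


def test_filter_removes_overhangs_and_weak_geometries():
    overhang = DimerGeometry(8, "three_prime_overhang", -20.0, 0, (0, 8))
    weak = DimerGeometry(4, "three_prime_recessed", -5.0, 10, (0, 4))
    strong = DimerGeometry(6, "three_prime_recessed", -12.0, 8, (0, 6))
    assert filter_productive_dimers([overhang]) == []
    assert filter_productive_dimers([weak]) == []
    assert filter_productive_dimers([overhang, weak, strong]) == [strong]


def test_filter_matches_brute_force_set_identity():
    rng = np.random.default_rng(23)
    for _ in range(50):
        oligo = "".join(rng.choice(list("ACGT"), size=30))
        geoms = scan_self_dimers(oligo)
        kept = filter_productive_dimers(geoms)
        expected = [
            g for g in geoms if g.end_state != "three_prime_overhang" and g.delta_g <= -9.0
        ]
        assert kept == expected


def test_f_dimer_top_productive_geometry_has_overlap_8(f_dimer):
    geoms = scan_self_dimers(f_dimer.oligo)
    productive = filter_productive_dimers(geoms)
    assert productive
    top = productive[0]
    assert top.overlap_len == 8
    assert top.end_state == "three_prime_recessed"
    assert top.delta_g == pytest.approx(-12.78)
    assert best_productive_dimer(f_dimer.oligo) == top


def test_dimer_insertion_reconstructs_net_plus_48(f_dimer):
    geom = best_productive_dimer(f_dimer.oligo)
    product = dimer_insertion_repair(f_dimer.locus, f_dimer.junction, f_dimer.oligo, geom)
    assert product.net_indel == 48
    assert product.pathway == "dimer-ExACT"
    # bookkeeping identity: (L - t - mh) + g - resected
    L, t, mh, g = len(f_dimer.oligo.seq), 2, 5, 0
    m0, m1 = product.detail["resected_interval"]
    assert product.net_indel == (L - t - mh) + g - (m1 - m0)
    # the incorporated segment is a contiguous substring of the oligo itself
    # (in-line incorporation against its templating orientation)
    assert product.detail["incorporated"] in f_dimer.oligo.seq
    assert product.detail["incorporated"] in product.seq


def test_dimer_insertion_without_upstream_microhomology_gives_no_product(f_dimer):
    # a locus whose upstream flank cannot contain the probe
    locus = "A" * 40 + f_dimer.locus[40:]
    assert (
        dimer_insertion_repair(locus, 40, f_dimer.oligo, best_productive_dimer(f_dimer.oligo))
        is None
    )


def test_unproductive_geometry_is_rejected_for_insertion(f_dimer):
    bad = DimerGeometry(8, "three_prime_overhang", -20.0, 0, (0, 8))
    with pytest.raises(SequenceError):
        dimer_insertion_repair(f_dimer.locus, f_dimer.junction, f_dimer.oligo, bad)


def test_geometry_ordering_is_deterministic():
    oligo = "GAGGAGGAGGAGGAGGAATT"
    a = scan_self_dimers(oligo)
    b = scan_self_dimers(oligo)
    assert a == b
    dgs = [g.delta_g for g in a]
    assert dgs == sorted(dgs)
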