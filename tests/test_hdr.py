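"""ssODN-templated repair: gap bridging, SDSA duplications, strand bias."""

import pytest

from exactsim.hdr import (
    Edit,
    Oligo,
    exact_bridge_repair,
    sdsa_two_step_repair,
    strand_bias_weight,
)
from exactsim.seqcore import SequenceError, revcomp

# toy locus for SDSA mispriming: the upstream flank's terminal 5-mer GCATT
# also occurs at the far end of a 13-nt homology arm (positions 7-12),
# 8 nt upstream of the cut at 20
SDSA_LOCUS = "ACCTGAA" + "GCATT" + "CAT" + "GCATT" + "GTACGATTACGGTCA"
SDSA_JUNCTION = 20


def _oligo(locus, junction, left, right, edit, orientation="S"):
    gene_sense = (
        locus[junction - left : junction]
        + edit.payload
        + locus[junction + edit.ref_span : junction + edit.ref_span + right]
    )
    seq = gene_sense if orientation == "S" else revcomp(gene_sense)
    return Oligo(seq, left, right, edit, orientation)


def test_reference_window_oligo_is_identity_repair():
    locus = "ACCTGAAGCATTCATGCATTGTACG"
    junction = 12
    edit = Edit(kind="substitution", payload=locus[12:13], ref_span=1)
    oligo = _oligo(locus, junction, 8, 8, edit)
    product = exact_bridge_repair(locus, junction, oligo)
    assert product.seq == locus
    assert product.net_indel == 0
    assert product.pathway == "ExACT"


def test_noti_insertion_oligo_yields_net_plus_8(f_noti):
    product = exact_bridge_repair(f_noti.locus, f_noti.junction, f_noti.oligo)
    assert product.net_indel == 8
    assert "GCGGCCGC" in product.seq
    # the payload appears exactly once, at the junction
    assert product.seq == (
        f_noti.locus[: f_noti.junction] + "GCGGCCGC" + f_noti.locus[f_noti.junction :]
    )
    assert product.seq.count("GCGGCCGC") == 1


def test_mismatched_arm_gives_no_product(f_noti):
    locus, junction, good = f_noti.locus, f_noti.junction, f_noti.oligo
    # corrupt 3 terminal bases of the gene-sense left arm (its 5' end)
    bad_arm = revcomp(good.seq[:3]) + good.seq[3:]
    if bad_arm == good.seq:
        bad_arm = "TTT" + good.seq[3:]
    bad = Oligo(bad_arm, good.left_arm_len, good.right_arm_len, good.edit, "S")
    assert exact_bridge_repair(locus, junction, bad) is None
    assert sdsa_two_step_repair(locus, junction, bad) == []


def test_deletion_and_substitution_edits_apply_at_the_junction():
    locus = "ACCTGAAGCATTCATGCATTGTACG"
    junction = 12
    deletion = _oligo(locus, junction, 8, 8, Edit(kind="deletion", ref_span=3))
    product = exact_bridge_repair(locus, junction, deletion)
    assert product.seq == locus[:12] + locus[15:]
    assert product.net_indel == -3
    sub = _oligo(locus, junction, 8, 8, Edit(kind="substitution", payload="G", ref_span=1))
    product = exact_bridge_repair(locus, junction, sub)
    assert product.seq == locus[:12] + "G" + locus[13:]
    assert product.net_indel == 0


def test_sdsa_without_alternative_anneal_site_converges_to_bridging(f_noti):
    products = sdsa_two_step_repair(f_noti.locus, f_noti.junction, f_noti.oligo)
    assert len(products) == 1
    bridged = exact_bridge_repair(f_noti.locus, f_noti.junction, f_noti.oligo)
    assert products[0].seq == bridged.seq
    assert products[0].pathway == "SDSA-ExACT"


def test_sdsa_mispriming_duplicates_bases_between_anneal_site_and_cut():
    edit = Edit(kind="insertion", payload="GG")
    oligo = _oligo(SDSA_LOCUS, SDSA_JUNCTION, 13, 10, edit)
    products = sdsa_two_step_repair(SDSA_LOCUS, SDSA_JUNCTION, oligo, min_anneal=5)
    dups = [p for p in products if "duplication_span" in p.detail]
    assert len(dups) == 1
    dup = dups[0]
    # the 5-nt terminal match sits at the arm's far end, 8 nt upstream of the
    # cut: the 8 intervening bases are copied twice
    assert dup.detail["anneal_site"] == (7, 12)
    assert dup.detail["duplicated"] == SDSA_LOCUS[12:20] == "CATGCATT"
    hand_assembled = SDSA_LOCUS[:20] + "CATGCATT" + "GG" + SDSA_LOCUS[20:]
    assert dup.seq == hand_assembled
    assert dup.net_indel == 2 + 8
    # duplication product length = reference + net(edit) + duplicated length
    assert len(dup.seq) == len(SDSA_LOCUS) + 2 + 8


def test_orientation_flip_preserves_the_product_set():
    edit = Edit(kind="insertion", payload="GG")
    s_oligo = _oligo(SDSA_LOCUS, SDSA_JUNCTION, 13, 10, edit, "S")
    ns_oligo = s_oligo.flipped()
    assert ns_oligo.seq == revcomp(s_oligo.seq)
    a = {p.seq for p in sdsa_two_step_repair(SDSA_LOCUS, SDSA_JUNCTION, s_oligo)}
    b = {p.seq for p in sdsa_two_step_repair(SDSA_LOCUS, SDSA_JUNCTION, ns_oligo)}
    assert a == b


def test_strand_bias_is_keyed_to_guide_orientation():
    edit = Edit(kind="insertion", payload="GG")
    s_oligo = _oligo(SDSA_LOCUS, SDSA_JUNCTION, 13, 10, edit, "S")
    ns_oligo = s_oligo.flipped()
    assert strand_bias_weight("S", s_oligo) == 2.0
    assert strand_bias_weight("S", ns_oligo) == 1.0
    # opposite-polarity guides each favor their own-polarity oligo
    assert strand_bias_weight("NS", ns_oligo) == 2.0
    assert strand_bias_weight("NS", s_oligo) == 1.0
    # neutral configuration
    assert strand_bias_weight("S", s_oligo, bias_ratio=1.0) == 1.0
    assert strand_bias_weight("S", ns_oligo, bias_ratio=1.0) == 1.0


def test_oligo_layout_validation():
    with pytest.raises(SequenceError):
        Oligo("ACGTACGT", 4, 4, Edit(kind="insertion", payload="GG"))  # length mismatch
    with pytest.raises(SequenceError):
        Edit(kind="substitution", payload="GG", ref_span=1)
    with pytest.raises(SequenceError):
        Edit(kind="insertion", payload="", ref_span=0)
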