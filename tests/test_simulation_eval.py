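"""Simulator determinism, spike-in geometry and the evaluation metrics."""

import numpy as np
import pytest

from ampvar import (
    ConfusionCounts,
    SimulationTruth,
    SpikedIndel,
    SpikedSNP,
    VariantRecord,
    apply_variants,
    calls_to_events,
    match_calls,
    random_panel,
    random_truth,
    recall,
    simulate_read_pairs,
    simulate_reads,
    tpr_fpr_accuracy,
    truth_events,
)
from ampvar.simulation_eval import read_truth


def test_apply_variants_snp_del_ins():
    target = "ACGTACGTAC"
    snp = SpikedSNP("a", 2, "C", "T", 1.0)
    dele = SpikedIndel("a", 5, "DEL", "AC", 1.0)
    ins = SpikedIndel("a", 9, "INS", "GG", 1.0)
    assert apply_variants(target, [snp], []) == "ATGTACGTAC"
    assert apply_variants(target, [], [dele]) == "ACGTGTAC"
    assert apply_variants(target, [], [ins]) == "ACGTACGTAGGC"
    assert apply_variants(target, [snp], [dele, ins]) == "ATGTGTAGGC"


def test_apply_variants_rejects_wrong_ref_or_out_of_range():
    with pytest.raises(ValueError):
        apply_variants("ACGT", [SpikedSNP("a", 2, "G", "T", 1.0)], [])
    with pytest.raises(ValueError):
        apply_variants("ACGT", [], [SpikedIndel("a", 4, "DEL", "TT", 1.0)])


def test_no_variant_error_free_depth_collapses_to_one_key():
    panel = random_panel(1, seed=41)
    truth = SimulationTruth(depth=10, seed=41)
    pairs = simulate_read_pairs(panel, truth)
    assert len(pairs) == 10
    assert len({(p.r1_seq, p.r2_seq) for p in pairs}) == 1


def test_simulator_deterministic_and_binomial_at_half_fraction():
    panel = random_panel(1, seed=42)
    amp = panel.amplicons[0]
    alt = "A" if amp.target_seq[19] != "A" else "C"
    truth = SimulationTruth(
        snps=[SpikedSNP(amp.amplicon_id, 20, amp.target_seq[19], alt, 0.5)],
        depth=100,
        seed=42,
    )
    pairs_a = simulate_read_pairs(panel, truth)
    pairs_b = simulate_read_pairs(panel, truth)
    assert [(p.r1_seq, p.r2_seq) for p in pairs_a] == [
        (p.r1_seq, p.r2_seq) for p in pairs_b
    ]
    # R2 layout: index (8) + forward primer (20) + target; the SNP base
    # sits at read offset 8 + 20 + 19
    offset = len(amp.index_seq) + len(amp.fwd_primer) + 19
    alt_reads = sum(1 for p in pairs_a if p.r2_seq[offset] == alt)
    assert 20 <= alt_reads <= 80  # binomial(100, .5) within generous bounds


def test_simulate_reads_files_byte_identical_across_runs(tmp_path):
    panel = random_panel(3, seed=7)
    truth = random_truth(panel, n_snps=3, n_indels=2, depth=20, seed=7)
    a = simulate_reads(panel, truth, tmp_path / "a")
    b = simulate_reads(panel, truth, tmp_path / "b")
    for pa, pb in zip(a, b):
        assert open(pa, "rb").read() == open(pb, "rb").read()


def test_reads_carry_intact_primer_after_index():
    """Error-free R2 = index + forward primer + ...; R1 ends the molecule."""
    panel = random_panel(3, seed=8)
    truth = SimulationTruth(depth=5, seed=8)
    pairs = simulate_read_pairs(panel, truth)
    by_amp = {a.amplicon_id: a for a in panel}
    for p in pairs:
        amp = by_amp[p.read_id.split(":")[0]]
        assert p.r2_seq.startswith(amp.index_seq + amp.fwd_primer)


def test_truth_round_trip_via_tsv(tmp_path):
    panel = random_panel(4, seed=9)
    truth = random_truth(panel, n_snps=4, n_indels=3, depth=30, seed=9)
    path = tmp_path / "truth.tsv"
    from ampvar import write_truth

    write_truth(truth, panel, path)
    reread, target_lens, normalized = read_truth(path)
    assert reread.depth == truth.depth
    assert target_lens == {
        a.amplicon_id: len(a.target_seq) for a in panel
    }
    assert normalized == truth_events(truth, panel)


def test_metric_formulas():
    c = ConfusionCounts(tp=9, fn=1)
    assert recall(c) == pytest.approx(0.9)
    assert recall(ConfusionCounts()) is None
    tpr, fpr, acc = tpr_fpr_accuracy(
        ConfusionCounts(tp=95, fn=5, fp=0, tn=100)
    )
    assert tpr == pytest.approx(0.95)
    assert fpr == 0.0
    assert acc == pytest.approx(0.975)
    assert tpr_fpr_accuracy(ConfusionCounts()) == (None, None, None)
    # identities: TPR equals recall; accuracy is 1 when FP = FN = 0
    c2 = ConfusionCounts(tp=5, fn=3, fp=2, tn=10)
    assert tpr_fpr_accuracy(c2)[0] == recall(c2)
    assert tpr_fpr_accuracy(ConfusionCounts(tp=4, tn=6))[2] == 1.0


def test_match_calls_positional_confusion():
    panel = random_panel(2, seed=10, target_len_range=(130, 130))
    truth = random_truth(panel, n_snps=2, n_indels=1, depth=20, seed=10)
    ev = truth_events(truth, panel)
    lens = {a.amplicon_id: len(a.target_seq) for a in panel}
    # perfect SNP calls, no indel calls
    calls = [
        VariantRecord(s.amplicon_id, s.position, s.ref, s.alt, "SNP", 0.5, 40)
        for s in truth.snps
    ]
    snp_cc, ind_cc = match_calls(calls, ev, lens)
    assert (snp_cc.tp, snp_cc.fp, snp_cc.fn) == (2, 0, 0)
    assert (ind_cc.tp, ind_cc.fn) == (0, 1)
    assert recall(snp_cc) == 1.0 and recall(ind_cc) == 0.0
    assert snp_cc.tn == sum(lens.values()) - 2
    # an oracle matcher over raw event tuples agrees
    call_ev = calls_to_events(calls)
    assert call_ev["snp"] == ev["snp"] and call_ev["indel"] == set()
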