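"""Pileup accumulation, the 90% frequency rule and indel emission."""

import pytest

from ampvar import (
    Amplicon,
    AssignedSequence,
    CallingThresholds,
    CollapsedSequence,
    PileupColumn,
    call_indels,
    call_snps,
    normalize_deletion,
    normalize_insertion,
    pileup,
    revcomp,
)
from ampvar.variant_calling import AmpliconPileup, IndelObservation

TARGET = "TGACCGTAGGCATCAACGGTTAGACCATTGCAAGGTCAAG"  # 40 bp toy exon


def _amplicon(target=TARGET):
    return Amplicon(
        amplicon_id="a1",
        fwd_primer="ACGGGTGA",
        rev_primer="GGTACCTA",
        target_seq=target,
        index_seq="AACCGGTT",
    )


def _assigned(amp, target_variant_seq, freq):
    """Build the collapsed key of an error-free read pair over the target."""
    molecule = amp.fwd_primer + target_variant_seq + amp.rev_primer
    r2 = molecule  # short toy molecule: both reads span it fully
    r1 = revcomp(molecule)
    return AssignedSequence(
        collapsed=CollapsedSequence(
            spliced_seq=r2 + revcomp(r1), frequency=freq, r2_len=len(r2)
        ),
        amplicon_id=amp.amplicon_id,
        matched_signature="",
    )


def _columns(ref_counts):
    cols = []
    for pos, counts in ref_counts:
        col = PileupColumn(position=pos)
        for base, n in counts.items():
            col.counts["ACGTN".index(base)] += n
        cols.append(col)
    return cols


def test_perfect_match_pileup_is_pure_reference():
    amp = _amplicon()
    pile = pileup([_assigned(amp, amp.target_seq, 5)], amp)
    assert len(pile.columns) == len(amp.target_seq)
    for col in pile.columns:
        ref = amp.target_seq[col.position - 1]
        # both mate segments cover the whole toy target
        assert col.depth == 10
        assert col.count_of(ref) == col.depth
    assert pile.indels == []


def test_depth_conservation_against_accepted_alignments():
    amp = _amplicon()
    mutated = amp.target_seq[:19] + "A" + amp.target_seq[20:]
    pile = pileup(
        [_assigned(amp, amp.target_seq, 30), _assigned(amp, mutated, 20)], amp
    )
    # every accepted alignment covers every column of the toy target
    assert pile.n_accepted == 4 and pile.n_rejected == 0
    for col in pile.columns:
        assert col.depth == 100


def test_garbled_sequence_contributes_nothing():
    amp = _amplicon()
    junk = "T" * len(amp.target_seq)
    pile = pileup([_assigned(amp, junk, 5)], amp)
    assert pile.n_accepted == 0
    assert all(col.depth == 0 for col in pile.columns)


def test_snp_rule_hundred_percent_reference_never_called():
    amp = _amplicon()
    cols = _columns([(1, {"T": 100})])  # ref T at position 1
    assert call_snps(cols, amp) == []


def test_snp_rule_called_below_threshold():
    amp = _amplicon()
    # position 1 ref T: 85% ref, 15% G
    cols = _columns([(1, {"T": 85, "G": 15})])
    (call,) = call_snps(cols, amp)
    assert (call.position, call.ref_base, call.alt) == (1, "T", "G")
    assert call.alt_fraction == pytest.approx(0.15)
    assert call.kind == "SNP" and call.depth == 100


def test_snp_rule_boundary_92_percent_not_called():
    amp = _amplicon()
    cols = _columns([(1, {"T": 92, "G": 8})])
    assert call_snps(cols, amp) == []


def test_snp_rule_exactly_90_percent_not_called():
    amp = _amplicon()
    cols = _columns([(1, {"T": 90, "G": 10})])
    assert call_snps(cols, amp) == []


def test_snp_below_min_depth_skipped():
    amp = _amplicon()
    cols = _columns([(1, {"T": 4, "G": 5})])
    assert call_snps(cols, amp, CallingThresholds(min_depth=10)) == []


def test_alt_tie_broken_alphabetically():
    amp = _amplicon()
    cols = _columns([(1, {"T": 50, "G": 25, "C": 25})])
    (call,) = call_snps(cols, amp)
    assert call.alt == "C"


def test_spiked_snp_recovered_from_pileup():
    amp = _amplicon()
    mutated = amp.target_seq[:19] + "A" + amp.target_seq[20:]  # T>A at 20
    assert amp.target_seq[19] == "T"
    pile = pileup(
        [_assigned(amp, amp.target_seq, 25), _assigned(amp, mutated, 25)], amp
    )
    calls = call_snps(pile.columns, amp)
    assert [(c.position, c.ref_base, c.alt) for c in calls] == [(20, "T", "A")]
    assert calls[0].alt_fraction == pytest.approx(0.5)


def test_deletion_emitted_left_anchored():
    amp = _amplicon()
    mutated = amp.target_seq[:19] + amp.target_seq[22:]  # drop bases 20-22
    pile = pileup(
        [_assigned(amp, amp.target_seq, 25), _assigned(amp, mutated, 25)], amp
    )
    dels = [c for c in call_indels(pile, amp) if c.kind == "DEL"]
    assert len(dels) == 1
    d = dels[0]
    npos, nallele = normalize_deletion(amp.target_seq, 20, 3)
    assert d.position == npos - 1
    assert d.ref_base == amp.target_seq[npos - 2] + nallele
    assert d.alt == d.ref_base[0]
    # SNP pass stays silent on a pure indel haplotype
    assert call_snps(pile.columns, amp) == []


def test_identical_read_and_target_yield_no_indel():
    amp = _amplicon()
    pile = pileup([_assigned(amp, amp.target_seq, 30)], amp)
    assert call_indels(pile, amp) == []


def test_insertion_emitted_with_anchor_base():
    amp = _amplicon()
    mutated = amp.target_seq[:20] + "CTTAC" + amp.target_seq[20:]
    pile = pileup(
        [_assigned(amp, amp.target_seq, 25), _assigned(amp, mutated, 25)], amp
    )
    ins = [c for c in call_indels(pile, amp) if c.kind == "INS"]
    assert len(ins) == 1
    i = ins[0]
    npos, nallele = normalize_insertion(amp.target_seq, 20, "CTTAC")
    assert i.position == npos
    assert i.ref_base == amp.target_seq[npos - 1]
    assert i.alt == i.ref_base + nallele


def test_indel_support_below_min_depth_not_emitted():
    amp = _amplicon()
    pile = AmpliconPileup(
        amplicon_id="a1",
        columns=[PileupColumn(position=i + 1) for i in range(len(TARGET))],
        indels=[IndelObservation(kind="DEL", position=5, allele="CG", support=4)],
    )
    assert call_indels(pile, amp, CallingThresholds(min_depth=10)) == []


def test_left_shift_normalization_in_repeats():
    #           123456789
    target = "TTAAAAGGCC"
    # deleting AA at positions 4-5 is equivalent to deleting at 3-4
    assert normalize_deletion(target, 5, 2) == (3, "AA")
    # inserting AA after position 6 left-shifts through the A run
    assert normalize_insertion(target, 6, "AA") == (2, "AA")
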