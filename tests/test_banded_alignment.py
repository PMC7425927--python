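"""Banded local alignment against an unbanded oracle, plus the k statistic."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampvar import align_local, band_width, effective_k, is_local_optimal
from conftest import full_smith_waterman_score

S_EXAMPLE = "CGTGAGCTG"
T_EXAMPLE = "CGTCGAGCTGA"

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


@pytest.mark.parametrize(
    "m,n,expected", [(9, 11, 3), (5, 5, 1), (1, 100, 100), (100, 1, 100)]
)
def test_band_width_rule(m, n, expected):
    assert band_width(m, n) == expected


def test_worked_example_alignment_layout():
    """9 matches, one 1-base gap in S opposite T's 4th character, k=0."""
    eps = band_width(len(S_EXAMPLE), len(T_EXAMPLE))
    assert eps == 3
    r = align_local(S_EXAMPLE, T_EXAMPLE, eps)
    assert r.score == 8
    assert r.matched_count == 9
    assert r.mismatch_count == 0
    assert r.k == 0
    assert len(r.gaps) == 1
    gap = r.gaps[0]
    assert gap.seq == "S" and gap.length == 1 and gap.t_pos == 4


def test_identity_alignment():
    r = align_local("ACGTACGT", "ACGTACGT")
    assert r.score == len("ACGTACGT") == r.matched_count
    assert r.k == 0 and r.gaps == []


def test_all_mismatch_alignment_floors_at_zero():
    r = align_local("AAAA", "CCCC", 10)
    assert r.score == 0 and r.matched_count == 0 and r.k == 4


@pytest.mark.parametrize("k,k_max,expected", [(0, 2, True), (2, 2, True), (3, 2, False)])
def test_local_optimal_threshold(k, k_max, expected):
    r = align_local("ACGT", "ACGT")
    r.k = k
    assert is_local_optimal(r, k_max) is expected


def test_wide_band_equals_full_smith_waterman_on_random_pairs():
    rng = random.Random(13)
    for _ in range(500):
        s = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 30)))
        t = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 30)))
        r = align_local(s, t, max(len(s), len(t)))
        assert r.score == full_smith_waterman_score(s, t)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(dna, dna)
def test_score_monotone_in_band_width(s, t):
    eps0 = band_width(len(s), len(t))
    scores = [
        align_local(s, t, e).score
        for e in (eps0, eps0 + 2, max(len(s), len(t)))
    ]
    assert scores == sorted(scores)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(dna, dna)
def test_result_invariants(s, t):
    r = align_local(s, t, max(len(s), len(t)))
    shorter = min(len(s), len(t))
    assert 0 <= r.matched_count <= shorter
    assert r.k == shorter - r.matched_count >= 0
    # each gap character costs one; mismatches are free
    assert r.score <= r.matched_count
    assert effective_k(r) <= r.k
    # path cells stay inside the band and the matrix bounds
    for i, j in r.path:
        assert 0 <= i <= len(s) and 0 <= j <= len(t)
        if (i, j) != r.path[-1]:
            assert abs(i - j) <= r.epsilon


def test_k_zero_iff_shorter_sequence_contained():
    # substring: every char of the shorter sequence matched
    r = align_local("GAGC", T_EXAMPLE, len(T_EXAMPLE))
    assert r.k == 0 and r.matched_count == 4
    # one substitution: exactly one shorter-sequence char unmatched
    r = align_local("GTGC", T_EXAMPLE, len(T_EXAMPLE))
    assert r.k == 1


def test_insertion_gap_is_contiguous_and_effective_k_discounts_it():
    # Penalised-substitution mode: with free mismatches a shifted gapless
    # path can tie the true gapped one, and the fewest-gaps tie-break
    # would then prefer it; penalising substitutions makes the gapped
    # path strictly optimal so the gap structure is deterministic.
    t = "TGACCGTAGGCATCAACGGTTAGACCATTGCAAGGTCAAG"
    # a read-like s: prefix of t carrying a 5-base insertion, still
    # shorter than t overall, as a sequencing read against its target
    s = t[:14] + "TTAGG" + t[14:25]
    r = align_local(s, t, 10, mismatch=-1)
    assert [g.seq for g in r.gaps] == ["T"]
    assert r.gaps[0].length == 5 and r.gaps[0].bases == "TTAGG"
    assert r.k == 5  # inserted bases count as unmatched shorter-seq chars
    assert effective_k(r) == 0


def test_deletion_gap_reports_target_run():
    t = "ACGTTGCATGCAAGCTTGGCACGT"
    s = t[:8] + t[13:]  # 5-base deletion
    r = align_local(s, t, 10, mismatch=-1)
    assert [g.seq for g in r.gaps] == ["S"]
    gap = r.gaps[0]
    assert gap.length == 5
    # placement may be any shift-equivalent layout of the same deletion
    assert gap.bases == t[gap.t_pos - 1 : gap.t_pos + 4]
    assert s == t[: gap.t_pos - 1] + t[gap.t_pos + 4 :]
    assert r.k == 0 and r.mismatch_count == 0
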