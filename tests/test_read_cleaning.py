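"""Public-sequence dropping and index trimming rules."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampvar import Amplicon, ReadPair, clean_index, clean_public, revcomp

PUBLIC = "TTAACCGGTTAACCGGTTAA"


def _pair(i, r1, r2):
    return ReadPair(read_id=f"q{i}", r1_seq=r1, r2_seq=r2)


def _random_read(rng, n=60, avoid=()):
    while True:
        seq = "".join(rng.choice("ACGT") for _ in range(n))
        if not any(a in seq for a in avoid):
            return seq


def test_pair_with_public_in_r1_only_is_dropped():
    """A public hit on one mate discards both mates."""
    rng = random.Random(0)
    clean_r2 = _random_read(rng, avoid=(PUBLIC, revcomp(PUBLIC)))
    dirty_r1 = "ACGT" + PUBLIC + "ACGT"
    kept, report = clean_public([_pair(0, dirty_r1, clean_r2)], PUBLIC)
    assert kept == []
    assert report.dropped_public == 1 and report.surviving_pairs == 0


def test_clean_pair_passes_unmodified():
    rng = random.Random(1)
    r1 = _random_read(rng, avoid=(PUBLIC, revcomp(PUBLIC)))
    r2 = _random_read(rng, avoid=(PUBLIC, revcomp(PUBLIC)))
    pair = _pair(0, r1, r2)
    kept, report = clean_public([pair], PUBLIC)
    assert kept == [pair]
    assert report.dropped_public == 0 and report.surviving_pairs == 1


def test_constructed_fixture_drop_count_matches_bruteforce():
    """100 pairs: 13 R1 hits, 7 R2 revcomp hits, 3 overlapping -> 17 drops."""
    rng = random.Random(2)
    rc = revcomp(PUBLIC)
    pairs = []
    for i in range(100):
        r1 = _random_read(rng, avoid=(PUBLIC, rc))
        r2 = _random_read(rng, avoid=(PUBLIC, rc))
        if i < 13:  # R1 carries the public sequence
            r1 = r1[:20] + PUBLIC + r1[20:]
        if 10 <= i < 17:  # R2 carries its reverse complement (3 overlap)
            r2 = r2[:20] + rc + r2[20:]
        pairs.append(_pair(i, r1, r2))
    # independent brute-force substring scan
    expected_drop = sum(
        1 for p in pairs if PUBLIC in p.r1_seq or rc in p.r2_seq
    )
    assert expected_drop == 17
    kept, report = clean_public(pairs, PUBLIC)
    assert report.dropped_public == 17
    assert len(kept) == 83
    assert report.surviving_pairs == report.input_pairs - report.dropped_public


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.text(alphabet="ACGT", min_size=10, max_size=80),
            st.text(alphabet="ACGT", min_size=10, max_size=80),
        ),
        max_size=20,
    )
)
def test_clean_public_idempotent_and_rescan_clean(reads):
    pairs = [_pair(i, r1, r2) for i, (r1, r2) in enumerate(reads)]
    kept, _ = clean_public(pairs, "ACGTAC")
    # survivors never contain the public sequence (rescan invariant)
    assert all(
        "ACGTAC" not in p.r1_seq and revcomp("ACGTAC") not in p.r2_seq
        for p in kept
    )
    again, report = clean_public(kept, "ACGTAC")
    assert again == kept and report.dropped_public == 0


def _amplicon(index="ACGTACGT", target_len=160):
    return Amplicon(
        amplicon_id="a1",
        fwd_primer="ACGGGTGACGGGTGACGGGT",
        rev_primer="GTACCTAGGTACCTAGGTAC",
        target_seq="AC" * (target_len // 2),
        index_seq=index,
    )


def test_exact_index_prefix_is_removed():
    amp = _amplicon()
    tail = "GGGTTTCCCAAAGGGTTTCC"
    pairs = [_pair(0, "A" * 30, amp.index_seq + tail)]
    cleaned, n_trim, n_trunc = clean_index(pairs, amp)
    assert cleaned[0].r2_seq == tail
    assert n_trim == 1 and n_trunc == 0


@pytest.mark.parametrize("n_mismatch,expect_trim", [(3, True), (4, False)])
def test_index_mismatch_budget_is_three(n_mismatch, expect_trim):
    amp = _amplicon(index="AAAAAAAA")
    corrupted = "C" * n_mismatch + amp.index_seq[n_mismatch:]
    tail = "GGGTTTCCCAAAGGGTTTCC"
    pairs = [_pair(0, "A" * 30, corrupted + tail)]
    cleaned, n_trim, _ = clean_index(pairs, amp)
    assert (cleaned[0].r2_seq == tail) is expect_trim
    assert n_trim == (1 if expect_trim else 0)


def test_r1_truncated_to_short_target_length():
    amp = _amplicon(target_len=120)
    pairs = [_pair(0, "A" * 150, "C" * 150)]
    cleaned, _, n_trunc = clean_index(pairs, amp)
    assert len(cleaned[0].r1_seq) == 120
    assert n_trunc == 1


def test_long_target_leaves_r1_untouched():
    amp = _amplicon(target_len=160)
    pairs = [_pair(0, "A" * 150, "C" * 150)]
    cleaned, _, n_trunc = clean_index(pairs, amp)
    assert len(cleaned[0].r1_seq) == 150 and n_trunc == 0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.text(alphabet="ACGT", min_size=1, max_size=200),
    st.text(alphabet="ACGT", min_size=1, max_size=200),
)
def test_clean_index_never_lengthens_reads(r1, r2):
    amp = _amplicon(target_len=120)
    pairs = [_pair(0, r1, r2)]
    cleaned, _, _ = clean_index(pairs, amp)
    assert len(cleaned[0].r1_seq) <= len(r1)
    assert len(cleaned[0].r2_seq) <= len(r2)
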