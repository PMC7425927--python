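"""Read cleaning: public-sequence filtering and index trimming.

Two cleaning passes run before any alignment:

* **Public-sequence cleaning** drops mate pairs whose reads contain the
  shared capture ("public") sequence.  A read that still carries the
  public sequence failed to capture a target, so the whole pair is
  discarded even when only one mate shows it.
* **Index cleaning** removes the sample-index prefix that bleeds into the
  start of R2 on short inserts (searched with a small mismatch budget),
  and truncates R1 to the target length when the target is shorter than
  the read, cutting adapter read-through off the 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

from .io_formats import Amplicon, ReadPair, revcomp

__all__ = [
    "CleaningReport",
    "clean_public",
    "clean_index",
    "trim_index_prefix",
    "truncate_r1",
]


@dataclass
class CleaningReport:
    """Stage counters accumulated by the cleaning passes."""

    input_pairs: int = 0
    dropped_public: int = 0
    index_trimmed: int = 0
    r1_truncated: int = 0
    surviving_pairs: int = 0


def clean_public(
    pairs: Iterable[ReadPair], public_seq: str
) -> tuple[list[ReadPair], CleaningReport]:
    """Drop pairs carrying the public sequence on either mate.

    A pair is removed when R1 contains ``public_seq`` as an exact
    substring or R2 contains its reverse complement (R2 reads the
    opposite strand).  Surviving pairs pass through unmodified.
    """
    if not public_seq:
        raise ValueError("public_seq must be non-empty")
    public_seq = public_seq.upper()
    rc = revcomp(public_seq)
    report = CleaningReport()
    kept: list[ReadPair] = []
    for pair in pairs:
        report.input_pairs += 1
        if public_seq in pair.r1_seq or rc in pair.r2_seq:
            report.dropped_public += 1
        else:
            kept.append(pair)
    report.surviving_pairs = report.input_pairs - report.dropped_public
    return kept, report


def _find_index_end(r2: str, index_seq: str, max_mismatch: int) -> int | None:
    """Leftmost end offset of an index match in R2's leading window.

    The window spans the first ``len(index)+2`` characters, so candidate
    start offsets are 0..2 (fewer when the read itself is shorter).
    Mismatches are substitutions only; the leftmost qualifying start is
    taken so that the most read is preserved after trimming.
    """
    k = len(index_seq)
    if k == 0 or len(r2) < k:
        return None
    last_start = min(2, len(r2) - k)
    for start in range(last_start + 1):
        mismatches = 0
        for a, b in zip(r2[start : start + k], index_seq):
            if a != b:
                mismatches += 1
                if mismatches > max_mismatch:
                    break
        else:
            return start + k
    return None


def trim_index_prefix(
    pairs: Iterable[ReadPair], index_seq: str, max_mismatch: int = 3
) -> tuple[list[ReadPair], int]:
    """Remove a leading index match (and anything before it) from R2."""
    out: list[ReadPair] = []
    n_trimmed = 0
    for pair in pairs:
        end = _find_index_end(pair.r2_seq, index_seq, max_mismatch)
        if end is not None and end < len(pair.r2_seq):
            qual = pair.r2_qual[end:] if pair.r2_qual is not None else None
            pair = replace(pair, r2_seq=pair.r2_seq[end:], r2_qual=qual)
            n_trimmed += 1
        out.append(pair)
    return out, n_trimmed


def truncate_r1(
    pairs: Iterable[ReadPair], target_len: int
) -> tuple[list[ReadPair], int]:
    """Cut R1 down to ``target_len`` characters (never lengthens)."""
    out: list[ReadPair] = []
    n_truncated = 0
    for pair in pairs:
        if len(pair.r1_seq) > target_len:
            qual = (
                pair.r1_qual[:target_len] if pair.r1_qual is not None else None
            )
            pair = replace(pair, r1_seq=pair.r1_seq[:target_len], r1_qual=qual)
            n_truncated += 1
        out.append(pair)
    return out, n_truncated


def clean_index(
    pairs: Iterable[ReadPair], amplicon: Amplicon, max_mismatch: int = 3
) -> tuple[list[ReadPair], int, int]:
    """Index-clean pairs against one amplicon.

    R2 prefixes matching the amplicon's index (up to ``max_mismatch``
    substitutions, searched in the first ``len(index)+2`` characters) are
    removed through the end of the match.  Independently, when the target
    is shorter than 150 bp, R1 is truncated to the target length: a read
    longer than its insert has run into adapter/index sequence.

    Returns ``(cleaned pairs, n index-trimmed, n R1-truncated)``.
    """
    pairs, n_trimmed = trim_index_prefix(pairs, amplicon.index_seq, max_mismatch)
    n_truncated = 0
    if len(amplicon.target_seq) < 150:
        pairs, n_truncated = truncate_r1(pairs, len(amplicon.target_seq))
    return pairs, n_trimmed, n_truncated
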