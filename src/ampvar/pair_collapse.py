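"""Mate-pair splicing and duplicate collapsing.

Each pair is spliced into a single key — R2 followed by the reverse
complement of R1, so both segments read the same strand — and identical
keys are counted.  Collapsing replaces millions of reads with one row per
distinct molecule plus its frequency; a minimum-occurrence threshold
``phi`` optionally discards rare keys (``phi = 1`` keeps everything).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .io_formats import ReadPair, revcomp

__all__ = ["CollapsedSequence", "splice_pair", "collapse", "split_collapsed"]


@dataclass
class CollapsedSequence:
    """One distinct spliced key with its occurrence count.

    ``r2_len`` records the R2 portion's length (taken from the first
    contributing pair) so the key can later be split back into mates.
    """

    spliced_seq: str
    frequency: int
    r2_len: int = 0

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")


def splice_pair(pair: ReadPair) -> str:
    """R2 concatenated with the reverse complement of R1."""
    return pair.r2_seq + revcomp(pair.r1_seq)


def collapse(pairs: Iterable[ReadPair], phi: int = 1) -> list[CollapsedSequence]:
    """Count identical spliced keys and keep those occurring >= ``phi`` times.

    Output is sorted by frequency descending, ties broken lexicographically
    by sequence so ordering is deterministic across runs.
    """
    if phi < 1:
        raise ValueError("phi must be >= 1")
    counts: Counter[str] = Counter()
    r2_lens: dict[str, int] = {}
    for pair in pairs:
        key = splice_pair(pair)
        counts[key] += 1
        r2_lens.setdefault(key, len(pair.r2_seq))
    rows = [
        CollapsedSequence(spliced_seq=seq, frequency=freq, r2_len=r2_lens[seq])
        for seq, freq in counts.items()
        if freq >= phi
    ]
    rows.sort(key=lambda cs: (-cs.frequency, cs.spliced_seq))
    return rows


def split_collapsed(
    cs: CollapsedSequence | str, r2_len: int
) -> tuple[str, str]:
    """Split a spliced key back into ``(r2_part, r1_part)``.

    ``r2_part`` is the prefix of length ``r2_len``; ``r1_part`` is the
    reverse complement of the remaining suffix, restoring the original R1
    orientation.  Inverse of :func:`splice_pair`.
    """
    seq = cs.spliced_seq if isinstance(cs, CollapsedSequence) else cs
    if not 0 < r2_len < len(seq):
        raise ValueError(
            f"r2_len {r2_len} out of range for spliced length {len(seq)}"
        )
    return seq[:r2_len], revcomp(seq[r2_len:])
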