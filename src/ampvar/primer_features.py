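"""Discriminating-position selection over forward primers.

Reads begin with their amplicon's forward primer, so amplicons can be
demultiplexed by looking at a handful of primer positions instead of
matching whole primers.  This module computes the pairwise difference
sets between primers (positions at which two primers disagree), then
selects a minimal set of positions whose per-primer character
projections — the *signatures* — are pairwise distinct.

For ``n`` primers at least ``ceil(log4 n)`` positions are required, since
each position carries at most four states.  Panels are small (tens of
primers), so the minimal set is found by exhaustive search over position
subsets of increasing size; the primers' published greedy heuristic
(take the most frequently differing positions first) is available as a
fast path but is not guaranteed minimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .io_formats import AmpliconPanel

__all__ = [
    "DifferenceSet",
    "FeatureCatalog",
    "CatalogError",
    "pairwise_fs",
    "minimal_discriminating_sets",
    "select_positions",
    "greedy_select_positions",
]


class CatalogError(ValueError):
    """Raised when no discriminating position set exists for a panel."""


@dataclass(frozen=True)
class DifferenceSet:
    """Positions (1-based) at which two sequences differ, with both characters.

    Comparison runs over the common prefix ``1..min(|a|, |b|)``; the set
    is empty iff the sequences agree over that range.
    """

    label_a: str
    label_b: str
    positions: tuple[tuple[int, str, str], ...]

    def position_indices(self) -> tuple[int, ...]:
        return tuple(p for p, _, _ in self.positions)


@dataclass
class FeatureCatalog:
    """Selected discriminating positions and per-amplicon signatures."""

    pairwise: list[DifferenceSet]
    selected_positions: tuple[int, ...]
    signatures: dict[str, str]
    minimal_sets: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        sigs = list(self.signatures.values())
        if len(set(sigs)) != len(sigs):
            raise CatalogError("signatures are not pairwise distinct")


def pairwise_fs(r: str, s: str, label_a: str = "", label_b: str = "") -> DifferenceSet:
    """Difference set between two sequences over their common prefix.

    Example: ``pairwise_fs("ACGTGC", "ACGCGC")`` differs only at position
    4 (T vs C).
    """
    if not r or not s:
        raise ValueError("sequences must be non-empty")
    positions = tuple(
        (i + 1, a, b) for i, (a, b) in enumerate(zip(r, s)) if a != b
    )
    return DifferenceSet(label_a or r, label_b or s, positions)


def _projection(primer: str, positions: Sequence[int]) -> str:
    return "".join(primer[p - 1] for p in positions)


def _is_discriminating(primers: Sequence[str], positions: Sequence[int]) -> bool:
    seen = set()
    for primer in primers:
        sig = _projection(primer, positions)
        if sig in seen:
            return False
        seen.add(sig)
    return True


def minimal_discriminating_sets(
    primers: Sequence[str],
) -> tuple[int, list[tuple[int, ...]]]:
    """All smallest position sets with pairwise-distinct projections.

    Returns ``(size, sets)`` where ``sets`` lists every valid combination
    of that minimal size in lexicographic order.  Positions are drawn
    from ``1..min primer length`` (the common prefix of the panel).
    Raises :class:`CatalogError` when no set exists, i.e. when two
    primers agree over the whole compared range.
    """
    if len(primers) < 2:
        return 0, [()]
    span = min(len(p) for p in primers)
    if len({p[:span] for p in primers}) != len(primers):
        raise CatalogError(
            "two primers are identical over the compared length; no "
            "discriminating position set exists"
        )
    lower = max(1, math.ceil(math.log(len(primers), 4)))
    for size in range(lower, span + 1):
        valid = [
            combo
            for combo in combinations(range(1, span + 1), size)
            if _is_discriminating(primers, combo)
        ]
        if valid:
            return size, valid
    raise CatalogError("no discriminating position set within primer length")


def _all_pairwise(panel: AmpliconPanel) -> list[DifferenceSet]:
    amps = panel.amplicons
    return [
        pairwise_fs(
            a.fwd_primer, b.fwd_primer, a.amplicon_id, b.amplicon_id
        )
        for i, a in enumerate(amps)
        for b in amps[i + 1 :]
    ]


def select_positions(panel: AmpliconPanel) -> FeatureCatalog:
    """Smallest discriminating position set for a panel's forward primers.

    Among equal-cardinality sets the lexicographically smallest position
    tuple is chosen, making the pick reproducible.
    """
    primers = [a.fwd_primer for a in panel.amplicons]
    size, sets = minimal_discriminating_sets(primers)
    selected = sets[0] if sets else ()
    signatures = {
        a.amplicon_id: _projection(a.fwd_primer, selected)
        for a in panel.amplicons
    }
    assert size >= math.ceil(math.log(max(len(primers), 1), 4)) or size == 0
    return FeatureCatalog(
        pairwise=_all_pairwise(panel),
        selected_positions=selected,
        signatures=signatures,
        minimal_sets=tuple(sets),
    )


def greedy_select_positions(panel: AmpliconPanel) -> FeatureCatalog:
    """Greedy fast path: add the most frequently differing positions first.

    Produces a valid (injective) but not necessarily minimal set; the
    exhaustive :func:`select_positions` result is canonical.
    """
    primers = [a.fwd_primer for a in panel.amplicons]
    span = min(len(p) for p in primers)
    if len({p[:span] for p in primers}) != len(primers):
        raise CatalogError("two primers identical over the compared length")
    pairwise = _all_pairwise(panel)
    tally: dict[int, int] = {p: 0 for p in range(1, span + 1)}
    for ds in pairwise:
        for p in ds.position_indices():
            if p <= span:
                tally[p] += 1
    ranked = sorted(tally, key=lambda p: (-tally[p], p))
    chosen: list[int] = []
    for p in ranked:
        chosen.append(p)
        if _is_discriminating(primers, sorted(chosen)):
            break
    else:
        raise CatalogError("no discriminating position set within primer length")
    selected = tuple(sorted(chosen))
    signatures = {
        a.amplicon_id: _projection(a.fwd_primer, selected)
        for a in panel.amplicons
    }
    return FeatureCatalog(
        pairwise=pairwise, selected_positions=selected, signatures=signatures
    )
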