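"""Banded Smith-Waterman local alignment with a match-count statistic.

Scoring is deliberately simple: +1 for a match, 0 for a mismatch, -1 per
gap character, with every cell floored at zero (local alignment).  The
dynamic program is restricted to a diagonal band ``|i - j| <= epsilon``;
cells outside the band hold zero.  The default half-width is
``|m - n| + 1``, just enough to absorb the length difference between the
two sequences, and callers may widen it when larger indels are expected.

Besides the DP score the traceback reports ``matched_count`` — the number
of aligned equal-character pairs on the optimal path — and the statistic

    k = min(m, n) - matched_count,

the number of characters of the shorter sequence left unmatched.  ``k = 0``
means the shorter sequence is contained in the longer one (a complete
subset relation); small ``k`` (conventionally up to 2) marks an
acceptable local alignment, and larger ``k`` marks sequences that should
not be compared further.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Gap",
    "AlignmentResult",
    "band_width",
    "align_local",
    "is_local_optimal",
    "effective_k",
    "format_alignment",
]


@dataclass(frozen=True)
class Gap:
    """One maximal gap run on the optimal path.

    ``seq`` names the sequence holding the gap characters: a gap in S
    means characters of T are aligned to nothing (a deletion from S), a
    gap in T means characters of S are inserted relative to T.
    ``s_pos``/``t_pos`` are 1-based; for a gap in S, ``t_pos`` is the
    first T position spanned and ``s_pos`` the S position after which the
    gap opens (symmetrically for a gap in T).  ``bases`` holds the
    characters aligned to the gap.
    """

    seq: str  # "S" or "T"
    s_pos: int
    t_pos: int
    length: int
    bases: str


@dataclass
class AlignmentResult:
    """Score matrix summary plus the traced optimal local path."""

    s: str
    t: str
    epsilon: int
    score: int
    max_i: int
    max_j: int
    path: list[tuple[int, int]]
    aligned_pairs: list[tuple[int, int]]
    matched_count: int
    mismatch_count: int
    k: int
    gaps: list[Gap] = field(default_factory=list)

    @property
    def s_gap_bases(self) -> int:
        """T characters aligned to gaps in S (deleted from S)."""
        return sum(g.length for g in self.gaps if g.seq == "S")

    @property
    def t_gap_bases(self) -> int:
        """S characters aligned to gaps in T (inserted relative to T)."""
        return sum(g.length for g in self.gaps if g.seq == "T")


def band_width(m: int, n: int) -> int:
    """Default band half-width for sequences of lengths ``m`` and ``n``.

    ``|m - n| + 1``: zero length difference still allows a one-cell
    deviation from the main diagonal.
    """
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return abs(m - n) + 1


def align_local(
    s: str, t: str, epsilon: int | None = None, *, mismatch: int = 0
) -> AlignmentResult:
    """Banded local alignment of ``s`` (rows) against ``t`` (columns).

    ``epsilon`` defaults to :func:`band_width` of the two lengths.  The
    maximum cell is located with ties broken by smallest row then
    smallest column; the traceback prefers, at equal scores, the diagonal
    predecessor, then the vertical one, then the horizontal one, and
    stops at the first zero cell.  The returned path runs from the
    maximum cell back to that zero cell.

    ``mismatch`` is the substitution score for unequal characters.  The
    conventional value here is 0 (substitutions are free; only gaps cost
    score), which callers may lower to -1 when free substitutions would
    let an accidental shifted-frame path outscore the true gapped one.
    """
    if not s or not t:
        raise ValueError("sequences must be non-empty")
    m, n = len(s), len(t)
    if epsilon is None:
        epsilon = band_width(m, n)
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")

    # Scaled-integer scoring: match +SCALE, mismatch 0, gap character
    # -SCALE, plus an extra -1 the first cell of every gap run.  Because
    # a path holds fewer than SCALE gap runs, the run surcharge can never
    # overturn the plain score: it only breaks ties in favour of the
    # path with the fewest gap openings.  Under the plain scheme a
    # contiguous indel ties score with the same indel fragmented across a
    # window of accidental shifted-frame matches, and fragmented gap
    # evidence is useless to the caller; the surcharge selects the
    # contiguous (affine-style canonical) layout among the score ties.
    scale = 2 * (m + n) + 4
    neg = -(2**60)
    # M: path ends in an aligned pair; X: ends in a gap in T (consuming
    # s); Y: ends in a gap in S (consuming t).
    M = [[0] * (n + 1) for _ in range(m + 1)]
    X = [[neg] * (n + 1) for _ in range(m + 1)]
    Y = [[neg] * (n + 1) for _ in range(m + 1)]
    best = 0
    bi = bj = 0
    mm = mismatch * scale
    for i in range(1, m + 1):
        lo = max(1, i - epsilon)
        hi = min(n, i + epsilon)
        si = s[i - 1]
        Mr, Xr, Yr = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(lo, hi + 1):
            sub = scale if si == t[j - 1] else mm
            diag = Mp[j - 1]
            if Xp[j - 1] > diag:
                diag = Xp[j - 1]
            if Yp[j - 1] > diag:
                diag = Yp[j - 1]
            v = diag + sub
            if v < 0:
                v = 0
            Mr[j] = v
            x = Mp[j] - (scale + 1)
            if Xp[j] - scale > x:
                x = Xp[j] - scale
            if Yp[j] - (scale + 1) > x:
                x = Yp[j] - (scale + 1)
            Xr[j] = x
            y = Mr[j - 1] - (scale + 1)
            if Yr[j - 1] - scale > y:
                y = Yr[j - 1] - scale
            if Xr[j - 1] - (scale + 1) > y:
                y = Xr[j - 1] - (scale + 1)
            Yr[j] = y
            if v > best:
                best, bi, bj = v, i, j

    # Traceback from the max cell (always an aligned pair: trailing gaps
    # only lower the score) down to a zero cell, tracking the state.
    path = [(bi, bj)]
    moves: list[str] = []  # recorded max-cell -> start, reversed later
    i, j = bi, bj
    state = "M"
    while not (state == "M" and M[i][j] <= 0):
        if state == "M":
            val = M[i][j]
            sub = scale if s[i - 1] == t[j - 1] else mm
            prev_val = val - sub
            if M[i - 1][j - 1] == prev_val:
                state = "M"
            elif X[i - 1][j - 1] == prev_val:
                state = "X"
            else:
                state = "Y"
            moves.append("D")
            i -= 1
            j -= 1
        elif state == "X":
            val = X[i][j]
            if X[i - 1][j] - scale == val:
                state = "X"
            elif M[i - 1][j] - (scale + 1) == val:
                state = "M"
            else:
                state = "Y"
            moves.append("V")  # gap in T, consumes s[i-1]
            i -= 1
        else:
            val = Y[i][j]
            if Y[i][j - 1] - scale == val:
                state = "Y"
            elif M[i][j - 1] - (scale + 1) == val:
                state = "M"
            else:
                state = "X"
            moves.append("H")  # gap in S, consumes t[j-1]
            j -= 1
        path.append((i, j))

    # Walk the path forward to classify columns and collect gap runs.
    start_i, start_j = i, j
    aligned_pairs: list[tuple[int, int]] = []
    matched = 0
    mismatched = 0
    gaps: list[Gap] = []
    run_kind: str | None = None
    run_start = (0, 0)
    run_bases: list[str] = []

    def close_run() -> None:
        nonlocal run_kind, run_bases
        if run_kind is None:
            return
        ri, rj = run_start
        if run_kind == "V":  # gap in T
            gaps.append(
                Gap(seq="T", s_pos=ri + 1, t_pos=rj, length=len(run_bases),
                    bases="".join(run_bases))
            )
        else:  # gap in S
            gaps.append(
                Gap(seq="S", s_pos=ri, t_pos=rj + 1, length=len(run_bases),
                    bases="".join(run_bases))
            )
        run_kind = None
        run_bases = []

    ci, cj = start_i, start_j
    for move in reversed(moves):
        if move == "D":
            close_run()
            ci += 1
            cj += 1
            aligned_pairs.append((ci, cj))
            if s[ci - 1] == t[cj - 1]:
                matched += 1
            else:
                mismatched += 1
        elif move == "V":
            if run_kind != "V":
                close_run()
                run_kind = "V"
                run_start = (ci, cj)
            run_bases.append(s[ci])
            ci += 1
        else:
            if run_kind != "H":
                close_run()
                run_kind = "H"
                run_start = (ci, cj)
            run_bases.append(t[cj])
            cj += 1
    close_run()

    gap_chars = sum(g.length for g in gaps)
    return AlignmentResult(
        s=s,
        t=t,
        epsilon=epsilon,
        # plain-scale DP maximum under the chosen substitution scores
        score=matched + mismatch * mismatched - gap_chars,
        max_i=bi,
        max_j=bj,
        path=path,
        aligned_pairs=aligned_pairs,
        matched_count=matched,
        mismatch_count=mismatched,
        k=min(m, n) - matched,
        gaps=gaps,
    )


def is_local_optimal(result: AlignmentResult, k_max: int = 2) -> bool:
    """Whether the alignment leaves at most ``k_max`` shorter-sequence
    characters unmatched."""
    return result.k <= k_max


def effective_k(result: AlignmentResult) -> int:
    """``k`` with gap-explained characters of the shorter sequence removed.

    ``k`` charges every unmatched character of the shorter sequence, so a
    clean b-base insertion still scores ``k = b`` even though each base is
    accounted for by a gap on the optimal path.  Subtracting the shorter
    sequence's gap-aligned characters leaves only substitutions and
    off-path characters, giving a statistic that treats insertions and
    deletions symmetrically.
    """
    if len(result.s) <= len(result.t):
        explained = result.t_gap_bases  # S characters sitting in T-gaps
    else:
        explained = result.s_gap_bases
    return max(0, result.k - explained)


def format_alignment(result: AlignmentResult) -> str:
    """Render the aligned pair as three gapped lines (debug helper)."""
    if not result.path:
        return "(empty alignment)"
    top: list[str] = []
    mid: list[str] = []
    bot: list[str] = []
    cells = list(reversed(result.path))
    for (pi, pj), (ci, cj) in zip(cells, cells[1:]):
        if ci == pi + 1 and cj == pj + 1:
            a, b = result.s[ci - 1], result.t[cj - 1]
            top.append(a)
            bot.append(b)
            mid.append("|" if a == b else ".")
        elif ci == pi + 1:
            top.append(result.s[ci - 1])
            bot.append("-")
            mid.append(" ")
        else:
            top.append("-")
            bot.append(result.t[cj - 1])
            mid.append(" ")
    return "\n".join(
        [
            f"S {''.join(top)}",
            f"  {''.join(mid)}",
            f"T {''.join(bot)}",
            f"score={result.score} matched={result.matched_count} k={result.k}",
        ]
    )
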