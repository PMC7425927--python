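"""Shared fixtures: small panels and an independent full Smith-Waterman."""

from __future__ import annotations

import pytest

from ampvar import Amplicon, AmpliconPanel


def full_smith_waterman_score(s: str, t: str) -> int:
    """Unbanded local-alignment DP maximum with match 1 / mismatch 0 /
    gap -1 — the independent oracle for the banded implementation."""
    m, n = len(s), len(t)
    d = [[0] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            v = max(
                d[i - 1][j - 1] + (1 if s[i - 1] == t[j - 1] else 0),
                d[i - 1][j] - 1,
                d[i][j - 1] - 1,
                0,
            )
            d[i][j] = v
            if v > best:
                best = v
    return best


# The four example forward primers whose minimal discriminating position
# sets are {3,4}, {3,6}, {4,5} and {5,6}.
EXAMPLE_PRIMERS = ["ACGGGTG", "ACAGCTG", "ACCGATG", "ACCTAGG"]


@pytest.fixture
def example_panel() -> AmpliconPanel:
    """Four-amplicon panel built around the example primer quartet."""
    targets = [
        "TTGACCGTAGGCATCAACGGTTAGACCATTGCAAGGTCAA",
        "GGCATTACCAGTTGACCTAGCATGCCAATTGGCACCATGG",
        "CAGTTAGCCATGGATCCGATTACAGGCTTAAGCCTGGTAC",
        "ATCCGGTTACAGCATGCAATGGCTTACCGGATCAGTTACC",
    ]
    amplicons = [
        Amplicon(
            amplicon_id=f"ex{i + 1}",
            fwd_primer=p,
            rev_primer="GTACCTAG",
            target_seq=targets[i],
            index_seq="ACGTACGT",
        )
        for i, p in enumerate(EXAMPLE_PRIMERS)
    ]
    return AmpliconPanel(amplicons=amplicons, public_seq="TTAACCGGTTAACCGGTTAA")
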