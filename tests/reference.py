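"""Independent oracles used by the test suite.

These are deliberately written as brute-force or naive reference
implementations, structurally unrelated to the package's optimized code
paths: exhaustive alignment enumeration, a plain quadratic Gotoh DP, and
transitive-closure clustering.
"""

from __future__ import annotations

import itertools

from famscape.alphabet import RESIDUES

NEG = float("-inf")


def enumerate_global_score(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Best global alignment score of a vs b by recursive enumeration of all
    monotone alignments, charging gap_open + k*gap_extend per gap run."""

    best = [NEG]

    def rec(i: int, j: int, acc: float, gap_state: int) -> None:
        # gap_state: 0 none, 1 gap consuming b, 2 gap consuming a
        if i == len(a) and j == len(b):
            best[0] = max(best[0], acc)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, acc + score(a[i], b[j]), 0)
        if j < len(b):
            cost = gap_extend if gap_state == 1 else gap_open + gap_extend
            rec(i, j + 1, acc - cost, 1)
        if i < len(a):
            cost = gap_extend if gap_state == 2 else gap_open + gap_extend
            rec(i + 1, j, acc - cost, 2)

    rec(0, 0, 0.0, 0)
    return best[0]


def enumerate_local_score(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Best local alignment score: maximum over every substring pair of the
    enumerated global score, floored at 0 (the empty alignment)."""
    best = 0.0
    for i0, i1 in itertools.combinations(range(len(a) + 1), 2):
        for j0, j1 in itertools.combinations(range(len(b) + 1), 2):
            s = enumerate_global_score(a[i0:i1], b[j0:j1], score, gap_open, gap_extend)
            best = max(best, s)
    return best


def gotoh_local_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Plain-Python quadratic Gotoh local DP (the written-first reference)."""
    idx = {c: i for i, c in enumerate(RESIDUES)}
    go = gap_open + gap_extend
    ge = gap_extend
    m, n = len(a), len(b)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - ge)
            sub = matrix[idx.get(a[i - 1], 20)][idx.get(b[j - 1], 20)]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def transitive_clusters(nodes: list[str], links: set[tuple[str, str]]) -> list[frozenset]:
    """Connected components by repeated transitive closure over a link set."""
    groups = {n: {n} for n in nodes}
    changed = True
    while changed:
        changed = False
        for u, v in links:
            if groups[u] is not groups[v]:
                merged = groups[u] | groups[v]
                for n in merged:
                    groups[n] = merged
                changed = True
    seen = []
    for g in groups.values():
        fg = frozenset(g)
        if fg not in seen:
            seen.append(fg)
    return seen
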