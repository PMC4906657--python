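"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: plain-list dynamic
programs and exhaustive enumeration, correct by inspection at small n.
"""

from __future__ import annotations

from typing import Tuple


def glocal_dp_score(q: str, t: str, match: int = 1, mismatch: int = -1,
                    gap: int = -1) -> int:
    """Unbanded optimum: global in q, free start/end in t, linear gaps."""
    prev = [0] * (len(t) + 1)
    for i in range(1, len(q) + 1):
        cur = [prev[0] + gap] + [0] * len(t)
        for j in range(1, len(t) + 1):
            s = match if q[i - 1] == t[j - 1] else mismatch
            cur[j] = max(prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return max(prev)


def edit_distance_alignment(a: str, b: str) -> Tuple[int, int]:
    """(edit distance, alignment columns of one optimal traceback)."""
    n, m = len(a), len(b)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        D[i][0] = i
    for j in range(m + 1):
        D[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            D[i][j] = min(D[i - 1][j - 1] + cost, D[i - 1][j] + 1,
                          D[i][j - 1] + 1)
    # traceback counting columns
    i, j, cols = n, m, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i][j] == D[i - 1][j - 1] + (
            0 if a[i - 1] == b[j - 1] else 1
        ):
            i, j = i - 1, j - 1
        elif i > 0 and D[i][j] == D[i - 1][j] + 1:
            i -= 1
        else:
            j -= 1
        cols += 1
    return D[n][m], cols


def enumerate_best_path(graph) -> float:
    """Max adjusted-weight score over all source-to-backbone-node paths."""
    best = float("-inf")

    def dfs(node, acc: float) -> None:
        nonlocal best
        if node.anchor >= 0 and node.offset == 0 and acc > best:
            best = acc
        for edge in graph.out_edges(node):
            dfs(edge.dst, acc + edge.adjusted_weight)

    dfs(graph.source, 0.0)
    return best
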