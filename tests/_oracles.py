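"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by the most direct route available —
explicit dictionary counting, textbook formulas, quadratic dynamic
programming, dense grid search — deliberately sharing no code with the
package implementations they check.
"""

from __future__ import annotations

import math
from collections import Counter

MISSING = {"-", "X"}


def nmi_oracle(col_i: str, col_j: str, weights: list[float]) -> float:
    """Weighted normalized mutual information by direct counting (bits)."""
    joint: Counter = Counter()
    total = 0.0
    for a, b, w in zip(col_i, col_j, weights):
        if a in MISSING or b in MISSING:
            continue
        joint[(a, b)] += w
        total += w
    pi: Counter = Counter()
    pj: Counter = Counter()
    for (a, b), w in joint.items():
        pi[a] += w / total
        pj[b] += w / total

    def h(dist):
        return -sum(p * math.log2(p) for p in dist if p > 0)

    hi = h(pi.values())
    hj = h(pj.values())
    hij = h(w / total for w in joint.values())
    mi = hi + hj - hij
    hmin = min(hi, hj)
    return 0.0 if hmin == 0 else mi / hmin


def henikoff_oracle(rows: list[str]) -> list[float]:
    """Position-based weights by the direct per-column 1/(k*n_a) sum."""
    n = len(rows)
    m = len(rows[0])
    raw = [0.0] * n
    for j in range(m):
        col = [r[j] for r in rows]
        counts = Counter(c for c in col if c not in MISSING)
        k = len(counts)
        if k == 0:
            continue
        for i, c in enumerate(col):
            if c not in MISSING:
                raw[i] += 1.0 / (k * counts[c])
    s = sum(raw)
    return [r * n / s for r in raw]


def nw_identity_oracle(a: str, b: str) -> float:
    """Global-alignment identity via an explicit Needleman-Wunsch DP.

    Scoring match 1 / mismatch 0 / linear gap -1; identity = matched
    identical pairs over the shorter sequence's length.  The traceback
    prefers diagonal moves, which is exact for the indel-free test
    sequences this oracle is used on.
    """
    la, lb = len(a), len(b)
    score = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        score[i][0] = -i
    for j in range(1, lb + 1):
        score[0][j] = -j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = score[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else 0)
            score[i][j] = max(diag, score[i - 1][j] - 1, score[i][j - 1] - 1)
    # traceback, diagonal first
    i, j, matches = la, lb, 0
    while i > 0 and j > 0:
        diag = score[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else 0)
        if score[i][j] == diag:
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif score[i][j] == score[i - 1][j] - 1:
            i -= 1
        else:
            j -= 1
    return matches / min(la, lb)


def greedy_cluster_oracle(seqs: list[tuple[str, str]], threshold: float) -> list[str]:
    """Representative ids by longest-first greedy clustering."""
    order = sorted(seqs, key=lambda it: (-len(it[1]), it[0]))
    reps: list[tuple[str, str]] = []
    for sid, s in order:
        for _, r in reps:
            if nw_identity_oracle(s, r) > threshold:
                break
        else:
            reps.append((sid, s))
    return [sid for sid, _ in reps]


def mm_grid_oracle(s, v, km_grid, vmax_grid):
    """(K_M, V_max) minimizing SSE over a dense grid."""
    best = (None, None, float("inf"))
    for km in km_grid:
        for vm in vmax_grid:
            sse = sum((vi - vm * si / (km + si)) ** 2 for si, vi in zip(s, v))
            if sse < best[2]:
                best = (km, vm, sse)
    return best[0], best[1]
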