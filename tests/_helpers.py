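"""Independent oracles for the dynamic-programming aligner.

``enumerate_min_cost`` brute-forces the minimum path cost by exhaustive
enumeration of every admissible monotone path (feasible for curves up to
~8 points); ``textbook_dtw`` is a plain dynamic-time-warping
implementation with the classical (1,1) start and no gap boundary.  Both
are written without reference to the package's DP code so they can serve
as cross-checks.
"""

from __future__ import annotations

import numpy as np


def enumerate_min_cost(x, y, gap_penalty: float,
                       boundary_mode: str = "cumulative") -> float:
    """Minimum cost over all monotone paths ending at (N, M).

    A path is a sequence of 1-based cells advancing each index by 0 or 1
    per step (not both 0), starting on the first row or column; its cost
    is the sum of local distances |x_i - y_j| over its cells plus the
    boundary penalty implied by its start (cumulative mode: P per skipped
    leading residue; constant mode: a flat P for any skipped start).
    """
    x = list(map(float, x))
    y = list(map(float, y))
    n, m = len(x), len(y)
    f = [[abs(xi - yj) for yj in y] for xi in x]

    # minimal local-distance sum over all paths from each admissible start,
    # found by exhaustive depth-first enumeration (penalty-independent)
    def min_sum_from(i0: int, j0: int) -> float:
        best = np.inf
        stack = [(i0, j0, 0.0)]
        while stack:
            i, j, cost = stack.pop()
            cost += f[i - 1][j - 1]
            if i == n and j == m:
                if cost < best:
                    best = cost
                continue
            if i < n and j < m:
                stack.append((i + 1, j + 1, cost))
            if i < n:
                stack.append((i + 1, j, cost))
            if j < m:
                stack.append((i, j + 1, cost))
        return best

    def entry_penalty(i0: int, j0: int) -> float:
        if (i0, j0) == (1, 1):
            return 0.0
        if boundary_mode == "cumulative":
            skipped = (j0 - 1) if i0 == 1 else (i0 - 1)
            return skipped * gap_penalty
        return gap_penalty

    starts = [(1, j) for j in range(1, m + 1)] + [(i, 1) for i in range(2, n + 1)]
    return min(entry_penalty(i, j) + min_sum_from(i, j) for i, j in starts)


def textbook_dtw(x, y) -> float:
    """Classical DTW cost: path constrained to start at (1, 1), no gaps."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    cost = np.full((n + 1, m + 1), np.inf)
    cost[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost[i, j] = (min(cost[i - 1, j - 1], cost[i - 1, j], cost[i, j - 1])
                          + abs(x[i - 1] - y[j - 1]))
    return float(cost[n, m])
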