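"""Dynamic-programming core: cost matrices and minimum-cost warping paths.

The aligner is a dynamic-time-warping variant for disorder curves.  Given
curves x (N residues) and y (M residues), the local distance is
``f[i, j] = |x_i - y_j|`` and the cumulative cost satisfies

    F[i, j] = min(F[i-1, j-1], F[i-1, j], F[i, j-1]) + f[i, j]

over a grid with an extra boundary row and column holding the gap
penalty P.  The boundary acts as an end-gap cost: in the default
``cumulative`` mode ``F[i, 0] = i*P`` and ``F[0, j] = j*P`` with
``F[0, 0] = 0``, so a path that enters the grid at (1, j) pays (j-1)*P
for skipping the first j-1 residues of y.  ``constant`` mode charges a
flat P for any skipped start instead.  The minimum-cost path is recovered
by greedy traceback from (N, M) toward the boundary, ties broken by a
fixed predecessor preference so results are deterministic.

With P large enough (P >= 1 suffices, since local distances never exceed
1) skipping is never profitable and the path starts at (1, 1); for small
P the optimal path may begin at (1, j) or (i, 1).  The terminal cost
F[N, M] is the alignment score; dividing by (N + M) gives a
length-comparable normalized score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .curves import DisorderCurve

__all__ = [
    "AlignmentConfig",
    "CostMatrix",
    "WarpingPath",
    "AlignmentResult",
    "local_distance",
    "build_cost_matrix",
    "traceback",
    "align",
]

_TIE_MOVES = ("diagonal", "vertical", "horizontal")


@dataclass(frozen=True)
class AlignmentConfig:
    """Tunable parameters of the aligner.

    gap_penalty
        Boundary (end-gap) cost P, dimensionless, >= 0.  Default 0.4, an
        intermediate value at which alignment scores have saturated while
        neither high- nor low-similarity pairs dominate the match counts.
    match_threshold
        V_match: two aligned residues with local distance strictly below
        this count as a match.  Default 0.05, the value at which the
        fraction of matches stabilizes.
    tie_break
        Predecessor preference in traceback when cumulative costs tie.
    min_segment_length
        Minimum run of consecutive matched steps reported as a matched
        segment.  Default 3 suppresses single-point highlights.
    boundary_mode
        'cumulative' (F[i,0] = i*P) or 'constant' (F[i,0] = P).
    """

    gap_penalty: float = 0.4
    match_threshold: float = 0.05
    tie_break: tuple[str, ...] = _TIE_MOVES
    min_segment_length: int = 3
    boundary_mode: str = "cumulative"

    def __post_init__(self) -> None:
        if self.gap_penalty < 0:
            raise ValueError("gap_penalty must be >= 0")
        if self.match_threshold < 0:
            raise ValueError("match_threshold must be >= 0")
        if self.min_segment_length < 1:
            raise ValueError("min_segment_length must be >= 1")
        if self.boundary_mode not in ("cumulative", "constant"):
            raise ValueError("boundary_mode must be 'cumulative' or 'constant'")
        if sorted(self.tie_break) != sorted(_TIE_MOVES):
            raise ValueError(f"tie_break must be a permutation of {_TIE_MOVES}")


def local_distance(x: float, y: float) -> float:
    """Distance between two disorder scores: ``|x - y|``."""
    return abs(x - y)


@dataclass(frozen=True)
class CostMatrix:
    """Local distances (N x M) and cumulative costs ((N+1) x (M+1)).

    ``cumulative`` includes the boundary row 0 and column 0; interior cell
    (i, j), 1-based, corresponds to residue pair (x_i, y_j).
    """

    local: np.ndarray
    cumulative: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.local.shape[0]

    @property
    def n_cols(self) -> int:
        return self.local.shape[1]

    @property
    def terminal_cost(self) -> float:
        """F[N, M], the alignment score."""
        return float(self.cumulative[-1, -1])


@dataclass(frozen=True)
class WarpingPath:
    """Monotone sequence of 1-based index pairs (i, j) ending at (N, M).

    Each step advances i by 0 or 1 and j by 0 or 1, never both by 0.  The
    path starts on the first row or column of the grid: at (1, 1) when the
    gap penalty makes end skips unprofitable, otherwise possibly at (1, j)
    or (i, 1) with the skipped prefix charged to the boundary.
    """

    steps: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        steps = tuple((int(i), int(j)) for i, j in self.steps)
        if not steps:
            raise ValueError("a warping path needs at least one step")
        if min(steps[0]) != 1:
            raise ValueError("path must start on the first row or column")
        for (i0, j0), (i1, j1) in zip(steps, steps[1:]):
            if not (0 <= i1 - i0 <= 1 and 0 <= j1 - j0 <= 1 and (i1, j1) != (i0, j0)):
                raise ValueError(f"invalid step {(i0, j0)} -> {(i1, j1)}")
        object.__setattr__(self, "steps", steps)

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)

    def transpose(self) -> "WarpingPath":
        return WarpingPath(tuple((j, i) for i, j in self.steps))


@dataclass(frozen=True)
class AlignmentResult:
    """Everything the aligner reports for one pair of curves."""

    path: WarpingPath
    score: float
    normalized_score: float
    step_distances: np.ndarray
    match_flags: np.ndarray
    segments: tuple
    fraction_matched: float
    n_match: int
    config: AlignmentConfig


def build_cost_matrix(a: DisorderCurve, b: DisorderCurve,
                      config: AlignmentConfig | None = None) -> CostMatrix:
    """Fill the local-distance grid and the cumulative-cost grid.

    The boundary row/column carries the gap penalty per
    ``config.boundary_mode``; interior cells follow the min-of-three
    recurrence, filled row-major.
    """
    config = config or AlignmentConfig()
    x = a.scores
    y = b.scores
    n, m = x.size, y.size
    local = np.abs(x[:, None] - y[None, :])

    p = config.gap_penalty
    cum = [[0.0] * (m + 1) for _ in range(n + 1)]
    if config.boundary_mode == "cumulative":
        for i in range(1, n + 1):
            cum[i][0] = i * p
        for j in range(1, m + 1):
            cum[0][j] = j * p
    else:
        for i in range(1, n + 1):
            cum[i][0] = p
        for j in range(1, m + 1):
            cum[0][j] = p

    # plain-list DP loop: fastest pure-python form for this recurrence
    local_rows = local.tolist()
    for i in range(1, n + 1):
        row = cum[i]
        prev = cum[i - 1]
        frow = local_rows[i - 1]
        for j in range(1, m + 1):
            best = prev[j - 1]
            v = prev[j]
            if v < best:
                best = v
            h = row[j - 1]
            if h < best:
                best = h
            row[j] = best + frow[j - 1]

    return CostMatrix(local=local, cumulative=np.asarray(cum))


def traceback(matrix: CostMatrix, config: AlignmentConfig | None = None) -> WarpingPath:
    """Recover the minimum-cost warping path from the filled cost grid.

    Starting at (N, M), repeatedly move to the predecessor (diagonal,
    vertical or horizontal) with the smallest cumulative cost, preferring
    earlier entries of ``config.tie_break`` on ties, until a boundary cell
    is reached; boundary cells are not part of the returned path, which is
    emitted in forward order.
    """
    config = config or AlignmentConfig()
    cum = matrix.cumulative
    i, j = matrix.n_rows, matrix.n_cols
    steps = [(i, j)]
    while True:
        moves = {
            "diagonal": (i - 1, j - 1),
            "vertical": (i - 1, j),
            "horizontal": (i, j - 1),
        }
        best_cell = None
        best_cost = np.inf
        for name in config.tie_break:
            pi, pj = moves[name]
            cost = cum[pi, pj]
            if cost < best_cost:
                best_cost = cost
                best_cell = (pi, pj)
        i, j = best_cell  # type: ignore[misc]
        if i == 0 or j == 0:
            break
        steps.append((i, j))
    steps.reverse()
    return WarpingPath(tuple(steps))


def align(a: DisorderCurve, b: DisorderCurve,
          config: AlignmentConfig | None = None) -> AlignmentResult:
    """Align two disorder curves and report path, score and match summary.

    The score is the terminal cumulative cost F[N, M]; the normalized
    score divides by (N + M).  Match flags, matched segments and the
    fraction of matches f_M = 2*N_match/(N + M) come from the match
    analysis at ``config.match_threshold``.
    """
    from .matching import flag_matches, fraction_of_matches, matched_segments

    config = config or AlignmentConfig()
    matrix = build_cost_matrix(a, b, config)
    path = traceback(matrix, config)
    dists = np.array([matrix.local[i - 1, j - 1] for i, j in path])
    flags = flag_matches(dists, config.match_threshold)
    segments = tuple(matched_segments(path, dists, config))
    n_match = int(flags.sum())
    f_m = fraction_of_matches(n_match, len(a), len(b))
    score = matrix.terminal_cost
    return AlignmentResult(
        path=path,
        score=score,
        normalized_score=score / (len(a) + len(b)),
        step_distances=dists,
        match_flags=flags,
        segments=segments,
        fraction_matched=f_m,
        n_match=n_match,
        config=config,
    )
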