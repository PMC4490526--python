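"""Parameter-selection sweeps for the gap penalty and the match threshold.

Both tunables are chosen by sweeping a grid over a dataset of curve pairs
and looking for saturation of the swept statistic:

* gap penalty P — the normalized alignment score of every pair is
  non-decreasing in P and saturates once end skips stop paying off; pairs
  split into two sub-groups by how their fraction of matches responds to
  P (low-similarity pairs gain matches with stiffer penalties,
  high-similarity pairs lose them), which argues for an intermediate P.
* match threshold V_match — the warping path does not depend on V_match,
  so each pair is aligned once and its fraction of matches is re-scored
  per threshold; the mean curve rises quickly and then stabilizes.

Because raw magnitudes differ widely between pairs, per-pair curves are
min-max normalized across the grid before averaging, so each pair
contributes its shape rather than its scale; raw values are retained in
``per_pair_values``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .align import AlignmentConfig, align
from .curves import DisorderCurve
from .matching import fraction_of_matches

__all__ = [
    "SweepResult",
    "DEFAULT_GAP_GRID",
    "DEFAULT_MATCH_GRID",
    "sweep_gap_penalty",
    "sweep_match_threshold",
    "select_saturation_point",
    "label_pair_groups",
    "sweep_to_table",
]

DEFAULT_GAP_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
DEFAULT_MATCH_GRID = np.round(np.arange(0.0, 0.2 + 1e-9, 0.01), 10)


@dataclass(frozen=True)
class SweepResult:
    """Outcome of one parameter sweep.

    ``per_pair_values`` holds the raw primary statistic (normalized
    alignment score for the gap sweep, fraction of matches for the
    threshold sweep), one row per pair; ``mean_curve``/``stderr_curve``
    are over the min-max normalized per-pair curves.  The gap sweep also
    records each pair's fraction-of-matches curve, the trend label it
    implies, and per-group mean/stderr curves.
    """

    parameter_name: str
    grid: np.ndarray
    per_pair_values: np.ndarray
    mean_curve: np.ndarray
    stderr_curve: np.ndarray
    selected_value: float
    pair_ids: tuple[str, ...]
    group_labels: tuple[str, ...] | None = None
    per_pair_fractions: np.ndarray | None = None
    group_mean_curves: dict | None = None
    group_stderr_curves: dict | None = None


def _minmax_rows(values: np.ndarray) -> np.ndarray:
    lo = values.min(axis=1, keepdims=True)
    span = values.max(axis=1, keepdims=True) - lo
    out = np.zeros_like(values, dtype=float)
    np.divide(values - lo, span, out=out, where=span > 0)
    return out


def _mean_stderr(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = rows.mean(axis=0)
    if rows.shape[0] > 1:
        stderr = rows.std(axis=0, ddof=1) / np.sqrt(rows.shape[0])
    else:
        stderr = np.zeros_like(mean)
    return mean, stderr


def _check_inputs(pairs, grid) -> np.ndarray:
    if not pairs:
        raise ValueError("at least one curve pair is required")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("parameter grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("parameter grid must be strictly increasing")
    return grid


def _pair_ids(pairs) -> tuple[str, ...]:
    return tuple(f"{a.id}|{b.id}" if (a.id or b.id) else f"pair{k}"
                 for k, (a, b) in enumerate(pairs))


def sweep_gap_penalty(pairs: list[tuple[DisorderCurve, DisorderCurve]],
                      grid: np.ndarray | None = None,
                      config: AlignmentConfig | None = None,
                      epsilon: float = 0.01) -> SweepResult:
    """Align every pair at every gap penalty on the grid.

    Records the normalized alignment score (primary) and the fraction of
    matches per pair and grid point, labels each pair's match-fraction
    trend, and selects the saturation point of the mean normalized-score
    curve.
    """
    config = config or AlignmentConfig()
    grid = _check_inputs(pairs, DEFAULT_GAP_GRID if grid is None else grid)
    scores = np.empty((len(pairs), grid.size))
    fracs = np.empty_like(scores)
    for k, (a, b) in enumerate(pairs):
        for g, p in enumerate(grid):
            res = align(a, b, replace(config, gap_penalty=float(p)))
            scores[k, g] = res.normalized_score
            fracs[k, g] = res.fraction_matched
    mean, stderr = _mean_stderr(_minmax_rows(scores))
    labels = label_pair_groups(fracs, grid)
    norm_fracs = _minmax_rows(fracs)
    group_mean: dict = {}
    group_stderr: dict = {}
    for label in ("increasing", "decreasing"):
        members = norm_fracs[[lab == label for lab in labels]]
        if members.size:
            group_mean[label], group_stderr[label] = _mean_stderr(members)
    return SweepResult(
        parameter_name="gap_penalty",
        grid=grid,
        per_pair_values=scores,
        mean_curve=mean,
        stderr_curve=stderr,
        selected_value=select_saturation_point(mean, grid, epsilon),
        pair_ids=_pair_ids(pairs),
        group_labels=labels,
        per_pair_fractions=fracs,
        group_mean_curves=group_mean,
        group_stderr_curves=group_stderr,
    )


def sweep_match_threshold(pairs: list[tuple[DisorderCurve, DisorderCurve]],
                          grid: np.ndarray | None = None,
                          config: AlignmentConfig | None = None,
                          epsilon: float = 0.01) -> SweepResult:
    """Score the fraction of matches per pair across a threshold grid.

    Each pair is aligned once (the path does not depend on V_match); the
    saturation point of the mean normalized curve is selected.
    """
    config = config or AlignmentConfig()
    grid = _check_inputs(pairs, DEFAULT_MATCH_GRID if grid is None else grid)
    fracs = np.empty((len(pairs), grid.size))
    for k, (a, b) in enumerate(pairs):
        res = align(a, b, config)
        dists = res.step_distances
        for g, v in enumerate(grid):
            fracs[k, g] = fraction_of_matches(int((dists < v).sum()), len(a), len(b))
    mean, stderr = _mean_stderr(_minmax_rows(fracs))
    return SweepResult(
        parameter_name="match_threshold",
        grid=grid,
        per_pair_values=fracs,
        mean_curve=mean,
        stderr_curve=stderr,
        selected_value=select_saturation_point(mean, grid, epsilon),
        pair_ids=_pair_ids(pairs),
    )


def select_saturation_point(mean_curve: np.ndarray, grid: np.ndarray,
                            epsilon: float = 0.01) -> float:
    """Smallest grid value after which the curve stops rising appreciably.

    Returns the first grid value from which every subsequent relative
    increase of the curve is strictly below ``epsilon``; the last grid
    value if the curve never saturates.
    """
    mean_curve = np.asarray(mean_curve, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if mean_curve.size != grid.size:
        raise ValueError("curve and grid must have the same length")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    diffs = np.diff(mean_curve)
    prev = mean_curve[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(prev > 0, diffs / prev,
                       np.where(diffs > 0, np.inf, 0.0))
    # guard the strict comparison against float noise at the boundary
    saturated = rel < epsilon * (1.0 - 1e-9)
    for k in range(grid.size):
        if saturated[k:].all():
            return float(grid[k])
    return float(grid[-1])


def label_pair_groups(per_pair_values: np.ndarray,
                      grid: np.ndarray) -> tuple[str, ...]:
    """Label each pair's trend by the sign of its least-squares slope.

    Slope >= 0 maps to ``"increasing"``, negative to ``"decreasing"``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("at least 2 grid points are needed to fit a trend")
    values = np.atleast_2d(np.asarray(per_pair_values, dtype=float))
    x = grid - grid.mean()
    slopes = values @ x / (x @ x)
    return tuple("increasing" if s >= 0 else "decreasing" for s in slopes)


def sweep_to_table(result: SweepResult) -> pd.DataFrame:
    """Long-format sweep table for plotting.

    Columns: pair_id, parameter, value (grid point), statistic_name,
    statistic (raw value), group_label (empty when not applicable).
    """
    records = []
    primary = ("normalized_score" if result.parameter_name == "gap_penalty"
               else "fraction_of_matches")
    labels = result.group_labels or ("",) * len(result.pair_ids)
    for k, pair_id in enumerate(result.pair_ids):
        for g, value in enumerate(result.grid):
            records.append((pair_id, result.parameter_name, value,
                            primary, result.per_pair_values[k, g], labels[k]))
            if result.per_pair_fractions is not None:
                records.append((pair_id, result.parameter_name, value,
                                "fraction_of_matches",
                                result.per_pair_fractions[k, g], labels[k]))
    return pd.DataFrame.from_records(
        records,
        columns=["pair_id", "parameter", "value",
                 "statistic_name", "statistic", "group_label"],
    )
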