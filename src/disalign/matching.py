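"""Match classification along a warping path and the fraction-of-matches statistic.

A path step whose local distance is strictly below the match threshold
V_match is a matched pair of residues.  The similarity statistic is

    f_M = 2 * N_match / (N1 + N2)

with N_match the number of matched steps and N1, N2 the curve lengths.
Because a warping path can be longer than either curve, f_M can exceed 1
for long paths under a generous threshold; it is reported unclipped.
Maximal runs of consecutive matched steps of at least
``min_segment_length`` steps are reported as matched segments — the
regions highlighted on stretched/aligned curve plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AlignmentConfig, WarpingPath

__all__ = [
    "MatchedSegment",
    "flag_matches",
    "fraction_of_matches",
    "matched_segments",
]


@dataclass(frozen=True)
class MatchedSegment:
    """A contiguous run of matched path steps.

    Residue ranges are 1-based inclusive on each curve; ``step_start`` and
    ``step_end`` are 0-based indices into the warping path.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    n_steps: int
    mean_distance: float
    step_start: int
    step_end: int


def flag_matches(step_distances: np.ndarray, v_match: float) -> np.ndarray:
    """Per-step match flags: distance strictly less than ``v_match``."""
    if v_match < 0:
        raise ValueError("v_match must be >= 0")
    return np.asarray(step_distances) < v_match


def fraction_of_matches(n_match: int, n1: int, n2: int) -> float:
    """f_M = 2 * N_match / (N1 + N2), unclipped."""
    if n_match < 0:
        raise ValueError("n_match must be >= 0")
    return 2.0 * n_match / (n1 + n2)


def matched_segments(path: WarpingPath, step_distances: np.ndarray,
                     config: AlignmentConfig | None = None) -> list[MatchedSegment]:
    """Group matched steps into maximal runs of length >= min_segment_length.

    Segments are returned in path order and are non-overlapping; each
    carries its residue ranges on both curves and the mean local distance
    over its steps.
    """
    config = config or AlignmentConfig()
    flags = flag_matches(step_distances, config.match_threshold)
    steps = path.steps
    segments: list[MatchedSegment] = []
    run_start: int | None = None
    for k in range(len(flags) + 1):
        flagged = k < len(flags) and bool(flags[k])
        if flagged and run_start is None:
            run_start = k
        elif not flagged and run_start is not None:
            run_end = k - 1
            n_steps = run_end - run_start + 1
            if n_steps >= config.min_segment_length:
                segments.append(MatchedSegment(
                    a_start=steps[run_start][0],
                    a_end=steps[run_end][0],
                    b_start=steps[run_start][1],
                    b_end=steps[run_end][1],
                    n_steps=n_steps,
                    mean_distance=float(np.mean(step_distances[run_start:k])),
                    step_start=run_start,
                    step_end=run_end,
                ))
            run_start = None
    return segments
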