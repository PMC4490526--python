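"""Plot-ready tables: cost-matrix contour grid and stretched/aligned curves.

Rendering (colors, contour levels) is deliberately out of scope; these
functions guarantee the data a plotting layer needs.  All tables are
pandas DataFrames written as tab-separated text with headers.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .align import AlignmentResult, CostMatrix, WarpingPath
from .curves import DisorderCurve, GAP_SENTINEL
from .matching import MatchedSegment

__all__ = [
    "export_contour_grid",
    "export_aligned_curves",
    "segments_table",
    "write_table",
]


def export_contour_grid(matrix: CostMatrix, path: WarpingPath) -> pd.DataFrame:
    """Long-format cumulative-cost grid with the warping path marked.

    One row per interior cell: columns ``i``, ``j`` (1-based),
    ``cumulative_cost`` and ``on_path``.  Suitable for contour rendering
    with the minimum-cost path overlaid.
    """
    n, m = matrix.n_rows, matrix.n_cols
    ii, jj = np.meshgrid(np.arange(1, n + 1), np.arange(1, m + 1), indexing="ij")
    on_path = np.zeros((n, m), dtype=bool)
    for i, j in path:
        on_path[i - 1, j - 1] = True
    return pd.DataFrame({
        "i": ii.ravel(),
        "j": jj.ravel(),
        "cumulative_cost": matrix.cumulative[1:, 1:].ravel(),
        "on_path": on_path.ravel(),
    })


def export_aligned_curves(result: AlignmentResult,
                          a: DisorderCurve,
                          b: DisorderCurve) -> pd.DataFrame:
    """The stretched/aligned dual-curve table with highlight flags.

    One row per path step: ``step_index`` (1-based), ``score_a`` and
    ``score_b`` (the gap sentinel -1 on the side whose index stalled),
    ``local_distance`` (NaN on gap rows), ``is_match`` and ``segment_id``
    (1-based id of the matched segment containing the step, 0 when
    unhighlighted).
    """
    steps = result.path.steps
    length = len(steps)
    score_a = np.empty(length)
    score_b = np.empty(length)
    dist = np.array(result.step_distances, dtype=float)
    prev = None
    for k, (i, j) in enumerate(steps):
        score_a[k] = a.scores[i - 1]
        score_b[k] = b.scores[j - 1]
        if prev is not None:
            if i == prev[0]:
                score_a[k] = GAP_SENTINEL
                dist[k] = np.nan
            if j == prev[1]:
                score_b[k] = GAP_SENTINEL
                dist[k] = np.nan
        prev = (i, j)
    segment_id = np.zeros(length, dtype=int)
    for sid, seg in enumerate(result.segments, start=1):
        segment_id[seg.step_start:seg.step_end + 1] = sid
    return pd.DataFrame({
        "step_index": np.arange(1, length + 1),
        "score_a": score_a,
        "score_b": score_b,
        "local_distance": dist,
        "is_match": np.asarray(result.match_flags, dtype=bool),
        "segment_id": segment_id,
    })


def segments_table(segments: Iterable[MatchedSegment]) -> pd.DataFrame:
    """Matched segments as a table of residue ranges and mean distances."""
    return pd.DataFrame.from_records(
        [(s.a_start, s.a_end, s.b_start, s.b_end, s.n_steps, s.mean_distance)
         for s in segments],
        columns=["a_start", "a_end", "b_start", "b_end",
                 "n_steps", "mean_distance"],
    )


def write_table(table: pd.DataFrame, sink: str | os.PathLike | IO[str]) -> None:
    """Write a table as tab-separated text with a header row."""
    if isinstance(sink, (str, os.PathLike)):
        table.to_csv(Path(sink), sep="\t", index=False)
    else:
        table.to_csv(sink, sep="\t", index=False)
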