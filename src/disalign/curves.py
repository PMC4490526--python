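"""Disorder-curve container and the plain-text input/output formats.

A disorder curve is the per-residue output of an intrinsic-disorder
predictor (PONDR-FIT, IUPred, ...): one propensity value in [0, 1] per
residue, plotted against sequence position.  Predictors are never invoked
here; their scores are opaque inputs.  Two input modes are supported,
matching common practice for such score lists: a single-column text file
(one score per line) and a comma-delimited string.  The aligned output is
a headerless three-column table — sequential index after alignment, score
of curve A, score of curve B — where ``-1`` marks the side of the pair
whose residue index did not advance at that alignment step (a gap in the
stretched curve).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .align import AlignmentResult

__all__ = [
    "DisorderCurve",
    "CurveParseError",
    "CurveValidationError",
    "read_single_column",
    "read_comma_delimited",
    "write_single_column",
    "write_aligned_table",
    "read_aligned_table",
    "GAP_SENTINEL",
]

#: Sentinel written in place of a score when one curve's index stalls.
GAP_SENTINEL = -1.0


class CurveParseError(ValueError):
    """A token or line could not be parsed as a numeric disorder score."""


class CurveValidationError(ValueError):
    """Parsed values violate the disorder-curve invariants."""


@dataclass(frozen=True)
class DisorderCurve:
    """Per-residue disorder scores of one protein.

    Parameters
    ----------
    scores
        Ordered per-residue disorder propensities, each in [0, 1].
        At least two residues are required (a single point cannot be
        aligned).
    id
        Free-text identifier, e.g. a UniProt accession or file name.
    """

    scores: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 1:
            raise CurveValidationError("scores must be a one-dimensional sequence")
        if scores.size < 2:
            raise CurveValidationError(
                f"curve {self.id!r}: at least 2 scores are required, got {scores.size}"
            )
        if not np.all(np.isfinite(scores)):
            raise CurveValidationError(f"curve {self.id!r}: scores must be finite")
        if scores.min() < 0.0 or scores.max() > 1.0:
            bad = scores[(scores < 0.0) | (scores > 1.0)][0]
            raise CurveValidationError(
                f"curve {self.id!r}: score {bad!r} outside [0, 1]; "
                "disorder scores are not clamped — check the input file"
            )
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return int(self.scores.size)

    @property
    def length(self) -> int:
        """Residue count."""
        return len(self)


def _parse_score(token: str, where: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise CurveParseError(f"{where}: {token!r} is not a number") from None


def read_single_column(source: str | os.PathLike | IO[str] | Iterable[str],
                       id: str | None = None) -> DisorderCurve:
    """Read a curve from single-column text: one score per line.

    Blank lines and surrounding whitespace are ignored.  ``source`` may be
    a path, an open text stream, or any iterable of lines.  The curve id
    defaults to the file name when a path is given.
    """
    close = False
    name = id
    if isinstance(source, (str, os.PathLike)):
        path = Path(source)
        if name is None:
            name = path.name
        handle: Iterable[str] = path.open("r", encoding="utf-8")
        close = True
    else:
        handle = source
        if name is None:
            name = getattr(source, "name", "<stream>")
    try:
        values = []
        for lineno, line in enumerate(handle, start=1):
            text = line.strip()
            if not text:
                continue
            values.append(_parse_score(text, f"{name}, line {lineno}"))
    finally:
        if close:
            handle.close()  # type: ignore[union-attr]
    if len(values) < 2:
        raise CurveValidationError(
            f"{name}: at least 2 scores are required, got {len(values)}"
        )
    return DisorderCurve(np.array(values), id=str(name))


def read_comma_delimited(text: str, id: str = "inline") -> DisorderCurve:
    """Read a curve from a comma-delimited string of scores.

    Whitespace around tokens is ignored and a trailing comma is tolerated;
    an empty token anywhere else is a parse error.
    """
    tokens = [t.strip() for t in text.split(",")]
    if tokens and tokens[-1] == "":
        tokens.pop()
    values = []
    for pos, token in enumerate(tokens, start=1):
        if token == "":
            raise CurveParseError(f"{id}: empty token at position {pos}")
        values.append(_parse_score(token, f"{id}, token {pos}"))
    if len(values) < 2:
        raise CurveValidationError(
            f"{id}: at least 2 scores are required, got {len(values)}"
        )
    return DisorderCurve(np.array(values), id=id)


def write_single_column(curve: DisorderCurve,
                        sink: str | os.PathLike | IO[str]) -> None:
    """Write a curve in the single-column input format (one score per line)."""
    lines = "".join(f"{s:.6f}\n" for s in curve.scores)
    if isinstance(sink, (str, os.PathLike)):
        Path(sink).write_text(lines, encoding="utf-8")
    else:
        sink.write(lines)


def write_aligned_table(result: "AlignmentResult",
                        a: DisorderCurve,
                        b: DisorderCurve,
                        sink: str | os.PathLike | IO[str]) -> None:
    """Write the three-column aligned output for an alignment of ``a`` and ``b``.

    One tab-separated row per warping-path step: a 1-based consecutive step
    index, then the two aligned scores printed with three decimals.  At a
    non-diagonal step the curve whose residue index did not advance is
    written as ``-1``; on the very first step both scores are written.
    """
    rows = []
    prev_i = prev_j = None
    for step, (i, j) in enumerate(result.path.steps, start=1):
        sa: str = f"{a.scores[i - 1]:.3f}"
        sb: str = f"{b.scores[j - 1]:.3f}"
        if prev_i is not None:
            if i == prev_i:
                sa = "-1"
            if j == prev_j:
                sb = "-1"
        rows.append(f"{step}\t{sa}\t{sb}\n")
        prev_i, prev_j = i, j
    text = "".join(rows)
    if isinstance(sink, (str, os.PathLike)):
        Path(sink).write_text(text, encoding="utf-8")
    else:
        sink.write(text)


def read_aligned_table(source: str | os.PathLike | IO[str]) -> np.ndarray:
    """Parse a three-column aligned table back into an (L, 3) float array.

    Column 0 holds the step index, columns 1 and 2 the aligned scores with
    ``-1`` gap sentinels preserved.
    """
    if isinstance(source, (str, os.PathLike)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise CurveParseError(f"line {lineno}: expected 3 columns, got {len(parts)}")
        rows.append([_parse_score(p, f"line {lineno}") for p in parts])
    return np.array(rows, dtype=float).reshape(-1, 3)
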