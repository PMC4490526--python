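"""Synthetic disorder curves: bounded, smooth, autocorrelated series in [0, 1].

Real disorder predictors score each residue from its sequence
neighbourhood (sliding windows of roughly 20-30 residues), so their
output is a bounded, strongly autocorrelated curve.  The generator
emulates that shape with a Gaussian-step random walk reflected into
[0, 1] and smoothed by a moving average; it makes no attempt to model any
particular predictor's error structure.  Pairs with a planted shared
motif — the identical score segment spliced into two independent
backgrounds — give ground truth for match-recovery tests: the planted
coordinates are returned alongside the curves.

Defaults mirror the study conditions the tool targets: protein lengths of
100-400 residues and a smoothing window of 21 residues (the middle of the
20-30 residue predictor-window range).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import DisorderCurve

__all__ = [
    "Motif",
    "SyntheticPairSpec",
    "generate_curve",
    "random_motif",
    "generate_related_pair",
    "generate_pair_set",
    "write_curve_pairs",
]

DEFAULT_SMOOTHNESS = 21
DEFAULT_LENGTH_RANGE = (100, 400)
_STEP_SD = 0.06


@dataclass(frozen=True)
class Motif:
    """A shared score segment and its 1-based insertion positions."""

    scores: np.ndarray
    a_insert_at: int
    b_insert_at: int

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.size < 1 or scores.min() < 0 or scores.max() > 1:
            raise ValueError("motif scores must be a non-empty sequence in [0, 1]")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return int(self.scores.size)


@dataclass(frozen=True)
class SyntheticPairSpec:
    """Recipe for one synthetic curve pair.

    ``noise_sd`` is the standard deviation of the independent Gaussian
    perturbation added to both curves after any motif insertion (then
    clipped back to [0, 1]); 0 leaves the planted motif windows exactly
    equal on the two curves.
    """

    length_a: int
    length_b: int
    smoothness: int = DEFAULT_SMOOTHNESS
    motif: Motif | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_a < 2 or self.length_b < 2:
            raise ValueError("curve lengths must be >= 2")
        if self.smoothness < 1:
            raise ValueError("smoothness must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.motif is not None:
            m = len(self.motif)
            if not (1 <= self.motif.a_insert_at and
                    self.motif.a_insert_at + m - 1 <= self.length_a):
                raise ValueError("motif does not fit inside curve a")
            if not (1 <= self.motif.b_insert_at and
                    self.motif.b_insert_at + m - 1 <= self.length_b):
                raise ValueError("motif does not fit inside curve b")


def _reflect_unit(values: np.ndarray) -> np.ndarray:
    """Fold arbitrary reals into [0, 1] by reflection at the boundaries."""
    m = np.mod(values, 2.0)
    return np.where(m > 1.0, 2.0 - m, m)


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    window = min(window, values.size)
    pad_left = window // 2
    pad_right = window - 1 - pad_left
    padded = np.pad(values, (pad_left, pad_right), mode="reflect")
    return np.convolve(padded, np.full(window, 1.0 / window), mode="valid")


def _raw_curve(length: int, smoothness: int, rng: np.random.Generator) -> np.ndarray:
    start = rng.uniform(0.25, 0.75)
    walk = start + np.concatenate([[0.0], np.cumsum(rng.normal(0.0, _STEP_SD, length - 1))])
    return np.clip(_smooth(_reflect_unit(walk), smoothness), 0.0, 1.0)


def generate_curve(length: int, smoothness: int = DEFAULT_SMOOTHNESS,
                   seed: int | np.random.Generator = 0,
                   id: str = "synthetic") -> DisorderCurve:
    """Generate one synthetic disorder curve.

    A reflected Gaussian random walk in [0, 1], moving-average smoothed
    with the given window; deterministic for a given integer seed.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return DisorderCurve(_raw_curve(length, smoothness, rng), id=id)


def random_motif(length: int, a_insert_at: int, b_insert_at: int,
                 smoothness: int = 3,
                 seed: int | np.random.Generator = 0,
                 score_range: tuple[float, float] = (0.1, 0.9)) -> Motif:
    """A random distinctive motif segment with its insertion positions.

    The segment is a smooth random curve rescaled to span ``score_range``,
    so it carries the pronounced peak/dip structure of real shared
    disorder features (e.g. a structure-prone dip inside a disordered
    region) rather than blending into the low-amplitude background.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = _raw_curve(max(length, 2), smoothness, rng)[:length]
    lo, hi = score_range
    span = raw.max() - raw.min()
    if span > 0:
        scores = lo + (hi - lo) * (raw - raw.min()) / span
    else:
        scores = np.full(length, (lo + hi) / 2.0)
    return Motif(scores=scores, a_insert_at=a_insert_at, b_insert_at=b_insert_at)


def generate_related_pair(spec: SyntheticPairSpec,
                          ids: tuple[str, str] = ("synthetic_a", "synthetic_b"),
                          ) -> tuple[DisorderCurve, DisorderCurve,
                                     tuple[int, int, int, int] | None]:
    """Generate a curve pair, optionally sharing a planted motif.

    Returns the two curves and the planted coordinates
    ``(a_start, a_end, b_start, b_end)`` (1-based inclusive), or ``None``
    when no motif was requested.
    """
    rng_a, rng_b, rng_noise = np.random.default_rng(spec.seed).spawn(3)
    a = _raw_curve(spec.length_a, spec.smoothness, rng_a)
    b = _raw_curve(spec.length_b, spec.smoothness, rng_b)
    planted = None
    if spec.motif is not None:
        m = len(spec.motif)
        ia, ib = spec.motif.a_insert_at, spec.motif.b_insert_at
        a[ia - 1:ia - 1 + m] = spec.motif.scores
        b[ib - 1:ib - 1 + m] = spec.motif.scores
        planted = (ia, ia + m - 1, ib, ib + m - 1)
    if spec.noise_sd > 0:
        a = np.clip(a + rng_noise.normal(0.0, spec.noise_sd, a.size), 0.0, 1.0)
        b = np.clip(b + rng_noise.normal(0.0, spec.noise_sd, b.size), 0.0, 1.0)
    return (DisorderCurve(a, id=ids[0]), DisorderCurve(b, id=ids[1]), planted)


def generate_pair_set(n_pairs: int, seed: int = 0,
                      length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
                      smoothness: int = DEFAULT_SMOOTHNESS,
                      related_fraction: float = 0.5,
                      motif_length: int = 25,
                      noise_sd: float = 0.02,
                      ) -> list[tuple[DisorderCurve, DisorderCurve]]:
    """A mixed dataset of unrelated and motif-sharing curve pairs.

    The first ``round(related_fraction * n_pairs)`` pairs carry a planted
    motif (high curve similarity); the rest are independent backgrounds
    (low similarity).  Used by the parameter sweeps, which expect both
    kinds of pairs to be present.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    n_related = round(related_fraction * n_pairs)
    pairs = []
    for k in range(n_pairs):
        la, lb = rng.integers(length_range[0], length_range[1] + 1, size=2)
        motif = None
        if k < n_related:
            # homolog-like placement: a common relative position plus a
            # small shift, as for shared features of related proteins
            r = rng.uniform(0.0, 1.0)
            jitter = int(rng.integers(-5, 6))
            ia = 1 + round(r * (la - motif_length))
            ib = min(max(1 + round(r * (lb - motif_length)) + jitter, 1),
                     int(lb) - motif_length + 1)
            motif = random_motif(motif_length, int(ia), int(ib),
                                 seed=int(rng.integers(2 ** 31)))
        spec = SyntheticPairSpec(length_a=int(la), length_b=int(lb),
                                 smoothness=smoothness, motif=motif,
                                 noise_sd=noise_sd,
                                 seed=int(rng.integers(2 ** 31)))
        a, b, _ = generate_related_pair(spec, ids=(f"pair{k}_a", f"pair{k}_b"))
        pairs.append((a, b))
    return pairs


def write_curve_pairs(pairs, outdir) -> None:
    """Write pairs as single-column score files plus a pair list.

    Each curve goes to ``pairNNN_a.txt`` / ``pairNNN_b.txt`` in the
    single-column input format; ``pairs.tsv`` lists the two file names of
    each pair, tab-separated, ready for the sweep commands.
    """
    from pathlib import Path

    from .curves import write_single_column

    outdir = Path(outdir)
    lines = []
    for k, (a, b) in enumerate(pairs):
        name_a = f"pair{k:03d}_a.txt"
        name_b = f"pair{k:03d}_b.txt"
        write_single_column(a, outdir / name_a)
        write_single_column(b, outdir / name_b)
        lines.append(f"{name_a}\t{name_b}\n")
    (outdir / "pairs.tsv").write_text("".join(lines), encoding="utf-8")
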