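# disalign

Dynamic-programming alignment of protein **disorder curves** — the
per-residue intrinsic-disorder score profiles produced by predictors
such as PONDR-FIT or IUPred.

Many intrinsically disordered proteins share characteristic patterns in
their disorder curves (double peaks, MoRF-like dips) even when their
sequences have little in common, and those shared patterns often point
to shared function or origin. `disalign` finds them: it aligns two
curves with a dynamic-time-warping-style algorithm, reports the
minimum-cost warping path, highlights *matched segments* of similar
flexibility, and summarizes similarity as the **fraction of matches**

    f_M = 2 · N_match / (N₁ + N₂)

where a step of the warping path counts as a match when its local
distance |x_i − y_j| falls below the match threshold V_match. The
cumulative cost follows the standard min-of-three DTW recurrence with a
gap penalty P on the boundary row/column acting as an end-gap cost:

    F[i, j] = min(F[i−1, j−1], F[i−1, j], F[i, j−1]) + |x_i − y_j|

Defaults (P = 0.4, V_match = 0.05) are the saturation points of the
built-in parameter sweeps; see `docs/methods.md` for the model, the
boundary modes, and known limitations.

Audience: anyone comparing disorder profiles — curves from any predictor
work, supplied as plain text. Disorder prediction itself is out of
scope.

## Worked example

Align a 3-residue curve against a 2-residue curve from the shell:

```sh
disalign align --inline-a "0.1,0.9,0.2" --inline-b "0.1,0.2" \
    --min-segment-length 1 --outdir demo
```

prints

```
score 0.700
normalized_score 0.140
fraction_matched 0.800
```

The score 0.700 is the terminal cumulative cost F[3, 2]: the optimal
warping path (1,1) → (2,2) → (3,2) pays |0.9 − 0.2| = 0.7 at its middle
step and 0 elsewhere. Two of its three steps lie below V_match = 0.05,
so f_M = 2·2/(3+2) = 0.800. `demo/aligned.tsv` holds the three-column
web-style output — step index, score of curve A, score of curve B, with
`-1` marking the side whose residue index stalled at a non-diagonal
step:

```
1	0.100	0.100
2	0.900	0.200
3	0.200	-1
```

`demo/` also receives the matched-segment table, the cost-matrix contour
grid with the path flagged (`contour.tsv`), the stretched/aligned
dual-curve table with highlight flags (`aligned_curves.tsv`), and a JSON
summary. Curve files in single-column format (one score per line) are
accepted via `--scores-a/--scores-b`.

The same from Python:

```python
import numpy as np
from disalign import DisorderCurve, AlignmentConfig, align

a = DisorderCurve(np.array([0.1, 0.9, 0.2]), id="A")
b = DisorderCurve(np.array([0.1, 0.2]), id="B")
res = align(a, b, AlignmentConfig(min_segment_length=1))
res.score, res.path.steps, res.fraction_matched
# (0.7, ((1, 1), (2, 2), (3, 2)), 0.8)
```

Parameter calibration over a dataset (here synthetic pairs from the
built-in generator):

```sh
disalign sweep-gap   --simulate 20 --seed 1 --outdir sweep_gap
disalign sweep-match --simulate 20 --seed 1 --outdir sweep_match
```

Each writes a long-format `sweep.tsv` (per pair, per grid value, per
statistic, with increasing/decreasing trend labels in the gap sweep) and
the selected saturation value.

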