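# Methods

## The model

`disalign` compares the structural flexibility of two proteins through
their *disorder curves*: the per-residue intrinsic-disorder propensities
produced by any disorder predictor (PONDR-FIT, IUPred, ...), each value
in [0, 1]. The predictors themselves are never invoked; curves are
opaque inputs.

Given curves x = (x_1, ..., x_N) and y = (y_1, ..., y_M), the aligner is
a dynamic-time-warping (DTW) variant. The local distance between two
residues is

    f[i, j] = |x_i − y_j|,

and the cumulative cost satisfies the standard min-of-three recurrence

    F[i, j] = min(F[i−1, j−1], F[i−1, j], F[i, j−1]) + f[i, j]

over an (N+1) × (M+1) grid whose boundary row and column carry a gap
penalty P. The alignment score is F[N, M]; the *normalized score*
divides by (N + M) so pairs of different sizes are comparable. The
minimum-cost warping path is recovered by greedy traceback from (N, M),
choosing at each cell the predecessor with the smallest cumulative cost.

The warping path induces per-step distances f along the path. Steps with
distance strictly below the match threshold V_match are *matches*; the
similarity statistic is the fraction of matches

    f_M = 2 · N_match / (N_1 + N_2).

Maximal runs of at least `min_segment_length` consecutive matched steps
are reported as *matched segments* — the stretches of similar disorder
patterning that the stretched/aligned curve plots highlight.

## Gap-penalty boundary and its consequences

Two boundary modes are provided:

* `cumulative` (default): F[i, 0] = i·P, F[0, j] = j·P, F[0, 0] = 0. A
  path entering the interior at (1, j) pays (j−1)·P for skipping the
  first j−1 residues of y — a per-residue end-gap cost, analogous to
  Needleman–Wunsch end gaps.
* `constant`: F[i, 0] = F[0, j] = P — a flat charge for any skipped
  start.

Because boundary cells are legitimate traceback predecessors for cells
in the first interior row/column, the optimal path *may start off
(1, 1)* when P is small: a prefix of one curve is left unaligned at
boundary cost. For P ≥ 1 this can never pay (each skipped residue costs
P ≥ 1 while aligning it costs at most 1, the maximum local distance), so
the path then provably starts at (1, 1), spans both curves, and the
score equals the classical DTW cost. At P = 0 skips are free and the
aligner behaves as open-beginning DTW. This behavior is deliberate: the
score's monotone, saturating response to P (end skips priced out as P
grows) is exactly what the gap-penalty sweep exploits, and it is why the
default P sits at an intermediate value.

Consequence for the three-column output: the −1 sentinels per column
count the path steps on which that curve's index stalled; they equal
(L − N) and (L − M) (L the path length) whenever the path spans both
curves — always true for P ≥ 1, and typically but not universally true
at the default P = 0.4.

## Defaults and what they mean

| parameter            | default      | meaning |
|----------------------|--------------|---------|
| `gap_penalty` P      | 0.4          | end-gap cost per skipped residue (cumulative mode); dimensionless, on the scale of disorder-score distances. An intermediate value: large enough that scores have saturated, small enough not to favor either of the two pair sub-groups the gap sweep exposes. |
| `match_threshold` V  | 0.05         | per-step distance below which two residues match (strict `<`); the value at which the fraction of matches stabilizes in the threshold sweep. |
| `min_segment_length` | 3 steps      | suppresses single-point highlights in the segment report. |
| `tie_break`          | diagonal, vertical, horizontal | deterministic traceback when predecessor costs tie. |
| `boundary_mode`      | cumulative   | see above. |

The recurrence is read with *cumulative* predecessors (F, not f): a min
over bare local distances cannot propagate cost and does not produce a
usable alignment.

f_M is reported unclipped. A warping path can be longer than both
curves, so with a generous V_match the statistic can exceed 1; clipping
would hide that the path stalled extensively.

## Parameter sweeps

Both tunables are calibrated by sweeping a grid over a dataset of curve
pairs (default grids: P ∈ 0..1 step 0.1, V_match ∈ 0..0.2 step 0.01):

* The per-pair normalized score is non-decreasing in P (each admissible
  path's cost is pointwise non-decreasing in P, hence so is the minimum)
  and constant beyond some P*. The selected value is the *saturation
  point*: the smallest grid value after which every relative increase of
  the mean curve is below `epsilon` (default 1%).
* V_match does not change the path, so each pair is aligned once and
  f_M is re-scored per threshold; the mean curve rises fast and then
  stabilizes.

Per-pair curves are min–max normalized across the grid before averaging
(pairs differ widely in magnitude; normalization averages shapes, not
scales); raw values are retained alongside. For the gap sweep each pair
is labeled `increasing`/`decreasing` by the sign of the least-squares
slope of its f_M-versus-P curve (slope 0 ties to `increasing`), and
group-conditional mean/stderr curves are reported — low-similarity pairs
tend to gain matches as P stiffens, high-similarity pairs to lose them,
which is the argument for an intermediate default P.

## Synthetic data

The generator emulates predictor output shape only: a Gaussian-step
random walk (step s.d. 0.06) reflected into [0, 1], then moving-average
smoothed (window 21 residues, the middle of the 20–30-residue windows
typical of disorder predictors) and clipped. Default protein lengths are
100–400 residues, the size band the tool targets. All randomness flows
from a single integer seed through `numpy.random.Generator`.

Related pairs splice an identical motif segment into two independently
generated backgrounds and optionally add independent Gaussian noise
(default s.d. 0.02, clipped). Motifs are rescaled to span [0.1, 0.9]
because a shared disorder feature (a MoRF-like dip, a double peak) is by
nature a pronounced excursion; a segment statistically identical to the
background would not be a recognizable feature. Placement is
homolog-like: a common relative sequence position ± up to 5 residues.

What the generator does **not** model: predictor error bands, long-range
interaction effects on scores, compositional biases, or any correlation
between the two backgrounds away from the motif. Tests passing on this
synthetic data show the algorithm's internal correctness and its
qualitative parameter responses; they do not certify recovery rates on
real predictor output.

## Known limitations

* **Global, end-anchored alignment.** The path runs border to border;
  there is no subsequence (local) alignment mode and no band constraint.
  A shared motif between otherwise *unrelated* curves is recovered fully
  only when the path's natural position at the motif already sits near
  the motif's diagonal: between independent backgrounds the warping
  offset at an interior position is a diffusive random quantity (median
  ≈ 35 residues for 150–250-residue backgrounds), and the monotone path
  can only merge into the motif's zero-cost corridor by stalling, losing
  roughly min(offset, motif length) matched cells. Measured on
  independent-background pairs with a 25-residue motif, ≥ 80% of the
  motif window is recovered in roughly half of the seeds. Between
  mutually similar (homologous) curves — the intended use case — the
  surrounding alignment carries the path to the feature.
* The DP fill is O(N·M) in pure Python; ~400×400 curves align in tens of
  milliseconds, comfortably covering the targeted length band.
* No statistical significance is attached to f_M or to segments; no
  null model is defined.
* Scores outside [0, 1] are rejected rather than clamped: disorder
  predictors emit [0, 1], so out-of-range values indicate a wrong file.

## Numerical choices

* Traceback ties broken diagonal → vertical → horizontal, fixed, so all
  outputs are deterministic; a transpose-consistent tie-break (vertical
  and horizontal swapped) makes the path of (b, a) the exact transpose
  of the path of (a, b).
* The saturation rule guards its strict comparison with a 1e-9 relative
  margin so decimal grid arithmetic cannot flip a boundary case.
* Aligned-table scores are printed with 3 decimals; round-trip tests
  compare at that precision. Degenerate inputs (fewer than 2 scores) are
  rejected at parse time.
* Problem sizes in the test-suite and acceptance computations (hundreds
  of pairs at lengths up to a few hundred residues; exhaustive path
  enumeration up to length 7) were chosen to give tight checks at
  interactive runtimes.
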