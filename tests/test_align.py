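"""Dynamic-programming core: cost matrices, traceback, alignment invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disalign import (
    AlignmentConfig,
    DisorderCurve,
    WarpingPath,
    align,
    build_cost_matrix,
    generate_curve,
    local_distance,
    traceback,
)

from _helpers import enumerate_min_cost, textbook_dtw

unit_scores = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
small_curves = st.lists(unit_scores, min_size=2, max_size=6).map(
    lambda v: DisorderCurve(np.array(v)))


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"gap_penalty": -0.1},
        {"match_threshold": -1},
        {"min_segment_length": 0},
        {"boundary_mode": "banded"},
        {"tie_break": ("diagonal", "diagonal", "vertical")},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AlignmentConfig(**kwargs)

    def test_defaults(self):
        config = AlignmentConfig()
        assert config.gap_penalty == 0.4
        assert config.match_threshold == 0.05
        assert config.min_segment_length == 3
        assert config.boundary_mode == "cumulative"


@pytest.mark.parametrize("x,y,expected", [
    (0.5, 0.5, 0.0),
    (0.9, 0.2, 0.7),
    (0.2, 0.9, 0.7),
])
def test_local_distance_is_absolute_difference(x, y, expected):
    assert local_distance(x, y) == pytest.approx(expected)


class TestCostMatrix:
    def test_worked_pair_cumulative_grid(self, worked_pair):
        a, b = worked_pair
        m = build_cost_matrix(a, b, AlignmentConfig(gap_penalty=0.4))
        assert m.cumulative[0].tolist() == pytest.approx([0.0, 0.4, 0.8])
        assert m.cumulative[:, 0].tolist() == pytest.approx([0.0, 0.4, 0.8, 1.2])
        assert m.terminal_cost == pytest.approx(0.7)

    def test_constant_boundary_mode(self, worked_pair):
        a, b = worked_pair
        m = build_cost_matrix(
            a, b, AlignmentConfig(gap_penalty=0.4, boundary_mode="constant"))
        assert m.cumulative[0].tolist() == pytest.approx([0.0, 0.4, 0.4])
        assert m.cumulative[:, 0].tolist() == pytest.approx([0.0, 0.4, 0.4, 0.4])

    def test_identical_curves_cost_zero_for_any_penalty(self):
        c = DisorderCurve(np.array([0.5, 0.5]))
        for p in (0.0, 0.4, 5.0):
            m = build_cost_matrix(c, c, AlignmentConfig(gap_penalty=p))
            assert m.terminal_cost == 0.0

    def test_interior_cells_dominate_their_min_predecessor(self, random_curve_pairs):
        (a, b), = random_curve_pairs(1, seed=4, min_len=5, max_len=9)
        cum = build_cost_matrix(a, b).cumulative
        for i in range(1, len(a) + 1):
            for j in range(1, len(b) + 1):
                pred = min(cum[i - 1, j - 1], cum[i - 1, j], cum[i, j - 1])
                assert cum[i, j] >= pred - 1e-12


class TestTraceback:
    def test_worked_pair_path(self, worked_pair):
        a, b = worked_pair
        config = AlignmentConfig(gap_penalty=0.4)
        path = traceback(build_cost_matrix(a, b, config), config)
        assert path.steps == ((1, 1), (2, 2), (3, 2))

    def test_identity_path_is_diagonal(self):
        c = generate_curve(40, seed=11)
        path = align(c, c).path
        assert path.steps == tuple((k, k) for k in range(1, 41))

    def test_tie_break_prefers_diagonal_on_flat_curves(self):
        c = DisorderCurve(np.array([0.5, 0.5, 0.5]))
        assert align(c, c).path.steps == ((1, 1), (2, 2), (3, 3))

    def test_path_validation_rejects_bad_steps(self):
        with pytest.raises(ValueError):
            WarpingPath(((1, 1), (3, 1)))
        with pytest.raises(ValueError):
            WarpingPath(((2, 2), (3, 3)))


class TestOracleEquivalence:
    @pytest.mark.parametrize("boundary_mode", ["cumulative", "constant"])
    def test_score_matches_exhaustive_enumeration(self, boundary_mode,
                                                  random_curve_pairs):
        pairs = random_curve_pairs(25, seed=13)
        for a, b in pairs:
            for p in (0.0, 0.2, 0.4, 1.0):
                config = AlignmentConfig(gap_penalty=p, boundary_mode=boundary_mode)
                got = align(a, b, config).score
                want = enumerate_min_cost(a.scores, b.scores, p, boundary_mode)
                assert got == pytest.approx(want, abs=1e-9)

    def test_traced_path_cost_equals_score(self, random_curve_pairs):
        # the traceback path must realize the terminal cost, including the
        # boundary penalty implied by its start
        for a, b in random_curve_pairs(20, seed=17):
            result = align(a, b)
            (i0, j0) = result.path.steps[0]
            skipped = (j0 - 1) if i0 == 1 else (i0 - 1)
            cost = skipped * 0.4 + result.step_distances.sum()
            assert cost == pytest.approx(result.score, abs=1e-9)


class TestAgainstTextbookDtw:
    def test_high_penalty_score_equals_classical_dtw(self, random_curve_pairs):
        # for P >= 1 skipping k residues costs k*P >= k, never less than
        # aligning them, so the score reduces to the classical DTW cost
        for a, b in random_curve_pairs(20, seed=19, min_len=3, max_len=15):
            got = align(a, b, AlignmentConfig(gap_penalty=1.5)).score
            assert got == pytest.approx(textbook_dtw(a.scores, b.scores), abs=1e-9)

    def test_zero_penalty_never_exceeds_classical_dtw(self, random_curve_pairs):
        # P = 0 makes end skips free (open-beginning alignment), which can
        # only lower the optimum
        for a, b in random_curve_pairs(20, seed=23, min_len=3, max_len=15):
            got = align(a, b, AlignmentConfig(gap_penalty=0.0)).score
            assert got <= textbook_dtw(a.scores, b.scores) + 1e-12


class TestAlignmentProperties:
    def test_identity_alignment(self):
        c = generate_curve(60, seed=29)
        result = align(c, c)
        assert result.score == 0.0
        assert result.fraction_matched == 1.0
        assert result.normalized_score == 0.0

    def test_score_is_symmetric(self, random_curve_pairs):
        for a, b in random_curve_pairs(50, seed=31, min_len=3, max_len=20):
            assert align(a, b).score == pytest.approx(align(b, a).score, abs=1e-12)

    def test_transposed_tie_break_transposes_the_path(self, random_curve_pairs):
        swapped = AlignmentConfig(
            tie_break=("diagonal", "horizontal", "vertical"))
        for a, b in random_curve_pairs(10, seed=37, min_len=3, max_len=12):
            forward = align(a, b).path
            reverse = align(b, a, swapped).path
            assert reverse.transpose().steps == forward.steps

    def test_score_nondecreasing_and_saturating_in_penalty(self, random_curve_pairs):
        grid = np.round(np.arange(0, 1.01, 0.1), 10)
        for a, b in random_curve_pairs(10, seed=41, min_len=4, max_len=15):
            scores = [align(a, b, AlignmentConfig(gap_penalty=p)).score
                      for p in grid]
            assert np.all(np.diff(scores) >= -1e-12)
            saturated = align(a, b, AlignmentConfig(gap_penalty=2.0)).score
            assert scores[-1] == pytest.approx(saturated, abs=1e-12)

    def test_score_bounds(self, random_curve_pairs):
        for a, b in random_curve_pairs(20, seed=43):
            result = align(a, b)
            assert 0.0 <= result.score <= len(a) + len(b) - 1

    def test_constant_shift_raises_diagonal_distances_by_shift(self):
        c = generate_curve(30, seed=47)
        scores = np.clip(c.scores, 0.0, 0.8)
        shift = 0.2
        a = DisorderCurve(scores)
        b = DisorderCurve(scores + shift)
        local = build_cost_matrix(a, b).local
        assert np.allclose(np.diag(local), shift)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=small_curves, b=small_curves)
    def test_path_validity_and_oracle_score(self, a, b):
        result = align(a, b)
        n, m = len(a), len(b)
        assert result.path.steps[-1] == (n, m)
        assert min(result.path.steps[0]) == 1
        assert result.score >= 0.0
        assert result.score == pytest.approx(
            enumerate_min_cost(a.scores, b.scores, 0.4), abs=1e-9)
        assert len(result.step_distances) == len(result.path)
        assert len(result.match_flags) == len(result.path)
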