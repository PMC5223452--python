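"""Rescaling, the Rasch expectation, and the joint Newton-Raphson fit."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import raschcir as rc
from raschcir.core import center_items, newton_step_items, newton_step_persons

logits = st.floats(min_value=-30, max_value=30, allow_nan=False)


class TestRescale:
    def test_likert_five_point_maps_to_quarters(self):
        m = rc.ResponseMatrix(["a", "b"], ["x", "y", "z", "w", "v"],
                              [[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]], 1, 5)
        r = rc.rescale(m)
        np.testing.assert_allclose(r.values[0], [0, 0.25, 0.5, 0.75, 1.0])
        np.testing.assert_allclose(r.values[1], [1.0, 0.75, 0.5, 0.25, 0])

    def test_affine_formula(self):
        m = rc.ResponseMatrix(["a", "b"], ["x", "y"],
                              [[30, 50], [80, 10]], 0, 100)
        r = rc.rescale(m)
        np.testing.assert_allclose(r.values, [[0.30, 0.50], [0.80, 0.10]])

    def test_unit_interval_data_is_unchanged(self, small_matrix):
        r = rc.rescale(small_matrix)
        np.testing.assert_array_equal(r.values, small_matrix.values)

    def test_missing_cells_stay_missing(self):
        m = rc.ResponseMatrix(["a", "b"], ["x", "y"],
                              [[np.nan, 2], [4, 1]], 0, 5)
        r = rc.rescale(m)
        assert np.isnan(r.values[0, 0]) and r.missing_mask[0, 0]


class TestRaschProbability:
    def test_origin_value_is_exactly_half(self):
        assert rc.rasch_probability(0.0, 0.0) == 0.5

    def test_closed_form_at_log_three(self):
        assert rc.rasch_probability(np.log(3.0), 0.0) == pytest.approx(0.75)

    @given(logits)
    def test_equal_measure_and_difficulty_gives_half(self, t):
        assert rc.rasch_probability(t, t) == pytest.approx(0.5)

    @given(logits, logits, logits)
    def test_bounded_and_monotone(self, t1, t2, d):
        p1 = rc.rasch_probability(t1, d)
        p2 = rc.rasch_probability(t2, d)
        assert 0.0 < p1 < 1.0
        if t1 < t2:
            assert p1 <= p2

    def test_rejects_non_finite_input(self):
        with pytest.raises(ValueError, match="finite"):
            rc.rasch_probability(np.inf, 0.0)


class TestResidualAndVariance:
    @pytest.mark.parametrize("x,p,r,v", [
        (0.5, 0.5, 0.0, 0.25),   # midpoint: largest variance of the curve
        (1.0, 0.5, 0.5, 0.25),
        (0.3, 0.3, 0.0, 0.21),
    ])
    def test_arithmetic(self, x, p, r, v):
        rr, vv = rc.residual_and_variance(x, p)
        assert rr == pytest.approx(r) and vv == pytest.approx(v)

    def test_variance_floor_applied(self):
        _, v = rc.residual_and_variance(0.0, 1e-12, variance_floor=1e-6)
        assert v == 1e-6


class TestNewtonSteps:
    def test_person_update_from_cold_start(self):
        # responses (0.9, 0.7) against p = 0.5, Var = 0.25 everywhere:
        # step = (0.4 + 0.2) / (0.25 + 0.25) = 1.2
        theta = newton_step_persons([0.0], [0.0, 0.0], [[0.9, 0.7]],
                                    max_step=np.inf)
        assert theta[0] == pytest.approx(1.2)

    def test_person_with_zero_residual_stays_put(self):
        theta = newton_step_persons([0.0], [0.0, 0.0], [[0.5, 0.5]])
        assert theta[0] == 0.0

    def test_step_is_capped_at_max_step(self):
        theta = newton_step_persons([0.0], [0.0, 0.0], [[1.0, 1.0]],
                                    max_step=1.0)
        assert theta[0] == pytest.approx(1.0)

    def test_item_update_from_cold_start(self):
        # column mean 0.6 with N = 10: step = -(10 * 0.1)/(10 * 0.25) = -0.4
        x = np.full((10, 2), 0.5)
        x[:, 0] = 0.6
        delta = newton_step_items(np.zeros(10), np.zeros(2), x, center=False,
                                  max_step=np.inf)
        assert delta[0] == pytest.approx(-0.4)
        assert delta[1] == pytest.approx(0.0)

    def test_item_matching_expectation_is_unchanged(self):
        x = np.full((5, 2), 0.5)
        delta = newton_step_items(np.zeros(5), np.zeros(2), x, center=False)
        np.testing.assert_allclose(delta, 0.0)

    def test_two_item_fit_is_antisymmetric_after_centering(self):
        m = rc.ResponseMatrix(["a", "b", "c"], ["x", "y"],
                              [[0.8, 0.3], [0.6, 0.4], [0.9, 0.2]], 0, 1)
        f = rc.fit(m)
        assert f.delta[0] == pytest.approx(-f.delta[1], abs=1e-9)

    def test_person_without_responses_rejected(self):
        x = np.array([[0.5, 0.5], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="at least one observed"):
            newton_step_persons([0.0, 0.0], [0.0, 0.0], x)


class TestCenterItems:
    def test_mean_subtraction(self):
        np.testing.assert_allclose(center_items([0.3, -0.1, 0.1]),
                                   [0.2, -0.2, 0.0], atol=1e-12)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=8))
    def test_centered_and_idempotent(self, vals):
        once = center_items(vals)
        assert abs(once.sum()) < 1e-12
        np.testing.assert_allclose(center_items(once), once, atol=1e-12)

    def test_single_free_item_set_to_zero(self):
        out = center_items([2.0, 9.0], free_items=[True, False])
        assert out[0] == 0.0 and out[1] == 9.0


class TestFit:
    def test_saddle_data_lands_at_the_origin(self):
        m = rc.ResponseMatrix(["a", "b"], ["x", "y"],
                              [[1.0, 0.0], [0.0, 1.0]], 0, 1)
        f = rc.fit(m)
        np.testing.assert_allclose(f.theta, 0.0, atol=1e-9)
        np.testing.assert_allclose(f.delta, 0.0, atol=1e-9)

    def test_reversed_responses_negate_all_estimates(self, beta_fit):
        matrix, _, result, _ = beta_fit
        rev = rc.ResponseMatrix(matrix.person_ids, matrix.item_ids,
                                1.0 - matrix.values, 0, 1)
        f_rev = rc.fit(rev)
        np.testing.assert_allclose(f_rev.theta, -result.theta, atol=1e-6)
        np.testing.assert_allclose(f_rev.delta, -result.delta, atol=1e-6)

    def test_affine_invariance_of_raw_bounds(self, small_matrix):
        scaled = rc.ResponseMatrix(
            small_matrix.person_ids, small_matrix.item_ids,
            small_matrix.values * 40 + 10, 10, 50)
        f_unit = rc.fit(small_matrix)
        f_raw = rc.fit(scaled)
        np.testing.assert_array_equal(f_unit.theta, f_raw.theta)
        np.testing.assert_array_equal(f_unit.delta, f_raw.delta)

    def test_difficulties_sum_to_zero(self, beta_fit):
        _, _, result, _ = beta_fit
        assert abs(result.delta.sum()) < 1e-6

    def test_expectations_strictly_inside_unit_interval(self, beta_fit):
        _, _, result, _ = beta_fit
        assert np.all(result.expected > 0) and np.all(result.expected < 1)

    def test_score_equations_hold_at_convergence(self, binary_fit):
        matrix, _, result = binary_fit
        cfg = result.config
        person_scores = np.nansum(result.residuals.R, axis=1)
        bound = 10 * cfg.convergence_tol / matrix.n_persons
        assert np.max(np.abs(person_scores)) < bound
        item_scores = np.nansum(result.residuals.R, axis=0)
        assert np.max(np.abs(item_scores)) < 10 * cfg.convergence_tol / matrix.n_items

    def test_residual_trace_non_increasing_at_the_end(self, beta_fit):
        _, _, result, _ = beta_fit
        tail = result.sum_abs_residual_trace[-5:]
        assert np.all(np.diff(tail) <= 1e-9)

    def test_exact_data_recovers_generating_difficulties(self):
        spec = rc.SimulationSpec(30, 5, noise_mode="exact", seed=3)
        matrix, truth = rc.simulate_matrix(spec)
        f = rc.fit(matrix, rc.RunConfig(change_tol=1e-8))
        np.testing.assert_allclose(f.delta, truth["delta"], atol=1e-3)

    def test_iteration_cap_warns_instead_of_raising(self, small_matrix):
        cfg = rc.RunConfig(max_iter=2, change_tol=1e-12,
                           convergence_tol=1e-12)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            f = rc.fit(small_matrix, cfg)
        assert not f.converged and f.n_iter == 2

    def test_extreme_person_clamped_and_flagged(self):
        m = rc.ResponseMatrix(["top", "b", "c"], ["x", "y"],
                              [[1.0, 1.0], [0.3, 0.6], [0.7, 0.2]], 0, 1)
        f = rc.fit(m)
        assert f.extreme_person_flags[0]
        assert f.theta[0] == pytest.approx(f.config.theta_clamp)
        # the flagged person stays out of the centering constraint
        assert abs(f.delta[~f.extreme_item_flags].sum()) < 1e-9
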