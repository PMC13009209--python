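"""Misbinding-model tests: sigmoid, probability surface, simulation, ML fit."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize
from sklearn.base import clone

from mobius_gate import (
    ConvergenceError,
    InvalidConfigError,
    MobiusLogistic,
    MobiusParams,
    compute_phase_space,
    fit_parameters,
    misbinding_probability,
    sigmoid,
    simulate_outcomes,
)
from mobius_gate.model import plausibility_score


class TestSigmoid:
    def test_exact_half_at_zero(self):
        assert sigmoid(0.0) == 0.5

    @pytest.mark.parametrize("x", [-3.0, -1.0, 1.0, 3.0])
    def test_tanh_identity(self, x):
        assert sigmoid(x) == pytest.approx(0.5 * (1 + np.tanh(x / 2)), abs=1e-14)

    @given(x=st.floats(-700, 700))
    def test_reflection(self, x):
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0, abs=1e-12)

    def test_extreme_arguments_stable(self):
        assert sigmoid(700.0) == pytest.approx(1.0)
        assert sigmoid(-700.0) == pytest.approx(0.0, abs=1e-300)
        assert np.all(np.isfinite(sigmoid(np.array([-700.0, 700.0]))))


class TestMisbindingProbability:
    def test_balanced_terms_give_half(self):
        par = MobiusParams(1.0, 1.0)
        assert misbinding_probability(0.7, 0.7, par) == 0.5
        par2 = MobiusParams(2.0, 0.5)
        assert misbinding_probability(0.5, 2.0, par2) == 0.5  # 2*0.5 == 0.5*2

    def test_null_model_is_half_everywhere(self, rng):
        par = MobiusParams(0.0, 0.0)
        vals = misbinding_probability(rng.normal(size=50), rng.normal(size=50), par)
        np.testing.assert_array_equal(vals, 0.5)

    def test_direct_evaluation(self):
        par = MobiusParams(2.0, 1.0)
        assert misbinding_probability(1.5, 0.5, par) == pytest.approx(
            1 / (1 + np.exp(-2.5)), abs=1e-12
        )

    @given(
        alpha=st.floats(0.1, 5),
        beta=st.floats(0.1, 5),
        p=st.floats(-3, 3),
        g=st.floats(-3, 3),
        eps=st.floats(0.01, 1.0),
    )
    def test_monotonicity(self, alpha, beta, p, g, eps):
        par = MobiusParams(alpha, beta)
        base = misbinding_probability(p, g, par)
        assert misbinding_probability(p + eps, g, par) > base
        assert misbinding_probability(p, g + eps, par) < base

    @given(p=st.floats(-3, 3), g=st.floats(-3, 3), c=st.floats(0.1, 10))
    def test_scale_confound(self, p, g, c):
        # alpha and beta are identified only relative to predictor scales
        a = misbinding_probability(p, g, MobiusParams(1.5, 2.0))
        b = misbinding_probability(c * p, g, MobiusParams(1.5 / c, 2.0))
        assert b == pytest.approx(a, abs=1e-12)

    def test_negative_weights_warn(self):
        with pytest.warns(UserWarning):
            MobiusParams(-1.0, 2.0)


class TestPhaseSpace:
    def test_grid_matches_pointwise_evaluation(self):
        par = MobiusParams(1.3, 0.7)
        grid = compute_phase_space(n_grid=21, params=par)
        pp, gg = np.meshgrid(grid.p_axis, grid.g_axis)
        np.testing.assert_allclose(grid.prob, misbinding_probability(pp, gg, par))

    def test_maximal_vulnerability_corner(self):
        grid = compute_phase_space(n_grid=31, params=MobiusParams(1.0, 2.0))
        # highest probability at max P_S (last column), min G (first row)
        assert grid.prob[0, -1] == grid.prob.max()
        # monotone along each axis
        assert np.all(np.diff(grid.prob, axis=1) >= 0)  # increasing in P_S
        assert np.all(np.diff(grid.prob, axis=0) <= 0)  # decreasing in G

    def test_symmetric_weights_give_diagonal_boundary(self):
        grid = compute_phase_space(n_grid=11, params=MobiusParams(1.7, 1.7))
        np.testing.assert_allclose(grid.boundary_g(grid.p_axis), grid.p_axis)

    def test_boundary_identity(self, rng):
        p = rng.uniform(-3, 3, 20)
        # power-of-two weight ratio: alpha*p - beta*(alpha/beta)*p is float-exact
        par = MobiusParams(2.0, 1.0)
        g = compute_phase_space(params=par, n_grid=5).boundary_g(p)
        np.testing.assert_array_equal(misbinding_probability(p, g, par), 0.5)
        # generic ratio: exact up to one rounding of the boundary line
        par = MobiusParams(1.2, 0.8)
        g = compute_phase_space(params=par, n_grid=5).boundary_g(p)
        np.testing.assert_allclose(misbinding_probability(p, g, par), 0.5, atol=1e-12)

    def test_beta_zero_flagged(self):
        with pytest.warns(UserWarning):
            grid = compute_phase_space(n_grid=5, params=MobiusParams(1.0, 0.0))
        assert not grid.has_boundary
        with pytest.raises(InvalidConfigError):
            grid.boundary_g(0.0)


class TestSimulation:
    def test_null_rate_half(self):
        out = simulate_outcomes(np.zeros(10_000), np.zeros(10_000), MobiusParams(0.0, 0.0), seed=1)
        assert out.mean() == pytest.approx(0.5, abs=0.02)

    def test_saturation(self):
        out = simulate_outcomes(np.full(100, 50.0), np.zeros(100), MobiusParams(1.0, 1.0), seed=2)
        assert out.min() == 1

    def test_calibration_per_cell(self, rng):
        par = MobiusParams(1.5, 2.0)
        p = np.repeat([-1.0, 0.0, 1.0], 4000)
        g = np.tile(np.repeat([-1.0, 1.0], 2000), 3)
        out = simulate_outcomes(p, g, par, seed=3)
        for pv in (-1.0, 0.0, 1.0):
            for gv in (-1.0, 1.0):
                cell = out[(p == pv) & (g == gv)]
                prob = misbinding_probability(pv, gv, par)
                se = np.sqrt(prob * (1 - prob) / cell.size)
                assert abs(cell.mean() - prob) < 4 * se + 1e-9


class TestFit:
    def _simulated(self, n=2000, alpha=1.5, beta=2.0, seed=0):
        rng = np.random.default_rng(seed)
        p, g = rng.standard_normal(n), rng.standard_normal(n)
        y = simulate_outcomes(p, g, MobiusParams(alpha, beta), seed=rng)
        return p, g, y

    def test_parameter_recovery(self):
        p, g, y = self._simulated()
        params, info = fit_parameters(p, g, y)
        assert params.alpha == pytest.approx(1.5, abs=0.15)
        assert params.beta == pytest.approx(2.0, abs=0.15)
        assert info["se_alpha"] < 0.15 and info["se_beta"] < 0.2

    def test_score_equations_hold_at_optimum(self):
        p, g, y = self._simulated(n=500, seed=1)
        est = MobiusLogistic().fit(np.column_stack([p, g]), y)
        mu = est.predict_proba(np.column_stack([p, g]))[:, 1]
        Z = np.column_stack([p, -g])
        np.testing.assert_allclose(Z.T @ (y - mu), 0.0, atol=1e-6)

    def test_loglik_at_fit_beats_truth(self):
        p, g, y = self._simulated(n=500, seed=2)
        est = MobiusLogistic().fit(np.column_stack([p, g]), y)

        def ll(alpha, beta):
            eta = alpha * p - beta * g
            return float(y @ eta - np.logaddexp(0.0, eta).sum())

        assert est.loglik_ >= ll(1.5, 2.0) - 1e-9

    def test_irls_agrees_with_direct_optimizer(self):
        p, g, y = self._simulated(n=80, seed=3)
        est = MobiusLogistic().fit(np.column_stack([p, g]), y)

        def nll(theta):
            eta = theta[0] * p - theta[1] * g
            return -(y @ eta - np.logaddexp(0.0, eta).sum())

        opt = minimize(nll, x0=[0.1, 0.1], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        assert est.alpha_ == pytest.approx(opt.x[0], abs=1e-6)
        assert est.beta_ == pytest.approx(opt.x[1], abs=1e-6)

    def test_perfect_separation_raises(self, rng):
        p = rng.standard_normal(100)
        g = rng.standard_normal(100)
        y = (p - g > 0).astype(int)
        with pytest.raises(ConvergenceError, match="separation"):
            MobiusLogistic().fit(np.column_stack([p, g]), y)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((50, 2))
        with pytest.raises(InvalidConfigError):
            MobiusLogistic().fit(X, np.ones(50))

    def test_collinear_predictors_rejected(self, rng):
        p = rng.standard_normal(50)
        y = (rng.random(50) < 0.5).astype(int)
        with pytest.raises(InvalidConfigError, match="collinear"):
            MobiusLogistic().fit(np.column_stack([p, 2 * p]), y)

    def test_sklearn_protocol(self, rng):
        est = MobiusLogistic(max_iter=50)
        assert clone(est).get_params()["max_iter"] == 50
        p, g, y = self._simulated(n=200, seed=4)
        est.fit(np.column_stack([p, g]), y)
        proba = est.predict_proba(np.column_stack([p, g]))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(np.unique(est.predict(np.column_stack([p, g])))) <= {0, 1}
        assert est.score(np.column_stack([p, g]), y) > 0.5


class TestPlausibilityScore:
    def test_mean_then_standardize(self):
        scores = plausibility_score([[0.2, 0.4], [0.6, 0.8], [0.1, 0.1]])
        assert scores.mean() == pytest.approx(0.0, abs=1e-12)
        assert scores.std(ddof=1) == pytest.approx(1.0)

    def test_raw_mean_mode(self):
        np.testing.assert_allclose(
            plausibility_score([[0.2, 0.4], [0.6, 0.8]], standardize=False), [0.3, 0.7]
        )
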