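"""Penalized-solver oracles: KKT stationarity, an independent
proximal-gradient solver, bisection for the entry point, and a hand-rolled
cross-validated-likelihood computation."""

import numpy as np
import pytest

from hierlasso import (
    breslow_partial_loglik,
    cvl_select,
    lambda_grid,
    newton_cox_fit,
    ridge_cox_fit,
    score_and_information,
    weighted_lasso_cox_path,
)
from hierlasso.design import build_interaction_design, standardize
from hierlasso.penalized import _stratified_folds
from hierlasso.weighting import WeightVector, lrt_weights, sw_weights

from conftest import random_dataset


def _setup(rng, n=80, p=3, censor_frac=0.25):
    data = random_dataset(rng, n=n, p=p, censor_frac=censor_frac)
    design = standardize(build_interaction_design(data))
    omega = np.ones(2 * p)
    weights = WeightVector(omega, "unit").normalized()
    return data, design, weights


def _augmented(design):
    return np.hstack([design.treatment[:, None], design.V])


def _grad_scaled(data, design, beta_aug):
    """Gradient of loglik/n on the standardized augmented design."""
    Z = _augmented(design)
    g, _ = score_and_information(data.time, data.event, Z, beta_aug)
    return g / data.n


def _to_std(design, coef_row):
    """Path coefficients (original scale) back to the standardized scale."""
    out = coef_row.copy()
    out[1:] = out[1:] * design.column_scales
    return out


def prox_grad_reference(data, design, omega, lam, n_iter=30000, step=None):
    """Independent ISTA solver for the weighted-lasso Cox objective."""
    Z = _augmented(design)
    n, m = Z.shape
    thresh = lam * np.concatenate([[0.0], omega])
    beta = np.zeros(m)
    if step is None:
        step = 0.5  # conservative for loglik/n with standardized columns
    for _ in range(n_iter):
        g, _ = score_and_information(data.time, data.event, Z, beta)
        beta_new = beta + step * g / n
        beta_new = np.sign(beta_new) * np.maximum(
            np.abs(beta_new) - step * thresh, 0.0
        )
        if np.abs(beta_new - beta).max() < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta


class TestLambdaGrid:
    def test_null_model_at_grid_start(self, rng):
        data, design, weights = _setup(rng)
        grid = lambda_grid(data.time, data.event, design, weights, n_lambda=10)
        path = weighted_lasso_cox_path(data.time, data.event, design, weights, grid[:1])
        assert np.all(path.coefficients_per_lambda[0, 1:] == 0.0)
        assert np.all(np.diff(grid) < 0)

    def test_doubling_weights_halves_lambda_max(self, rng):
        data, design, _ = _setup(rng)
        w1 = WeightVector(np.ones(6), "unit")
        w2 = WeightVector(2 * np.ones(6), "unit")
        g1 = lambda_grid(data.time, data.event, design, w1, n_lambda=5)
        g2 = lambda_grid(data.time, data.event, design, w2, n_lambda=5)
        assert g2[0] == pytest.approx(g1[0] / 2, rel=1e-12)

    def test_lambda_max_matches_bisection(self, rng):
        data, design, weights = _setup(rng, n=60)
        grid = lambda_grid(data.time, data.event, design, weights, n_lambda=5)
        lam_max = grid[0]

        def is_null(lam):
            path = weighted_lasso_cox_path(
                data.time, data.event, design, weights, np.array([lam])
            )
            return np.all(path.coefficients_per_lambda[0, 1:] == 0.0)

        lo, hi = lam_max / 3, lam_max * 3
        assert is_null(hi) and not is_null(lo)
        for _ in range(25):
            mid = np.sqrt(lo * hi)
            if is_null(mid):
                hi = mid
            else:
                lo = mid
        assert hi == pytest.approx(lam_max, rel=0.01)

    def test_all_capped_weights_rejected(self, rng):
        data, design, _ = _setup(rng)
        from hierlasso.weighting import WEIGHT_CAP
        w = WeightVector(np.full(6, WEIGHT_CAP), "unit")
        with pytest.raises(ValueError, match="cap"):
            lambda_grid(data.time, data.event, design, w)


class TestLassoPath:
    def test_unpenalized_limit_matches_newton(self, rng):
        data, design, weights = _setup(rng, n=100, p=3)
        grid = lambda_grid(data.time, data.event, design, weights, n_lambda=8)
        full_grid = np.append(grid, 0.0)
        path = weighted_lasso_cox_path(
            data.time, data.event, design, weights, full_grid, tol=1e-13
        )
        Z = _augmented(design)
        ref = newton_cox_fit(data.time, data.event, Z)
        beta_std = _to_std(design, path.coefficients_per_lambda[-1])
        assert np.allclose(beta_std, ref.coefficients, atol=1e-4)

    def test_kkt_conditions_along_path(self, rng):
        data, design, weights = _setup(rng, n=70, p=4)
        grid = lambda_grid(data.time, data.event, design, weights, n_lambda=12)
        path = weighted_lasso_cox_path(
            data.time, data.event, design, weights, grid, tol=1e-13
        )
        omega_aug = np.concatenate([[0.0], weights.omega])
        for i, lam in enumerate(path.grid):
            beta_std = _to_std(design, path.coefficients_per_lambda[i])
            g = _grad_scaled(data, design, beta_std)
            zero = beta_std == 0
            zero[0] = False
            assert np.all(np.abs(g[zero]) <= lam * omega_aug[zero] + 1e-7)
            active = ~zero
            resid = g[active] - lam * omega_aug[active] * np.sign(beta_std[active])
            assert np.abs(resid).max() < 1e-5

    def test_matches_proximal_gradient_reference(self, rng):
        data, design, weights = _setup(rng, n=100, p=5)
        grid = lambda_grid(data.time, data.event, design, weights, n_lambda=6)
        lam = grid[3]
        path = weighted_lasso_cox_path(
            data.time, data.event, design, weights, grid[:4], tol=1e-13
        )
        ref = prox_grad_reference(data, design, weights.omega, lam)
        beta_std = _to_std(design, path.coefficients_per_lambda[3])
        assert np.allclose(beta_std, ref, atol=1e-3)

    def test_adaptive_weights_against_reference(self, rng):
        data = random_dataset(rng, n=90, p=4, censor_frac=0.2)
        design = standardize(build_interaction_design(data))
        weights = sw_weights(data).normalized()
        grid = lambda_grid(data.time, data.event, design, weights, n_lambda=6)
        lam = grid[2]
        path = weighted_lasso_cox_path(
            data.time, data.event, design, weights, grid[:3], tol=1e-13
        )
        ref = prox_grad_reference(data, design, weights.omega, lam)
        assert np.allclose(
            _to_std(design, path.coefficients_per_lambda[2]), ref, atol=1e-3
        )

    def test_support_monotone_in_weight(self, rng):
        data, design, weights = _setup(rng, n=80, p=3)
        grid = lambda_grid(data.time, data.event, design, weights, n_lambda=10)
        lam = np.array([grid[6]])
        base = weighted_lasso_cox_path(data.time, data.event, design, weights, lam)
        for col in range(6):
            om = weights.omega.copy()
            om[col] *= 3.0
            bumped = weighted_lasso_cox_path(
                data.time, data.event, design, WeightVector(om, "unit"), lam
            )
            assert (
                abs(bumped.coefficients_per_lambda[0, 1 + col])
                <= abs(base.coefficients_per_lambda[0, 1 + col]) + 1e-9
            )

    def test_path_continuity(self, rng):
        data, design, weights = _setup(rng, n=100, p=4)
        grid = lambda_grid(data.time, data.event, design, weights, n_lambda=30)
        path = weighted_lasso_cox_path(data.time, data.event, design, weights, grid)
        steps = np.abs(np.diff(path.coefficients_per_lambda, axis=0)).max(axis=1)
        positive = steps[steps > 1e-12]
        assert steps.max() <= 10 * np.median(positive) + 0.05


class TestRidge:
    def test_unpenalized_limit(self, rng):
        data, design, _ = _setup(rng, n=60, p=2)
        coef = ridge_cox_fit(data.time, data.event, design, 0.0, tol=1e-14)
        Z = _augmented(design)
        ref = newton_cox_fit(data.time, data.event, Z)
        coef_std = coef.copy()
        coef_std[1:] *= design.column_scales
        assert np.allclose(coef_std, ref.coefficients, atol=1e-6)

    def test_heavy_shrinkage_keeps_treatment(self, rng):
        data, design, _ = _setup(rng, n=80, p=3)
        coef = ridge_cox_fit(data.time, data.event, design, 1e8)
        assert np.max(np.abs(coef[1:])) < 1e-4
        ref = newton_cox_fit(
            data.time, data.event, np.asarray(design.treatment)[:, None]
        )
        assert coef[0] == pytest.approx(ref.coefficients[0], abs=1e-3)

    def test_first_order_condition(self, rng):
        data, design, _ = _setup(rng, n=70, p=3)
        lam = 0.05
        coef = ridge_cox_fit(data.time, data.event, design, lam, tol=1e-15)
        beta_std = coef.copy()
        beta_std[1:] *= design.column_scales
        g = _grad_scaled(data, design, beta_std)
        g[1:] -= 2 * lam * beta_std[1:]
        assert np.abs(g).max() < 1e-6

    def test_negative_lambda_rejected(self, rng):
        data, design, _ = _setup(rng)
        with pytest.raises(ValueError, match="nonnegative"):
            ridge_cox_fit(data.time, data.event, design, -1.0)


class TestCvl:
    def test_fold_partition(self, rng):
        event = (rng.random(37) < 0.7).astype(int)
        fold = _stratified_folds(event, 5, rng)
        assert fold.shape == (37,)
        assert set(fold) == set(range(5))
        # every subject in exactly one fold, events spread across folds
        counts = np.bincount(fold[event == 1], minlength=5)
        assert counts.max() - counts.min() <= 1

    def test_two_fold_recomputation(self, rng):
        data, design, weights = _setup(rng, n=30, p=2)
        grid = lambda_grid(data.time, data.event, design, weights, n_lambda=6)
        seed = 77
        path = cvl_select(
            data.time, data.event, design, weights, grid, k=2, seed=seed,
            stop_drop=None,
        )
        # hand-rolled: same folds, per-fold path fits, Verweij-van Houwelingen
        fold = _stratified_folds(data.event, 2, np.random.default_rng(seed))
        Zfull = _augmented(design)
        cvl = np.zeros(grid.size)
        from hierlasso.penalized import _restrict_design
        for f in range(2):
            keep = fold != f
            sub = _restrict_design(design, keep)
            sub_path = weighted_lasso_cox_path(
                data.time[keep], data.event[keep], sub, weights, grid
            )
            Zsub = np.hstack([sub.treatment[:, None], sub.V])
            for i in range(grid.size):
                b_std = _to_std(design, sub_path.coefficients_per_lambda[i])
                cvl[i] += breslow_partial_loglik(
                    data.time, data.event, Zfull, b_std
                ) - breslow_partial_loglik(
                    data.time[keep], data.event[keep], Zsub, b_std
                )
        assert np.allclose(path.cvl_per_lambda, cvl, atol=1e-6)
        assert path.selected_index == int(np.argmax(cvl))

    def test_null_entry_identical_across_schemes(self, rng):
        data = random_dataset(rng, n=60, p=3, censor_frac=0.2)
        design = standardize(build_interaction_design(data))
        cvls = []
        for scheme in (sw_weights, lrt_weights):
            w = scheme(data).normalized()
            grid = lambda_grid(data.time, data.event, design, w, n_lambda=4)
            # inflate the entry point so the first fit is surely null
            grid = np.concatenate([[2 * grid[0]], grid])
            path = cvl_select(
                data.time, data.event, design, w, grid, k=3, seed=4
            )
            cvls.append(path.cvl_per_lambda[0])
        assert cvls[0] == pytest.approx(cvls[1], abs=1e-8)

    def test_selected_lambda_in_grid(self, rng):
        data, design, weights = _setup(rng, n=50, p=2)
        grid = lambda_grid(data.time, data.event, design, weights, n_lambda=8)
        path = cvl_select(data.time, data.event, design, weights, grid, k=3, seed=1)
        assert path.selected_lambda in path.grid
        assert np.all(np.diff(path.grid) < 0)

    def test_k_less_than_two_rejected(self, rng):
        data, design, weights = _setup(rng)
        grid = lambda_grid(data.time, data.event, design, weights, n_lambda=4)
        with pytest.raises(ValueError, match="k >= 2"):
            cvl_select(data.time, data.event, design, weights, grid, k=1)
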