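"""Weighted-lasso and ridge Cox solvers with cross-validated-likelihood tuning.

The solver maximizes the scaled objective

    loglik(alpha, theta) / n  -  lambda * sum_c omega_c |theta_c|

(ridge: ``- lambda * sum theta_c^2``) over the standardized design
``(T | V)`` with the treatment column unpenalized.  Optimization is IRLS with
coordinate-wise soft-thresholding (compiled in :mod:`hierlasso._fast`),
warm-started along a decreasing lambda grid.  Columns are screened by their
Karush-Kuhn-Tucker (KKT) condition: each lambda is solved on the ever-active
set, the full gradient is checked, and violating columns are added until the
solution is stationary for the complete problem, so inactive coordinates are
exact zeros.

Tuning follows the cross-validated log-likelihood of Verweij and van
Houwelingen:  ``cvl(lambda) = sum_folds [ l_full(b_(-k)) - l_(-k)(b_(-k)) ]``
with event-stratified folds, maximized over the grid with ties broken toward
the larger (sparser) lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _fast
from .core_survival import SurvivalDataset, _risk_order, newton_cox_fit
from .design import InteractionDesign
from .weighting import WeightVector, WEIGHT_CAP

__all__ = [
    "LambdaPath",
    "PenalizedFit",
    "lambda_grid",
    "weighted_lasso_cox_path",
    "ridge_cox_fit",
    "cvl_select",
    "cvl_ridge_select",
]

CD_TOL = 1e-7
MAX_UPDATES = 100_000
MAX_IRLS = 50
_KKT_ROUNDS = 50


@dataclass
class LambdaPath:
    """Coefficient path over a decreasing lambda grid.

    ``coefficients_per_lambda`` holds, per grid point, the treatment
    coefficient followed by the 2p penalized coefficients on the original
    (unstandardized) scale.
    """

    grid: np.ndarray
    coefficients_per_lambda: np.ndarray  # (L, 1 + 2p), original scale
    cvl_per_lambda: np.ndarray | None = None
    selected_index: int | None = None
    n_irls: np.ndarray | None = None

    @property
    def selected_lambda(self) -> float:
        if self.selected_index is None:
            raise ValueError("no lambda has been selected on this path")
        return float(self.grid[self.selected_index])

    @property
    def n_nonzero(self) -> np.ndarray:
        return (self.coefficients_per_lambda[:, 1:] != 0).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Diagnostic table (lambda, cvl, n_nonzero)."""
        return pd.DataFrame(
            {
                "lambda": self.grid,
                "cvl": np.full(len(self.grid), np.nan)
                if self.cvl_per_lambda is None
                else self.cvl_per_lambda,
                "n_nonzero": self.n_nonzero,
            }
        )


@dataclass
class PenalizedFit:
    """Final model at the tuned lambda.

    Selection sets are 1-based group indices: group ``j`` pairs main-effect
    column ``j`` with interaction column ``p + j``.
    """

    alpha_hat: float
    theta_hat: np.ndarray  # 2p, original scale
    lambda_: float
    weights: WeightVector
    path: LambdaPath | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.theta_hat.shape[0] // 2

    @property
    def selected_mains(self) -> np.ndarray:
        return np.flatnonzero(self.theta_hat[: self.p] != 0) + 1

    @property
    def selected_interactions(self) -> np.ndarray:
        return np.flatnonzero(self.theta_hat[self.p :] != 0) + 1


class _CoxProblem:
    """Sorted, treatment-augmented view of a standardized design."""

    def __init__(self, time, event, design: InteractionDesign):
        if not design.standardized:
            raise ValueError("design must be standardized before penalized fitting")
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if event.sum() == 0:
            raise ValueError("no events: no risk information in the data")
        order, _, ev, risk_start = _risk_order(time, event)
        self.order = order
        self.ev = ev
        self.risk_start = risk_start
        full = np.hstack([design.treatment[:, None], design.V])
        self.V = np.asfortranarray(full[order])
        self.n, self.m = self.V.shape
        self.scales = design.column_scales
        self.time = time
        self.event = event

    def subject_gradient(self, beta: np.ndarray):
        """Per-subject score contributions and log-likelihood at ``beta``."""
        eta = self.V @ beta
        w = np.empty(self.n)
        g = np.empty(self.n)
        ll = _fast.cox_weights_sorted(eta, self.ev, self.risk_start, w, g)
        return g, ll

    def loglik(self, beta: np.ndarray) -> float:
        return float(
            _fast.cox_loglik_sorted(self.V @ beta, self.ev, self.risk_start)
        )

    def to_original(self, beta: np.ndarray) -> np.ndarray:
        out = beta.copy()
        out[1:] = out[1:] / self.scales
        return out


def _pen1_vector(lam: float, omega: np.ndarray) -> np.ndarray:
    return lam * np.concatenate([[0.0], omega])


def _solve_restricted(prob: _CoxProblem, beta, pen1, pen2, cols, cd_tol, max_updates):
    sub = np.asfortranarray(prob.V[:, cols])
    b = beta[cols].copy()
    ll, n_irls, n_upd, conv = _fast.fit_penalized_sorted(
        sub,
        prob.ev,
        prob.risk_start,
        b,
        pen1[cols],
        pen2[cols],
        cd_tol,
        max_updates,
        MAX_IRLS,
    )
    beta[cols] = b
    return ll, n_irls, n_upd, conv


def _fit_at_lambda(prob: _CoxProblem, beta, pen1, pen2, cd_tol, max_updates):
    """Solve one lambda with ever-active KKT screening; updates beta in place."""
    n_irls_total = 0
    in_set = beta != 0.0
    in_set[0] = True  # treatment always solved
    for _ in range(_KKT_ROUNDS):
        cols = np.flatnonzero(in_set)
        ll, n_irls, n_upd, conv = _solve_restricted(
            prob, beta, pen1, pen2, cols, cd_tol, max_updates
        )
        n_irls_total += n_irls
        if not conv:
            raise RuntimeError(
                f"coordinate descent did not converge (lambda component "
                f"{pen1.max():.3g}, {n_upd} updates on {cols.size} columns)"
            )
        g, _ = prob.subject_gradient(beta)
        grad_all = (prob.V.T @ g) / prob.n
        viol = (~in_set) & (np.abs(grad_all) > pen1 + 1e-10)
        if not viol.any():
            return n_irls_total
        in_set |= viol
    raise RuntimeError("KKT screening failed to stabilize the active set")


def lambda_grid(
    time,
    event,
    design: InteractionDesign,
    weights: WeightVector,
    n_lambda: int = 100,
    min_ratio: float | None = None,
):
    """Decreasing log-spaced grid from the null-model entry point.

    ``lambda_max`` is the smallest lambda whose KKT conditions hold at the
    treatment-only fit:  ``max_c |score_c| / (n omega_c)`` with the score
    evaluated at the null model (treatment fitted alone, all penalized
    coefficients 0).
    """
    omega = weights.omega
    if np.all(omega >= WEIGHT_CAP):
        raise ValueError("all penalty factors are at the cap; nothing can enter")
    prob = _CoxProblem(time, event, design)
    fit0 = newton_cox_fit(time, event, np.asarray(design.treatment)[:, None])
    beta = np.zeros(prob.m)
    beta[0] = fit0.coefficients[0]
    g, _ = prob.subject_gradient(beta)
    grad_all = (prob.V.T @ g) / prob.n
    lam_max = float(np.max(np.abs(grad_all[1:]) / omega))
    if min_ratio is None:
        # the cross-validated optimum sits around lambda/lambda_max ~ 0.005-0.3
        # for trial-scale data; below ~1e-3 the fits saturate (more active
        # columns than events) and cvl selection never reaches them
        min_ratio = 1e-3
    return lam_max * np.logspace(0.0, np.log10(min_ratio), n_lambda)


def weighted_lasso_cox_path(
    time,
    event,
    design: InteractionDesign,
    weights: WeightVector,
    grid: np.ndarray,
    tol: float = CD_TOL,
    max_updates: int = MAX_UPDATES,
) -> LambdaPath:
    """Warm-started weighted-lasso path over a decreasing lambda grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")
    prob = _CoxProblem(time, event, design)
    pen2 = np.zeros(prob.m)
    beta = np.zeros(prob.m)
    coefs = np.empty((grid.size, prob.m))
    n_irls = np.empty(grid.size, dtype=np.int64)
    for i, lam in enumerate(grid):
        pen1 = _pen1_vector(lam, weights.omega)
        try:
            n_irls[i] = _fit_at_lambda(prob, beta, pen1, pen2, tol, max_updates)
        except RuntimeError as err:
            if i == 0:
                raise RuntimeError(
                    f"path fit failed at lambda={lam:.5g}: {err}"
                ) from err
            # saturated deep end: stop the path early (glmnet convention)
            grid, coefs, n_irls = grid[:i], coefs[:i], n_irls[:i]
            break
        coefs[i] = prob.to_original(beta)
    return LambdaPath(grid=grid.copy(), coefficients_per_lambda=coefs, n_irls=n_irls)


def ridge_cox_fit(
    time,
    event,
    design: InteractionDesign,
    lam: float,
    tol: float = 1e-9,
    warm: np.ndarray | None = None,
) -> np.ndarray:
    """Ridge Cox fit (treatment unpenalized); returns ``(alpha, theta)`` on
    the original scale.  No coefficient is exactly zero for finite lambda."""
    if lam < 0:
        raise ValueError("ridge lambda must be nonnegative")
    prob = _CoxProblem(time, event, design)
    beta = np.zeros(prob.m) if warm is None else warm.copy()
    pen1 = np.zeros(prob.m)
    pen2 = np.full(prob.m, 2.0 * lam)
    pen2[0] = 0.0
    ll, n_irls, n_upd, conv = _fast.fit_penalized_sorted(
        prob.V, prob.ev, prob.risk_start, beta, pen1, pen2, tol, 10 * MAX_UPDATES, MAX_IRLS
    )
    if not conv:
        raise RuntimeError(f"ridge fit did not converge at lambda={lam:.5g}")
    return prob.to_original(beta)


def _stratified_folds(event: np.ndarray, k: int, rng: np.random.Generator):
    """Fold labels balancing events and censorings across folds."""
    n = event.shape[0]
    fold = np.empty(n, dtype=np.int64)
    for flag in (0, 1):
        idx = np.flatnonzero(event == flag)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % k
    return fold


def _restrict_design(design: InteractionDesign, keep: np.ndarray) -> InteractionDesign:
    return InteractionDesign(
        V=design.V[keep],
        treatment=design.treatment[keep],
        p=design.p,
        column_means=design.column_means,
        column_scales=design.column_scales,
        zero_variance=design.zero_variance,
        standardized=True,
    )


def cvl_select(
    time,
    event,
    design: InteractionDesign,
    weights: WeightVector,
    grid: np.ndarray,
    k: int = 5,
    seed: int = 0,
    stop_drop: float | None = 200.0,
) -> LambdaPath:
    """K-fold cross-validated-likelihood tuning of the weighted lasso.

    The full-data path and the k fold paths advance down the grid in
    lockstep.  Two events end the walk early, neither of which can affect
    the selected model: a fit that saturates (stops converging, as glmnet
    paths do at the deep end — selection is restricted to the grid prefix
    every fold reached), and, when ``stop_drop`` is set, a cvl that has
    fallen more than ``stop_drop`` log-likelihood units below its running
    maximum, far beyond any plateau noise.

    Returns the full-data path with the cvl curve attached and
    ``selected_index`` set to its maximizer (ties toward the larger,
    sparser lambda).
    """
    if k < 2:
        raise ValueError("k-fold cross-validation needs k >= 2")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(event, k, rng)

    full_prob = _CoxProblem(time, event, design)
    fold_probs = []
    for f in range(k):
        keep = fold != f
        if event[keep].sum() == 0:
            raise ValueError(
                f"fold {f} leaves no events in the retained data; "
                "re-seed or use stratified folds"
            )
        prob_f = _CoxProblem(time[keep], event[keep], _restrict_design(design, keep))
        fold_probs.append((prob_f, np.zeros(prob_f.m)))

    beta_full = np.zeros(full_prob.m)
    pen2 = np.zeros(full_prob.m)
    coefs = []
    cvl = []
    n_irls = []
    for i, lam in enumerate(grid):
        pen1 = _pen1_vector(lam, weights.omega)
        try:
            n_irls.append(
                _fit_at_lambda(full_prob, beta_full, pen1, pen2, CD_TOL, MAX_UPDATES)
            )
            cv_i = 0.0
            for prob_f, beta_f in fold_probs:
                _fit_at_lambda(prob_f, beta_f, pen1, pen2, CD_TOL, MAX_UPDATES)
                cv_i += full_prob.loglik(beta_f) - prob_f.loglik(beta_f)
        except RuntimeError:
            if i == 0:
                raise
            if len(n_irls) > len(cvl):
                n_irls.pop()
            break
        coefs.append(full_prob.to_original(beta_full))
        cvl.append(cv_i)
        if stop_drop is not None and max(cvl) - cv_i > stop_drop:
            break

    cvl = np.asarray(cvl)
    path = LambdaPath(
        grid=grid[: cvl.size].copy(),
        coefficients_per_lambda=np.asarray(coefs[: cvl.size]),
        cvl_per_lambda=cvl,
        selected_index=int(np.argmax(cvl)),  # first max = larger lambda
        n_irls=np.asarray(n_irls[: cvl.size], dtype=np.int64),
    )
    return path


def cvl_ridge_select(
    time,
    event,
    design: InteractionDesign,
    grid: np.ndarray,
    k: int = 5,
    seed: int = 0,
    stop_drop: float | None = 200.0,
):
    """Tune the ridge penalty by k-fold cvl; returns the full-data ridge
    coefficients (2p, original scale, treatment excluded) and the lambda.

    Walks the grid from large to small lambda in lockstep across folds with
    the same early-stop rules as :func:`cvl_select` (a saturating fit or a
    cvl far past its peak ends the walk).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(event, k, rng)
    full_prob = _CoxProblem(time, event, design)
    fold_probs = []
    for f in range(k):
        keep = fold != f
        if event[keep].sum() == 0:
            raise ValueError(f"fold {f} leaves no events in the retained data")
        prob_f = _CoxProblem(time[keep], event[keep], _restrict_design(design, keep))
        fold_probs.append((prob_f, np.zeros(prob_f.m)))
    cvl = []
    for i, lam in enumerate(grid):
        cv_i = 0.0
        saturated = False
        for prob_f, beta in fold_probs:
            pen1 = np.zeros(prob_f.m)
            pen2 = np.full(prob_f.m, 2.0 * lam)
            pen2[0] = 0.0
            ll, n_irls, n_upd, conv = _fast.fit_penalized_sorted(
                prob_f.V, prob_f.ev, prob_f.risk_start, beta,
                pen1, pen2, 1e-6, 10 * MAX_UPDATES, MAX_IRLS,
            )
            if not conv:
                if i == 0:
                    raise RuntimeError(
                        f"ridge CV fit did not converge at lambda={lam:.4g}"
                    )
                saturated = True
                break
            cv_i += full_prob.loglik(beta) - prob_f.loglik(beta)
        if saturated:
            break
        cvl.append(cv_i)
        if stop_drop is not None and max(cvl) - cv_i > stop_drop:
            break
    best = int(np.argmax(np.asarray(cvl)))
    full = ridge_cox_fit(time, event, design, float(grid[best]), tol=1e-7)
    return full[1:], float(grid[best])
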