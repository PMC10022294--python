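"""Cox proportional-hazards primitives.

Breslow-tie partial likelihood, its analytic score and observed information,
and a damped Newton fitter for low-dimensional working models.  These are the
building blocks for the adaptive-weight stage (univariable Wald and nested
likelihood-ratio statistics) and the oracles the penalized solvers are tested
against.

The partial likelihood is a function of the risk-set ordering only, so all
routines pre-sort subjects by observed time once.  Tied event times are
handled with the Breslow approximation: every tied event uses the full risk
set at that time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "CoxFit",
    "breslow_partial_loglik",
    "score_and_information",
    "newton_cox_fit",
    "wald_chisq",
    "lrt_stat",
    "read_survival_csv",
    "write_survival_csv",
]

#: coefficients larger than this flag a monotone-likelihood divergence
COEF_CLAMP = 50.0


@dataclass
class SurvivalDataset:
    """A randomized-trial survival table.

    Parameters
    ----------
    time : array of positive observed times (years).
    event : array of 0/1 flags, 1 = event observed, 0 = censored.
    treatment : array coded -0.5 (control) / +0.5 (experimental).
    X : (n, p) biomarker matrix, no missing values.
    ids : optional per-patient labels.
    """

    time: np.ndarray
    event: np.ndarray
    treatment: np.ndarray
    X: np.ndarray
    ids: Sequence | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        self.treatment = np.asarray(self.treatment, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.time.shape[0]
        if self.X.shape[0] != n and self.X.shape[1] == n:
            self.X = self.X.T
        if not (self.event.shape[0] == self.treatment.shape[0] == self.X.shape[0] == n):
            raise ValueError("time, event, treatment and X must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("all observed times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event must be coded 0/1")
        self.event = self.event.astype(np.int64)
        if not np.isin(self.treatment, (-0.5, 0.5)).all():
            raise ValueError("treatment must be coded -0.5 / +0.5")
        if not np.isfinite(self.X).all():
            raise ValueError("biomarker matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        ids = None if self.ids is None else list(np.asarray(self.ids)[idx])
        return SurvivalDataset(
            self.time[idx], self.event[idx], self.treatment[idx], self.X[idx], ids
        )


@dataclass
class CoxFit:
    """Result of a maximum-partial-likelihood fit."""

    coefficients: np.ndarray
    log_partial_likelihood: float
    observed_information: np.ndarray
    converged: bool
    n_iterations: int
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def _risk_order(time: np.ndarray, event: np.ndarray):
    """Sort ascending by time and precompute, for every subject, the first
    sorted position sharing its time (start of its Breslow risk set)."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    # first index with the same time value (ties share a risk set)
    risk_start = np.searchsorted(t, t, side="left")
    return order, t, event[order].astype(np.int64), risk_start


def _check_design(design: np.ndarray, event: np.ndarray, coefficients: np.ndarray):
    design = np.atleast_2d(np.asarray(design, dtype=float))
    coefficients = np.asarray(coefficients, dtype=float).ravel()
    if design.shape[1] != coefficients.shape[0]:
        raise ValueError(
            f"coefficient length {coefficients.shape[0]} does not match "
            f"design with {design.shape[1]} columns"
        )
    if event.sum() == 0:
        raise ValueError("no events: no risk information in the data")
    return design, coefficients


def breslow_partial_loglik(
    time: np.ndarray,
    event: np.ndarray,
    design: np.ndarray,
    coefficients: np.ndarray,
    offset: np.ndarray | None = None,
) -> float:
    """Breslow-tie Cox partial log-likelihood.

    ``sum over events [eta_i - log S(t_i)]`` with ``S(t) = sum_{t_j >= t}
    exp(eta_j)``.  Invariant under strictly monotone transforms of the time
    axis.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    design, coefficients = _check_design(design, event, coefficients)
    eta = design @ coefficients
    if offset is not None:
        eta = eta + np.asarray(offset, dtype=float)
    order, _, ev, risk_start = _risk_order(time, event)
    eta_s = eta[order]
    # guard against overflow in exp by shifting (partial lik is shift invariant)
    shift = eta_s.max()
    e = np.exp(eta_s - shift)
    rev_cum = np.cumsum(e[::-1])[::-1]
    ev_pos = np.flatnonzero(ev == 1)
    return float(np.sum(eta_s[ev_pos] - shift - np.log(rev_cum[risk_start[ev_pos]])))


def score_and_information(
    time: np.ndarray,
    event: np.ndarray,
    design: np.ndarray,
    coefficients: np.ndarray,
    offset: np.ndarray | None = None,
):
    """Analytic gradient and observed information (negative Hessian) of
    :func:`breslow_partial_loglik`.  O(n d^2) via reverse cumulative sums."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    design, coefficients = _check_design(design, event, coefficients)
    eta = design @ coefficients
    if offset is not None:
        eta = eta + np.asarray(offset, dtype=float)
    order, _, ev, risk_start = _risk_order(time, event)
    Z = design[order]
    eta_s = eta[order]
    shift = eta_s.max()
    e = np.exp(eta_s - shift)

    rev = slice(None, None, -1)
    s0 = np.cumsum(e[rev])[rev]                                  # (n,)
    s1 = np.cumsum((Z * e[:, None])[rev], axis=0)[rev]           # (n, d)
    zz = Z[:, :, None] * Z[:, None, :] * e[:, None, None]
    s2 = np.cumsum(zz[rev], axis=0)[rev]                         # (n, d, d)

    ev_pos = np.flatnonzero(ev == 1)
    rs = risk_start[ev_pos]
    zbar = s1[rs] / s0[rs][:, None]
    grad = Z[ev_pos].sum(axis=0) - zbar.sum(axis=0)
    info = (s2[rs] / s0[rs][:, None, None]).sum(axis=0) - np.einsum(
        "ed,ef->df", zbar, zbar
    )
    info = 0.5 * (info + info.T)
    return grad, info


def newton_cox_fit(
    time: np.ndarray,
    event: np.ndarray,
    design: np.ndarray,
    offset: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 25,
) -> CoxFit:
    """Damped Newton maximizer of the Breslow partial log-likelihood.

    Intended for low-dimensional working models (the weighting stage fits
    models with at most three columns).  Degenerate columns (zero variance,
    hence a flat likelihood direction) get coefficient 0 and are flagged;
    monotone-likelihood divergence is clamped at ``|b| = 50`` and flagged as
    non-converged rather than raising.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if event.sum() == 0:
        raise ValueError("no events: no risk information in the data")
    d = design.shape[1]
    degenerate = design.std(axis=0) < 1e-12
    active = ~degenerate
    beta = np.zeros(d)
    ll = breslow_partial_loglik(time, event, design, beta, offset)
    converged = False
    it = 0
    if active.any():
        sub = design[:, active]
        b = beta[active]
        for it in range(1, max_iter + 1):
            grad, info = score_and_information(time, event, sub, b, offset)
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, grad, rcond=None)[0]
            new_b = b + step
            new_ll = breslow_partial_loglik(time, event, sub, new_b, offset)
            # step halving
            halvings = 0
            while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 20:
                step *= 0.5
                new_b = b + step
                new_ll = breslow_partial_loglik(time, event, sub, new_b, offset)
                halvings += 1
            b, prev_ll, ll = new_b, ll, new_ll
            if np.abs(b).max() > COEF_CLAMP:
                b = np.clip(b, -COEF_CLAMP, COEF_CLAMP)
                ll = breslow_partial_loglik(time, event, sub, b, offset)
                break
            if abs(ll - prev_ll) < tol * (abs(prev_ll) + 1.0):
                converged = True
                break
        beta[active] = b
    else:
        converged = True

    information = np.zeros((d, d))
    if active.any():
        _, info = score_and_information(time, event, design[:, active], beta[active], offset)
        information[np.ix_(active, active)] = info
    ll = breslow_partial_loglik(time, event, design, beta, offset)
    # monotone likelihood: a large coefficient with vanishing curvature means
    # the partial likelihood is monotone in that direction (no finite MLE)
    diverging = (np.abs(beta) > 10.0) & (
        np.diag(information) < 1e-6 * max(int(np.asarray(event).sum()), 1)
    )
    if diverging.any():
        converged = False
    return CoxFit(beta, ll, information, converged, it, degenerate)


def wald_chisq(fit: CoxFit, index: int = 0) -> float:
    """Chi-square Wald statistic ``(coef / se)^2`` for one coefficient."""
    info = fit.observed_information
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as err:
        raise ValueError("observed information is singular") from err
    var = cov[index, index]
    if not np.isfinite(var) or var <= 0:
        raise ValueError("degenerate information: variance not positive")
    return float(fit.coefficients[index] ** 2 / var)


def lrt_stat(fit_null: CoxFit, fit_alt: CoxFit, tol: float = 1e-6) -> float:
    """Likelihood-ratio statistic ``2 (l_alt - l_null)`` for nested fits.

    Small negative values (numerical noise) are clamped to 0; a clearly
    negative value signals a fitting failure and raises.
    """
    stat = 2.0 * (fit_alt.log_partial_likelihood - fit_null.log_partial_likelihood)
    if stat < -tol:
        raise ValueError(
            f"alternative model has lower partial likelihood (LRT={stat:.3g}); "
            "models are not nested or a fit failed"
        )
    return max(stat, 0.0)


# ---------------------------------------------------------------------------
# delimited-text round trip

def write_survival_csv(data: SurvivalDataset, path) -> None:
    """Write the CSV layout ``time,event,treatment,X0001..Xp``."""
    width = max(4, len(str(data.p)))
    cols = {f"X{j + 1:0{width}d}": data.X[:, j] for j in range(data.p)}
    df = pd.DataFrame(
        {"time": data.time, "event": data.event, "treatment": data.treatment, **cols}
    )
    df.to_csv(path, index=False)


def read_survival_csv(path) -> SurvivalDataset:
    df = pd.read_csv(path)
    xcols = [c for c in df.columns if c.startswith("X")]
    return SurvivalDataset(
        df["time"].to_numpy(),
        df["event"].to_numpy(),
        df["treatment"].to_numpy(),
        df[xcols].to_numpy(),
    )
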