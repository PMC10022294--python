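"""Adaptive penalty-factor schemes.

Three preliminary-stage weightings for the bi-level adaptive lasso, each
producing one penalty factor per column of ``V = (X | XT)``:

* ``SW``  — inverse of the univariable Wald chi-square of the interaction-only
  model ``lambda0(t) exp(gamma_j X_j T)``, shared by the main effect and the
  interaction of group ``j``.  Sharing the weight ties the fate of the pair
  together and thereby favors the strong-heredity pattern.
* ``LRT`` — reciprocals of the nested likelihood-ratio statistics
  ``Lambda(M2/M0)`` (main-effect weight) and ``Lambda(M2/M1)`` (interaction
  weight), where M0 = treatment only, M1 = treatment + X_j and
  M2 = treatment + X_j + X_j T.  A prognostic-only marker gets a small
  main-effect weight but a large interaction weight, steering selection
  toward the main effect.
* ``ridge`` — reciprocals of absolute ridge Cox coefficients on the full
  2p-column design, ridge penalty tuned by 5-fold cross-validated
  log-likelihood.

Degenerate statistics are floored at 1e-8 so weights are capped at 1e8 —
columns with capped weights are effectively excluded but keep the design at
full width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _fast
from .core_survival import SurvivalDataset, _risk_order
from .design import build_interaction_design, standardize

__all__ = ["WeightVector", "sw_weights", "lrt_weights", "ridge_weights"]

STAT_FLOOR = 1e-8
WEIGHT_CAP = 1e8


@dataclass
class WeightVector:
    """2p penalty factors plus diagnostics; the treatment slot is always 0."""

    omega: np.ndarray
    scheme: str
    diagnostics: dict = field(default_factory=dict)
    treatment_penalty: float = 0.0

    @property
    def p(self) -> int:
        return self.omega.shape[0] // 2

    def normalized(self) -> "WeightVector":
        """Rescale so the mean over the 2p penalized entries equals 1.

        Keeps the lambda grid comparable across schemes and replicates; the
        rescale is absorbed by the tuning of lambda and does not change the
        selected model at the cross-validated optimum.
        """
        scale = self.omega.mean()
        return WeightVector(self.omega / scale, self.scheme, self.diagnostics)

    def to_frame(self) -> pd.DataFrame:
        """Two-column audit table (column_id, omega); columns are 1..2p."""
        return pd.DataFrame(
            {"column_id": np.arange(1, self.omega.shape[0] + 1), "omega": self.omega}
        )


def _cap_inverse(stats: np.ndarray) -> np.ndarray:
    return np.clip(1.0 / np.maximum(stats, STAT_FLOOR), 1.0 / WEIGHT_CAP, WEIGHT_CAP)


def _sorted_arrays(data: SurvivalDataset):
    order, _, ev, risk_start = _risk_order(data.time, data.event)
    return order, ev, risk_start


def sw_weights(data: SurvivalDataset) -> WeightVector:
    """Single-Wald weights: ``(omega_j, omega_{p+j}) = (1/W_j, 1/W_j)``."""
    if data.n_events == 0:
        raise ValueError("no events: no risk information in the data")
    order, ev, risk_start = _sorted_arrays(data)
    W = _fast.sw_wald_batch(
        np.ascontiguousarray(data.X[order]),
        np.ascontiguousarray(data.treatment[order]),
        ev,
        risk_start,
        1e-9,
        25,
    )
    w_group = _cap_inverse(W)
    omega = np.concatenate([w_group, w_group])
    return WeightVector(omega, "SW", {"wald": W})


def lrt_weights(data: SurvivalDataset) -> WeightVector:
    """LRT weights: ``(1/Lambda(M2/M0), 1/Lambda(M2/M1))`` per group."""
    if data.n_events == 0:
        raise ValueError("no events: no risk information in the data")
    order, ev, risk_start = _sorted_arrays(data)
    lam20, lam21 = _fast.lrt_batch(
        np.ascontiguousarray(data.X[order]),
        np.ascontiguousarray(data.treatment[order]),
        ev,
        risk_start,
        1e-9,
        25,
    )
    omega = np.concatenate([_cap_inverse(lam20), _cap_inverse(lam21)])
    return WeightVector(omega, "LRT", {"lambda_m2_m0": lam20, "lambda_m2_m1": lam21})


def ridge_weights(
    data: SurvivalDataset,
    lambda_grid: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
) -> WeightVector:
    """Ridge-based weights: ``(1/|theta_j^R|, 1/|theta_{p+j}^R|)``.

    Fits a ridge Cox model on the standardized 2p design (treatment
    unpenalized), tunes the ridge penalty on a log-spaced grid by k-fold
    cross-validated log-likelihood, and inverts the absolute coefficients on
    the original scale.
    """
    # imported here: penalized imports nothing from weighting, so no cycle
    from .penalized import cvl_ridge_select

    if data.n_events == 0:
        raise ValueError("no events: no risk information in the data")
    design = standardize(build_interaction_design(data))
    if lambda_grid is None:
        # on the loglik/n scale the useful shrinkage range is ~[1e-3, 30];
        # smaller ridge penalties leave a p >> events fit unstabilized
        lambda_grid = np.logspace(1.5, -3, 20)
    theta, lam = cvl_ridge_select(
        data.time, data.event, design, lambda_grid, k=folds, seed=seed
    )
    if np.max(np.abs(theta)) < 1e-8:
        raise ValueError(
            "ridge solution is numerically zero at the tuned penalty; "
            "widen the ridge lambda grid toward smaller values"
        )
    omega = _cap_inverse(np.abs(theta))
    return WeightVector(omega, "ridge", {"theta_ridge": theta, "ridge_lambda": lam})
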