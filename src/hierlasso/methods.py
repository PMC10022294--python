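"""One-call fitting of the named adaptive-lasso methods.

``fit_method`` runs the full pipeline on a trial dataset: build the
``(X | XT)`` design, standardize it, compute the scheme's penalty factors,
normalize them, lay out the lambda grid, tune lambda by 5-fold
cross-validated log-likelihood, and return the fit at the tuned lambda.
"A biomarker is selected" means its coefficient is exactly nonzero there;
the treatment coefficient is never penalized.
"""

from __future__ import annotations

import numpy as np

from .core_survival import SurvivalDataset
from .design import build_interaction_design, standardize
from .penalized import PenalizedFit, cvl_select, lambda_grid
from .weighting import (
    WEIGHT_CAP,
    WeightVector,
    lrt_weights,
    ridge_weights,
    sw_weights,
)

__all__ = ["METHODS", "fit_method", "hierarchy_ratio"]

METHODS = ("AL-SW", "AL-LRT", "AL-ridge")


def _compute_weights(data: SurvivalDataset, method: str, seed: int) -> WeightVector:
    if method == "AL-SW":
        return sw_weights(data)
    if method == "AL-LRT":
        return lrt_weights(data)
    if method == "AL-ridge":
        # independent fold seed for the preliminary ridge tuning
        ridge_seed = int(np.random.SeedSequence([seed, 104729]).generate_state(1)[0] % (2**31))
        return ridge_weights(data, seed=ridge_seed)
    raise ValueError(f"unknown method {method!r}; choose one of {METHODS}")


def fit_method(
    data: SurvivalDataset,
    method: str,
    k: int = 5,
    seed: int = 0,
    n_lambda: int = 100,
    min_ratio: float | None = None,
) -> PenalizedFit:
    """Fit one named method (AL-SW, AL-LRT or AL-ridge) on a dataset.

    Deterministic for fixed ``(data, method, seed)``: the cross-validation
    folds (and the ridge preliminary folds for AL-ridge) are drawn from
    seeds derived from ``seed``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose one of {METHODS}")
    try:
        design = standardize(build_interaction_design(data))
        weights = _compute_weights(data, method, seed)
        omega = weights.omega.copy()
        if design.zero_variance is not None:
            omega[design.zero_variance] = WEIGHT_CAP  # flat columns never enter
        weights_norm = WeightVector(omega, weights.scheme, weights.diagnostics).normalized()
        grid = lambda_grid(
            data.time, data.event, design, weights_norm, n_lambda, min_ratio
        )
        fold_seed = int(np.random.SeedSequence([seed, 15485863]).generate_state(1)[0] % (2**31))
        path = cvl_select(
            data.time, data.event, design, weights_norm, grid, k=k, seed=fold_seed
        )
    except Exception as err:
        raise type(err)(f"[method={method} seed={seed}] {err}") from err
    best = path.selected_index
    coef = path.coefficients_per_lambda[best]
    return PenalizedFit(
        alpha_hat=float(coef[0]),
        theta_hat=coef[1:].copy(),
        lambda_=float(path.grid[best]),
        weights=weights_norm,
        path=path,
        diagnostics={"method": method, "seed": seed, "scheme_weights": weights},
    )


def hierarchy_ratio(fit: PenalizedFit) -> float:
    """Share of selected interactions whose main effect is also selected.

    ``|{j: interaction j and main j selected}| / |{j: interaction j
    selected}|``; NaN (undefined) when no interaction is selected.
    """
    inter = set(fit.selected_interactions.tolist())
    if not inter:
        return float("nan")
    mains = set(fit.selected_mains.tolist())
    return len(inter & mains) / len(inter)
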