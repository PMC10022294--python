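"""Hierarchy-aware selection metrics, IPCW concordance, and resampling.

Selection accounting
--------------------
Interactions are scored against the true predictive set directly.  Main
effects are scored *conditionally on the interaction*: the main effect of a
truly predictive marker is a true positive when both its interaction and the
main effect are selected, and a false negative when the interaction is
selected without the main effect or not selected at all; the main effect of
a non-predictive marker contributes a false positive only when it accompanies
a (falsely) selected interaction.  FDR = FP/(TP+FP) and FNR = FN/(TP+FN) are
computed per replicate and averaged over replicates where they are defined
(an empty denominator is reported as NaN and excluded, with the exclusion
count carried along).

Concordance
-----------
``uno_cstat`` is the inverse-probability-of-censoring-weighted C-statistic:
usable pairs are (i, j) with an event for i, ``t_i < t_j`` and ``t_i < tau``,
each weighted by ``1 / G(t_i)^2`` where G is the Kaplan-Meier curve of the
censoring distribution; tied scores count 1/2.  ``delta_cstat`` is the
absolute between-arm difference of the concordance of the interaction score
(selected interaction coefficients times their biomarker values), a measure
of treatment-effect-modification strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_survival import SurvivalDataset
from .penalized import PenalizedFit
from .simulation import ScenarioConfig

__all__ = [
    "ReplicateMetrics",
    "selection_metrics",
    "interaction_score",
    "uno_cstat",
    "delta_cstat",
    "aggregate_replicates",
    "stability_selection",
]


@dataclass
class ReplicateMetrics:
    """Per-replicate selection and concordance summaries (NaN = undefined)."""

    n_pe: int
    n_po: int
    tp_int: int
    fp_int: int
    fn_int: int
    tp_main: int
    fp_main: int
    fn_main: int
    fdr_int: float
    fnr_int: float
    fdr_main: float
    fnr_main: float
    c_train: float = np.nan
    c_valid: float = np.nan
    delta_c_train: float = np.nan
    delta_c_valid: float = np.nan


def _rate(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def selection_metrics(fit: PenalizedFit, truth: ScenarioConfig) -> ReplicateMetrics:
    """Score one fit against the scenario's true predictive set."""
    true_pe = set(truth.predictive_indices)
    sel_int = set(fit.selected_interactions.tolist())
    sel_main = set(fit.selected_mains.tolist())

    tp_int = len(sel_int & true_pe)
    fp_int = len(sel_int - true_pe)
    fn_int = len(true_pe - sel_int)

    # conditional main-effect accounting (see module docstring)
    tp_main = len(sel_int & true_pe & sel_main)
    fn_main = len(true_pe - (sel_int & sel_main))
    fp_main = len((sel_int - true_pe) & sel_main)

    return ReplicateMetrics(
        n_pe=tp_int + fp_int,
        n_po=tp_main + fp_main,
        tp_int=tp_int,
        fp_int=fp_int,
        fn_int=fn_int,
        tp_main=tp_main,
        fp_main=fp_main,
        fn_main=fn_main,
        fdr_int=_rate(fp_int, tp_int + fp_int),
        fnr_int=_rate(fn_int, tp_int + fn_int),
        fdr_main=_rate(fp_main, tp_main + fp_main),
        fnr_main=_rate(fn_main, tp_main + fn_main),
    )


def interaction_score(fit: PenalizedFit, data: SurvivalDataset) -> np.ndarray:
    """Per-patient score: sum of selected interaction coefficients times the
    patient's biomarker values (no treatment factor)."""
    gamma = fit.theta_hat[fit.p :]
    sel = np.flatnonzero(gamma != 0)
    if sel.size == 0:
        return np.zeros(data.n)
    return data.X[:, sel] @ gamma[sel]


def _censoring_km(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier curve of the censoring distribution G(t)."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    cens = 1 - event[order]
    uniq, first = np.unique(t, return_index=True)
    n = t.shape[0]
    surv = np.empty(uniq.shape[0])
    g = 1.0
    for k, (u, i0) in enumerate(zip(uniq, first)):
        i1 = first[k + 1] if k + 1 < uniq.shape[0] else n
        at_risk = n - i0
        d = cens[i0:i1].sum()
        if at_risk > 0:
            g *= 1.0 - d / at_risk
        surv[k] = g
    return uniq, surv


def _km_eval(uniq: np.ndarray, surv: np.ndarray, t: np.ndarray) -> np.ndarray:
    """G evaluated just before t (left limit), right-continuous step curve."""
    idx = np.searchsorted(uniq, t, side="left") - 1
    out = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
    return out


def uno_cstat(
    score: np.ndarray, data: SurvivalDataset, tau: float | None = None
) -> float:
    """IPCW-weighted concordance of a risk score with shorter survival."""
    if data.n_events == 0:
        raise ValueError("concordance needs at least one event")
    time, event = data.time, data.event
    if tau is None:
        tau = float(np.quantile(time, 0.95))
    uniq, surv = _censoring_km(time, event)
    g_at = _km_eval(uniq, surv, time)

    score = np.asarray(score, dtype=float)
    i_idx = np.flatnonzero((event == 1) & (time < tau))
    num = 0.0
    den = 0.0
    for i in i_idx:
        usable = time > time[i]
        if not usable.any():
            continue
        gi = g_at[i]
        if gi <= 0:
            continue
        w = 1.0 / gi**2
        diff = score[i] - score[usable]
        num += w * (np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
        den += w * usable.sum()
    if den == 0:
        return 0.5
    return float(num / den)


def delta_cstat(
    fit: PenalizedFit, data: SurvivalDataset, tau: float | None = None
) -> float:
    """Absolute between-arm difference of the Uno concordance of the
    interaction score.  NaN when an arm has no events."""
    score = interaction_score(fit, data)
    cs = []
    for arm in (0.5, -0.5):
        mask = data.treatment == arm
        sub = data.subset(np.flatnonzero(mask))
        if sub.n == 0 or sub.n_events == 0:
            return float("nan")
        cs.append(uno_cstat(score[mask], sub, tau))
    return float(abs(cs[0] - cs[1]))


_MEAN_FIELDS = [
    "n_pe",
    "n_po",
    "tp_int",
    "fp_int",
    "fn_int",
    "tp_main",
    "fp_main",
    "fn_main",
    "fdr_int",
    "fnr_int",
    "fdr_main",
    "fnr_main",
    "c_train",
    "c_valid",
    "delta_c_train",
    "delta_c_valid",
]


def aggregate_replicates(metrics: list[ReplicateMetrics]) -> pd.DataFrame:
    """Tidy per-metric summary: mean, sd, count of undefined replicates.

    Ratio metrics are averaged per replicate (mean of ratios); undefined
    replicates are excluded from the mean and counted.
    """
    if not metrics:
        raise ValueError("need at least one replicate")
    rows = []
    for name in _MEAN_FIELDS:
        vals = np.array([getattr(m, name) for m in metrics], dtype=float)
        defined = np.isfinite(vals)
        rows.append(
            {
                "metric": name,
                "mean": float(vals[defined].mean()) if defined.any() else np.nan,
                "sd": float(vals[defined].std(ddof=1))
                if defined.sum() > 1
                else np.nan,
                "n_undefined": int((~defined).sum()),
                "n": len(metrics),
            }
        )
    out = pd.DataFrame(rows).set_index("metric")
    n_pe, n_po = out.loc["n_pe", "mean"], out.loc["n_po", "mean"]
    out.loc["hierarchy_pct", ["mean", "sd", "n_undefined", "n"]] = [
        100.0 * n_po / n_pe if n_pe > 0 else np.nan,
        np.nan,
        0,
        len(metrics),
    ]
    return out


def stability_selection(
    data: SurvivalDataset,
    method: str,
    n_splits: int = 500,
    train_fraction: float = 0.6,
    seed: int = 0,
    fit_kwargs: dict | None = None,
):
    """Resampled train/validation selection stability.

    Repeatedly splits the cohort (stratified draws are not used; a split
    whose training part has no events is redrawn and logged), fits the
    method on the training part, and tracks per-biomarker selection
    frequencies of the interaction, the hierarchy proportion (share of
    interaction-selecting splits that also select the main effect), and the
    validation-set concordances.

    Returns ``(per_marker: DataFrame, per_split: DataFrame)``.
    """
    from .methods import fit_method  # local import to avoid a cycle

    if n_splits < 1:
        raise ValueError("need at least one split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train fraction must be in (0, 1)")
    fit_kwargs = fit_kwargs or {}
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * data.n))
    int_count = np.zeros(data.p, dtype=np.int64)
    both_count = np.zeros(data.p, dtype=np.int64)
    split_rows = []
    redraws = 0
    for b in range(n_splits):
        while True:
            perm = rng.permutation(data.n)
            tr, va = perm[:n_train], perm[n_train:]
            if data.event[tr].sum() > 0 and data.event[va].sum() > 0:
                break
            redraws += 1
        train, valid = data.subset(tr), data.subset(va)
        fit_seed = int(
            np.random.SeedSequence([seed, b, 32452843]).generate_state(1)[0] % (2**31)
        )
        fit = fit_method(train, method, seed=fit_seed, **fit_kwargs)
        sel_i = fit.selected_interactions - 1
        sel_m = set(fit.selected_mains.tolist())
        int_count[sel_i] += 1
        for j in fit.selected_interactions:
            if j in sel_m:
                both_count[j - 1] += 1
        score_v = interaction_score(fit, valid)
        lp_v = (
            fit.alpha_hat * valid.treatment
            + valid.X @ fit.theta_hat[: fit.p]
            + (valid.X * valid.treatment[:, None]) @ fit.theta_hat[fit.p :]
        )
        split_rows.append(
            {
                "split": b,
                "n_selected_interactions": int(sel_i.size),
                "delta_c_valid": delta_cstat(fit, valid),
                "c_valid": uno_cstat(lp_v, valid),
            }
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        hier = np.where(int_count > 0, both_count / np.maximum(int_count, 1), np.nan)
    per_marker = pd.DataFrame(
        {
            "biomarker": np.arange(1, data.p + 1),
            "interaction_frequency": int_count / n_splits,
            "hierarchy_proportion": hier,
        }
    )
    per_split = pd.DataFrame(split_rows)
    per_split.attrs["n_redraws"] = redraws
    return per_marker, per_split
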