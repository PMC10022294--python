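# hierlasso

Selection of biomarker–treatment interactions in high-dimensional Cox models
for randomized clinical trials, with adaptive-lasso weighting schemes that
*favor* the hierarchical (strong-heredity) constraint: when an interaction
`X_j × T` enters the model, its biomarker main effect `X_j` should come
along.

Intended users: biostatisticians analysing RCTs with omics covariates who
want sparse treatment-effect-modifier discovery with interpretable
(hierarchical) models, and methodologists running simulation studies of such
selectors.

## Model

For treatment `T ∈ {−1/2, +1/2}` (1:1 randomization) and `p` standardized
biomarkers `X`, the full Cox proportional-hazards interaction model is

    λ(t | T, X) = λ0(t) · exp( αT + Σ_j β_j X_j + Σ_j γ_j X_j T )

Selection works on the bi-level reparametrization `V = (X | XT)` with
coefficients `θ = (θ_1..θ_2p)`, grouping each main effect `θ_j` with its
interaction `θ_{p+j}`.  The adaptive lasso maximizes the penalized partial
log-likelihood

    ℓ(α, θ) − λ Σ_j ( ω_j |θ_j| + ω_{p+j} |θ_{p+j}| )

with the treatment coefficient α unpenalized and per-column penalty factors
ω estimated in a preliminary stage:

* **AL-SW** — `ω_j = ω_{p+j} = 1 / W_j`, where `W_j` is the Wald chi-square
  of the univariable interaction-only Cox model `λ0(t)·exp(γ_j X_j T)`.
  Sharing one weight per group ties the pair's fate together.
* **AL-LRT** — `ω_j = 1/Λ(M2/M0)`, `ω_{p+j} = 1/Λ(M2/M1)` from the nested
  Cox models M0 (treatment), M1 (+ biomarker), M2 (+ interaction).  A purely
  prognostic marker gets a small main-effect weight but a large interaction
  weight.
* **AL-ridge** — `ω = 1/|θ̃^R|` from a cross-validation-tuned ridge Cox fit
  on the full design.

λ is tuned by 5-fold cross-validated partial log-likelihood
(`cvl(λ) = Σ_folds [ℓ_full(β̂^(−k)) − ℓ^(−k)(β̂^(−k))]`, event-stratified
folds, ties toward the sparser λ).  The package also ships the matching RCT
simulator (blockwise AR(1)-correlated Gaussian biomarkers, exponential
survival with 1-year median modulated by the Cox linear predictor, U(2,5)
censoring), hierarchy-aware selection metrics (main-effect TP/FP/FN inherit
the status of the selected interaction), Uno's IPCW C-statistic and the
between-arm ΔC-statistic, scenario sweeps, and resampled selection
stability.  See `docs/methods.md` for assumptions and numerical choices.

## Worked example

```bash
python examples/02_fit_adaptive_lasso.py
```

```
treatment log-HR estimate: -0.590 (true ln 0.5 = -0.693)
tuned lambda             : 8.8206
selected interactions    : [1]
selected main effects    : []
hierarchy ratio          : 0.00
interaction-1 coefficient: -0.544 (true gamma = -0.693)
```

A 600-patient, 50-marker trial with one true treatment-modifying biomarker:
AL-LRT recovers exactly the true interaction (marker 1) with a shrunken
coefficient (−0.544 vs the true −0.693, the usual lasso bias), and the
unpenalized treatment estimate sits near the true log hazard ratio.  On a
cohort this small the main effect of marker 1 (whose true `β` is 0) is not
selected, so the hierarchy ratio is 0; `examples/04_evaluate_selection.py`
and `examples/06_stability_selection.py` show the hierarchy-aware metrics on
richer fits.  The other examples cover the simulator, the weighting schemes,
replicated scenario sweeps and stability selection.

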