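# Methods

## Problem and model

A two-arm randomized trial (treatment coded `T = ±1/2`) with survival
outcome and `p` biomarkers, `p` of the order of the sample size or larger.
The working model is the full Cox proportional-hazards interaction model

    λ(t | T, X) = λ0(t) exp( αT + Σ_j β_j X_j + Σ_j γ_j X_j T ),

estimated through the Breslow partial likelihood (ties share the full risk
set; no Efron correction, no stratified baselines, no time-varying effects).
The target of inference is the support of `γ` — which biomarkers modify the
treatment effect — under a preference for *strong heredity*: a selected
interaction should be accompanied by its main effect.  The constraint is
favored, not forced: selection happens on the bi-level design
`V = (X | XT)` with group `j = {θ_j, θ_{p+j}}` and per-column adaptive
weights, so a lone interaction is possible but expensive.

## Weighting schemes

All schemes invert a first-stage measure of evidence, with the statistic
floored at `1e-8` and the weight capped at `1e8` (a capped column stays in
the design but effectively cannot enter; this keeps bookkeeping of column
indices trivial).  Degenerate fits (flat likelihood, zero-variance columns)
produce the cap.  Before use, weights are rescaled so their mean over the
2p penalized entries is 1 — the convention of penalty-factor solvers — which
only relabels λ and keeps grids comparable across schemes and replicates.

* Single Wald (SW): the univariable interaction-only model
  `λ0(t) exp(γ_j X_j T)` is fitted per marker *without* a treatment main
  effect; `W_j = (γ̂_j/se)²` and both group members get `1/W_j`.
* Likelihood ratio (LRT): `M0` (treatment only, fitted once), `M1`
  (treatment + marker), `M2` (treatment + marker + interaction);
  `ω_j = 1/Λ(M2/M0)`, `ω_{p+j} = 1/Λ(M2/M1)`, statistics clamped at zero.
* Ridge: the 2p-column ridge Cox fit (treatment unpenalized), ridge penalty
  tuned by 5-fold cross-validated likelihood on a log-spaced grid
  `10^1.5 … 10^-3` (on the `loglik/n` scale; smaller penalties leave a
  `p ≫ events` fit unstabilized), weights `1/|θ̃|` on the original scale.

The small Cox models use damped Newton iterations (step halving, relative
log-likelihood tolerance `1e-9`, 25 iterations).  Monotone-likelihood
divergence is detected as a coefficient above 10 in absolute value with
vanishing observed information and is reported as a flagged, clamped
(|b| ≤ 50) fit rather than an error; weights are computed from the clamped
statistic.

## Standardization

Penalized columns are standardized to mean 0, variance 1 on the training
data; interaction columns on their own statistics (a `±1/2` treatment halves
the scale of `X_j T`, and leaving that distortion in would misprice the
interaction block under a common λ).  Centering shifts the linear predictor
by a per-subject constant which the partial likelihood ignores; scales are
kept so coefficients are reported on the original scale.  Validation designs
reuse training statistics.

## Penalized solver

The objective is maximized as `ℓ/n − λ Σ ω_c |θ_c|` (ridge: `− λ Σ θ_c²`)
by iteratively reweighted least squares with coordinate-wise
soft-thresholding: per IRLS round the Breslow gradient and diagonal-Hessian
weights give a working response, and coordinate descent solves the weighted
penalized least-squares problem with an active-set cycle.  Convergence uses
the weighted squared coefficient change (`max_c colsq_c Δ_c² < 1e-7`), the
convention of the coordinate-descent Cox solvers this package mirrors; an
absolute per-coefficient criterion was tried first and proved incompatible
with a bounded update budget on blockwise-correlated designs near the path's
deep end.  Each λ is solved on the set of currently nonzero columns and the
full Karush–Kuhn–Tucker conditions are then checked from the exact gradient;
violating columns are added and the solve repeats, so inactive coordinates
are exact zeros and every reported solution is stationary for the complete
problem.

The λ grid is log-spaced over 3 decades (`min_ratio = 1e-3`, 100 points by
default, 50 in the quick mode used for replicated sweeps) from
`λ_max = max_c |score_c| / (n ω_c)` with the score taken at the
treatment-only fit, so the first grid point yields the exactly-null
penalized model.  Across trial-scale simulations the cross-validated optimum
sits at `λ/λ_max ≈ 0.005–0.3`; below `~1e-3` fits saturate (more active
columns than events).  Two early exits protect the replicated sweeps without
affecting selection: a fit that stops converging ends the path (selection is
then restricted to the grid prefix all folds reached), and the walk stops
once the cvl has fallen 200 log-likelihood units below its running maximum —
two orders of magnitude beyond any plateau noise observed.

## Tuning

`cvl(λ) = Σ_k [ ℓ_full(β̂^{(−k)}) − ℓ^{(−k)}(β̂^{(−k)}) ]` with `k = 5`
folds stratified by event status (guards against event-free folds) and drawn
from the replicate's seed stream; ties break toward the larger, sparser λ.
"Selected" means exactly nonzero at the tuned λ; no post-hoc thresholding.

## Simulator

Each replicate draws `n_total = 3000` patients (split into equal training
and validation halves), 1:1 randomization, biomarkers standard Gaussian with
correlation `0.7^|i−j|` inside 20-marker blocks and independence across
blocks, latent event times exponential with rate `ln 2 · exp(lp)` (median
survival 1 year at `lp = 0`), `lp = αT + Σ β_j X_j + Σ γ_j X_j T`, censoring
uniform on 2–5 years (3-year accrual, 2-year follow-up), observed time the
minimum of the two.  Effect sizes default to `α = β = γ = ln 0.5`.  True
predictive markers occupy the first column of successive blocks and
prognostic markers the following blocks, keeping true markers mutually
near-uncorrelated; both sets are configurable.  Scenario presets: null
(s1), one predictive (s2), ten predictive (s3), ten predictive + ten
disjoint prognostic (s4), and s4 with `p = 5000` (s4b).

The closed-form censoring probability of this generator
(`E_lp[(e^{−2r} − e^{−5r})/(3r)]`, `r = ln 2 · e^{lp}`) is 0.121 / 0.133 /
0.204 / 0.307 for s1–s4.  A reference tabulation this study tracks lists
0.10 for the null scenario, which corresponds to dropping the treatment
effect from the linear predictor — its own non-null rows match only with
the effect included — so the generator keeps the effect and the null-row
comparison is expected to disagree by ~0.015.

What a green simulation test does *not* establish: the generator has
independent, non-informative censoring, exponential baselines, and
effect sizes far above what trial biomarker panels usually show; real-data
behavior (measurement error, non-PH effects, correlated censoring) is out
of its scope.

## Evaluation

Interactions are scored against the true predictive set.  Main effects are
scored conditionally on the interaction: for a truly predictive marker the
main effect is a TP only when interaction and main are both selected, and an
FN when the interaction is selected alone or missed; for a non-predictive
marker the main effect is an FP only when it accompanies the falsely
selected interaction.  FDR = FP/(TP+FP) and FNR = FN/(TP+FN) are computed
per replicate and averaged over replicates where defined (mean of ratios;
undefined replicates are excluded and counted — zero-filling them would
distort the low-selection scenarios).

The interaction score is `Σ_{j selected} γ̂_j X_ij` (no treatment factor).
Concordance is Uno's IPCW C-statistic: usable pairs `(i, j)` with an event
for `i`, `t_i < t_j`, `t_i < τ`, weighted `1/G(t_i−)²` with `G` the
Kaplan–Meier curve of the censoring distribution; tied scores count 1/2;
`τ` defaults to the 95th percentile of observed times in the evaluated
sample.  ΔC is the absolute between-arm difference of the score's
concordance, computed per arm; an event-free arm yields an undefined value.

Stability selection repeats 60/40 train/validation splits, re-fits, and
reports per-marker interaction selection frequency and the hierarchy
proportion (splits selecting main and interaction over splits selecting the
interaction), plus per-split validation concordances.

## Reproducibility

Replicate `r` of an experiment with base seed `s` uses the child stream
`SeedSequence([s, r])`; fold seeds derive from the fit seed.  Summaries are
bit-identical across worker counts and run orders.

## Known limitations

* The comparator penalties (minimax-concave, group-exponential) are
  evaluable functions only; no solver is provided for them, and no
  sparse-group-lasso variant is included.
* In weak-signal scenarios the cross-validated-likelihood maximum is flat
  and the selected models are noise-dense (interaction FDR near 1); this is
  a property of max-cvl tuning itself — an independent R coordinate-descent
  Cox solver tuned the same way reproduces it — and sparser rules (e.g.
  one-standard-error or size-penalized criteria) would trade FNR for FDR.
* `p = 5000` configurations run but are slow (minutes per fit); the
  replicated sweeps target `p = 500`.
* The Newton fitter is for low-dimensional working models (≤ ~10 columns),
  as used by the weighting stage.
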