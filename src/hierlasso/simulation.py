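"""RCT survival simulator.

Emulates a two-arm 1:1 randomized trial with high-dimensional gene-expression
biomarkers:

* biomarkers are standard multivariate Gaussian, correlated in 20-marker
  blocks with AR(1) structure ``rho^|i-j|`` (rho = 0.7) and independence
  across blocks;
* latent event times are exponential with a median survival of 1 year at a
  null linear predictor, modulated by the Cox model
  ``lp = alpha T + sum_j beta_j X_j + sum_j gamma_j X_j T``;
* censoring times are uniform U(2, 5) years (3-year accrual, 2-year
  follow-up), observed time = min(latent, censoring);
* the cohort splits into equal training and validation halves.

Predictive markers (nonzero gamma) and prognostic markers (nonzero beta) are
placed by default on the first column of successive blocks, keeping the true
markers mutually near-uncorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

from .core_survival import SurvivalDataset

__all__ = [
    "ScenarioConfig",
    "TrialReplicate",
    "block_ar_covariance",
    "generate_replicate",
    "scenario_presets",
]

LN2 = float(np.log(2.0))
LN_HALF = float(np.log(0.5))


@dataclass(frozen=True)
class ScenarioConfig:
    """True-effect layout and generator settings for one scenario."""

    name: str = "custom"
    n_total: int = 3000
    p: int = 500
    block_size: int = 20
    rho: float = 0.7
    predictive_indices: tuple = ()  # 1-based biomarker indices with gamma != 0
    prognostic_indices: tuple = ()  # 1-based biomarker indices with beta != 0
    alpha_true: float = LN_HALF
    beta_true: float = LN_HALF
    gamma_true: float = LN_HALF
    baseline_rate: float = LN2  # events per year: median survival 1 year
    censoring_window: tuple = (2.0, 5.0)
    seed: int = 0

    def __post_init__(self):
        pe = set(self.predictive_indices)
        po = set(self.prognostic_indices)
        if pe & po:
            raise ValueError("predictive and prognostic index sets must be disjoint")
        for idx in pe | po:
            if not 1 <= idx <= self.p:
                raise ValueError(f"true-marker index {idx} outside 1..{self.p}")

    @property
    def q_pe(self) -> int:
        return len(self.predictive_indices)

    @property
    def q_po(self) -> int:
        return len(self.prognostic_indices)

    def linear_predictor(self, X: np.ndarray, treatment: np.ndarray) -> np.ndarray:
        lp = self.alpha_true * treatment
        for j in self.predictive_indices:
            lp = lp + self.gamma_true * X[:, j - 1] * treatment
        for j in self.prognostic_indices:
            lp = lp + self.beta_true * X[:, j - 1]
        return lp

    def to_json(self, path) -> None:
        """Truth sidecar for serialized replicates."""
        payload = {
            "name": self.name,
            "n_total": self.n_total,
            "p": self.p,
            "block_size": self.block_size,
            "rho": self.rho,
            "predictive_indices": list(self.predictive_indices),
            "prognostic_indices": list(self.prognostic_indices),
            "alpha_true": self.alpha_true,
            "beta_true": self.beta_true,
            "gamma_true": self.gamma_true,
            "baseline_rate": self.baseline_rate,
            "censoring_window": list(self.censoring_window),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class TrialReplicate:
    """Disjoint training/validation halves drawn from one generative law."""

    training: SurvivalDataset
    validation: SurvivalDataset
    truth: ScenarioConfig
    replicate_id: int


def block_ar_covariance(p: int, block_size: int = 20, rho: float = 0.7) -> np.ndarray:
    """Block-diagonal AR(1) correlation: ``rho^|i-j|`` within blocks of
    ``block_size`` markers, zero across blocks (last block may be short)."""
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    cov = np.zeros((p, p))
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        idx = np.arange(start, stop)
        cov[np.ix_(idx, idx)] = rho ** np.abs(idx[:, None] - idx[None, :])
    return cov


def _draw_biomarkers(rng: np.random.Generator, n: int, p: int, block_size: int, rho: float):
    """Sample blockwise-AR(1) Gaussians via a per-block Cholesky factor."""
    X = np.empty((n, p))
    chol_cache: dict[int, np.ndarray] = {}
    for start in range(0, p, block_size):
        b = min(block_size, p - start)
        if b not in chol_cache:
            idx = np.arange(b)
            chol_cache[b] = np.linalg.cholesky(
                rho ** np.abs(idx[:, None] - idx[None, :])
            )
        Z = rng.standard_normal((n, b))
        X[:, start : start + b] = Z @ chol_cache[b].T
    return X


def generate_replicate(config: ScenarioConfig, replicate_id: int = 0) -> TrialReplicate:
    """Draw one trial replicate, split into equal training/validation halves.

    Reproducibility contract: the stream is derived from
    ``(config.seed, replicate_id)``, so replicates can be generated
    independently (and in parallel) in any order.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, replicate_id]))
    n = config.n_total
    treatment = np.where(rng.random(n) < 0.5, 0.5, -0.5)
    X = _draw_biomarkers(rng, n, config.p, config.block_size, config.rho)
    lp = config.linear_predictor(X, treatment)
    rate = config.baseline_rate * np.exp(lp)
    latent = rng.exponential(1.0 / rate)
    lo, hi = config.censoring_window
    censor = rng.uniform(lo, hi, n)
    observed = np.minimum(latent, censor)
    event = (latent <= censor).astype(np.int64)

    half = n // 2
    training = SurvivalDataset(observed[:half], event[:half], treatment[:half], X[:half])
    validation = SurvivalDataset(observed[half:], event[half:], treatment[half:], X[half:])
    return TrialReplicate(training, validation, config, replicate_id)


def _spaced_block_leads(n_blocks: int, block_size: int, offset: int = 0) -> tuple:
    """1-based indices of the first marker of ``n_blocks`` successive blocks
    starting after ``offset`` blocks."""
    return tuple(1 + (offset + b) * block_size for b in range(n_blocks))


def scenario_presets(seed: int = 0) -> dict[str, ScenarioConfig]:
    """The simulation-study scenarios.

    s1: null (no biomarker effect); s2: one predictive marker; s3: ten
    predictive markers; s4: ten predictive + ten disjoint prognostic
    markers; s4b: as s4 with p = 5000.
    """
    base = dict(n_total=3000, p=500, block_size=20, rho=0.7, seed=seed)
    return {
        "s1": ScenarioConfig(name="s1", **base),
        "s2": ScenarioConfig(
            name="s2", predictive_indices=_spaced_block_leads(1, 20), **base
        ),
        "s3": ScenarioConfig(
            name="s3", predictive_indices=_spaced_block_leads(10, 20), **base
        ),
        "s4": ScenarioConfig(
            name="s4",
            predictive_indices=_spaced_block_leads(10, 20),
            prognostic_indices=_spaced_block_leads(10, 20, offset=10),
            **base,
        ),
        "s4b": ScenarioConfig(
            name="s4b",
            n_total=3000,
            p=5000,
            block_size=20,
            rho=0.7,
            predictive_indices=_spaced_block_leads(10, 20),
            prognostic_indices=_spaced_block_leads(10, 20, offset=10),
            seed=seed,
        ),
    }


def expected_censoring_fraction(config: ScenarioConfig) -> float:
    """Closed-form censoring probability of the generator, by quadrature.

    ``P(censored) = E_lp [ integral_lo^hi (1/(hi-lo)) exp(-rate(lp) c) dc ]``
    with the expectation over the linear-predictor distribution taken by
    Monte Carlo over a large Gaussian draw of the true markers only.
    """
    rng = np.random.default_rng(12345)
    n = 200_000
    treatment = np.where(rng.random(n) < 0.5, 0.5, -0.5)
    q = config.q_pe + config.q_po
    if q:
        # true markers are mutually independent under the default placement
        X = rng.standard_normal((n, q))
        lp = config.alpha_true * treatment
        k = 0
        for _ in config.predictive_indices:
            lp = lp + config.gamma_true * X[:, k] * treatment
            k += 1
        for _ in config.prognostic_indices:
            lp = lp + config.beta_true * X[:, k]
            k += 1
    else:
        lp = config.alpha_true * treatment
    rate = config.baseline_rate * np.exp(lp)
    lo, hi = config.censoring_window
    # integral of exp(-r c) / (hi - lo) over [lo, hi]
    prob = (np.exp(-rate * lo) - np.exp(-rate * hi)) / (rate * (hi - lo))
    return float(prob.mean())


def write_replicate(rep: TrialReplicate, out_dir) -> None:
    """Serialize a replicate as training/validation CSVs plus truth JSON."""
    import os

    from .core_survival import write_survival_csv

    os.makedirs(out_dir, exist_ok=True)
    write_survival_csv(rep.training, os.path.join(out_dir, "training.csv"))
    write_survival_csv(rep.validation, os.path.join(out_dir, "validation.csv"))
    rep.truth.to_json(os.path.join(out_dir, "truth.json"))
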