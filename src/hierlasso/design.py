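"""Bi-level interaction design ``V = (X | XT)``.

Column ``j`` (0-based ``j-1``) is biomarker ``X_j`` and column ``p+j`` is the
product ``X_j T``; the two form group ``j``.  Group indices in all reports are
1-based.  The treatment column itself lives outside ``V`` and is never
penalized.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_survival import SurvivalDataset

__all__ = ["InteractionDesign", "build_interaction_design", "standardize"]


@dataclass
class InteractionDesign:
    """The ``n x 2p`` penalized design plus its group structure."""

    V: np.ndarray
    treatment: np.ndarray
    p: int
    column_means: np.ndarray | None = None
    column_scales: np.ndarray | None = None
    zero_variance: np.ndarray | None = None
    standardized: bool = False

    @property
    def n(self) -> int:
        return self.V.shape[0]

    def group_of_column(self, col: int) -> int:
        """1-based group index of a 0-based column of ``V``."""
        if not 0 <= col < 2 * self.p:
            raise IndexError(f"column {col} outside 0..{2 * self.p - 1}")
        return (col % self.p) + 1

    def main_column(self, group: int) -> int:
        return group - 1

    def interaction_column(self, group: int) -> int:
        return self.p + group - 1


def build_interaction_design(data: SurvivalDataset) -> InteractionDesign:
    """Assemble ``V = (X | XT)`` from a trial dataset (treatment +-0.5)."""
    if not np.isin(data.treatment, (-0.5, 0.5)).all():
        raise ValueError("treatment must be coded -0.5 / +0.5")
    V = np.hstack([data.X, data.X * data.treatment[:, None]])
    return InteractionDesign(V=V, treatment=data.treatment.copy(), p=data.p)


def standardize(
    design: InteractionDesign, reference: InteractionDesign | None = None
) -> InteractionDesign:
    """Center and scale every penalized column to mean 0, variance 1.

    Interaction columns are standardized on their own statistics, not those
    of the parent biomarker.  Zero-variance columns are flagged (they must be
    assigned the penalty cap downstream) and left centered with scale 1.
    When ``reference`` is given, its training statistics are applied instead
    (for validation designs).
    """
    if reference is not None:
        if reference.column_means is None:
            raise ValueError("reference design carries no standardization statistics")
        means, scales, zv = (
            reference.column_means,
            reference.column_scales,
            reference.zero_variance,
        )
    else:
        means = design.V.mean(axis=0)
        scales = design.V.std(axis=0)
        zv = scales < 1e-12
        scales = np.where(zv, 1.0, scales)
    Vs = (design.V - means) / scales
    return replace(
        design,
        V=Vs,
        column_means=means.copy(),
        column_scales=scales.copy(),
        zero_variance=zv.copy(),
        standardized=True,
    )


def unstandardize_coefficients(
    design: InteractionDesign, theta_std: np.ndarray
) -> np.ndarray:
    """Map coefficients on the standardized scale back to the original scale.

    Centering only shifts the linear predictor by a per-subject constant,
    which the partial likelihood ignores, so the back-transform is a pure
    rescale: ``theta = theta_std / scale``.  Zero patterns are preserved.
    """
    if not design.standardized:
        raise ValueError("design is not standardized")
    return theta_std / design.column_scales


def invert_standardization(design: InteractionDesign) -> np.ndarray:
    """Recover the original-design matrix from a standardized one."""
    if not design.standardized:
        raise ValueError("design is not standardized")
    return design.V * design.column_scales + design.column_means
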