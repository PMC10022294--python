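"""Evaluable comparator penalty functions (no solvers).

These are the building blocks of the bi-level comparator methods — the
composite minimax concave penalty and the group exponential lasso — kept
here as documented, testable functions.  Fitting with them is out of scope;
the package's selection methods are the adaptive-lasso schemes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mcp_penalty", "gel_penalty"]


def mcp_penalty(theta, lam: float, a: float):
    """Minimax concave penalty on ``theta >= 0``.

    ``lam*theta - theta^2/(2a)`` on ``theta <= a*lam`` and the constant
    ``a*lam^2/2`` beyond; continuously differentiable at the knot.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("MCP is defined on theta >= 0; pass |theta|")
    if lam < 0 or a <= 0:
        raise ValueError("require lam >= 0 and a > 0")
    return np.where(
        theta <= a * lam, lam * theta - theta**2 / (2.0 * a), 0.5 * a * lam**2
    )


def gel_penalty(theta, lam: float, tau: float):
    """Exponential penalty ``(lam^2/tau) * (1 - exp(-tau*theta/lam))``.

    Concave, increasing, bounded by ``lam^2/tau``, with slope ``lam`` at 0.
    ``lam = 0`` gives 0 by continuity.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("exponential penalty is defined on theta >= 0")
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must lie in (0, 1]")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if lam == 0:
        return np.zeros_like(theta)
    return (lam**2 / tau) * (1.0 - np.exp(-tau * theta / lam))
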