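"""Partial-correlation conditional-independence test (ParCorr).

The dependence measure used throughout graph discovery: regress ``x`` and
``y`` each on ``[intercept, Z]`` by least squares, take the Pearson
correlation ``rho`` of the residuals, and convert to a two-sided p-value
through the t statistic

.. math::

    t = \\rho \\sqrt{\\frac{n - |Z| - 2}{1 - \\rho^2}}

with ``n - |Z| - 2`` degrees of freedom (intercept counted).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["CITestResult", "parcorr_test"]


@dataclass
class CITestResult:
    rho: float
    p_value: float
    n_eff: int
    cond_set: list[tuple[int, int]] = field(default_factory=list)


def _residual_corr(x: np.ndarray, y: np.ndarray, Z: np.ndarray | None) -> tuple[float, int]:
    """(rho, dof) for the residual correlation of x, y given [1, Z]."""
    n = x.shape[0]
    k = 0 if Z is None else Z.shape[1]
    if n <= k + 2:
        raise ValueError("sample too small for conditioning set (need n > |Z| + 2)")
    design = np.empty((n, k + 1))
    design[:, 0] = 1.0
    if k:
        design[:, 1:] = Z
    rhs = np.column_stack([x, y])
    coef, _, rank, _ = np.linalg.lstsq(design, rhs, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("degenerate conditioning set: rank-deficient design")
    resid = rhs - design @ coef
    norms = np.linalg.norm(resid, axis=0)
    scale = max(np.linalg.norm(x - x.mean()), np.linalg.norm(y - y.mean()), 1.0)
    if np.any(norms <= 1e-12 * scale):
        raise ValueError("degenerate conditioning set: zero residual variance")
    rho = float(resid[:, 0] @ resid[:, 1] / (norms[0] * norms[1]))
    return float(np.clip(rho, -1.0, 1.0)), n - k - 2


def _rho_to_p(rho: float, dof: int) -> float:
    if 1.0 - rho * rho <= 0.0:
        return 0.0
    t = rho * np.sqrt(dof / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), dof))


def parcorr_test(
    x: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    cond_set: list[tuple[int, int]] | None = None,
) -> CITestResult:
    """ParCorr CI test of ``x`` against ``y`` given the columns of ``Z``.

    ``cond_set`` is an optional list of ``(variable, lag)`` labels recorded
    in the result for bookkeeping; it does not affect the computation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if Z is not None:
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != x.shape[0]:
            raise ValueError("Z must have the same number of rows as x and y")
        if Z.shape[1] == 0:
            Z = None
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have equal length")
    rho, dof = _residual_corr(x, y, Z)
    return CITestResult(
        rho=rho,
        p_value=_rho_to_p(rho, dof),
        n_eff=x.shape[0],
        cond_set=list(cond_set) if cond_set else [],
    )
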