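"""Pairwise Granger-causality F-tests (restricted vs. full nested OLS).

The restricted model regresses the sink on an intercept and its own ``L``
lags; the full model adds the ``L`` lags of the source.  Both are fitted
on the identical row set (rows lost to the longest lag dropped once), so
the nested-model F-statistic

.. math::

    F = \\frac{(RSS_r - RSS_f)/q}{RSS_f/(n - k)},
    \\qquad q = L, \\; k = 2L + 1

follows ``F(q, n - k)`` under the null that the source's lags add nothing.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import TimeSeriesPanel

__all__ = ["GrangerResult", "granger_f_test", "granger_scan", "scan_to_frame"]


@dataclass
class GrangerResult:
    source: int
    sink: int
    lag_order: int
    f_stat: float
    p_value: float
    rss_restricted: float
    rss_full: float
    n_used: int
    q: int
    k: int
    source_name: str | None = None
    sink_name: str | None = None


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient regression")
    resid = y - X @ coef
    return float(resid @ resid)


def granger_f_test(
    panel: TimeSeriesPanel | np.ndarray,
    source: int,
    sink: int,
    L: int,
) -> GrangerResult:
    """F-test of whether ``source``'s first ``L`` lags help predict ``sink``."""
    values = panel.values if isinstance(panel, TimeSeriesPanel) else np.asarray(panel, float)
    names = panel.names if isinstance(panel, TimeSeriesPanel) else None
    if L < 1:
        raise ValueError("lag order must be >= 1")
    T = values.shape[0]
    n_used = T - L
    k = 2 * L + 1
    if n_used <= k:
        raise ValueError("series too short for the requested lag order")
    y = values[L:, sink]
    sink_lags = np.column_stack([values[L - l: T - l, sink] for l in range(1, L + 1)])
    source_lags = np.column_stack([values[L - l: T - l, source] for l in range(1, L + 1)])
    ones = np.ones((n_used, 1))
    rss_r = _ols_rss(np.hstack([ones, sink_lags]), y)
    rss_f = _ols_rss(np.hstack([ones, sink_lags, source_lags]), y)
    f_stat = ((rss_r - rss_f) / L) / (rss_f / (n_used - k))
    p = float(stats.f.sf(f_stat, L, n_used - k))
    return GrangerResult(
        source=source,
        sink=sink,
        lag_order=L,
        f_stat=float(f_stat),
        p_value=p,
        rss_restricted=rss_r,
        rss_full=rss_f,
        n_used=n_used,
        q=L,
        k=k,
        source_name=names[source] if names else None,
        sink_name=names[sink] if names else None,
    )


def granger_scan(
    panel: TimeSeriesPanel | np.ndarray,
    sink: int,
    lags=range(1, 8),
) -> list[GrangerResult]:
    """One result per (source != sink, lag order), in deterministic order."""
    values = panel.values if isinstance(panel, TimeSeriesPanel) else np.asarray(panel, float)
    n_vars = values.shape[1]
    return [
        granger_f_test(panel, source, sink, L)
        for source in range(n_vars)
        if source != sink
        for L in lags
    ]


def scan_to_frame(results: list[GrangerResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "source": r.source_name if r.source_name is not None else r.source,
                "sink": r.sink_name if r.sink_name is not None else r.sink,
                "lag": r.lag_order,
                "f_stat": r.f_stat,
                "p_value": r.p_value,
                "n_used": r.n_used,
            }
        )
    return pd.DataFrame(rows)
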