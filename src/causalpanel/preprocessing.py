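"""Seasonal adjustment, detrending, and stationarity gating for daily panels.

Seasonality is removed by harmonic regression: an intercept plus one
sine/cosine pair per period ``p`` at angular frequency ``2*pi/p``.  A period
equal to the sampling interval (1 day) aliases to a constant, so it
contributes only the intercept; at period 2 the sine column vanishes on an
integer grid and is dropped.  Non-integer periods (365.25/12, 365.25) are
handled naturally.

Trends are removed by a local-linear smooth with a boxcar kernel (default
bandwidth 365 days), computed in O(T) with running sums.

Stationarity of the processed series is gated jointly: the ADF unit-root
test must reject (p < 0.05) *and* the KPSS level-stationarity test must not
(bracket "> 0.1").  Both tests come from statsmodels; KPSS p-values are
reported as brackets against the standard critical-value table since the
asymptotic tabulation only covers [0.01, 0.1].
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tools.sm_exceptions import InterpolationWarning
from statsmodels.tsa.stattools import adfuller, kpss

from .panel import TimeSeriesPanel

__all__ = [
    "DEFAULT_PERIODS",
    "StationarityReport",
    "seasonal_adjust",
    "detrend",
    "preprocess",
    "adf_test",
    "kpss_test",
    "stationarity_report",
]

#: The nine adjustment periods, in days.
DEFAULT_PERIODS = (1.0, 2.0, 3.0, 5.0, 7.0, 30.0, 31.0, 365.25 / 12.0, 365.25)

KPSS_BRACKETS = ("<0.01", "0.01–0.025", "0.025–0.05", "0.05–0.1", ">0.1")


@dataclass
class StationarityReport:
    """Per-variable ADF/KPSS record with the joint stationarity verdict."""

    variable: str
    adf_stat: float
    adf_p: float
    kpss_stat: float
    kpss_p_bracket: str
    kpss_p: float | None
    verdict: bool


def _harmonic_design(T: int, periods) -> np.ndarray:
    t = np.arange(T, dtype=float)
    cols = [np.ones(T)]
    for p in periods:
        if p <= 0:
            raise ValueError("periods must be positive")
        if p >= T:
            raise ValueError("period exceeds series length")
        if abs(p - 1.0) < 1e-12:
            continue  # aliases to the intercept on a daily grid
        w = 2.0 * np.pi / p
        for col in (np.sin(w * t), np.cos(w * t)):
            if np.ptp(col) > 1e-9:  # sin at period 2 vanishes on integers
                cols.append(col)
    return np.column_stack(cols)


def seasonal_adjust(panel: TimeSeriesPanel, periods=DEFAULT_PERIODS) -> TimeSeriesPanel:
    """Subtract the least-squares harmonic fit at the given periods."""
    if not len(tuple(periods)):
        raise ValueError("periods must be nonempty")
    design = _harmonic_design(panel.T, periods)
    coef, *_ = np.linalg.lstsq(design, panel.values, rcond=None)
    return panel.with_values(panel.values - design @ coef)


def _local_linear(y: np.ndarray, halfwidth: int) -> np.ndarray:
    """Boxcar local-linear smooth of y, evaluated at every index, via prefix sums."""
    T = y.shape[0]
    t = np.arange(T, dtype=float)
    ones = np.ones(T)

    def windowed(series: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0.0], np.cumsum(series)])
        lo = np.clip(np.arange(T) - halfwidth, 0, T)
        hi = np.clip(np.arange(T) + halfwidth + 1, 0, T)
        return c[hi] - c[lo]

    s0 = windowed(ones)
    s1 = windowed(t)
    s2 = windowed(t * t)
    sy = windowed(y)
    sty = windowed(t * y)
    # center the index at the evaluation point for conditioning
    c1 = s1 - t * s0
    c2 = s2 - 2.0 * t * s1 + t * t * s0
    cy = sty - t * sy
    det = s0 * c2 - c1 * c1
    return (sy * c2 - c1 * cy) / det


def detrend(panel: TimeSeriesPanel, bandwidth: int = 365) -> TimeSeriesPanel:
    """Remove a slowly varying trend (local-linear smooth, default 365-day window)."""
    if panel.T < 30:
        raise ValueError("detrend needs T >= 30")
    halfwidth = max(int(bandwidth) // 2, 2)
    out = np.empty_like(panel.values)
    for k in range(panel.n_vars):
        resid = panel.values[:, k] - _local_linear(panel.values[:, k], halfwidth)
        out[:, k] = resid - resid.mean()
    return panel.with_values(out)


def preprocess(
    panel: TimeSeriesPanel,
    periods=DEFAULT_PERIODS,
    bandwidth: int = 365,
) -> TimeSeriesPanel:
    """Seasonal adjustment followed by detrending."""
    return detrend(seasonal_adjust(panel, periods), bandwidth=bandwidth)


def _check_series(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] < 50:
        raise ValueError("stationarity tests need length >= 50")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: constant series")
    return x


def adf_test(x: np.ndarray) -> tuple[float, float]:
    """Augmented Dickey–Fuller test (intercept only, AIC lag selection).

    Small p-values support stationarity.  The regression includes no
    deterministic trend term: series are detrended before gating.
    """
    x = _check_series(x)
    stat, p, *_ = adfuller(x, regression="c", autolag="AIC")
    return float(stat), float(p)


def kpss_test(x: np.ndarray) -> tuple[float, str, float | None]:
    """KPSS level-stationarity test: (statistic, p bracket, point p when interpolable).

    Large p-values (bracket "> 0.1") support stationarity.  Uses the
    Newey–West long-run variance with automatic bandwidth.
    """
    x = _check_series(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", InterpolationWarning)
        stat, p, _, crit = kpss(x, regression="c", nlags="auto")
    if stat < crit["10%"]:
        bracket, point = ">0.1", None
    elif stat < crit["5%"]:
        bracket, point = "0.05–0.1", float(p)
    elif stat < crit["2.5%"]:
        bracket, point = "0.025–0.05", float(p)
    elif stat < crit["1%"]:
        bracket, point = "0.01–0.025", float(p)
    else:
        bracket, point = "<0.01", None
    return float(stat), bracket, point


def stationarity_report(panel: TimeSeriesPanel, alpha: float = 0.05) -> list[StationarityReport]:
    """Run both tests per variable and apply the joint verdict.

    A variable passes iff ADF rejects a unit root at ``alpha`` and KPSS
    fails to reject level stationarity (bracket "> 0.1").  Failing series
    are flagged, not dropped.
    """
    reports = []
    for k, name in enumerate(panel.names):
        adf_stat, adf_p = adf_test(panel.values[:, k])
        kpss_stat, bracket, point = kpss_test(panel.values[:, k])
        reports.append(
            StationarityReport(
                variable=name,
                adf_stat=adf_stat,
                adf_p=adf_p,
                kpss_stat=kpss_stat,
                kpss_p_bracket=bracket,
                kpss_p=point,
                verdict=bool(adf_p < alpha and bracket == ">0.1"),
            )
        )
    return reports


def report_to_frame(reports: list[StationarityReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])
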