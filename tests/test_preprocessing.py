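"""Seasonal adjustment, detrending, and the ADF/KPSS stationarity gate."""
import numpy as np
import pandas as pd
import pytest

from causalpanel import (
    TimeSeriesPanel,
    adf_test,
    detrend,
    kpss_test,
    preprocess,
    seasonal_adjust,
    stationarity_report,
    simulate_panel,
    study_mimic_spec,
)
from causalpanel.preprocessing import DEFAULT_PERIODS


def _panel(values):
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[0] == 1:
        values = values.T
    dates = pd.date_range("2012-01-01", periods=values.shape[0], freq="D")
    return TimeSeriesPanel(dates=dates, values=values)


def test_constant_series_becomes_zero_mean():
    out = seasonal_adjust(_panel(np.full(400, 7.3)), periods=(1, 7))
    np.testing.assert_allclose(out.values, 0.0, atol=1e-10)


def test_weekly_sine_power_is_removed():
    t = np.arange(2800)
    x = np.sin(2 * np.pi * t / 7)
    out = seasonal_adjust(_panel(x), periods=DEFAULT_PERIODS)
    freqs = np.fft.rfftfreq(2800)
    k = np.argmin(np.abs(freqs - 1 / 7))
    power_in = np.abs(np.fft.rfft(x))[k] ** 2
    power_out = np.abs(np.fft.rfft(out.values[:, 0]))[k] ** 2
    assert power_out <= 0.01 * power_in


def test_white_noise_is_barely_touched():
    rng = np.random.default_rng(0)
    x = rng.normal(size=2800)
    out = seasonal_adjust(_panel(x), periods=DEFAULT_PERIODS)
    assert np.corrcoef(x, out.values[:, 0])[0, 1] > 0.95


def test_seasonal_adjust_is_idempotent():
    rng = np.random.default_rng(1)
    t = np.arange(1000)
    x = np.cos(2 * np.pi * t / 30) + rng.normal(size=1000)
    once = seasonal_adjust(_panel(x), periods=DEFAULT_PERIODS)
    twice = seasonal_adjust(once, periods=DEFAULT_PERIODS)
    assert np.max(np.abs(twice.values - once.values)) < 1e-8


def test_period_exceeding_length_is_rejected():
    with pytest.raises(ValueError, match="period exceeds"):
        seasonal_adjust(_panel(np.zeros(100)), periods=(150,))


def test_detrend_removes_linear_ramp():
    t = np.arange(2000, dtype=float)
    out = detrend(_panel(0.01 * t))
    slope = np.polyfit(t, out.values[:, 0], 1)[0]
    assert abs(slope) < 1e-4
    assert abs(out.values[:, 0].mean()) < 1e-10


def test_detrend_leaves_white_noise_alone():
    rng = np.random.default_rng(2)
    x = rng.normal(size=2000)
    out = detrend(_panel(x))
    assert np.corrcoef(x, out.values[:, 0])[0, 1] > 0.95


def test_detrend_restores_stationarity_of_ramp_plus_ar_noise():
    hits = 0
    n_seeds = 40
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        eps = rng.normal(size=800)
        x = np.empty(800)
        x[0] = eps[0]
        for t in range(1, 800):
            x[t] = 0.4 * x[t - 1] + eps[t]
        x += 0.02 * np.arange(800)
        _, p = adf_test(detrend(_panel(x)).values[:, 0])
        hits += p < 0.05
    assert hits >= 0.95 * n_seeds


@pytest.mark.parametrize(
    "kind,expect",
    [("iid", "reject_unit_root"), ("walk", "keep_unit_root")],
)
def test_adf_level_and_power(kind, expect):
    n_seeds, T = 60, 600
    hits = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        eps = rng.normal(size=T)
        x = eps if kind == "iid" else np.cumsum(eps)
        _, p = adf_test(x)
        hits += (p < 0.05) if expect == "reject_unit_root" else (p > 0.05)
    assert hits >= (0.95 if expect == "reject_unit_root" else 0.90) * n_seeds


@pytest.mark.parametrize(
    "kind,bracket",
    [("iid", ">0.1"), ("walk", "<0.01")],
)
def test_kpss_brackets(kind, bracket):
    n_seeds, T = 60, 600
    hits = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(2000 + seed)
        eps = rng.normal(size=T)
        x = eps if kind == "iid" else np.cumsum(eps)
        _, got, _ = kpss_test(x)
        hits += got == bracket
    assert hits >= 0.90 * n_seeds


def test_degenerate_series_rejected_by_both_tests():
    x = np.ones(100)
    with pytest.raises(ValueError, match="degenerate"):
        adf_test(x)
    with pytest.raises(ValueError, match="degenerate"):
        kpss_test(x)


def test_preprocess_preserves_shape_and_dates(mimic_panel):
    clean = preprocess(mimic_panel)
    assert clean.values.shape == mimic_panel.values.shape
    assert (clean.dates == mimic_panel.dates).all()
    assert clean.names == mimic_panel.names


def test_contaminated_mimic_panel_passes_the_gate():
    """Seasonality at the nine periods + trend is cleaned to stationarity."""
    spec = study_mimic_spec(seasonal_amplitude=1.0, trend_slope=0.002)
    panel = simulate_panel(spec, T=2923, seed=42)
    reports = stationarity_report(preprocess(panel))
    assert all(r.verdict for r in reports)
    assert all(r.kpss_p_bracket == ">0.1" for r in reports)
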