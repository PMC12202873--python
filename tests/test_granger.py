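"""Granger F-tests: oracle equivalence, nesting, calibration, invariances."""
import numpy as np
import pytest
from scipy import stats

from causalpanel import SCMSpec, granger_f_test, granger_scan, simulate_panel
from conftest import noise_panel


def _normal_equations_f(values, source, sink, L):
    """Independent oracle: explicit normal-equations OLS for both models."""
    T = values.shape[0]
    n = T - L
    y = values[L:, sink]
    Xr = np.hstack(
        [np.ones((n, 1))] + [values[L - l: T - l, [sink]] for l in range(1, L + 1)]
    )
    Xf = np.hstack(
        [Xr] + [values[L - l: T - l, [source]] for l in range(1, L + 1)]
    )

    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return r @ r

    rss_r, rss_f = rss(Xr), rss(Xf)
    k = 2 * L + 1
    return ((rss_r - rss_f) / L) / (rss_f / (n - k))


@pytest.mark.parametrize("instance", range(100))
def test_f_statistic_matches_normal_equations(instance):
    rng = np.random.default_rng(instance)
    L = int(rng.integers(1, 4))
    values = rng.normal(size=(200, 2))
    values[:, 1] += 0.2 * np.roll(values[:, 0], 1)
    res = granger_f_test(values, source=0, sink=1, L=L)
    oracle = _normal_equations_f(values, 0, 1, L)
    assert res.f_stat == pytest.approx(oracle, abs=1e-8)
    assert res.rss_full <= res.rss_restricted


def test_matches_statsmodels_reference():
    import warnings

    from statsmodels.tsa.stattools import grangercausalitytests

    rng = np.random.default_rng(77)
    values = rng.normal(size=(400, 2))
    values[1:, 1] += 0.3 * values[:-1, 0]
    res = granger_f_test(values, source=0, sink=1, L=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        ref = grangercausalitytests(values[:, [1, 0]], maxlag=[2], verbose=False)
    f_ref, p_ref, *_ = ref[2][0]["ssr_ftest"]
    assert res.f_stat == pytest.approx(f_ref, rel=1e-6)
    assert res.p_value == pytest.approx(p_ref, rel=1e-6)


def test_null_rejection_rate_is_nominal():
    """White-noise source, AR(1) sink: size stays near the nominal level.

    Dynamic regressions carry a small finite-sample size distortion (the
    true size here is ~0.055, not 0.05), so the check runs 1000 replicates
    to keep sampling noise well below the band width.
    """
    from scipy.signal import lfilter

    rng = np.random.default_rng(0)
    rejections = 0
    n_rep = 1000
    for _ in range(n_rep):
        x = rng.normal(size=1000)
        y = lfilter([1.0], [1.0, -0.5], rng.normal(size=1000))
        rejections += granger_f_test(np.column_stack([x, y]), 0, 1, L=2).p_value < 0.05
    assert 0.03 <= rejections / n_rep <= 0.07


def test_planted_link_is_detected_with_tiny_p():
    spec = SCMSpec(n_vars=2, links=((0, 1, 1, 0.5),), auto_coeffs=(0.0, 0.3))
    hits = 0
    n_seeds = 50
    for seed in range(n_seeds):
        panel = simulate_panel(spec, T=1000, seed=1000 + seed)
        hits += granger_f_test(panel, source=0, sink=1, L=1).p_value < 0.001
    assert hits >= 0.99 * n_seeds


def test_f_stat_invariant_to_affine_rescaling():
    rng = np.random.default_rng(5)
    values = rng.normal(size=(300, 2))
    base = granger_f_test(values, 0, 1, L=3)
    scaled = values * [250.0, 0.004] + [3.0, -17.0]
    again = granger_f_test(scaled, 0, 1, L=3)
    assert again.f_stat == pytest.approx(base.f_stat, abs=1e-8)


def test_scan_enumerates_all_source_lag_combinations(mimic_panel):
    results = granger_scan(mimic_panel, sink=5, lags=range(1, 8))
    assert len(results) == 35  # 5 sources x 7 lag orders
    assert all(r.sink == 5 and r.source != 5 for r in results)
    assert [r.f_stat >= 0 for r in results]


def test_null_p_values_are_uniform():
    """Pooled null p-values pass a Kolmogorov–Smirnov uniformity check."""
    pvals = []
    for seed in range(125):
        panel = noise_panel(T=300, n=5, seed=3000 + seed)
        for source in range(1, 5):
            pvals.append(granger_f_test(panel, source, 0, L=2).p_value)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_collinear_design_is_rejected():
    values = np.ones((200, 2))
    values[:, 0] = np.arange(200)
    with pytest.raises(ValueError, match="rank-deficient"):
        granger_f_test(np.column_stack([values[:, 0], values[:, 0]]), 0, 1, L=2)
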