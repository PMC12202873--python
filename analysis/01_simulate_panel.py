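"""Simulate the six-variable study-mimic daily panel.

Draws 2,923 days (2012-01-01 through 2020-01-01) from the reference
structural-causal network — 13 weak cross-links plus AR(1) self-dependence
— contaminated with harmonic seasonality at the nine study periods and a
slow linear trend, the way the raw media/tweet/background-check counts
look before cleaning.  Writes results/panel_raw.csv.
"""
from pathlib import Path

from causalpanel import simulate_panel, study_mimic_spec, write_panel_csv

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = study_mimic_spec(seasonal_amplitude=1.0, trend_slope=0.002)
    print(f"spec: {spec.n_vars} variables, {len(spec.cross_links())} cross-links, "
          f"spectral radius {spec.spectral_radius():.3f}")
    panel = simulate_panel(spec, T=2923, start_date="2012-01-01", seed=SEED)
    out = RESULTS / "panel_raw.csv"
    write_panel_csv(panel, out)
    print(f"wrote {out}: T={panel.T} days, N={panel.n_vars} variables")
    print(f"  span {panel.dates[0].date()} .. {panel.dates[-1].date()}")


if __name__ == "__main__":
    main()
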