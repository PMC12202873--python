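# causalpanel

Causal discovery for daily multivariate count panels — the kind of data
behind questions like *does media coverage of violent crime drive firearm
background checks, or the other way around?*  The package implements, as a
tested pipeline, the analysis used to untangle six interacting daily
series (three media-coverage counts, two advocacy-group tweet counts, and
NICS firearm background checks, 2,923 days from 2012-01-01 to 2020-01-01):

1. **Preprocessing to stationarity** — harmonic seasonal adjustment at
   periods {1, 2, 3, 5, 7, 30, 31, 365.25/12, 365.25} days, local-linear
   detrending, and a joint ADF/KPSS stationarity gate.
2. **Graph discovery** — a PCMCI+-style engine: PC-stable skeleton search
   over all lagged and contemporaneous candidate links
   `X_{t-τ}^i → X_t^j` (τ = 0..7), orientation by time order plus
   collider/Meek rules, and momentary-conditional-independence (MCI)
   validation of every link.  The conditional-independence test is
   partial correlation: regress both variables on the conditioning set,
   correlate the residuals, and convert ρ to a p-value via
   `t = ρ √((n − |Z| − 2)/(1 − ρ²))`.
3. **Link-persistence robustness** — discovery rerun over the 30-cell
   grid τ_max ∈ 5..14 × α ∈ {0.05, 0.01, 0.001}; a link's persistence is
   the fraction of runs in which it appears at its exact lag.
4. **Granger validation** — pairwise nested-OLS F-tests
   `F = ((RSS_r − RSS_f)/L) / (RSS_f/(n − 2L − 1))` of each source's lags
   into a designated sink.

Because the engine must be trusted before it is believed on real data,
the package ships a linear-Gaussian structural-causal simulator with
known ground truth (`synthetic`), including a six-variable fixture that
mimics the reference network's 13 weak links (|ρ| ≈ 0.05–0.11, lags 0–7,
AR(1) self-dependence 0.4), plus the packaged reference tables
(`fixtures`): the 20 advocacy accounts and the 13-row link table.

Intended users: computational social scientists and epidemiologists who
work with observational daily count panels and need lag-resolved,
autocorrelation-aware causal structure rather than pairwise correlations.

## Worked example

```python
from causalpanel import (study_mimic_spec, simulate_panel, run_pcmciplus,
                         true_graph, score_recovery)

spec = study_mimic_spec()                      # 6 variables, 13 planted links
panel = simulate_panel(spec, T=2923, seed=1)   # 2012-01-01 .. 2020-01-01
graph = run_pcmciplus(panel, tau_max=7, alpha=0.05)
print(f"{len(graph.cross_links())} cross-links discovered")
for link in sorted(graph.cross_links(), key=lambda l: -abs(l.rho))[:5]:
    arrow = "->" if link.orientation == "directed" else "--"
    print(f"  {graph.names[link.source]:>17} {arrow} {graph.names[link.sink]:<17}"
          f" lag {link.lag}  rho {link.rho:+.3f}  p {link.p_value:.1e}")
score = score_recovery(true_graph(spec), graph)
print(f"recall of the 13 planted links: {score['recall']:.2f}")
```

prints

```
27 cross-links discovered
         media_laws -> media_crime       lag 0  rho +0.135  p 3.4e-13
  background_checks -> media_crime       lag 1  rho +0.122  p 4.5e-11
    media_shootings -> media_crime       lag 1  rho +0.105  p 1.5e-08
  background_checks -> media_laws        lag 1  rho +0.100  p 7.0e-08
    media_shootings -> media_laws        lag 1  rho +0.088  p 2.3e-06
recall of the 13 planted links: 1.00
```

Every planted link was recovered at its exact lag with the correct sign;
the discovered ρ's sit close to the planted coefficients, and the
remaining links are the level-α false positives expected among ~200
candidate links.

## Analysis scripts and CLI

The numbered drivers under `analysis/` run the full narrative on a
simulated study-scale panel and write their tables under `results/`:

```bash
python analysis/01_simulate_panel.py    # contaminated 6-variable panel
python analysis/02_preprocess.py        # clean + ADF/KPSS gate
python analysis/03_discover_graph.py    # graph at tau_max=7, alpha=0.05
python analysis/04_link_persistence.py  # 30-cell robustness grid
python analysis/05_granger_validation.py
```

The same stages are exposed as a CLI for use on your own panel CSV
(ISO-8601 `date` column plus one numeric column per variable):

```bash
causalpanel run --input panel.csv --outdir out/
causalpanel discover --input clean.csv --tau-max 7 --alpha 0.05 --out graph.json
```

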