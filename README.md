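# codnet

Movement-network analysis for passive acoustic telemetry of coastal fish.

Juvenile Atlantic cod (*Gadus morhua*) in a fjord system carry ultrasonic
transmitters; an array of moored receivers logs every detection. `codnet`
turns those raw detection logs into an analysis of how water temperature
structures fish movement and habitat connectivity:

- **QC**: linear clock-drift correction and a short-interval false-detection
  screen;
- **movements**: consecutive detections of one fish at two different
  receivers become directed edges; transits faster than 4 min are treated as
  detection-range overlap and removed;
- **indices**: per fish, a residency index `RI = days detected / days
  monitored` and a movement index `MI = movements / days detected`;
- **networks**: weighted movement networks per fish and time window, node
  strength and degree summed weekly per fish, seasonal aggregate networks;
- **motifs**: a from-scratch directed triad census over the 16 isomorphism
  classes (003 … 300), monthly per fish — on an 11-receiver array every
  census sums to C(11,3) = 165;
- **models**: maximum-likelihood negative-binomial GLMMs with per-fish
  random intercepts (adaptive Gauss–Hermite quadrature), a zero-inflated
  variant for weekly degree, Welch's heteroscedastic F with Games–Howell
  post hocs for seasonal contrasts, Spearman/t/Wilcoxon for size and site
  effects, and VIF screening of environmental covariates.

The model at the core is

```
y_ij | b_i ~ NB2(mu_ij, theta),   log mu_ij = x_ij' beta + b_i,   b_i ~ N(0, sigma_b^2)
```

for weekly connectivity counts `y_ij` of fish `i` in week `j`, with sea
surface temperature (SST) the focal covariate; the zero-inflated variant
mixes in an intercept-only structural-zero process.

A synthetic generator (`codnet.synthetic`) emulates the study design — 48
tagged fish over 11 receivers in two sites for five months, 30–90 s
transmitter intervals, a seasonal SST decline from ~16 °C to ~4 °C, and a
per-fish movement rate log-linear in SST — so the entire pipeline is
testable without any field data.

## Worked example

```python
from codnet.synthetic import SimulationConfig, simulate_bundle
from codnet.pipeline import PipelineConfig, run_pipeline
from codnet.networks import total_weight

bundle = simulate_bundle(SimulationConfig(seed=1))      # 48 fish, full study
out = run_pipeline(PipelineConfig(seed=1), bundle=bundle)

out["manifest"]["counts"]
# {'detections_in': 3195902, 'detections_valid': 3195902,
#  'detections_post_release': 3154808, 'movements': 1193,
#  'fish_tagged': 48, 'fish_retained': 47, 'weekly_rows': 940}

{k: total_weight(v) for k, v in out["seasonal_networks"].items()}
# {'summer': 959, 'autumn': 224, 'winter': 10}
```

Movement activity collapses from summer to winter; the seasonal contrast in
relative daily movements (movements per day over fish detected per day) is

```python
w = out["seasonal_tests"]["welch"]       # F = 178.19, p = 7.3e-33
out["seasonal_tests"]["games_howell"].table
#    group1  group2  mean_diff        pvalue
# 0  summer  autumn   0.390923  1.487699e-14
# 1  summer  winter   0.490459  0.000000e+00
# 2  autumn  winter   0.099536  5.017727e-08
```

and the weekly connectivity models recover a strong positive temperature
effect (generative SST slope 0.25 on the per-day movement rate):

```python
out["model_table"]
# response      predictor  estimate     se        z      p
# strength    (Intercept)   -4.7465 0.3177 -14.9409 0.0000
# strength            sst    0.3401 0.0136  24.9366 0.0000
# strength log_wind_speed    0.3150 0.1212   2.5999 0.0093
# strength wind_direction    0.0005 0.0004   1.3353 0.1818
#   degree    (Intercept)   -3.5499 0.2749 -12.9128 0.0000
#   degree            sst    0.3029 0.0133  22.6884 0.0000
#   degree wind_direction    0.0001 0.0003   0.2102 0.8335
```

Monthly motif models show the signature connectivity pattern: the null
triad (motif 003, "no movement anywhere in the triple") *decreases* with
temperature (slope −0.024, p ≈ 5e-48) while the simple one-edge motif 012
increases (slope 0.30, p ≈ 8e-38).

The same analysis runs from the shell:

```
codnet simulate --seed 1 --outdir data/
codnet all --config config.yaml --outdir results/
```

(`codnet all` writes the fish summary, movement edge log, seasonal GraphML
networks, weekly metric series, motif censuses, model summary tables and a
reproducibility manifest; the other verbs — `qc`, `movements`, `summarize`,
`networks`, `motifs`, `models` — run the pipeline up to one stage.)

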