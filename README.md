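# heliwork

Quantitative pilot-workload analysis for helicopter autorotation.

After a sudden engine failure, a single-engine helicopter pilot must enter
autorotation — lower the collective, manage rotor RPM, flare and land — in
roughly a second of reaction time and under intense workload.  Which
height/speed combinations of the "Dead Man's Curve" (Height-Speed diagram)
are safely flyable is traditionally judged with subjective ratings.
`heliwork` implements an objective companion to that judgement for flight-test
teams and human-factors researchers: it turns synchronized flight-control and
physiological recordings of simulated engine failures into workload metrics
and tests how those metrics vary across the diagram and across
pilot-experience groups.

The pipeline computes, per maneuver:

* **CPF (Cumulative Power Frequency)** of the four control axes: per 3-s
  moving window, `ω_cum = ω_cutoff · P / 10`, with `P` the window's
  mean-square control displacement (%², Parseval-normalized spectrum) and
  `ω_cutoff` the median-power frequency; the four axes are summed and the
  post-failure peak is the workload statistic.
* **Event-locked physiology** at 500 Hz: first skin-conductance-response
  amplitude (valid only for onsets 0.5–5 s after the failure), heart-rate
  percent-change AUC over 40 s, and the promediated (power-weighted mean)
  respiratory frequency from a Morlet scalogram in 0.05–0.50 Hz.
* **Performance**: autorotation Mission-Task-Element scoring
  (desirable/adequate/fail), success rates, reaction times, and the
  1-HQR-unit inter-pilot agreement check.
* **Inference**: linear mixed-effects models (random intercept per pilot),
  AIC + likelihood-ratio factor retention, Shapiro-driven log transform, and
  Benjamini–Hochberg-corrected pairwise contrasts, for each feature against
  the classical (Outside/Line/Inside) and four-zone
  (Take-off/Knee/Cruise/High-hover) partitions and the experience groups.

A seeded synthetic-campaign generator produces full campaigns (64 Hz FTI
channels, 500 Hz physiology, metadata, ground truth) so the whole chain is
testable without flight data; see `docs/methods.md` for the model details
and its limits.

## Worked example

Run the full pipeline on a synthetic campaign (6 pilots, 60 maneuvers):

```python
from heliwork.synthetic import CampaignConfig
from heliwork.pipeline import run_pipeline

cfg = CampaignConfig(seed=7, pilots_per_group=(2, 2, 2), maneuvers_per_pilot=10)
result = run_pipeline(cfg, "out", cpf_step=4)
print(result["matrix"])
```

prints the factor-retention matrix (True = the factor survived AIC + ANOVA):

```
     classical   zone  group
cpf       True   True  False
eda       True   True  False
hqr       True  False  False
hr       False   True  False
```

Control activity (cpf) and electrodermal amplitude (eda) separate both
partitions of the diagram, heart rate (hr) separates only the four-zone
partition, and no objective measure separates the experience groups — the
qualitative pattern the package's constructed campaign is designed to carry.
`out/report.json` holds the model AICs, p-values and contrasts;
`out/features.csv` the per-maneuver features.  The same run is available from
the shell as `heliwork all --seed 7 --out out`, and `heliwork mte` prints the
shipped rating-table dispersion summary (20 of 21 test points within one HQR
unit of inter-pilot agreement).

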