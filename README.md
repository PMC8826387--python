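# heterostat

Energy-allocation analysis for captive heterotherm temperature-treatment
studies: torpor and thermoregulation metrics from skin-temperature logger
series, and a Bayesian hierarchical ordinal model that estimates when male
bats pass successive sexual-maturation stages — and how ambient
temperature, body mass and thermoregulation effort shift those transition
days.

It is written for ecophysiologists running (or re-analysing) experiments
of the following shape: males of a heterothermic species are held under
two constant ambient-temperature treatments (here 10 °C vs 25 °C), carry
iButton-style loggers recording skin temperature (T_sk) every 10 min at
0.5 °C resolution, are weighed daily, and are staged for seasonal sexual
maturation on an ordinal 0–4 scale roughly every ten days.

## What it computes

**Thermoregulation stage** (`heterostat.thermo`)

- Individual torpor-onset thresholds from the published linear rule
  `T_onset = 0.041·M_b + 0.04·T_a + 31.083` (°C, with M_b in g).
- Torpor events: maximal runs of ≥ 3 consecutive included sub-threshold
  readings, with handling/flight windows excluded.
- Daily summaries, including the thermoregulation-effort proxy
  ΔT = mean(T_sk − T_a) over a day's included readings.

**Maturation transition-time model** (`heterostat.model`)

The ordinal stage y_ij of bat *i* on day t_ij follows a cumulative
ordered probit *on the day axis*:

    P(y_ij ≥ k) = Φ( (t_ij + u_i − T_k,ij) / σ_ε )

    T_1,ij = 10                       (fixed: treatment onset)
    T_k,ij = τ_k + d_k·1[T10]
           + γ^M_{g,k}·mass_c + γ^Δ_{g,k}·ΔT_c      (k ≥ 2)

so every reported quantity is a model parameter in days: τ_k the
baseline (25 °C) transition days, d_k the cold-treatment delays,
γ the covariate effects (days per centred gram, days per centred °C)
per treatment and transition, u_i ~ N(0, σ_u²) a per-bat random
intercept.  Missing exam-day covariates are imputed from estimated
Gaussians inside the model.  Inference is seeded multi-chain adaptive
Metropolis-within-Gibbs with Brooks–Gelman–Rubin convergence checks
(R̂ < 1.1) and Table-style posterior summaries (mean, sd, 2.5/50/97.5
percentiles, CI-excludes-zero significance flags).

**Synthetic cohorts** (`heterostat.simulate`) — a seeded generator of
complete studies (cohort, logger traces, masses, ordinal exams drawn
from the transition-time model itself), so the full pipeline is testable
without any data download.

## Worked example

Generate a synthetic study, run the thermoregulation stage, build the
exam covariate table and fit the model:

```bash
heterostat simulate --seed 4 --outdir study
heterostat thermo --temps study/temps.csv --cohort study/cohort.csv \
    --masses study/masses.csv --out daily.csv --events events.csv
heterostat prep --obs study/obs.csv --masses study/masses.csv \
    --daily daily.csv --cohort study/cohort.csv --out exams.csv
heterostat fit --exams exams.csv --iters 2000 --burnin 800 --seed 2 \
    --summary table.csv
```

The thermo stage prints `2086 torpor events, 2016 bat-days`; the fit
prints the posterior table, beginning

```
parameter            mean   sd    q2.5  q50   q97.5  rhat  significant
transition_1to2_T25  36.07  3.11  30.56 35.88 41.99  1.02  True
delay_1to2_T10       33.72  4.85  24.57 33.43 44.76  1.01  True
...
max R-hat: 1.0458 (converged)
```

Read: bats at 25 °C pass the class-1→2 threshold around day 36 of
captivity (95% CI 31–42), and the 10 °C treatment delays that transition
by ~34 days — the cohort here was generated with a true delay of
33.5 days, so the model recovers it.  A `significant` flag means the
95% credible interval excludes zero.  The same fit is available in
Python via `heterostat.fit(...)` / `heterostat.summarize(...)`.

In Python, the torpor threshold for an 11.1 g bat at 25 °C:

```python
>>> import heterostat as hs
>>> hs.torpor_onset_threshold(11.1, 25.0)
32.5381
```

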