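# Methods

This note documents the models, conventions and numerical choices behind
`heterostat`, in the order the pipeline runs them.

## Study conventions

Day 0 is the day of capture; the temperature treatment begins on day 10
(after acclimation), and "experiment day" = day − 10.  All model
quantities are expressed in days since capture.  Loggers sample every
10 minutes at 0.5 °C resolution; timestamps are ISO-8601 and day
boundaries fall at midnight clock time.  CSV is the interchange format
throughout (vendor logger exports are CSVs); missing values are empty
fields.

Readings more than one sampling interval apart split a logger deployment
(loggers detach spontaneously); every `TempSeries` is therefore a
gap-free 10-minute grid, which makes run-based torpor detection
unambiguous.  Readings that are not 0.5 °C multiples are kept with a
warning rather than rejected — they occur in practice when vendors
change calibration.

## Torpor and thermoregulation metrics

The torpor-onset threshold is the published linear rule
`0.041·M_b + 0.04·T_a + 31.083` (°C); the right-hand side is used
directly as the cutoff (its 1-SE buffer is already part of the printed
expression).  Each bat gets one threshold from its **mean mass over the
deployment** and its treatment's ambient temperature: a single stable
cutoff per individual matches how the thresholds were established, and
daily-mass thresholds remain available behind a config flag
(`StudyConfig.daily_mass_thresholds`).

A torpor event is a maximal run of at least `torpor_min_run` (default 3)
consecutive *included* readings below the threshold.  Excluded readings
(daily handling and flight windows, `StudyConfig.exclusion_windows`,
default 18:00–19:00) break runs: there is no information about the bat
while it is out of the cage, and crediting a bridged bout would
overstate torpor depth.  Event duration is `n_readings × 10 min` rather
than `end − start`, so a single reading contributes exactly one sampling
interval and durations stay well defined next to gaps.  Events are
credited to the day containing their start.

ΔT is the mean of (T_sk − T_a) over a day's included readings.  It is
signed and unclamped — logger noise can push T_sk below T_a, and
clamping would bias the mean upward, breaking its interpretation as
energy spent keeping warm.  Days with fewer than
`StudyConfig.min_daily_readings` (default 6, one hour of data) included
readings are not summarised.

## Covariate preparation

The model consumes, per maturation examination, the body mass and ΔT of
the exam day.  Exam days without logger coverage yield *missing* ΔT —
deliberately not interpolated, because the model has explicit
imputation machinery and interpolation would fabricate precision.
Covariates are centred on their pooled (across-treatment) means over
non-missing values; pooled centering keeps the treatment contrasts
interpretable, and the constants are stored with the table so raw
values can be recovered exactly.

Treatment assignment for synthetic cohorts ranks bats by body condition
index — defined, as in the source protocol, as forearm length divided by
body mass — and splits consecutive pairs randomly between treatments,
which matches the two BCI distributions to within the within-pair gaps.

`scale_time(day) = day/365` is provided for sampler-internal use; the
likelihood here works directly on the day scale (the two are identical
up to reparameterization) and every interface is in days.

## The transition-time model

A continuous latent maturation variable advances with time since
capture; the day it crosses threshold *k* is the transition time point
between classes k−1 and k.  Concretely the observation model is a
cumulative ordered probit on the day axis,

    P(y_ij ≥ k) = Φ((t_ij + u_i − T_k,ij)/σ_ε),

with per-transition effective thresholds

    T_1 = 10 (fixed, no effects),
    T_k,ij = τ_k + d_k·1[T10] + γ^M_{g,k}·mass_c + γ^Δ_{g,k}·ΔT_c  (k ≥ 2).

This parameterization was chosen because it makes every reported
quantity — transition day, delay, effect — a direct model parameter in
days.  The probit link matches the Gaussian random-intercept structure;
σ_ε is the latent day-scale residual per examination, distinct from the
between-bat intercept σ_u.  Covariate effects are per-treatment and
per-transition (they are reported that way), which is equivalent to a
baseline-plus-interaction coding.  The first threshold is fixed at day
10 — the onset of the treatment, by which time about half the cohort
has passed it — anchoring the latent scale.

Cell probabilities come from differencing cumulative probabilities.
When a draw's covariate effects reorder an observation's thresholds the
difference can be non-positive; such cells are floored at
`prob_floor = 1e-12` and counted (`FitResult.n_clipped`).  The floor is
far below any data-supported probability, so it acts only as a barrier
against log(0) in the tails of the prior.

Missing covariates: each covariate has a Gaussian model
x ~ N(μ, σ²) with a single estimated mean and spread.  Observed values
inform (μ, σ); missing values are sampled jointly with everything else.
Because this factor is separable from the ordinal likelihood, enabling
imputation on complete data leaves all other posteriors unchanged — a
property the test suite checks.

Priors (all in days; `prior_scale_factor` doubles/halves every scale
for sensitivity checks):

| parameter | prior | default scale |
|---|---|---|
| τ increments (τ_2 − 10, τ_3 − τ_2, …) | half-Normal | 50 |
| delays d_k, effects γ | Normal(0, s²) | 50 |
| σ_u, σ_ε | half-Normal | 20 |
| imputation μ | Normal(0, s²) | 10 |
| imputation σ | half-Normal | 10 |

The increment parameterization enforces τ_2 < τ_3 < τ_4 by prior
support.  These are weakly-informative choices on the scale of a
two-month study; they are the package's own (the original analysis
code's priors are not published in the main text).

### Sampler

Adaptive Metropolis-within-Gibbs:

- scalar Gaussian random-walk updates for each structural parameter
  (τ's, d's, γ's, σ's, imputation hyperparameters), with the prior term
  evaluated incrementally per parameter;
- one vectorized block update for all random intercepts u_i — they are
  conditionally independent across bats, so per-bat accept/reject on
  per-bat likelihood sums is exact;
- one vectorized block update for imputed covariates (independent
  across exams) per covariate.

Proposal scales adapt by Robbins–Monro toward 0.44 acceptance during
burn-in only and are frozen afterwards, so the post-burn-in kernel is a
fixed, valid Metropolis–Hastings kernel.  Chains start from broad
seeded draws spanning the plausible range (transition increments
uniform 5–30 d, σ's uniform 2–10 d) and run sequentially from seeds
spawned off one root `SeedSequence`, making runs bit-reproducible for a
given seed and platform.  Default settings mirror the original
protocol: 3 chains × 50,000 iterations, 20,000 burn-in, thinning by 3.
The test suite uses 3 × 5,000 (burn-in 2,000), which mixes well at
cohort sizes of a few dozen bats.

### Diagnostics and reporting

Convergence uses the Brooks–Gelman–Rubin potential scale reduction
factor computed from per-chain means and variances,
R̂ = sqrt(((n−1)/n·W + B/n)/W), floored at 1.0 — values below 1 are
finite-sample noise, and the floor makes R̂ of identical chains exactly
1. (A split-chain variant was considered and rejected: splitting
duplicated chains leaves R̂ off 1 by O(1/√n) even for perfectly mixed
chains, which breaks the identical-chains invariant the test suite
pins.)  Zero within-chain variance with non-identical chains returns
+inf with a warning.  Any R̂ ≥ 1.1 flags the fit as non-converged; the
result is returned regardless.

Summaries report mean, sd and the 2.5/50/97.5 percentiles (linear
interpolation), R̂, and a significance flag (95% CI excludes zero).
The last transition (class 3 → 4) is reported only when at least two
bats were ever observed in class 4; otherwise its posterior reflects
the prior, not the data (the original study discarded it for exactly
this reason — a single bat reached class 4).

## Synthetic cohorts

`SimConfig` defaults encode the study conditions: 32 bats in groups of
three, treatments at 10/25 °C, 62 study days (10 acclimation + 52
treatment), exams every 10 days, intake mass uniform on 9.4–12.8 g and
forearm on 34.0–46.9 mm, BCI-matched assignment.  The generating
transition-time parameters default to the reported posterior means
(transition days 39.37/62.81; delays 33.48/37.12; per-treatment mass
and ΔT effects), with σ_u = σ_ε = 5 d as a realistic between-bat /
residual spread for a two-month maturation season.

Skin-temperature traces: cold-treatment bats sit at T_a + 0.7 °C with a
normothermic excursion in the evening handling window (18:00–19:30) and
an exponential cooling tail afterwards (time constant 2.5 h, lognormal
day-to-day jitter, log-sd 0.5) — digesting bats stay warm for hours and
cool passively, which is also what keeps daily ΔT comparable between
treatments, as observed in the study.  Warm-treatment bats fluctuate
within the shallow-torpor band (24.2–30.6 °C) with the same evening
excursion and tail.  Gaussian noise (sd 0.3 °C) is added, values are
quantized to 0.5 °C, and T_sk ≥ T_a is enforced.  The day-to-day
cooling jitter is the generator's main source of within-treatment ΔT
variation and hence what makes the ΔT effect identifiable in refits.

Mass trajectories are piecewise-linear treatment-specific trends (dip
then recovery at 25 °C; small rise then decline at 10 °C) plus Gaussian
noise — qualitative mimics of the observed treatment-level patterns,
not refits of the original smoothing models, since the transition-time
model only consumes exam-day values.

Maturation classes are drawn from the transition-time model itself:
per-bat u_i ~ N(0, σ_u), per-exam ε ~ N(0, σ_ε), emitted class =
number of effective thresholds crossed by t + u_i + ε.  Monotone
post-processing (a bat's class never decreases) is on by default —
spermatogenesis stages are sequential — with a flag to disable it for
likelihood-consistency checks, because monotonization is the one place
the generator deliberately departs from the fitted likelihood.

One root seed feeds named substreams (cohort, masses, traces,
maturation), and per-bat streams are keyed by a CRC of the bat id, so
adding a stage or resizing the cohort never perturbs other draws.

What the generator does **not** emulate: ad libitum feeding dynamics,
social thermoregulation and group-composition effects, multi-bout
intra-day torpor patterns at 25 °C (real warm-treatment bats showed
2–3 bouts/day; the generator produces one long daily bout), logger
mid-deployment dropouts (coverage is one contiguous window), and any
seasonal drift in T_sk beyond the fixed daily shape.  Passing tests
therefore demonstrate correctness of the pipeline's computations and
calibration of the model under the generative assumptions — not that
the model is well specified for every feature of real traces.

## Verification strategy and problem sizes

- Torpor detection is checked exactly against a brute-force maximal-run
  scan on 1,000 random quantized series, plus monotonicity and
  disjointness properties.
- The likelihood is pinned to an independent hand computation on a toy
  dataset at 1e-10, and cell probabilities must sum to 1 at 1e-10.
- The posterior machinery is validated on a reduced model (2 bats, one
  free threshold, fixed σ's) against dense grid quadrature over
  (τ_2, u_a, u_b); the MCMC mean must land within twice its Monte-Carlo
  standard error of the quadrature value.
- A 20-replicate simulate-and-refit study (30 bats, exams to day 60,
  3 chains × 5,000) checks bias, CI coverage, convergence, and the
  false-positive rate of the significance rule under truly-zero
  effects.
- End-to-end determinism: the full simulate → thermo → prep → fit chain
  is bit-reproducible under a fixed seed.

These sizes were chosen so the whole suite runs in minutes on one CPU
while leaving the Monte-Carlo error well below the tolerances checked.

## Known limitations

- **Right-censored delays.**  When a treatment's true crossing day lies
  beyond the last examination (the cold treatment's class-1→2 crossing
  sits at day ~70 against exams ending near day 60), replicates in
  which no bat is observed to cross carry only one-sided information.
  The delay posterior then becomes a ramp against the diffuse
  Normal(0, 50²) prior, whose mass at large delays pushes the
  equal-tailed 95% interval's lower bound above moderate generating
  values; HPD intervals behave almost identically.  This is a property
  of the posterior itself, not of the sampler — on censored scenarios
  the MCMC matches independent grid quadrature to two decimals — and it
  is visible in the recovery study as under-coverage for the censored
  delay and the marginally censored second transition day.  It mirrors
  the wide delay intervals the original study reported.  Analysts who
  need calibrated intervals for barely-observable transitions should
  extend the exam window or tighten the delay prior on subject-matter
  grounds.
- The monotone post-processing in the generator is not represented in
  the likelihood; at the default noise levels its effect on refits is
  below Monte-Carlo error, but it becomes material if σ_ε is made large
  relative to the spacing of transitions.
- The imputation model is a single pooled Gaussian per covariate; if a
  covariate differs strongly by treatment, pooled imputation shrinks
  imputed values toward the grand mean.  The generator's balanced ΔT
  keeps this benign; real datasets with treatment-separated ΔT would
  warrant a per-treatment imputation mean.
- Metropolis-within-Gibbs mixes slowly for near-unidentified parameters
  (e.g. effects on transitions nobody reaches); their R̂ stays fine but
  effective sample sizes are small.  Gradient-based samplers would help
  and the model surface does not preclude swapping one in.
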