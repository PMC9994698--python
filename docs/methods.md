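# Methods

## Model

The package implements the POPAN formulation of the Jolly-Seber open
population model, specialized to release programs in which entry is known.
Occasions are whole study years (2015–2020); dated field records collapse to
one binary detection per year, and survival applies over the intervals
between occasions.  Dead recoveries are encoded as non-detection: the model
uses live encounters only, so the death of a telemetered animal is
informative purely through the certain-detection (p = 1) cell in which it
fails to appear.

For each of the 23 cohort × telemetry-duration groups, the probability of
entry is fixed at 1 at the release occasion and 0 elsewhere, and the group
superpopulation is fixed at the number released.  Consequently the usual
POPAN entry (multinomial-logit) and superpopulation (log-link) parameters
are degenerate and are not estimated; entry is handled deterministically and
population size is a *derived* quantity.  Each released individual then
contributes an independent encounter-history probability built from
per-interval survival φ and per-occasion detection p, with the detection
mask per (group, occasion):

- `FIXED_1` at the group's telemetry occasions (assumed consecutive from
  release, since the field protocol attaches transmitters at release and the
  group table records a single duration);
- `FIXED_0` before release and in years without survey effort;
- `FREE` (estimated) at survey occasions 2018–2020 after telemetry ends.

Individuals released but never detected contribute the never-seen
probability ζ_r; the multinomial coefficient is dropped everywhere (it is a
data-only constant, so estimates, ΔAICc and weights are unaffected; reported
deviances are −2·logL under this convention and are not comparable in level
with software that keeps the constant).

## Submodel structures and parameter counting

Survival structures: `constant`, `t` (interval), `acc` (two-level
acclimation: New in the first interval after release, Exp after), `cohort`,
`t*acc`, `t+acc`, `t+acc2019` (time plus a 2019-cohort first-interval
effect), `acc+t2019`, `acc2019`, `2019`.  Detection structures: `t`,
`t+acc`, `t*acc` (acclimation for detection applies at the release-year
occasion).  Structures are realized as logit-scale design matrices over the
cells the study design actually contains; the reported parameter count k is
this structural count — factor combinations never realized (e.g. an
"experienced" level in the first study interval) contribute no parameter.
Counting k structurally matches the published table for every one-hot and
interaction model; for additive detection models (`p(t+acc)`) the original
MARK analysis counted more parameters than the additive structure has
columns, a software bookkeeping difference that the package reports rather
than emulates.

The 2020 cohort enters at the final occasion; it contributes no survival
interval, only the 2020 detection cell.

## Fitting and uncertainty

Maximum likelihood on the logit scale with L-BFGS-B (finite-difference
gradients), convergence tolerance 1e-8 on the objective, and up to 5 seeded
random restarts (jitter SD 1.5) on failure.  The covariance matrix is the
inverse finite-difference Hessian at the optimum; parameters with |logit| > 9
or a non-positive variance are flagged boundary/inestimable (overparameterized
models, e.g. a first-interval cell informed by a handful of animals with no
deaths, routinely produce such flags, mirroring practice with this model
family).  Wald intervals are computed on the link scale and back-transformed,
so they are asymmetric on the probability scale and respect [0, 1].

Model ranking uses AICc with an effective sample size of 260 (the analysis
superpopulation) by default; because n_eff is shared across the candidate
set, the ranking and weights are insensitive to this choice (it shifts all
AICc values by the same k-dependent correction only through k, which differs
across models — the default is configurable).  Among models within ΔAICc < 2
the table *annotates* the fewest-parameter model as preferred; nothing is
auto-selected.

Fletcher's ĉ is computed over the full multinomial cell set: for each group,
every possible encounter history with positive probability under the fitted
parameters (histories contradicting a p = 1 fix are not cells), including
the never-seen cell.  ĉ = (X²/df)/(1 + s̄) with df = cells − k − groups and
s̄ the mean relative residual.  Under the true model this calibrates near 1
on the study's sample sizes (simulation mean ≈ 0.94; slightly below 1
because many cells are sparse).

Derived abundance follows N̂_{g,r} = n_released, N̂_{g,t+1} = N̂_{g,t}·φ̂_{g,t},
summed over groups per occasion.  Entrants are counted alive at their
release occasion and first face mortality over the following interval; the
2019 cohort therefore experiences exactly one interval (at its shock
survival) before 2020.  Variances come from the Delta method: central
finite-difference gradient of each occasion total with respect to the
link-scale parameters, sandwiched with the fitted covariance; intervals are
normal-approximation, floored at 0.  Flagged covariance entries are treated
as 0 in the sandwich, so inestimable directions do not poison the interval
(they understate it; the trajectory carries the flag through `se`).

The sex-ratio comparison is a Pearson χ² goodness-of-fit test with df = 1
and no continuity correction (the uncorrected statistic reproduces the
printed value on the published counts; Yates' correction would give 1.55
instead of 1.92), with the expected split taken from "a:b" odds.

## Synthetic data

The generator emulates the study conditions exactly: release schedule
21/36/49/49/48/57 (2015–2020; the 10 animals of 2014 are excluded from
analysis and not simulated by default), the 23-group telemetry plan,
Bernoulli survival at 0.89 per interval with the 2019 cohort's first
interval at 0.43 (the published estimates, standing in for a mass-mortality
event), certain detection while tracked, Bernoulli detection at
0.34/0.10/0.04 in the 2018–2020 survey years otherwise, and presumed sex
assigned 1:1.5 male:female at release.  A mass-mortality option applies a
multiplicative extra hazard to a chosen year instead of setting the cell
directly.  Capture records are simulated as physical trappings
(Bernoulli(p_year) for any animal alive in a survey year), coinciding with
detections for untracked animals.

What the generator does *not* emulate: individual heterogeneity in survival
or catchability, emigration (apparent survival confounds death and
permanent emigration in the real data; the generator has no movement),
tag loss, opportunistic sightings outside survey years, and the 184
direct-release hatchlings (simulatable via a near-zero-detection cohort but
excluded by default, as in the analysis).  Passing parameter-recovery tests
therefore shows the estimator is correct *for data meeting the model's
assumptions*, not that the real population meets them.

For goodness-of-fit checks, overdispersion is injected as shared
per-(group, interval) logit-scale survival shocks.  This choice is
deliberate: independent per-individual heterogeneity *under*-disperses
multinomial counts (sums of unequal-probability Bernoullis), and a shock
common to a whole year is absorbed by any time-dependent survival structure;
group-level shocks are the simplest mechanism that produces genuine lack of
fit against every candidate structure.

## Problem sizes used in the checks

Parameter recovery uses 200 replicates at 10× the study's group sizes (mean
absolute bias of the five preferred-model parameters < 0.01); interval
coverage uses 100 replicates at 10×; ĉ calibration uses 100 replicates at
1× under the general model and 50 under injected overdispersion; the
sex-ratio null calibration uses 10⁴ multinomial draws at n = 46.  These
sizes give Monte-Carlo error comfortably below the tolerances being
asserted while keeping the whole suite quick to run.

## Known limitations

- Structural k can differ from MARK's *estimable*-parameter count for
  additive detection structures (reported, not reconciled).
- Fletcher's ĉ is computed without cell pooling; with very sparse cells it
  sits slightly below 1 under the true model.
- The Delta method is first-order; for small groups or boundary survival
  estimates the abundance intervals are approximate (the Monte-Carlo
  cross-check in the tests bounds the error at large n only).
- No model averaging of abundance, no bootstrap GOF, no Bayesian fitting,
  no individual covariates beyond cohort/telemetry/acclimation, and no
  dead-recovery or multi-state extensions.
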