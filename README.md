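# jspopan

Open-population Jolly-Seber (POPAN) mark-recapture models for release
programs with known entry: fixed per-group superpopulations, deterministic
probability of entry, and radio-telemetry encoded as certain detection.

## The problem

Headstarting programs release captive-reared juveniles into the wild in known
annual cohorts and then monitor them by live-trapping and radio-telemetry.
The monitoring design this package is built around follows a headstarted
Blanding's Turtle (*Emydoidea blandingii*) population over six annual
occasions (2015–2020): 260 juveniles released in cohorts of
21/36/49/49/48/57, a subset of each cohort radio-tracked for 1–6 years, and
trapping surveys run only in 2018–2020.  The questions are the standard ones
of conservation monitoring: how many released animals are still alive
(abundance N̂), what is their apparent annual survival (Φ), and how
detectable are they (p)?

Because release timing and cohort sizes are known, the usual POPAN entry
parameters are not estimated.  Each cohort × telemetry-duration group (23
groups in the default design) has its probability of entry fixed at 1 at the
release occasion and 0 elsewhere, and its superpopulation fixed at the number
released.  Detection is fixed at 1 while a turtle carries a transmitter
(telemetered animals are always found, so a non-detection there means death),
and fixed at 0 wherever no survey ran.  What remains is a product-multinomial
likelihood over encounter histories ω:

```
P(ω) = [ Π_{t=r}^{f-1} (1-p_t) φ_t ] · p_f ·
       [ Π_{t=f}^{l-1} φ_t p_{t+1}^{x_{t+1}} (1-p_{t+1})^{1-x_{t+1}} ] · χ_l
```

with the never-seen-again recursion χ_t = (1-φ_t) + φ_t (1-p_{t+1}) χ_{t+1}
and the never-seen probability ζ_r for animals released but never detected.
Submodels for Φ and p (time, acclimation, cohort, and combinations such as
`Phi(t+acc2019) p(t)`) are fitted by maximum likelihood on the logit scale
and ranked by AICc with Akaike weights; goodness of fit uses Fletcher's ĉ;
abundance is derived through N̂_{g,t+1} = N̂_{g,t} φ̂_{g,t} with Delta-method
confidence intervals; and a χ² test compares the post-release sex ratio of
first captures to the 1:1.5 male:female incubation target.

A seeded synthetic-data generator reproduces the full design (releases,
telemetry plan, the 2019 first-interval mortality shock, survey-year
detection), so every stage is testable without any field data.

## Worked example

```python
import jspopan as jp

design = jp.default_design()                      # the 23-group design
histories, truth = jp.simulate_histories(jp.SimulationScenario(seed=1))
data = jp.prepare_data(histories, design)

fit = jp.fit_mle(data, design, jp.ModelSpec.parse("Phi(acc2019) p(t)"))
print(jp.wald_ci(fit))
traj = jp.delta_method_ci(fit, design)
print(traj.totals[-1], traj.lo[-1], traj.hi[-1])
```

With seed 1 this prints (abridged):

```
  phi:baseline    0.936  (95% CI 0.882-0.966)
  phi:2019 New    0.321  (95% CI 0.151-0.558)
  p:2018          0.331  (95% CI 0.240-0.436)
  p:2019          0.114  (95% CI 0.068-0.185)
  p:2020          0.033  (95% CI 0.015-0.071)
198.1 178.4 217.8
```

i.e. the fit recovers the generating values (survival 0.89 with the 2019
first-interval drop to 0.43, detection 0.34/0.10/0.04) within their
confidence intervals, and the derived 2020 abundance interval covers the
truth-implied expectation of 185.3 animals.  The same pipeline is laid out as
numbered drivers under `analysis/` (simulate → fit & rank → abundance →
goodness of fit → sex ratio), each writing its tables under `results/`:

```bash
python analysis/01_simulate_study.py 1
python analysis/02_fit_and_rank_models.py
python analysis/03_abundance.py
python analysis/04_goodness_of_fit.py
python analysis/05_sex_ratio.py
```

A `jspopan` console script exposes the same steps
(`jspopan simulate/fit/rank/abundance/sexratio`); e.g.

```bash
jspopan sexratio --observed 23,23 --expected 1:1.5
```

prints the published comparison: χ² = 1.92, df = 1, p = 0.166.

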