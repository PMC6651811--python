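# exposuremc

Monte Carlo uncertainty analysis for self-reported mobile-phone call
exposure and cognitive outcomes in longitudinal school cohorts.

Epidemiological studies of radiofrequency exposure from mobile phones
usually treat a child's "average calls per week" as a single number,
even though it comes from two parent-reported surveys taken about a year
apart. `exposuremc` replaces that point estimate with an **uncertainty
interval**: the lower of the two wave reports is the interval's lower
limit and the higher report its upper limit, and the true average over
the study period is modelled as uniform on the interval. The package is
aimed at epidemiologists and biostatisticians who want to propagate this
kind of epistemic (self-report) uncertainty through an exposure
classification and into a regression analysis, and to validate the whole
pipeline by simulation.

## What it computes

For participant *i* with wave reports *r₁ᵢ*, *r₂ᵢ*:

- **Exposure interval** `Xᵢ ~ Uniform(aᵢ, bᵢ)` with
  `aᵢ = min(r₁ᵢ, r₂ᵢ)`, `bᵢ = max(r₁ᵢ, r₂ᵢ)`.
- **Monte Carlo propagation** — seeded Latin Hypercube sampling (LHS,
  one draw per equal-probability stratum, Mersenne Twister streams
  derived per participant from a master seed), 1000 trials by default,
  at the participant level and for the across-participant mean. LHS
  bounds the empirical-CDF error by 1/n and cuts the variance of sample
  means by ~n² versus simple random sampling (an SRS mode is kept for
  comparison).
- **Probabilistic classification** at the threshold *t* = 2 calls/week:
  never-users (`[0, 0]`) are the reference group; otherwise a
  participant is *low* when `P(Xᵢ ≤ t) ≥ ½` (equivalently the interval
  midpoint is ≤ *t*) and *higher* otherwise.
- **Outcome transforms** — mean response times (ms) are log₁₀
  transformed, accuracy proportions arcsine-square-root transformed,
  maze error counts left raw, and Stroop interference expressed as the
  relative slow-down `(t₂ − t₁)/t₁` between matched forms.
- **Adjusted regression** per outcome: follow-up score on exposure-group
  dummies plus age, sex, country of birth, physical activity, SES
  quintile, time between examinations, baseline score, console-gaming
  quintile and a sex × gaming interaction, with the clustered sandwich
  (CR1) variance estimator over schools,
  `V = c (X'X)⁻¹ (Σ_g X_g'u_g u_g'X_g) (X'X)⁻¹`,
  `c = G/(G−1)·(N−1)/(N−k)`, and t(G−1) confidence intervals.
- **Synthetic cohorts** — a generator with known coefficients, school
  random intercepts, and calibrated exposure quantiles, plus a fully
  deterministic fixture cohort (382 children, 36 schools; 219 never /
  84 low / 79 higher users) whose exposure quartiles and exposed-group
  mean of 3.42 calls/week are met exactly. These make parameter-recovery
  and CI-coverage experiments for the full pipeline turnkey.

## Worked example

```python
from exposuremc import (build_table1_fixture, interval_from_reports, classify,
                        mc_group_mean, summarize, RNGSpec,
                        fit_outcome, DesignMatrixSpec)
from exposuremc.regression import classification_table

iv = interval_from_reports(0.5, 2.25)
print((iv.lower, iv.upper), round(iv.cdf(2), 3), classify(iv))

cohort = build_table1_fixture()
cls = classification_table(cohort)
print(cls["exposure_class"].value_counts().to_dict())

exposed = cls[cls["exposure_class"] != "none"]
intervals = [interval_from_reports(a, b) for a, b in zip(exposed["a"], exposed["b"])]
s = summarize(mc_group_mean(intervals, 1000, RNGSpec(1)))
print(f"{s.mean:.3f} calls/week [{s.lower:.3f}, {s.upper:.3f}]")

fit = fit_outcome(cohort, DesignMatrixSpec("go_nogo_speed"))
print(round(fit.params["exposure_low"], 4))
```

prints

```
(0.5, 2.25) 0.857 low
{'none': 219, 'low': 84, 'higher': 79}
3.420 calls/week [3.251, 3.595]
-0.0248
```

The first participant's interval places 85.7% probability at or below
two calls/week, so they join the low-exposure group. The fixture cohort
classifies into exactly 219/84/79 never/low/higher users; the
1000-trial LHS Monte Carlo over the 163 exposed intervals estimates a
group mean of 3.420 calls/week with a narrow percentile interval (the
interval reflects uncertainty in the *mean*, not between-child spread);
and the adjusted cluster-robust model on the fixture's deterministic
outcomes estimates a low-vs-never contrast of −0.0248 log₁₀ ms on
Go/No Go response speed.

There is also a CLI:

```sh
exposuremc run --mode fixture --seed 1 --out runs/demo
exposuremc recover --replicates 200 --outcomes go_nogo_speed --out runs/recovery
```

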