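# Methods

## Exposure model

Each participant's average weekly mobile-phone calls over the study
period is treated as uncertain between the two survey waves: the lower
wave report is the lower limit *a* and the higher report the upper
limit *b* of a uniform distribution on [*a*, *b*]. Using min/max rather
than (baseline, follow-up) order handles the minority of participants
whose reported use decreased. A participant reporting zero at both
waves has the degenerate interval [0, 0] and is a never-user. Any
degenerate interval (*a* = *b*) is a point mass.

Classification at the threshold *t* = 2 calls/week: never-users form
the reference group; otherwise the participant is **low** when
P(X ≤ t) ≥ ½ and **higher** otherwise. For a uniform interval this is
exactly the midpoint rule (midpoint ≤ *t* ⇒ low), so the analytic CDF
is used as the primary classifier and Monte Carlo classification is
retained only as a logged cross-check (`mc_agreement_rate` in the run
log surfaces borderline intervals). Ties at probability exactly ½ — and
degenerate intervals sitting exactly on the threshold — go to the low
group, matching the inclusive "averaged at most two calls" definition.
Whether the probability is computed as P(X ≤ t) or P(X < t) is
immaterial for non-degenerate uniform intervals.

## Monte Carlo propagation

Sampling uses Latin Hypercube stratification: for n trials, one uniform
variate is drawn in each probability stratum ((i−1)/n, i/n], the strata
are randomly permuted, and the probabilities are mapped through the
interval's inverse CDF. Exactly one draw per stratum bounds the
empirical-CDF error at any threshold by 1/n and reduces the variance of
the sample mean by a factor ≈ n² relative to simple random sampling
(uniform stratum variance (b−a)²/12n² ⇒ variance of the mean
(b−a)²/12n³). A simple-random-sampling mode is kept behind a flag for
variance comparisons.

The group-level statistic is the across-participant mean: each trial
draws one value per participant and records the mean; 1000 trials
produce the output distribution, summarised by its mean and the
empirical 2.5/97.5 percentile interval (percentiles use linear
interpolation between order statistics). Because each participant's
stream is a permuted stratified grid, the draw entering any single
trial is still marginally uniform, so trial-to-trial variability
reflects genuine input uncertainty while the *mean* of the output
distribution converges at the accelerated LHS rate.

All streams use the Mersenne Twister (numpy `MT19937`). A master seed
plus a hierarchical spawn key (`RNGSpec(seed).child(stage, participant)`)
derives an independent stream per participant per stage; the stage ids
are documented in `pipeline.py` and stable across versions. Identical
(config, seed) yields byte-identical artifacts.

## Outcome transforms

Mean response times (ms) are log₁₀-transformed; accuracy is divided by
100 and arcsine-square-root transformed (radians) — the standard
variance-stabilising convention, applied to proportions because the
transform is undefined for raw percentages above 1; Groton maze error
counts and the Stroop interference ratios (B−A)/A and (D−C)/C enter the
models untransformed. Both non-trivial transforms are strictly
increasing and exactly invertible on their domains.

## Regression and inference

For each of the thirteen outcomes (five tasks × speed and accuracy,
maze errors, two Stroop ratios) the transformed follow-up score is
regressed on low/higher exposure dummies (reference: never-users), age,
sex, country of birth, physical activity, SES quintile, time between
examinations, the transformed baseline score, console-gaming quintile,
and sex × gaming. Quintiles enter as integer scores by default; a
`gaming_categorical` flag switches the gaming quintile (and its sex
interaction) to indicator coding. The sex × gaming interaction is the
product of the sex indicator and the quintile score. Rows with any
missing field are dropped and counted (complete-case analysis); the
design is checked for full column rank and offending columns are named.

Coefficients come from a numerically stable least-squares solve
(`lstsq`, SVD-based). Variance uses the clustered sandwich estimator
over schools with the CR1 small-sample factor
c = G/(G−1)·(N−1)/(N−k) and t(G−1) reference distribution — the default
clustered-SE convention of mainstream survey software, reproduced
exactly (verified against both a brute-force cluster summation and
statsmodels). With singleton clusters the estimator reduces
algebraically to the HC1-type heteroskedasticity-robust form with the
same factor. A coefficient with zero estimate *and* zero robust SE is
reported with p = 1 rather than 0/0.

## Synthetic cohorts

The generator emulates a two-wave cohort of primary-school children
(default 382 = 219 never + 84 low + 79 higher users across 36 schools)
with the statistical structure the analysis assumes, on the analysis
scale directly:

- **Exposure.** Group midpoints come from piecewise-linear quantile
  functions with knots at probabilities (0, ¼, ½, ¾, 1) through the
  target quartiles — (0.5, 1, 1.5) calls/week for the low group and
  (3, 5, 7.5) for the higher group — with ends continuing the adjacent
  segment's slope. The low group's extrapolation is floored at 0 and
  tops out at the classification threshold; the higher group's lower
  extrapolation is floored *at* the threshold, so classification of
  synthetic cohorts is exact by construction. The higher group's top
  quartile is stretched about its 75th percentile by a single constant,
  solved in closed form so the exposed-group midpoint mean equals the
  target (default 3.42 calls/week); an unreachable target raises a
  calibration error. Random cohorts draw midpoints by inverse-CDF
  sampling from these functions; the deterministic fixture places them
  at plotting positions (i−½)/n, which pins the group medians and
  quartiles to the targets within the grid spacing. Reported intervals
  are midpoint ± 0.4·midpoint (the halfwidth fraction is configurable
  in [0, 1); the value is immaterial to classification because the
  midpoint rule is halfwidth-invariant, and interval widths were never
  reported for the original instrument). A configurable 10% of exposed
  participants have their wave reports swapped to emulate decreasing
  use.
- **Covariates.** Age ~ Uniform(9.4, 10.4) years, sex ~ Bernoulli(0.53),
  country of birth ~ Bernoulli(0.75), physical activity ~ Poisson(3)
  times/week, SES and gaming quintiles uniform on {1..5}, time between
  examinations ~ Normal(1.0, 0.1) years (clipped at 0.5). These
  marginals are plausible for the target population; none of them
  affects recovery of the exposure contrasts, which is the structural
  property the generator exists to test.
- **Outcomes.** Baseline transformed scores are Normal with centre and
  spread taken from the observed score distributions of the respective
  tasks (IQR/1.349 ⇒ SD). Follow-up = intercept + β_low·LOW +
  β_higher·HIGHER + covariate effects + sex × gaming effect + school
  random intercept + residual. Default exposure contrasts are the
  published adjusted estimates; covariate effects are small fixed
  multiples of the residual SD; intercepts are solved so the mean
  follow-up score at typical covariate levels matches the observed
  follow-up centre.
- **Noise scales.** Residual SDs are calibrated once, analytically,
  from the published CI half-widths: sd ≈ hw / t₀.₉₇₅,₃₅ /
  √(1/84 + 1/219) / 1.25, the last factor a nominal allowance for the
  clustering design effect — e.g. 0.058 log₁₀ ms for Go/No Go speed,
  10.5 errors for the maze task. The school random-intercept SD is
  expressed as a multiple of each outcome's residual SD (default 0.3,
  intraclass correlation ≈ 0.08) so one parameter induces comparable
  clustering on every outcome scale.
- **The fixture involves no RNG at all.** Where noise-like variation is
  needed (covariate assignment, outcome residuals), it uses additive
  quasi-uniform sequences frac(i·√p) for distinct primes p, mapped
  through Φ⁻¹ for Gaussian residuals. The fixture is therefore
  byte-identical across runs by construction, not merely by seeding.

What the generator does **not** emulate: non-response and attrition,
measurement error in covariates or outcomes beyond additive Gaussian
noise, non-uniform exposure uncertainty, heteroskedastic or skewed
residuals, and school-level confounding (school effects are independent
of exposure). Passing recovery and coverage tests therefore show the
pipeline is unbiased and correctly calibrated *under its own model
assumptions*; they do not validate the uniform-interval assumption or
the covariate structure against real data.

## Experiment harness and problem sizes

`recovery_experiment` generates replicate cohorts with per-replicate
seeds derived from the master seed, fits every configured outcome, and
aggregates the mean estimate, empirical SE, Monte Carlo SE of the mean,
and empirical 95% CI coverage per exposure contrast. The default
experiments use 200 replicates of the 382-child cohort for recovery
(Monte Carlo SE of the mean contrast ≈ 0.0008 log₁₀ ms for Go/No Go
speed) and 300 replicates for coverage; both complete in seconds, and
the sizes match the cohort the analysis design targets.

## Numerical and degenerate-input choices

- Percentile summaries of MC distributions use linear interpolation
  (numpy default); point-mass distributions collapse to their value.
- The empirical CDF is right-continuous (`P(X ≤ t)` via binary search on
  the sorted sample).
- Rank deficiency is diagnosed by comparing `matrix_rank` with and
  without each column, so the error names the collinear columns (e.g. a
  cohort with no exposed participants reports the all-zero dummies).
- `build_design(..., check_rank=False)` permits inspecting toy designs
  with fewer rows than predictors; estimation always checks rank.
- An exposed-mean target requiring upper-tail midpoints below the
  higher group's 75th-percentile target (negative tail scale) raises
  `CalibrationError`; configuration invariants (group sizes, quantile
  monotonicity, threshold consistency, positive residual SDs) each
  raise `ConfigurationError` naming the violated condition.

## Known limitations

- The uniform interval is an assumption of convenience; real recall
  error need not be symmetric or bounded by the two reports.
- Cluster-robust OLS treats school effects as a nuisance; no
  mixed-effects estimation is attempted, and no multiple-testing
  adjustment is applied across the thirteen outcomes (matching the
  analysis design the package reproduces).
- The fixture's outcome values are synthetic constructions for
  exercising the pipeline deterministically; only its *exposure*
  structure is calibrated to published summaries.
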