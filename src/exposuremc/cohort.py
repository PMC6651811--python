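"""Synthetic school cohorts with interval-valued call exposure.

Two entry points:

``generate_cohort``
    Stochastic cohorts with the full statistical structure the analysis
    assumes — fixed exposure-group sizes, interval midpoints drawn from
    calibrated quantile functions, covariates, school random intercepts,
    and follow-up cognitive outcomes generated from known linear-model
    coefficients on the analysis (transformed) scale.  Used for
    parameter-recovery and coverage experiments.

``build_table1_fixture``
    A fully deterministic cohort whose exposure structure reproduces the
    published group sizes (219 never-users, 84 low, 79 higher of 382
    complete cases), the quartiles of weekly calls in the low (0.5, 1,
    1.5) and higher (3, 5, 7.5) groups, and the exposed-group mean of
    3.42 calls/week.  Midpoints sit on a piecewise-linear quantile grid
    through the target quartiles; the upper tail of the higher group is
    scaled by a single solved constant so the exposed mean is met
    exactly.  No random number generator is involved: covariates and
    outcome residuals come from golden-ratio quasi-uniform sequences.

All synthetic outcome columns are generated directly on the transformed
scale (log10 speed, arcsine-root accuracy, raw error counts and ratios),
so the regression stage consumes them without further transformation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .exposure import DEFAULT_THRESHOLD, RNGSpec
from .transforms import OUTCOMES

__all__ = [
    "CohortConfig",
    "CohortTable",
    "ConfigurationError",
    "CalibrationError",
    "OutcomeModel",
    "build_table1_fixture",
    "default_outcome_models",
    "generate_cohort",
]


class ConfigurationError(ValueError):
    """A cohort configuration violates an invariant."""


class CalibrationError(ValueError):
    """The requested exposure summaries cannot be realised jointly."""


# Typical covariate levels used to anchor outcome intercepts so that
# generated follow-up scores sit near realistic centres.
_COVARIATE_MEANS = {
    "age": 9.9,
    "sex": 0.53,
    "country_of_birth": 0.75,
    "physical_activity": 3.0,
    "ses_quintile": 3.0,
    "time_between_exams": 1.0,
    "gaming_quintile": 3.0,
}


@dataclass(frozen=True)
class OutcomeModel:
    """Generating linear model for one transformed outcome.

    follow-up = intercept + beta_low*LOW + beta_higher*HIGHER
                + covariate effects + beta_sex_gaming*sex*gaming
                + school intercept + residual
    with the baseline score drawn Normal(baseline_mean, baseline_sd).
    """

    intercept: float
    beta_low: float
    beta_higher: float
    beta_age: float
    beta_sex: float
    beta_country: float
    beta_activity: float
    beta_ses: float
    beta_time: float
    beta_baseline: float
    beta_gaming: float
    beta_sex_gaming: float
    baseline_mean: float
    baseline_sd: float

    def linear_predictor(
        self,
        low,
        higher,
        age,
        sex,
        country,
        activity,
        ses,
        time_between,
        baseline,
        gaming,
    ):
        return (
            self.intercept
            + self.beta_low * low
            + self.beta_higher * higher
            + self.beta_age * age
            + self.beta_sex * sex
            + self.beta_country * country
            + self.beta_activity * activity
            + self.beta_ses * ses
            + self.beta_time * time_between
            + self.beta_baseline * baseline
            + self.beta_gaming * gaming
            + self.beta_sex_gaming * sex * gaming
        )


# Published adjusted group contrasts (low, higher vs never-users) on the
# transformed scale, and centres/spreads of the transformed baseline
# score distributions, per outcome.  Residual SDs are set so that a
# 382-child, 36-school fit yields cluster-robust confidence intervals of
# roughly the published width (half-width hw -> sd ~= hw * 3.07; the
# factor combines the t quantile, the group-contrast leverage
# sqrt(1/84 + 1/219), and a nominal 1.25 clustering design effect).
_OUTCOME_TABLE = {
    # name: (beta_low, beta_higher, baseline_mean, baseline_sd, residual_sd, followup_center)
    "detection_speed": (-0.015, -0.0002, 2.5416, 0.100, 0.0614, 2.5011),
    "detection_accuracy": (-0.002, 0.002, 1.3971, 0.239, 0.1428, 1.3971),
    "identification_speed": (0.001, -0.010, 2.7752, 0.083, 0.0660, 2.7340),
    "identification_accuracy": (0.006, 0.028, 1.3233, 0.156, 0.1336, 1.3233),
    "one_back_speed": (0.013, -0.0001, 2.9877, 0.110, 0.0737, 2.9370),
    "one_back_accuracy": (0.001, -0.030, 1.2345, 0.196, 0.1520, 1.2661),
    "one_card_speed": (0.001, 0.009, 3.0426, 0.130, 0.0752, 3.0141),
    "one_card_accuracy": (0.005, -0.016, 0.8746, 0.120, 0.0829, 0.9273),
    "go_nogo_speed": (-0.023, -0.024, 2.8007, 0.083, 0.0583, 2.7619),
    "go_nogo_accuracy": (-0.014, -0.002, 1.3694, 0.183, 0.0921, 1.4289),
    "groton_maze_errors": (4.53, 1.77, 69.0, 22.2, 10.5, 56.0),
    "stroop_ab_ratio": (0.034, 0.004, 0.09, 0.111, 0.103, 0.11),
    "stroop_cd_ratio": (-0.036, -0.042, 0.69, 0.267, 0.249, 0.65),
}


def default_outcome_models() -> dict[str, OutcomeModel]:
    """Generating models for all thirteen outcomes.

    Covariate effects are small fixed multiples of each outcome's
    residual SD (their exact values are immaterial to recovery of the
    exposure contrasts, but keep the design realistic and exercised);
    intercepts are solved so the mean follow-up score at typical
    covariate levels matches the outcome's follow-up centre.
    """
    models = {}
    cm = _COVARIATE_MEANS
    for name, (b_low, b_high, base_mu, base_sd, resid_sd, follow_mu) in _OUTCOME_TABLE.items():
        betas = {
            "beta_age": -0.10 * resid_sd,
            "beta_sex": 0.10 * resid_sd,
            "beta_country": 0.05 * resid_sd,
            "beta_activity": 0.02 * resid_sd,
            "beta_ses": 0.03 * resid_sd,
            "beta_time": -0.20 * resid_sd,
            "beta_baseline": 0.5,
            "beta_gaming": 0.05 * resid_sd,
            "beta_sex_gaming": -0.03 * resid_sd,
        }
        anchor = (
            betas["beta_age"] * cm["age"]
            + betas["beta_sex"] * cm["sex"]
            + betas["beta_country"] * cm["country_of_birth"]
            + betas["beta_activity"] * cm["physical_activity"]
            + betas["beta_ses"] * cm["ses_quintile"]
            + betas["beta_time"] * cm["time_between_exams"]
            + betas["beta_baseline"] * base_mu
            + betas["beta_gaming"] * cm["gaming_quintile"]
            + betas["beta_sex_gaming"] * cm["sex"] * cm["gaming_quintile"]
        )
        models[name] = OutcomeModel(
            intercept=follow_mu - anchor,
            beta_low=b_low,
            beta_higher=b_high,
            baseline_mean=base_mu,
            baseline_sd=base_sd,
            **betas,
        )
    return models


def default_residual_sd() -> dict[str, float]:
    return {name: row[4] for name, row in _OUTCOME_TABLE.items()}


@dataclass(frozen=True)
class CohortConfig:
    """Full generating specification for a synthetic cohort.

    ``school_sd`` is the school random-intercept SD expressed as a
    multiple of each outcome's residual SD, so a single number induces a
    comparable intraclass correlation on every outcome scale.
    """

    n_none: int = 219
    n_low: int = 84
    n_higher: int = 79
    n_schools: int = 36
    midpoint_quantiles_low: tuple[float, float, float] = (0.5, 1.0, 1.5)
    midpoint_quantiles_higher: tuple[float, float, float] = (3.0, 5.0, 7.5)
    exposed_mean_target: float = 3.42
    interval_halfwidth_fraction: float = 0.4
    threshold: float = DEFAULT_THRESHOLD
    true_coefficients: dict[str, OutcomeModel] = field(default_factory=default_outcome_models)
    residual_sd: dict[str, float] = field(default_factory=default_residual_sd)
    school_sd: float = 0.3
    decrease_fraction: float = 0.1
    school_imbalance: float = 0.0
    seed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_none + self.n_low + self.n_higher

    @property
    def n_exposed(self) -> int:
        return self.n_low + self.n_higher

    def validate(self) -> None:
        if min(self.n_none, self.n_low, self.n_higher) < 0:
            raise ConfigurationError("group sizes must be non-negative")
        if self.n_schools < 1:
            raise ConfigurationError("n_schools must be a positive integer")
        for label, q in (
            ("low", self.midpoint_quantiles_low),
            ("higher", self.midpoint_quantiles_higher),
        ):
            if len(q) != 3:
                raise ConfigurationError(f"{label} quantile target must be a triple")
            if any(v < 0 for v in q):
                raise ConfigurationError(f"{label} quantile targets must be non-negative")
            if not (q[0] <= q[1] <= q[2]):
                raise ConfigurationError(f"{label} quantile targets must be non-decreasing")
        if not 0 <= self.interval_halfwidth_fraction < 1:
            raise ConfigurationError("interval_halfwidth_fraction must lie in [0, 1)")
        if self.exposed_mean_target < 0:
            raise ConfigurationError("exposed_mean_target must be non-negative")
        if self.threshold < 0:
            raise ConfigurationError("threshold must be non-negative")
        if self.school_sd < 0:
            raise ConfigurationError("school_sd must be non-negative")
        if not 0 <= self.decrease_fraction <= 1:
            raise ConfigurationError("decrease_fraction must lie in [0, 1]")
        unknown = set(self.true_coefficients) - set(OUTCOMES)
        if unknown:
            raise ConfigurationError(f"unknown outcomes in true_coefficients: {sorted(unknown)}")
        for name in self.true_coefficients:
            sd = self.residual_sd.get(name)
            if sd is None or sd <= 0:
                raise ConfigurationError(f"residual_sd for outcome {name!r} must be positive")
        # low-group midpoints must stay strictly below the threshold so
        # that classification of synthetic cohorts is exact by construction
        if self.n_low and _quantile_knots(self.midpoint_quantiles_low)[1][-1] > self.threshold:
            raise ConfigurationError(
                "low-group quantile targets extrapolate above the classification threshold"
            )
        if self.n_higher and self.midpoint_quantiles_higher[0] < self.threshold:
            raise ConfigurationError(
                "higher-group quantile targets reach below the classification threshold"
            )

    # -- config file round trip ------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_none", "n_low", "n_higher", "n_schools", "exposed_mean_target",
                "interval_halfwidth_fraction", "threshold", "school_sd",
                "decrease_fraction", "school_imbalance", "seed",
            )
        }
        d["midpoint_quantiles_low"] = list(self.midpoint_quantiles_low)
        d["midpoint_quantiles_higher"] = list(self.midpoint_quantiles_higher)
        d["residual_sd"] = dict(self.residual_sd)
        d["true_coefficients"] = {
            name: vars(model).copy() for name, model in self.true_coefficients.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "midpoint_quantiles_low" in d:
            d["midpoint_quantiles_low"] = tuple(d["midpoint_quantiles_low"])
        if "midpoint_quantiles_higher" in d:
            d["midpoint_quantiles_higher"] = tuple(d["midpoint_quantiles_higher"])
        if "true_coefficients" in d:
            d["true_coefficients"] = {
                name: coeffs if isinstance(coeffs, OutcomeModel) else OutcomeModel(**coeffs)
                for name, coeffs in d["true_coefficients"].items()
            }
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def restricted_to(self, outcomes) -> "CohortConfig":
        """Copy of the config generating only the named outcomes."""
        outcomes = list(outcomes)
        return replace(
            self,
            true_coefficients={k: self.true_coefficients[k] for k in outcomes},
            residual_sd={k: self.residual_sd[k] for k in outcomes},
        )


# column order of the cohort CSV, before the outcome columns
BASE_COLUMNS = [
    "participant_id",
    "school_id",
    "baseline_calls",
    "followup_calls",
    "age",
    "sex",
    "country_of_birth",
    "physical_activity",
    "ses_quintile",
    "time_between_exams",
    "gaming_quintile",
]


@dataclass
class CohortTable:
    """Participant-level records consumed by every analysis stage.

    ``transformed`` records whether outcome columns are already on the
    analysis scale (always true for generated and fixture cohorts).
    """

    data: pd.DataFrame
    provenance: str  # generated | fixture | loaded
    seed: int | None = None
    transformed: bool = True

    def __post_init__(self) -> None:
        if self.provenance not in ("generated", "fixture", "loaded"):
            raise ConfigurationError(f"unknown provenance {self.provenance!r}")
        missing = [c for c in BASE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"cohort table missing columns: {missing}")
        if self.data["participant_id"].duplicated().any():
            raise ConfigurationError("participant_ids must be unique")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def outcomes(self) -> list[str]:
        return [
            name for name in OUTCOMES
            if f"{name}_baseline" in self.data.columns
            and f"{name}_followup" in self.data.columns
        ]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path, transformed: bool = False) -> "CohortTable":
        df = pd.read_csv(path)
        return cls(df, provenance="loaded", transformed=transformed)


# -- midpoint quantile machinery ----------------------------------------------


def _quantile_knots(quartiles, lower_floor=0.0):
    """Piecewise-linear quantile knots through the quartile triple.

    Knots at probabilities (0, .25, .5, .75, 1); the end values continue
    the adjacent quartile segment linearly, floored below at
    ``lower_floor`` (0 for the low group, the classification threshold
    for the higher group so that no higher-group midpoint can fall into
    the low class).
    """
    q25, q50, q75 = (float(v) for v in quartiles)
    v0 = max(lower_floor, q25 - (q50 - q25))
    v4 = q75 + (q75 - q50)
    return np.array([0.0, 0.25, 0.5, 0.75, 1.0]), np.array([v0, q25, q50, q75, v4])


def _midpoint_grid(n: int) -> np.ndarray:
    """Plotting-position probabilities (i - 0.5)/n, i = 1..n."""
    return (np.arange(1, n + 1) - 0.5) / n


def _solve_tail_scale(config: CohortConfig) -> float:
    """Scale for the higher group's top quartile meeting the exposed mean.

    Low and higher midpoints on their deterministic grids fix everything
    except the higher group's values above the 75th percentile, which
    are stretched about that percentile: v -> q75 + s*(v - q75).  The
    exposed-group mean is linear in s, so s is solved in closed form.
    """
    if config.n_higher == 0:
        return 1.0
    kp_low, kv_low = _quantile_knots(config.midpoint_quantiles_low)
    kp_hi, kv_hi = _quantile_knots(config.midpoint_quantiles_higher, lower_floor=config.threshold)
    low = np.interp(_midpoint_grid(config.n_low), kp_low, kv_low) if config.n_low else np.array([])
    p_hi = _midpoint_grid(config.n_higher)
    base = np.interp(p_hi, kp_hi, kv_hi)
    q75 = config.midpoint_quantiles_higher[2]
    top = p_hi > 0.75
    excess = base[top] - q75
    target_sum = config.exposed_mean_target * config.n_exposed
    fixed_sum = low.sum() + base[~top].sum() + q75 * top.sum()
    if excess.sum() == 0:
        if abs(fixed_sum - target_sum) > 1e-9 * max(1.0, target_sum):
            raise CalibrationError(
                "no free upper tail: exposed mean cannot be calibrated to the target"
            )
        return 1.0
    s = (target_sum - fixed_sum) / excess.sum()
    if s < 0:
        raise CalibrationError(
            "exposed mean target requires upper-tail midpoints below the 75th-percentile target"
        )
    return float(s)


def _scaled_higher_midpoints(config: CohortConfig, p: np.ndarray, s: float) -> np.ndarray:
    kp, kv = _quantile_knots(config.midpoint_quantiles_higher, lower_floor=config.threshold)
    base = np.interp(p, kp, kv)
    q75 = config.midpoint_quantiles_higher[2]
    top = p > 0.75
    base[top] = q75 + s * (base[top] - q75)
    return base


def _low_midpoints(config: CohortConfig, p: np.ndarray) -> np.ndarray:
    kp, kv = _quantile_knots(config.midpoint_quantiles_low)
    return np.interp(p, kp, kv)


def _intervals_from_midpoints(midpoints: np.ndarray, fraction: float):
    half = fraction * midpoints
    return np.clip(midpoints - half, 0.0, None), midpoints + half


def _check_midpoint_classes(config: CohortConfig, low_mid: np.ndarray, hi_mid: np.ndarray) -> None:
    if low_mid.size and low_mid.max() >= config.threshold:
        raise ConfigurationError(
            "low-group midpoints must stay strictly below the classification threshold"
        )
    if low_mid.size and low_mid.min() <= 0:
        raise ConfigurationError("low-group midpoints must be strictly positive")
    if hi_mid.size and hi_mid.min() <= config.threshold:
        raise ConfigurationError(
            "higher-group midpoints must stay strictly above the classification threshold"
        )


# -- quasi-uniform sequences for the deterministic fixture ---------------------

_QUASI_SHIFTS = np.sqrt(np.array([2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59]))


def _quasi_uniform(n: int, channel: int) -> np.ndarray:
    """Low-discrepancy uniforms on (0, 1): fractional parts of i*sqrt(prime).

    Used in place of a pseudo-random stream wherever the fixture cohort
    needs noise-like but fully deterministic variation.
    """
    alpha = _QUASI_SHIFTS[channel % len(_QUASI_SHIFTS)] + 0.5 * (channel // len(_QUASI_SHIFTS))
    u = np.modf(np.arange(1, n + 1) * alpha)[0]
    return np.clip(u, 1e-9, 1 - 1e-9)


# -- covariate and outcome generation -----------------------------------------


def _school_assignment(config: CohortConfig, order: np.ndarray) -> np.ndarray:
    """Round-robin allocation over schools, optionally weight-skewed.

    With ``school_imbalance`` w > 0, school k receives weight (1 + w)^k
    (normalised), producing unequal cluster sizes.
    """
    n, m = config.n_total, config.n_schools
    if config.school_imbalance == 0:
        ids = np.arange(n) % m
    else:
        weights = (1.0 + config.school_imbalance) ** np.arange(m)
        counts = np.floor(weights / weights.sum() * n).astype(int)
        while counts.sum() < n:
            counts[np.argmax(weights / (counts + 1))] += 1
        ids = np.repeat(np.arange(m), counts)
    return ids[order]


def _assemble(config, low_mid, hi_mid, covars, outcome_cols, provenance, seed, swap_mask):
    n = config.n_total
    midpoints = np.concatenate([np.zeros(config.n_none), low_mid, hi_mid])
    lower = np.zeros(n)
    upper = np.zeros(n)
    exposed = midpoints > 0
    lo, up = _intervals_from_midpoints(midpoints[exposed], config.interval_halfwidth_fraction)
    lower[exposed], upper[exposed] = lo, up
    baseline_calls = np.where(swap_mask, upper, lower)
    followup_calls = np.where(swap_mask, lower, upper)
    data = {"participant_id": [f"P{i:04d}" for i in range(1, n + 1)]}
    data["school_id"] = covars.pop("school_id")
    data["baseline_calls"] = baseline_calls
    data["followup_calls"] = followup_calls
    data.update(covars)
    data.update(outcome_cols)
    df = pd.DataFrame(data, columns=BASE_COLUMNS + list(outcome_cols))
    return CohortTable(df, provenance=provenance, seed=seed, transformed=True)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> CohortTable:
    """Draw one stochastic synthetic cohort.

    Deterministic given (config, seed): every random stream is derived
    from the master seed through named substreams.  Exposure midpoints
    are inverse-CDF draws from the calibrated group quantile functions,
    so their distribution matches the configured quartile targets and
    exposed-group mean in expectation; classification is exact by
    construction (low midpoints below the threshold, higher above).
    """
    config.validate()
    if seed is None:
        seed = config.seed
    root = RNGSpec(int(seed))
    g_exposure = root.child(0).generator()
    g_covar = root.child(1).generator()
    g_school = root.child(2).generator()
    s = _solve_tail_scale(config)
    low_mid = _low_midpoints(config, g_exposure.random(config.n_low))
    hi_mid = _scaled_higher_midpoints(config, g_exposure.random(config.n_higher), s)
    _check_midpoint_classes(config, low_mid, hi_mid)

    n = config.n_total
    order = g_school.permutation(n)
    covars = {
        "school_id": _school_assignment(config, order),
        "age": g_covar.uniform(9.4, 10.4, n),
        "sex": (g_covar.random(n) < 0.53).astype(int),
        "country_of_birth": (g_covar.random(n) < 0.75).astype(int),
        "physical_activity": g_covar.poisson(3.0, n),
        "ses_quintile": g_covar.integers(1, 6, n),
        "time_between_exams": np.clip(g_covar.normal(1.0, 0.1, n), 0.5, None),
        "gaming_quintile": g_covar.integers(1, 6, n),
    }
    swap = np.zeros(n, dtype=bool)
    n_exp = config.n_exposed
    swap[config.n_none:] = g_exposure.random(n_exp) < config.decrease_fraction

    low = np.concatenate([np.zeros(config.n_none), np.ones(config.n_low), np.zeros(config.n_higher)])
    higher = np.concatenate([np.zeros(config.n_none + config.n_low), np.ones(config.n_higher)])
    outcome_cols = {}
    for k, name in enumerate(config.true_coefficients):
        model = config.true_coefficients[name]
        resid_sd = config.residual_sd[name]
        g_out = root.child(3, k).generator()
        baseline = g_out.normal(model.baseline_mean, model.baseline_sd, n)
        school_fx = g_out.normal(0.0, config.school_sd * resid_sd, config.n_schools)
        lp = model.linear_predictor(
            low, higher,
            covars["age"], covars["sex"], covars["country_of_birth"],
            covars["physical_activity"], covars["ses_quintile"],
            covars["time_between_exams"], baseline, covars["gaming_quintile"],
        )
        followup = lp + school_fx[covars["school_id"]] + g_out.normal(0.0, resid_sd, n)
        outcome_cols[f"{name}_baseline"] = baseline
        outcome_cols[f"{name}_followup"] = followup
    return _assemble(config, low_mid, hi_mid, covars, outcome_cols,
                     "generated", int(seed), swap)


def build_table1_fixture(config: CohortConfig | None = None) -> CohortTable:
    """Deterministic cohort reproducing the published exposure summaries.

    Midpoints are placed on the piecewise-linear quantile grid at
    plotting positions (i - 0.5)/n; the higher group's top quartile is
    stretched by the solved constant so the exposed-group midpoint mean
    equals ``exposed_mean_target`` exactly.  Covariates and outcome
    residuals use quasi-uniform (golden-ratio-style) sequences: the
    fixture involves no random number generator and is byte-identical
    across runs.
    """
    if config is None:
        config = CohortConfig()
    config.validate()
    s = _solve_tail_scale(config)
    low_mid = _low_midpoints(config, _midpoint_grid(config.n_low))
    hi_mid = _scaled_higher_midpoints(config, _midpoint_grid(config.n_higher), s)
    _check_midpoint_classes(config, low_mid, hi_mid)

    n = config.n_total
    idx = np.arange(n)
    covars = {
        "school_id": idx % config.n_schools,
        "age": 9.4 + (idx % 21) / 20.0,
        "sex": (_quasi_uniform(n, 0) < 0.53).astype(int),
        "country_of_birth": (_quasi_uniform(n, 1) < 0.75).astype(int),
        "physical_activity": np.floor(7 * _quasi_uniform(n, 2)).astype(int),
        "ses_quintile": 1 + idx % 5,
        "time_between_exams": 0.9 + 0.2 * _quasi_uniform(n, 3),
        "gaming_quintile": 1 + (idx // 5) % 5,
    }
    low = np.concatenate([np.zeros(config.n_none), np.ones(config.n_low), np.zeros(config.n_higher)])
    higher = np.concatenate([np.zeros(config.n_none + config.n_low), np.ones(config.n_higher)])
    outcome_cols = {}
    for k, name in enumerate(config.true_coefficients):
        model = config.true_coefficients[name]
        resid_sd = config.residual_sd[name]
        baseline = model.baseline_mean + model.baseline_sd * norm.ppf(_quasi_uniform(n, 4 + 2 * k))
        lp = model.linear_predictor(
            low, higher,
            covars["age"], covars["sex"], covars["country_of_birth"],
            covars["physical_activity"], covars["ses_quintile"],
            covars["time_between_exams"], baseline, covars["gaming_quintile"],
        )
        followup = lp + resid_sd * norm.ppf(_quasi_uniform(n, 5 + 2 * k))
        outcome_cols[f"{name}_baseline"] = baseline
        outcome_cols[f"{name}_followup"] = followup
    return _assemble(config, low_mid, hi_mid, covars, outcome_cols,
                     "fixture", None, np.zeros(n, dtype=bool))
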