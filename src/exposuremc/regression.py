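"""Adjusted linear models with school-clustered robust standard errors.

For each transformed cognitive outcome, the follow-up score is regressed
on exposure-group dummies (reference: never-users) and the adjustment
set — age, sex, country of birth, physical activity, socioeconomic
quintile, time between examinations, baseline score, console-gaming
quintile, and a sex x gaming interaction.  Inference uses the clustered
sandwich (CR1) variance estimator with the small-sample factor
G/(G-1) * (N-1)/(N-k) and t(G-1) reference distribution, the default
convention of clustered regression in mainstream survey software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BASE_COLUMNS, CohortTable
from .exposure import DEFAULT_THRESHOLD, ExposureClass, classify, interval_from_reports
from .transforms import OUTCOMES, transform_column

__all__ = [
    "DesignMatrixSpec",
    "RegressionFit",
    "build_design",
    "classification_table",
    "cluster_robust_vcov",
    "confidence_intervals",
    "fit_ols",
    "fit_outcome",
    "table3_report",
]


class DesignError(ValueError):
    """Design matrix cannot be built or is rank deficient."""


@dataclass(frozen=True)
class DesignMatrixSpec:
    """Response and predictor layout for one outcome's model.

    ``gaming_categorical`` switches the console-gaming quintile (and its
    sex interaction) from an integer score to indicator coding.
    """

    outcome: str
    threshold: float = DEFAULT_THRESHOLD
    gaming_categorical: bool = False

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise DesignError(f"unknown outcome {self.outcome!r}")


@dataclass
class RegressionFit:
    """Coefficients and cluster-robust inference for one outcome."""

    outcome: str
    params: pd.Series
    vcov: pd.DataFrame
    G: int
    N: int
    k: int
    n_dropped: int = 0
    level: float = 0.95

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.values)), index=self.params.index)

    @property
    def df(self) -> int:
        return self.G - 1

    @property
    def tvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        t = self.tvalues.to_numpy(dtype=float)
        p = 2 * stats.t.sf(np.abs(t), self.df)
        p = np.where(np.isnan(t), np.nan, p)
        # zero-SE, zero-estimate coefficients carry no evidence against zero
        p = np.where((self.bse == 0) & (self.params == 0), 1.0, p)
        return pd.Series(p, index=self.params.index)

    def conf_int(self, level: float | None = None) -> pd.DataFrame:
        level = self.level if level is None else level
        half = stats.t.ppf((1 + level) / 2, self.df) * self.bse
        return pd.DataFrame(
            {"lower": self.params - half, "upper": self.params + half},
            index=self.params.index,
        )


def classification_table(table: CohortTable, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Per-participant exposure intervals, class probabilities, and groups."""
    rows = []
    for _, r in table.data.iterrows():
        iv = interval_from_reports(r["baseline_calls"], r["followup_calls"])
        rows.append(
            {
                "participant_id": r["participant_id"],
                "a": iv.lower,
                "b": iv.upper,
                "p_le_threshold": iv.cdf(threshold),
                "exposure_class": classify(iv, threshold).value,
            }
        )
    return pd.DataFrame(rows)


def _transformed_response(table: CohortTable, outcome: str, wave: str) -> pd.Series:
    col = f"{outcome}_{wave}"
    if col not in table.data.columns:
        raise DesignError(f"cohort table has no column {col!r}")
    values = table.data[col]
    if table.transformed:
        return values.astype(float)
    return pd.Series(transform_column(OUTCOMES[outcome], values.to_numpy()), index=values.index)


def build_design(table: CohortTable, spec: DesignMatrixSpec, check_rank: bool = True):
    """Design matrix, response vector and cluster ids for one outcome.

    Exposure dummies come from the probabilistic interval classifier;
    complete-case rows only; columns in a fixed documented order.
    ``check_rank=False`` skips the full-rank requirement, for inspecting
    toy designs too small to be estimable.  Returns
    ``(X, y, clusters, n_dropped)``.
    """
    df = table.data
    needed = BASE_COLUMNS + [f"{spec.outcome}_baseline", f"{spec.outcome}_followup"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DesignError(f"cohort table missing columns: {missing}")
    complete = df[needed].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    sub = CohortTable(
        df.loc[complete].reset_index(drop=True),
        provenance=table.provenance,
        seed=table.seed,
        transformed=table.transformed,
    )
    d = sub.data

    classes = np.array(
        [
            classify(interval_from_reports(b, f), spec.threshold)
            for b, f in zip(d["baseline_calls"], d["followup_calls"])
        ]
    )
    X = pd.DataFrame(index=d.index)
    X["const"] = 1.0
    X["exposure_low"] = (classes == ExposureClass.LOW).astype(float)
    X["exposure_higher"] = (classes == ExposureClass.HIGHER).astype(float)
    X["age"] = d["age"].astype(float)
    X["sex"] = d["sex"].astype(float)
    X["country_of_birth"] = d["country_of_birth"].astype(float)
    X["physical_activity"] = d["physical_activity"].astype(float)
    X["ses_quintile"] = d["ses_quintile"].astype(float)
    X["time_between_exams"] = d["time_between_exams"].astype(float)
    X["baseline_score"] = _transformed_response(sub, spec.outcome, "baseline")
    if spec.gaming_categorical:
        for q in (2, 3, 4, 5):
            dummy = (d["gaming_quintile"] == q).astype(float)
            X[f"gaming_q{q}"] = dummy
            X[f"sex_gaming_q{q}"] = X["sex"] * dummy
    else:
        X["gaming_quintile"] = d["gaming_quintile"].astype(float)
        X["sex_gaming"] = X["sex"] * X["gaming_quintile"]
    y = _transformed_response(sub, spec.outcome, "followup")

    clusters = d["school_id"].to_numpy()
    if np.unique(clusters).size < 2:
        raise DesignError("clustered inference requires at least 2 schools")
    if check_rank:
        _check_rank(X)
    return X, y, clusters, n_dropped


def _check_rank(X: pd.DataFrame) -> None:
    """Raise naming (near-)collinear columns if X is rank deficient."""
    M = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(M)
    if rank == X.shape[1]:
        return
    offenders = []
    # columns whose removal restores full rank relative to the rest
    for j, name in enumerate(X.columns):
        others = np.delete(M, j, axis=1)
        if np.linalg.matrix_rank(others) == rank:
            offenders.append(name)
    raise DesignError(f"design matrix is rank deficient; collinear columns: {offenders}")


def fit_ols(X, y):
    """Least-squares coefficients and residuals via QR/SVD factorisation."""
    M = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise DesignError("design matrix is singular")
    beta, *_ = np.linalg.lstsq(M, yv, rcond=None)
    resid = yv - M @ beta
    if isinstance(X, pd.DataFrame):
        beta = pd.Series(beta, index=X.columns)
    return beta, resid


def cluster_robust_vcov(X, residuals, cluster_ids, small_sample: bool = True):
    """Clustered sandwich covariance of the OLS coefficients.

    V = c (X'X)^-1 [sum_g X_g' u_g u_g' X_g] (X'X)^-1 with the CR1
    small-sample factor c = G/(G-1) * (N-1)/(N-k).  With every cluster a
    single observation this reduces to the heteroskedasticity-robust
    (HC1-type) estimator carrying the same factor.
    """
    M = np.asarray(X, dtype=float)
    u = np.asarray(residuals, dtype=float)
    groups = np.asarray(cluster_ids)
    if groups.shape[0] != M.shape[0]:
        raise DesignError("cluster ids must cover every design row")
    labels = np.unique(groups)
    G, (N, k) = labels.size, M.shape
    if G < 2:
        raise DesignError("clustered variance requires at least 2 clusters")
    bread = np.linalg.inv(M.T @ M)
    # score sums per cluster, via grouped accumulation
    Xu = M * u[:, None]
    codes = np.searchsorted(labels, groups)
    S = np.zeros((G, k))
    np.add.at(S, codes, Xu)
    meat = S.T @ S
    c = (G / (G - 1)) * ((N - 1) / (N - k)) if small_sample else 1.0
    V = c * bread @ meat @ bread
    V = (V + V.T) / 2  # enforce symmetry against round-off
    if isinstance(X, pd.DataFrame):
        V = pd.DataFrame(V, index=X.columns, columns=X.columns)
    return V


def confidence_intervals(fit: RegressionFit, level: float = 0.95) -> pd.DataFrame:
    """CIs estimate +/- t(G-1) * robust SE and two-sided p-values."""
    ci = fit.conf_int(level)
    ci["p_value"] = fit.pvalues
    return ci


def fit_outcome(table: CohortTable, spec: DesignMatrixSpec) -> RegressionFit:
    """End-to-end adjusted fit for one outcome."""
    X, y, clusters, n_dropped = build_design(table, spec)
    beta, resid = fit_ols(X, y)
    V = cluster_robust_vcov(X, resid, clusters)
    return RegressionFit(
        outcome=spec.outcome,
        params=beta,
        vcov=V,
        G=int(np.unique(clusters).size),
        N=int(len(y)),
        k=int(X.shape[1]),
        n_dropped=n_dropped,
    )


def table3_report(
    table: CohortTable,
    outcomes: list[str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Adjusted exposure-group contrasts for every outcome.

    One row per outcome x exposure group with the estimate, robust SE,
    95% CI, p-value, and a significance flag at ``alpha``.
    """
    outcomes = table.outcomes if outcomes is None else outcomes
    rows = []
    for name in outcomes:
        fit = fit_outcome(table, DesignMatrixSpec(name, threshold=threshold))
        ci = fit.conf_int()
        for group in ("exposure_low", "exposure_higher"):
            est = fit.params[group]
            p = fit.pvalues[group]
            rows.append(
                {
                    "outcome": name,
                    "label": OUTCOMES[name].label,
                    "group": group.removeprefix("exposure_"),
                    "estimate": est,
                    "robust_se": fit.bse[group],
                    "ci_lower": ci.loc[group, "lower"],
                    "ci_upper": ci.loc[group, "upper"],
                    "p_value": p,
                    "significant": bool(p <= alpha),
                    "n_obs": fit.N,
                    "n_clusters": fit.G,
                }
            )
    return pd.DataFrame(rows)
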