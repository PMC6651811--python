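"""Design construction, OLS, and the clustered sandwich estimator.

Brute-force normal-equation and cluster-summation oracles, plus
statsmodels' clustered covariance, serve as independent references.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exposuremc import (
    CohortConfig,
    DesignMatrixSpec,
    RegressionFit,
    build_design,
    cluster_robust_vcov,
    confidence_intervals,
    fit_ols,
    fit_outcome,
    generate_cohort,
    table3_report,
)
from exposuremc.regression import DesignError


def brute_force_cr1(X, u, groups):
    """Direct loop-over-clusters sandwich with the CR1 factor."""
    M = np.asarray(X, float)
    N, k = M.shape
    G = len(np.unique(groups))
    XtXi = np.linalg.inv(M.T @ M)
    meat = np.zeros((k, k))
    for g in np.unique(groups):
        s = (M[groups == g] * u[groups == g, None]).sum(axis=0)
        meat += np.outer(s, s)
    c = G / (G - 1) * (N - 1) / (N - k)
    return c * XtXi @ meat @ XtXi


def toy_problem(seed=0, n=18, k=4, n_groups=3):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    beta = rng.normal(size=k)
    y = X @ beta + rng.normal(size=n)
    groups = np.arange(n) % n_groups
    return X, y, groups


class TestBuildDesign:
    def test_fixture_dummy_sums(self, fixture_cohort):
        X, y, clusters, dropped = build_design(fixture_cohort, DesignMatrixSpec("go_nogo_speed"))
        assert X["exposure_low"].sum() == 84
        assert X["exposure_higher"].sum() == 79
        assert dropped == 0
        assert len(np.unique(clusters)) == 36
        assert list(X.columns) == [
            "const", "exposure_low", "exposure_higher", "age", "sex",
            "country_of_birth", "physical_activity", "ses_quintile",
            "time_between_exams", "baseline_score", "gaming_quintile", "sex_gaming",
        ]

    def test_all_none_cohort_is_rank_deficient(self):
        cfg = CohortConfig(n_none=40, n_low=0, n_higher=0, n_schools=4).restricted_to(
            ["go_nogo_speed"]
        )
        table = generate_cohort(cfg, seed=0)
        with pytest.raises(DesignError, match="exposure"):
            build_design(table, DesignMatrixSpec("go_nogo_speed"))

    def test_three_row_toy_matrix_by_hand(self):
        from exposuremc.cohort import CohortTable

        df = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c"],
                "school_id": [0, 1, 0],
                "baseline_calls": [0.0, 1.0, 4.0],
                "followup_calls": [0.0, 1.5, 6.0],
                "age": [9.5, 10.0, 10.2],
                "sex": [0, 1, 1],
                "country_of_birth": [1, 1, 0],
                "physical_activity": [2, 3, 4],
                "ses_quintile": [1, 3, 5],
                "time_between_exams": [1.0, 1.1, 0.9],
                "gaming_quintile": [2, 4, 5],
                "go_nogo_speed_baseline": [2.8, 2.7, 2.9],
                "go_nogo_speed_followup": [2.7, 2.6, 2.85],
            }
        )
        table = CohortTable(df, provenance="loaded", transformed=True)
        X, y, clusters, _ = build_design(
            table, DesignMatrixSpec("go_nogo_speed"), check_rank=False
        )
        # a: never-user; b: midpoint 1.25 -> low; c: midpoint 5 -> higher
        assert X["exposure_low"].tolist() == [0.0, 1.0, 0.0]
        assert X["exposure_higher"].tolist() == [0.0, 0.0, 1.0]
        assert X["sex_gaming"].tolist() == [0.0, 4.0, 5.0]
        assert y.tolist() == [2.7, 2.6, 2.85]
        assert clusters.tolist() == [0, 1, 0]

    def test_complete_case_rows_dropped_and_counted(self, fixture_cohort):
        df = fixture_cohort.data.copy()
        df.loc[df.index[:7], "go_nogo_speed_followup"] = np.nan
        from exposuremc.cohort import CohortTable

        table = CohortTable(df, provenance="fixture", transformed=True)
        X, y, clusters, dropped = build_design(table, DesignMatrixSpec("go_nogo_speed"))
        assert dropped == 7
        assert len(y) == fixture_cohort.n - 7

    def test_gaming_categorical_flag_expands_design(self, fixture_cohort):
        X, *_ = build_design(
            fixture_cohort, DesignMatrixSpec("go_nogo_speed", gaming_categorical=True)
        )
        assert {"gaming_q2", "gaming_q5", "sex_gaming_q3"} <= set(X.columns)
        assert "gaming_quintile" not in X.columns


class TestFitOLS:
    def test_exact_linear_fit_has_zero_residuals(self):
        X, _, _ = toy_problem(1)
        y = X @ np.array([1.0, -2.0, 0.5, 3.0])
        beta, resid = fit_ols(X, y)
        assert np.allclose(resid, 0, atol=1e-10)
        assert beta == pytest.approx([1.0, -2.0, 0.5, 3.0])

    def test_intercept_only_returns_mean(self):
        y = np.array([1.0, 2.0, 6.0])
        beta, _ = fit_ols(np.ones((3, 1)), y)
        assert beta[0] == pytest.approx(y.mean())

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(6), rng.normal(size=(6, 2))])
        y = rng.normal(size=6)
        beta, resid = fit_ols(X, y)
        oracle = np.linalg.inv(X.T @ X) @ X.T @ y
        assert np.allclose(beta, oracle, atol=1e-10)
        assert np.allclose(X.T @ resid, 0, atol=1e-8)  # residual orthogonality

    def test_singular_design_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(DesignError):
            fit_ols(X, np.arange(5.0))


class TestClusterRobustVcov:
    def test_zero_residuals_give_zero_matrix(self):
        X, _, groups = toy_problem(2)
        V = cluster_robust_vcov(X, np.zeros(len(X)), groups)
        assert np.allclose(V, 0)

    def test_matches_brute_force_on_small_instances(self):
        for seed in range(5):
            X, y, groups = toy_problem(seed, n=20, k=4, n_groups=5)
            _, u = fit_ols(X, y)
            V = cluster_robust_vcov(X, u, groups)
            assert np.allclose(V, brute_force_cr1(X, u, groups), atol=1e-8)

    def test_singleton_clusters_reduce_to_heteroskedastic_form(self):
        X, y, _ = toy_problem(3, n=12, k=3)
        _, u = fit_ols(X, y)
        V = cluster_robust_vcov(X, u, np.arange(12))
        XtXi = np.linalg.inv(X.T @ X)
        hc = XtXi @ (X * u[:, None] ** 2).T @ X @ XtXi
        c = 12 / 11 * 11 / 9
        assert np.allclose(V, c * hc, atol=1e-10)

    def test_matches_statsmodels_clustered_covariance(self):
        import statsmodels.api as sm

        X, y, groups = toy_problem(7, n=60, k=5, n_groups=9)
        beta, u = fit_ols(X, y)
        V = cluster_robust_vcov(X, u, groups)
        res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": groups}, use_t=True)
        assert np.allclose(beta, res.params, atol=1e-10)
        assert np.allclose(np.sqrt(np.diag(V)), res.bse, atol=1e-10)

    def test_requires_two_clusters_and_full_coverage(self):
        X, y, _ = toy_problem(0)
        _, u = fit_ols(X, y)
        with pytest.raises(DesignError):
            cluster_robust_vcov(X, u, np.zeros(len(X)))
        with pytest.raises(DesignError):
            cluster_robust_vcov(X, u, np.zeros(len(X) - 1))


def make_fit(estimate, se, G=36):
    params = pd.Series({"const": 0.0, "x": estimate})
    V = pd.DataFrame(np.diag([0.0, se**2]), index=params.index, columns=params.index)
    return RegressionFit("go_nogo_speed", params, V, G=G, N=382, k=2)


class TestInference:
    def test_interval_width_from_t35(self):
        fit = make_fit(-0.023, 0.0097)
        ci = confidence_intervals(fit)
        half = stats.t.ppf(0.975, 35) * 0.0097
        assert ci.loc["x", "lower"] == pytest.approx(-0.023 - half)
        assert ci.loc["x", "upper"] == pytest.approx(-0.023 + half)
        assert (ci.loc["x", "lower"], ci.loc["x", "upper"]) == pytest.approx(
            (-0.043, -0.003), abs=5e-4
        )

    def test_zero_se_collapses_interval(self):
        fit = make_fit(1.5, 0.0)
        ci = fit.conf_int()
        assert ci.loc["x", "lower"] == ci.loc["x", "upper"] == 1.5

    def test_zero_estimate_gives_p_one(self):
        fit = make_fit(0.0, 0.2)
        assert fit.pvalues["x"] == pytest.approx(1.0)

    def test_scale_equivariance(self, fixture_cohort):
        """Multiplying the response rescales estimates and SEs alike."""
        fit1 = fit_outcome(fixture_cohort, DesignMatrixSpec("groton_maze_errors"))
        df = fixture_cohort.data.copy()
        df["groton_maze_errors_followup"] *= 10
        from exposuremc.cohort import CohortTable

        scaled = CohortTable(df, provenance="fixture", transformed=True)
        fit10 = fit_outcome(scaled, DesignMatrixSpec("groton_maze_errors"))
        assert fit10.params["exposure_low"] == pytest.approx(10 * fit1.params["exposure_low"])
        assert fit10.bse["exposure_low"] == pytest.approx(10 * fit1.bse["exposure_low"])
        assert fit10.pvalues["exposure_low"] == pytest.approx(fit1.pvalues["exposure_low"])


class TestEndToEnd:
    def test_fit_outcome_matches_statsmodels_everywhere(self, target_config):
        import statsmodels.api as sm

        table = generate_cohort(target_config, seed=12)
        fit = fit_outcome(table, DesignMatrixSpec("stroop_ab_ratio"))
        X, y, clusters, _ = build_design(table, DesignMatrixSpec("stroop_ab_ratio"))
        res = sm.OLS(np.asarray(y), X.to_numpy()).fit(
            cov_type="cluster", cov_kwds={"groups": clusters}, use_t=True
        )
        assert np.allclose(fit.params, res.params, atol=1e-10)
        assert np.allclose(fit.bse, res.bse, atol=1e-10)
        assert np.allclose(fit.conf_int().to_numpy(), res.conf_int(), atol=1e-8)
        assert np.allclose(fit.pvalues, res.pvalues, atol=1e-10)

    def test_report_shape_and_flags(self, fixture_cohort):
        report = table3_report(fixture_cohort, outcomes=["go_nogo_speed", "stroop_ab_ratio"])
        assert len(report) == 4
        assert set(report["group"]) == {"low", "higher"}
        assert report["significant"].dtype == bool
        assert (report["ci_lower"] <= report["estimate"]).all()
        assert (report["estimate"] <= report["ci_upper"]).all()
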