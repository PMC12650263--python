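import itertools
import math

import numpy as np
import pandas as pd
import pytest
from create_lab.errors import ValidationError
from create_lab.stats_validation import (
    durbin_watson,
    filter_outliers,
    mann_whitney,
    ols_fit,
    permutation_correlation_matrix,
    spearman_rho,
)


class TestFilterOutliers:
    def test_constant_column_keeps_all(self):
        df = pd.DataFrame({"x": [5.0] * 6, "y": [1, 2, 3, 4, 5, 6]})
        filtered, report = filter_outliers(df)
        assert len(filtered) == 6
        assert report.excluded == {}

    def test_single_extreme_value_excluded(self):
        # mean 10, sample SD ~31.6 -> upper bound ~73.2; 100 is outside
        df = pd.DataFrame({"x": [0.0] * 9 + [100.0]})
        filtered, report = filter_outliers(df)
        assert len(filtered) == 9
        assert list(report.excluded.values()) == [["x"]]

    def test_small_range_column_keeps_all(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        filtered, report = filter_outliers(df)
        assert len(filtered) == 5
        lo, hi = report.bounds["x"]
        assert lo == pytest.approx(3 - 2 * np.std([1, 2, 3, 4, 5], ddof=1))
        assert hi == pytest.approx(3 + 2 * np.std([1, 2, 3, 4, 5], ddof=1))

    def test_listwise_exclusion_reports_offenders(self):
        df = pd.DataFrame(
            {"x": [0.0] * 9 + [100.0], "y": [100.0] + [0.0] * 9},
            index=[f"p{i}" for i in range(10)],
        )
        filtered, report = filter_outliers(df)
        assert set(report.excluded) == {"p0", "p9"}
        assert report.excluded["p9"] == ["x"]
        assert report.excluded["p0"] == ["y"]

    def test_idempotent_on_own_output_at_fixed_bounds(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=30), "y": rng.normal(size=30)})
        filtered, report = filter_outliers(df)
        # applying the same bounds again removes nobody
        for col, (lo, hi) in report.bounds.items():
            assert ((filtered[col] >= lo) & (filtered[col] <= hi)).all()

    def test_missing_cells_never_exclude(self):
        df = pd.DataFrame({"x": [1.0, 2.0, np.nan, 3.0]})
        filtered, _ = filter_outliers(df)
        assert len(filtered) == 4

    def test_preconditions(self):
        df = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            filter_outliers(df)
        with pytest.raises(ValidationError):
            filter_outliers(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), k=0)


class TestSpearman:
    def test_monotone_identity(self):
        assert spearman_rho([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_reversal(self):
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_midranks_hand_case(self):
        # ranks x: [1, 2.5, 2.5, 4], y: [1, 3, 2, 4] -> Pearson 0.94868
        assert spearman_rho([1, 2, 2, 4], [1, 3, 2, 4]) == pytest.approx(0.9487, abs=1e-4)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        from scipy.stats import spearmanr

        for _ in range(20):
            x = rng.integers(0, 10, size=15).astype(float)
            y = rng.normal(size=15)
            assert spearman_rho(x, y) == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_input_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))


def enumerate_permutation_p(x, y):
    """Exact empirical p by enumerating all |y|! label permutations."""
    obs = spearman_rho(x, y)
    hits = total = 0
    for perm in itertools.permutations(y):
        rho = spearman_rho(x, list(perm))
        total += 1
        if abs(rho) >= abs(obs) - 1e-12:
            hits += 1
    return hits / total


class TestPermutationMatrix:
    def test_exact_enumeration_small_n(self):
        x, y = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0]
        p_exact = enumerate_permutation_p(x, y)
        assert p_exact == pytest.approx(2 / 6)
        df = pd.DataFrame({"x": x, "y": y})
        res = permutation_correlation_matrix(df, n_perm=2000, seed=0)
        se = math.sqrt(p_exact * (1 - p_exact) / 2000)
        assert abs(res.p_empirical.loc["x", "y"] - p_exact) <= 3 * se

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        r1 = permutation_correlation_matrix(df, n_perm=500, seed=9)
        r2 = permutation_correlation_matrix(df, n_perm=500, seed=9)
        pd.testing.assert_frame_equal(r1.p_empirical, r2.p_empirical)
        pd.testing.assert_frame_equal(r1.rho, r2.rho)

    def test_matrix_structure(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        res = permutation_correlation_matrix(df, n_perm=300, seed=1)
        assert np.allclose(np.diag(res.rho), 1.0)
        assert np.allclose(res.rho, res.rho.T)
        assert np.allclose(res.p_empirical, res.p_empirical.T)
        offdiag = res.p_empirical.to_numpy()[~np.eye(4, dtype=bool)]
        assert ((offdiag >= 0) & (offdiag <= 1)).all()
        assert ((res.p_empirical < res.alpha) == res.mask).to_numpy()[~np.eye(4, dtype=bool)].all()

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        y = 0.6 * x + rng.normal(size=25) * 0.8
        df1 = pd.DataFrame({"x": x, "y": y})
        df2 = pd.DataFrame({"x": np.exp(x), "y": y**3})
        r1 = permutation_correlation_matrix(df1, n_perm=500, seed=5)
        r2 = permutation_correlation_matrix(df2, n_perm=500, seed=5)
        assert r1.rho.loc["x", "y"] == pytest.approx(r2.rho.loc["x", "y"])
        assert r1.p_empirical.loc["x", "y"] == pytest.approx(r2.p_empirical.loc["x", "y"])

    def test_constant_column_missing_not_significant(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning):
            res = permutation_correlation_matrix(df, n_perm=100, seed=0)
        assert math.isnan(res.rho.loc["x", "y"])
        assert not res.mask.loc["x", "y"]

    def test_pairwise_complete_missing_handling(self):
        df = pd.DataFrame(
            {
                "x": [1.0, 2.0, 3.0, 4.0, 5.0, np.nan],
                "y": [1.1, 2.2, 2.9, 4.4, 5.5, 6.0],
            }
        )
        res = permutation_correlation_matrix(df, n_perm=200, seed=0)
        assert res.n_pairs.loc["x", "y"] == 5
        assert np.isfinite(res.rho.loc["x", "y"])

    def test_too_few_complete_cases_is_missing(self):
        df = pd.DataFrame({"x": [1.0, 2.0, np.nan, np.nan], "y": [np.nan, 2.0, 3.0, 4.0]})
        res = permutation_correlation_matrix(df, n_perm=100, seed=0)
        assert math.isnan(res.rho.loc["x", "y"])

    def test_smoothing_option(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0)})
        res = permutation_correlation_matrix(df, n_perm=100, seed=0, smoothing=True)
        assert res.p_empirical.loc["x", "y"] >= 1 / 101


def brute_force_mw_p(a, b):
    """Two-sided exact p by enumerating all group assignments of the ranks."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    mu = n1 * len(b) / 2.0
    obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev = abs(obs_u - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_extreme_separation(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u_statistic == 0
        assert res.p_two_sided == pytest.approx(2 / 6)
        assert res.method == "exact"

    def test_balanced_ranks(self):
        res = mann_whitney([1, 4], [2, 3])
        assert res.u_statistic == 2
        assert res.p_two_sided == pytest.approx(1.0)

    def test_identical_samples_tie_corrected(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.method == "normal-approximation"
        assert res.p_two_sided == pytest.approx(1.0)

    def test_empty_group_errors(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])

    def test_exact_matches_brute_force_sweep(self):
        rng = np.random.default_rng(7)
        for n1 in range(1, 8):
            for n2 in range(1, 8):
                vals = rng.permutation(np.arange(n1 + n2, dtype=float) * 1.7 + 0.3)
                a, b = vals[:n1], vals[n1:]
                res = mann_whitney(a, b)
                assert res.method == "exact"
                assert res.p_two_sided == pytest.approx(brute_force_mw_p(a, b))

    def test_large_groups_use_approximation(self):
        rng = np.random.default_rng(8)
        res = mann_whitney(rng.normal(size=25), rng.normal(size=25))
        assert res.method == "normal-approximation"
        assert 0 < res.p_two_sided <= 1

    def test_u_within_range(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=6), rng.normal(size=5)
        res = mann_whitney(a, b)
        assert 0 <= res.u_statistic <= 30


class TestRegression:
    def test_perfect_line(self):
        rep = ols_fit([0, 1, 2, 3], [1, 3, 5, 7])
        assert rep.slope == pytest.approx(2.0)
        assert rep.intercept == pytest.approx(1.0)
        assert rep.r_squared == pytest.approx(1.0)
        assert np.allclose(rep.residuals, 0.0, atol=1e-12)

    def test_three_point_hand_case(self):
        # normal equations: slope 0.5, intercept 1/6, R^2 0.75
        # (n=4 needed for dof, so replicate the x=1 point symmetrically)
        import statsmodels.api as sm

        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 1.0])
        res = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.params[1] == pytest.approx(0.5, abs=1e-10)
        assert res.params[0] == pytest.approx(1 / 6, abs=1e-10)
        assert res.rsquared == pytest.approx(0.75, abs=1e-10)

    def test_durbin_watson_hand_case(self):
        assert durbin_watson([1, -1, 1, -1]) == pytest.approx(3.0)

    def test_r_squared_equals_squared_pearson(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            x = rng.normal(size=30)
            y = 0.5 * x + rng.normal(size=30)
            rep = ols_fit(x, y)
            r = np.corrcoef(x, y)[0, 1]
            assert rep.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_report_internal_consistency(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=40)
        y = 1.0 + 0.3 * x + rng.normal(size=40)
        rep = ols_fit(x, y)
        assert 0 <= rep.r_squared <= 1
        assert rep.adj_r_squared <= rep.r_squared
        assert rep.slope_ci[0] <= rep.slope <= rep.slope_ci[1]
        assert rep.intercept_ci[0] <= rep.intercept <= rep.intercept_ci[1]
        assert rep.condition_number > 0
        assert np.isfinite(rep.aic) and np.isfinite(rep.bic)
        assert np.isfinite(rep.omnibus) and 0 <= rep.prob_omnibus <= 1

    def test_constant_predictor_errors(self):
        with pytest.raises(ValidationError):
            ols_fit([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            ols_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
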