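import numpy as np
import pandas as pd
import pytest
import scipy.stats

from fearscr.errors import AnalysisError, DegenerateDataError
from fearscr.stats import (ChangeScoreAncova, baseline_difference, correlation,
                           group_by_time_interaction, paired_t,
                           practice_hours_total, practice_regression)


def rmancova_interaction_oracle(pre, post, group, covariates=None):
    """Brute-force two-occasion repeated measures ANCOVA interaction.

    Long-format cell-means linear model: subject dummies absorb the
    between-subject variation; time, group-by-time and covariate-by-time
    columns model the within part. The interaction F compares the full
    model against one without the group-by-time column, using the
    within-subject error.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    n = pre.size
    g = (np.asarray(group) == np.asarray(group)[0]).astype(float)
    covs = [] if covariates is None else [np.asarray(c, float) for c in covariates]

    y = np.concatenate([pre, post])
    time = np.concatenate([np.zeros(n), np.ones(n)])
    subj = np.vstack([np.eye(n), np.eye(n)])

    def ssr(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    base_cols = [subj, time[:, None]]
    for c in covs:
        base_cols.append((time * np.concatenate([c, c]))[:, None])
    gx = (time * np.concatenate([g, g]))[:, None]
    X_full = np.hstack(base_cols + [gx])
    X_red = np.hstack(base_cols)
    df_err = 2 * n - (n + 2 + len(covs))
    ss_effect = ssr(X_red) - ssr(X_full)
    f = ss_effect / (ssr(X_full) / df_err)
    p = float(scipy.stats.f.sf(f, 1, df_err))
    return f, p, df_err


def _records(pre, post, group, **covs):
    n = len(pre)
    ids = [f"s{i}" for i in range(n)]
    rows = []
    for visit, vals in (("pre", pre), ("post", post)):
        for i in range(n):
            rows.append({"subject_id": ids[i], "visit": visit, "group": group[i],
                         "y": vals[i], **{k: v[i] for k, v in covs.items()}})
    return pd.DataFrame(rows)


class TestGroupByTimeInteraction:
    def test_null_case_equal_group_means(self):
        pre = [1.0, 2.0, 3.0, 4.0] * 2
        post = [2.0, 1.0, 4.0, 3.0] * 2  # same change-score distribution
        group = ["A"] * 4 + ["B"] * 4
        res = group_by_time_interaction(_records(pre, post, group), "y")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0, abs=1e-12)

    def test_textbook_2x2_hand_anova(self):
        # change scores A: [1,2,3,4], B: [3,4,5,6]; hand one-way ANOVA on
        # differences: SSB = 8, SSW = 10 on 6 df -> F = 8 / (10/6) = 4.8
        pre = [0.0] * 8
        post = [1, 2, 3, 4, 3, 4, 5, 6]
        group = ["A"] * 4 + ["B"] * 4
        res = group_by_time_interaction(_records(pre, post, group), "y")
        assert res.statistic == pytest.approx(4.8)
        assert res.df == (1.0, 6.0)
        assert res.effect_size == pytest.approx(8 / 18)  # SSB/(SSB+SSW)

    def test_equals_bruteforce_rmancova_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(6, 15))
            group = rng.choice(["A", "B"], size=n)
            if len(set(group)) < 2 or min((group == g).sum() for g in "AB") < 2:
                continue
            pre = rng.normal(0, 1, n)
            post = pre + rng.normal(0.2, 1, n)
            age = rng.normal(40, 10, n)
            days = rng.normal(60, 8, n)
            rec = _records(pre, post, group, age=age, days=days)
            res = group_by_time_interaction(rec, "y", covariates=("age", "days"))
            f, p, df_err = rmancova_interaction_oracle(pre, post, group, [age, days])
            assert res.statistic == pytest.approx(f, rel=1e-8)
            assert res.pvalue == pytest.approx(p, rel=1e-8)
            assert res.df[1] == df_err

    def test_unpaired_subjects_dropped_with_warning(self):
        rec = _records([1, 2, 3, 4, 5, 6], [2, 3, 4, 5, 6, 9],
                       ["A", "A", "A", "B", "B", "B"])
        rec = rec.drop(rec[(rec.subject_id == "s0") & (rec.visit == "post")].index)
        with pytest.warns(UserWarning, match="s0"):
            res = group_by_time_interaction(rec, "y")
        assert res.n == 5

    def test_covariate_centering_does_not_change_f(self):
        rng = np.random.default_rng(3)
        n = 12
        group = ["A"] * 6 + ["B"] * 6
        pre = rng.normal(0, 1, n)
        post = pre + rng.normal(0, 1, n)
        age = rng.normal(40, 10, n)
        r1 = group_by_time_interaction(_records(pre, post, group, age=age), "y",
                                       covariates=("age",))
        r2 = group_by_time_interaction(
            _records(pre, post, group, age=age + 1000), "y", covariates=("age",))
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)

    def test_summary_mentions_multiplicity_caveat(self):
        model = ChangeScoreAncova([1, 2, 3, 4.5], ["A", "A", "B", "B"])
        text = model.fit().summary()
        assert "not corrected for multiple comparisons" in text
        assert "partial eta^2" in text


class TestPairedT:
    def test_hand_arithmetic(self):
        # differences [1,2,3]: mean 2, sd 1 -> t = 2*sqrt(3), df 2
        res = paired_t([0, 0, 0], [1, 2, 3])
        assert res.statistic == pytest.approx(2 * np.sqrt(3))
        assert res.df == (2.0,)

    def test_antisymmetric_differences(self):
        res = paired_t([0, 0, 0], [-1, 0, 1])
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_t([1, 2, 3], [1, 2, 3])


class TestBaselineDifference:
    def test_matches_hand_oneway_anova(self):
        # groups [1,2,3,4] and [6,7,8,9]: SSB = 50, SSW = 10 on 6 df -> F = 30
        df = pd.DataFrame({"group": ["A"] * 4 + ["B"] * 4,
                           "y": [1, 2, 3, 4, 6, 7, 8, 9]})
        res = baseline_difference(df, "y")
        assert res.statistic == pytest.approx(30.0)
        assert res.df == (1.0, 6.0)

    def test_collinear_covariate_raises(self):
        df = pd.DataFrame({"group": ["A"] * 3 + ["B"] * 3,
                           "y": [1.0, 2, 3, 4, 5, 6],
                           "z": [0.0, 0, 0, 1, 1, 1]})  # z == group indicator
        with pytest.raises(AnalysisError, match="rank"):
            baseline_difference(df, "y", covariates=("z",))


class TestCorrelation:
    def test_perfect_correlation(self):
        res = correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(1.0)
        assert res.pvalue == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_four_points(self):
        # x=[1,2,3,4], y=[1,3,2,4]: r = 4/5 = 0.8
        res = correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.statistic == pytest.approx(0.8)
        assert res.df == (2.0,)
        # p from t transform: t = 0.8*sqrt(2/0.36)
        t = 0.8 * np.sqrt(2 / (1 - 0.64))
        assert res.pvalue == pytest.approx(2 * scipy.stats.t.sf(t, 2))

    def test_partial_correlation_removes_confounder(self):
        rng = np.random.default_rng(11)
        rejected = 0
        for _ in range(200):
            z = rng.normal(0, 1, 40)
            x = z + rng.normal(0, 0.3, 40)  # x, y related only through z
            y = z + rng.normal(0, 1, 40)
            res = correlation(x, y, partial_covariates={"z": z})
            rejected += res.pvalue < 0.05
        assert rejected / 200 <= 0.10  # approx nominal alpha under the null

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateDataError):
            correlation([1, 1, 1], [1, 2, 3])


class TestPracticeRegression:
    def test_noise_free_standardized_recovery(self):
        hours = np.array([5.0, 10, 20, 30, 45])
        res = practice_regression(50 - 0.3 * hours, hours)
        assert res.statistic == pytest.approx(-1.0)  # perfectly linear, negative
        assert res.pvalue == pytest.approx(0.0, abs=1e-9)

    def test_three_collinear_points_hand_df(self):
        res = practice_regression([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.df == (1.0,)
        assert res.statistic == pytest.approx(1.0)

    def test_constant_predictor_raises(self):
        with pytest.raises(DegenerateDataError):
            practice_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_null_slope_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(5)
        rejected = 0
        for _ in range(400):
            hours = rng.uniform(5, 50, 20)
            post = rng.normal(30, 5, 20)  # independent of practice
            rejected += practice_regression(post, hours).pvalue < 0.05
        assert 0.02 <= rejected / 400 <= 0.09


class TestPracticeHoursTotal:
    def test_complete_week(self):
        assert practice_hours_total([30] * 7) == pytest.approx(3.5)

    def test_missing_log_imputed_with_individual_mean(self):
        assert practice_hours_total([30, 30, None], n_expected_logs=3) == pytest.approx(1.5)

    def test_all_missing_raises(self):
        with pytest.raises(AnalysisError, match="impute"):
            practice_hours_total([None, None])


class TestPValueUniformityUnderNull:
    """Kolmogorov-Smirnov checks (alpha = 0.01) on 1000 simulated nulls."""

    def test_paired_t_pvalues_uniform(self):
        rng = np.random.default_rng(21)
        ps = []
        for _ in range(1000):
            pre = rng.normal(0, 1, 15)
            post = pre + rng.normal(0, 1, 15)
            ps.append(paired_t(pre, post).pvalue)
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_correlation_pvalues_uniform(self):
        rng = np.random.default_rng(22)
        ps = [correlation(rng.normal(0, 1, 20), rng.normal(0, 1, 20)).pvalue
              for _ in range(1000)]
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_baseline_ancova_pvalues_uniform(self):
        rng = np.random.default_rng(23)
        ps = []
        for _ in range(1000):
            df = pd.DataFrame({"group": ["A"] * 10 + ["B"] * 10,
                               "y": rng.normal(0, 1, 20),
                               "age": rng.normal(40, 10, 20)})
            ps.append(baseline_difference(df, "y", covariates=("age",)).pvalue)
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_interaction_pvalues_uniform(self, null_interaction_pvalues):
        """Full generate->score->test path: p uniform under the null."""
        assert scipy.stats.kstest(null_interaction_pvalues, "uniform").pvalue > 0.01
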