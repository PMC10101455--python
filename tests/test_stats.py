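"""Cohort statistics: group tests, adjusted correlations, ROC/AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nmvol.errors import DegenerateDataError
from nmvol.phantom import CohortSpec, sample_cohort_table
from nmvol.stats import (
    ancova_group_effect,
    cohort_report,
    combine_markers,
    partial_correlation,
    roc_auc,
    shapiro_wilk,
    welch_t,
    welch_t_from_summary,
)


class TestWelch:
    def test_published_lc_summaries_reproduce_printed_t(self):
        # control 8.0 ± 0.6 (n=33) vs patients 5.2 ± 0.6 (n=39)
        res = welch_t_from_summary(8.0, 0.6, 33, 5.2, 0.6, 39)
        assert res.statistic == pytest.approx(3.306, rel=0.005)
        assert res.p_value < 0.01

    def test_identical_groups_give_t_zero_p_one(self):
        res = welch_t([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_closed_form_and_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(4, 30))
            b = rng.normal(0.3, 2, rng.integers(4, 30))
            res = welch_t(a, b)
            va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
            t_direct = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df_direct = (va + vb) ** 2 / (
                va**2 / (a.size - 1) + vb**2 / (b.size - 1)
            )
            assert res.statistic == pytest.approx(t_direct, abs=1e-10)
            assert res.df == pytest.approx(df_direct, abs=1e-10)
            scipy_res = sps.ttest_ind(a, b, equal_var=False)
            assert res.statistic == pytest.approx(scipy_res.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(scipy_res.pvalue, abs=1e-10)

    def test_rescaling_volumes_leaves_t_invariant(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(429, 100, 33), rng.normal(329, 100, 39)
        t_mm3 = welch_t(a, b).statistic
        t_cm3 = welch_t(a / 1000.0, b / 1000.0).statistic
        assert t_mm3 == pytest.approx(t_cm3, abs=1e-9)

    def test_invalid_summaries_rejected(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(1.0, 0.0, 10, 2.0, 0.5, 10)
        with pytest.raises(ValueError):
            welch_t([1.0], [2.0, 3.0])


class TestShapiroWilk:
    def test_normal_samples_rarely_rejected(self):
        rng = np.random.default_rng(2)
        rejections = sum(
            shapiro_wilk(rng.normal(size=200))[1] < 0.05 for _ in range(100)
        )
        assert rejections <= 10

    def test_skewed_samples_usually_rejected(self):
        rng = np.random.default_rng(3)
        rejections = sum(
            shapiro_wilk(rng.exponential(size=200))[1] < 0.05 for _ in range(100)
        )
        assert rejections >= 95

    def test_degenerate_and_short_samples_rejected(self):
        with pytest.raises(DegenerateDataError):
            shapiro_wilk([4.0, 4.0, 4.0, 4.0])
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestAncova:
    @staticmethod
    def _records(rng, n=40, effect=50.0):
        group = np.repeat(["control", "pd"], n // 2)
        age = rng.normal(64, 9, n)
        education = rng.normal(17, 3, n)
        outcome = (
            400.0
            - effect * (group == "pd")
            - 1.2 * (age - 64)
            + rng.normal(0, 40, n)
        )
        return pd.DataFrame(
            {"group": group, "age": age, "education": education, "snc_volume": outcome}
        )

    def test_no_covariates_reduces_to_anova_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        records = self._records(rng)
        res = ancova_group_effect(records, "snc_volume", covariates=[])
        a = records.loc[records["group"] == "control", "snc_volume"]
        b = records.loc[records["group"] == "pd", "snc_volume"]
        t_pooled = sps.ttest_ind(a, b, equal_var=True).statistic
        assert res.statistic == pytest.approx(t_pooled**2, abs=1e-8)

    def test_matches_normal_equations_brute_force(self):
        rng = np.random.default_rng(5)
        records = self._records(rng, n=12)
        res = ancova_group_effect(records, "snc_volume", ["age", "education"])
        # explicit least-squares oracle
        X = np.column_stack(
            [
                np.ones(12),
                (records["group"] == "pd").astype(float),
                records["age"],
                records["education"],
            ]
        )
        y = records["snc_volume"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (12 - 4)
        se_group = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        f_oracle = (beta[1] / se_group) ** 2
        assert res.statistic == pytest.approx(f_oracle, abs=1e-8)
        assert res.df == (1.0, 8.0)

    def test_reports_covariate_p_values(self):
        rng = np.random.default_rng(6)
        res = ancova_group_effect(
            self._records(rng, n=60), "snc_volume", ["age", "education"]
        )
        assert set(res.covariate_p_values) == {"age", "education"}
        assert all(0 <= p <= 1 for p in res.covariate_p_values.values())

    def test_duplicated_group_indicator_is_rank_deficient(self):
        rng = np.random.default_rng(7)
        records = self._records(rng)
        records["dup"] = (records["group"] == "pd").astype(float)
        with pytest.raises(np.linalg.LinAlgError):
            ancova_group_effect(records, "snc_volume", ["dup"])

    def test_f_invariant_under_volume_rescaling(self):
        rng = np.random.default_rng(8)
        records = self._records(rng)
        f_mm3 = ancova_group_effect(records, "snc_volume", ["age"]).statistic
        records["snc_volume"] /= 1000.0
        f_cm3 = ancova_group_effect(records, "snc_volume", ["age"]).statistic
        assert f_mm3 == pytest.approx(f_cm3, abs=1e-9)


class TestPartialCorrelation:
    def test_identical_variables_fully_correlated(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        res = partial_correlation(x, x, z)
        assert res.r == pytest.approx(1.0)

    def test_covariate_determined_variables_degenerate(self):
        age = np.linspace(50, 80, 20)
        with pytest.raises(DegenerateDataError):
            partial_correlation(2 * age + 1, -3 * age, age)

    def test_recovers_population_partial_correlation(self):
        rng = np.random.default_rng(10)
        n = 5000
        z = rng.normal(size=n)
        rho = 0.3
        e1 = rng.normal(size=n)
        e2 = rho * e1 + np.sqrt(1 - rho**2) * rng.normal(size=n)
        x = 0.8 * z + e1
        y = -0.5 * z + e2
        res = partial_correlation(x, y, z)
        assert res.r == pytest.approx(rho, abs=0.04)

    def test_matches_independent_partial_corr_routine(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(60, 3)), columns=["x", "y", "age"])
        res = partial_correlation(df["x"], df["y"], df["age"])
        oracle = pingouin.partial_corr(df, x="x", y="y", covar="age")
        assert res.r == pytest.approx(float(oracle["r"].iloc[0]), abs=1e-8)
        assert res.p_value == pytest.approx(float(oracle["p_val"].iloc[0]), abs=1e-8)


class TestRoc:
    def test_perfect_separation_gives_unit_auc(self):
        scores = [400, 410, 420, 300, 310, 320]
        labels = ["control"] * 3 + ["pd"] * 3
        res = roc_auc(scores, labels, positive_label="pd")
        assert res.auc == 1.0
        assert res.ci95[1] <= 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=2000)
        labels = np.where(rng.random(2000) < 0.5, "pd", "control")
        res = roc_auc(scores, labels, positive_label="pd")
        assert res.auc == pytest.approx(0.5, abs=0.05)
        assert res.p_value > 0.05

    @settings(derandomize=True, max_examples=60)
    @given(
        pos=st.lists(st.integers(0, 8), min_size=1, max_size=8),
        neg=st.lists(st.integers(0, 8), min_size=1, max_size=8),
    )
    def test_auc_equals_mann_whitney_pair_count(self, pos, neg):
        scores = list(pos) + list(neg)
        labels = ["pd"] * len(pos) + ["control"] * len(neg)
        res = roc_auc(scores, labels, positive_label="pd",
                      positive_direction="higher")
        concordant = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        )
        assert res.auc == pytest.approx(concordant / (len(pos) * len(neg)), abs=1e-12)

    def test_lower_orientation_flips_auc(self):
        scores = [1, 2, 3, 4, 5, 6]
        labels = ["pd"] * 3 + ["control"] * 3
        low = roc_auc(scores, labels, "pd", positive_direction="lower")
        high = roc_auc(scores, labels, "pd", positive_direction="higher")
        assert low.auc == pytest.approx(1.0 - high.auc, abs=1e-12)

    def test_delong_se_available_and_comparable(self):
        rng = np.random.default_rng(13)
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(1, 1, 40)])
        labels = np.array(["control"] * 40 + ["pd"] * 40)
        hm = roc_auc(scores, labels, "pd", "higher", se_method="hanley-mcneil")
        dl = roc_auc(scores, labels, "pd", "higher", se_method="delong")
        assert hm.auc == dl.auc
        assert dl.se == pytest.approx(hm.se, rel=0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], ["pd", "pd", "pd"], "pd")


class TestCombineMarkers:
    @staticmethod
    def _cohort(rng, n=200, delta=(1.0, 0.5), rho=0.3):
        cov = np.array([[1, rho], [rho, 1]])
        controls = rng.multivariate_normal([0, 0], cov, n)
        patients = rng.multivariate_normal(list(delta), cov, n)
        return pd.DataFrame(
            {
                "group": ["control"] * n + ["pd"] * n,
                "snc_volume": np.r_[controls[:, 0], patients[:, 0]],
                "lc_volume": np.r_[controls[:, 1], patients[:, 1]],
            }
        )

    def test_constant_marker_equals_single_marker_auc(self):
        rng = np.random.default_rng(14)
        records = self._cohort(rng, n=60)
        records["lc_volume"] = 5.0
        _, combined = combine_markers(records)
        single = roc_auc(
            records["snc_volume"], records["group"], "pd", "higher"
        )
        assert combined.auc == pytest.approx(single.auc, abs=1e-6)

    def test_matches_analytic_binormal_auc(self):
        rng = np.random.default_rng(15)
        delta, rho = np.array([1.0, 0.5]), 0.3
        records = self._cohort(rng, n=5000, delta=tuple(delta), rho=rho)
        _, combined = combine_markers(records)
        cov = np.array([[1, rho], [rho, 1]])
        mahalanobis = np.sqrt(delta @ np.linalg.solve(cov, delta))
        analytic = sps.norm.cdf(mahalanobis / np.sqrt(2))
        assert combined.auc == pytest.approx(analytic, abs=0.01)

    def test_combined_at_least_best_single_in_sample(self):
        table = sample_cohort_table(CohortSpec(seed=16))
        records = table.rename(
            columns={"snc_volume_true": "snc_volume", "lc_volume_true": "lc_volume"}
        )
        _, combined = combine_markers(records)
        singles = [
            roc_auc(records[m], records["group"], "pd", "lower").auc
            for m in ("snc_volume", "lc_volume")
        ]
        assert combined.auc >= max(singles) - 0.02

    def test_perfect_separation_warns_and_still_ranks(self):
        records = pd.DataFrame(
            {
                "group": ["control"] * 5 + ["pd"] * 5,
                "snc_volume": [10, 11, 12, 13, 14, 1, 2, 3, 4, 5],
                "lc_volume": [5, 5, 5, 6, 6, 1, 1, 2, 2, 2],
            }
        )
        with pytest.warns(UserWarning, match="separation"):
            _, combined = combine_markers(records)
        assert combined.auc == 1.0


class TestCohortReport:
    def test_report_contains_all_blocks(self):
        table = sample_cohort_table(CohortSpec(seed=17))
        records = table.rename(
            columns={"snc_volume_true": "snc_volume", "lc_volume_true": "lc_volume"}
        )
        report = cohort_report(records)
        assert {"normality", "group_comparisons", "correlations_pd_group", "roc"} <= set(
            report
        )
        assert {"SNc", "LC", "combined"} <= set(report["roc"])
        assert "welch" in report["group_comparisons"]["SNc"]
        assert "ancova" in report["group_comparisons"]["LC"]

    def test_single_group_skips_comparisons_with_notice(self):
        table = sample_cohort_table(CohortSpec(n_pd=0, seed=18))
        records = table.rename(
            columns={"snc_volume_true": "snc_volume", "lc_volume_true": "lc_volume"}
        )
        report = cohort_report(records)
        assert "group_comparisons" not in report
        assert report["notices"]

    def test_identical_group_volumes_give_t_zero(self):
        records = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(8)],
                "group": ["control"] * 4 + ["pd"] * 4,
                "age": np.linspace(55, 75, 8),
                "snc_volume": [400.0] * 8,
                "lc_volume": [6.0] * 8,
            }
        )
        report = cohort_report(records, covariates=[])
        assert report["group_comparisons"]["SNc"]["welch"]["statistic"] == 0.0
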