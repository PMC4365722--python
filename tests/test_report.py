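"""Profile summaries and covariate-statistics tests."""

import numpy as np
import pandas as pd
import pytest

from cogtypology.cohort import CompoundMatrix, compound_scores, standardize_and_orient
from cogtypology.report import (anova_oneway, chi_square_education, covariate_tests,
                                pairwise_posthoc, summarize_profiles)
from cogtypology.simulate import default_spec

from conftest import anova_oracle, chi_square_oracle


class TestSummarizeProfiles:
    def test_single_member_community_collapses_summary(self):
        cm = CompoundMatrix(ids=["a", "b"], scores=np.vstack([np.arange(8.0),
                                                              np.arange(8.0) + 1]))
        summaries = summarize_profiles(cm, [0, 1], age_groups=["young", "old"])
        solo = summaries[0].stats
        assert (solo["min"] == solo["max"]).all()
        assert (solo["q1"] == solo["median"]).all()

    def test_median_of_symmetric_triplet_is_zero(self):
        Z = np.zeros((3, 8))
        Z[:, 0] = [-1.0, 0.0, 1.0]
        Z[:, 1:] = np.random.default_rng(0).normal(size=(3, 7))
        cm = CompoundMatrix(ids=["a", "b", "c"], scores=Z)
        s = summarize_profiles(cm, [0, 0, 0])[0]
        assert s.stats.loc["phonemic_fluency", "median"] == pytest.approx(0.0)

    def test_scores_sorted_by_median(self, default_cohort):
        table, labels = default_cohort
        cm = standardize_and_orient(compound_scores(table))
        codes = pd.Categorical(labels).codes
        for s in summarize_profiles(cm, codes, table.data["age_group"]):
            assert s.stats["median"].is_monotonic_increasing

    def test_community_sizes_conserved_and_medians_near_planted(self, default_cohort):
        table, labels = default_cohort
        spec = default_spec(seed=0)
        cm = standardize_and_orient(compound_scores(table))
        codes = pd.Categorical(labels).codes
        summaries = summarize_profiles(cm, codes, table.data["age_group"])
        assert sum(s.size for s in summaries) == 155
        order = {i: lab for i, lab in enumerate(pd.Categorical(labels).categories)}
        profiles = {p.label: np.array(p.mean_profile) for p in spec.profiles}
        # planted means live in anchor-population z-units; the pipeline
        # standardizes over the realized mixture, so transform the planted
        # profiles with the mixture's per-score mean and sd before comparing
        M = np.array([p.mean_profile for p in spec.profiles])
        w = np.array([p.n_members for p in spec.profiles], float)
        w /= w.sum()
        mix_mean = w @ M
        mix_sd = np.sqrt(w @ (M - mix_mean) ** 2 + spec.profiles[0].within_sd ** 2)
        for s in summaries:
            expected = (profiles[order[s.community]] - mix_mean) / mix_sd
            med = s.stats["median"].reindex(list(cm.score_names)).to_numpy()
            # ~3x the standard error of a sample median of the compressed
            # within-group noise (sd ~0.5 cohort-z units)
            tol = 3 * 1.253 * 0.5 / np.sqrt(s.size)
            assert np.max(np.abs(med - expected)) < tol, order[s.community]


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        f, df_b, df_w, p = anova_oneway([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_worked_two_group_example(self):
        f, df_b, df_w, _ = anova_oneway([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert f == pytest.approx(13.5)
        assert (df_b, df_w) == (1, 4)

    def test_six_groups_of_155_has_df_5_149(self, default_cohort):
        table, labels = default_cohort
        f, df_b, df_w, p = anova_oneway(table.data["mmse"].to_numpy(), labels.to_numpy())
        assert (df_b, df_w) == (5, 149)
        assert f > 0

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            k = int(rng.integers(2, 6))
            sizes = rng.integers(2, 9, size=k)
            groups = [rng.normal(rng.normal(0, 2), 1, size=s) for s in sizes]
            labels = np.concatenate([[i] * s for i, s in enumerate(sizes)])
            f, df_b, df_w, _ = anova_oneway(np.concatenate(groups), labels)
            f_ref, db_ref, dw_ref = anova_oracle(groups)
            assert f == pytest.approx(f_ref, abs=1e-9)
            assert (df_b, df_w) == (db_ref, dw_ref)

    def test_degenerate_constant_data_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            anova_oneway([2.0, 2.0, 2.0, 2.0], ["a", "a", "b", "b"])


class TestPosthoc:
    def test_identical_groups_not_significant_with_zero_sign(self):
        table = pairwise_posthoc([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert (table["sign"] == 0).all()
        np.testing.assert_allclose(table["p_adj"], 1.0)

    def test_large_shift_detected_with_positive_sign(self):
        rng = np.random.default_rng(2)
        a = 0.1 * rng.normal(size=10)
        b = 4 + 0.1 * rng.normal(size=10)
        table = pairwise_posthoc(np.r_[b, a], ["hi"] * 10 + ["lo"] * 10)
        row = table.iloc[0]
        assert row["row"] == "hi" and row["col"] == "lo"
        assert row["sign"] == 1
        assert row["p_adj"] < 0.001

    def test_one_shifted_group_yields_two_significant_pairs(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.5, 12)
        b = rng.normal(0, 0.5, 12)
        c = rng.normal(4, 0.5, 12)
        values = np.r_[a, b, c]
        labels = ["a"] * 12 + ["b"] * 12 + ["c"] * 12
        table = pairwise_posthoc(values, labels)
        sig = table[table["p_adj"] < 0.05]
        assert set(map(tuple, sig[["row", "col"]].to_numpy())) == {("a", "c"), ("b", "c")}

    def test_tukey_variant_agrees_on_obvious_case(self):
        rng = np.random.default_rng(4)
        values = np.r_[rng.normal(0, 0.3, 10), rng.normal(5, 0.3, 10)]
        labels = ["a"] * 10 + ["b"] * 10
        table = pairwise_posthoc(values, labels, method="tukey")
        assert table.iloc[0]["p_adj"] < 0.001 and table.iloc[0]["sign"] == -1


class TestChiSquare:
    def test_perfect_association(self):
        x2, df, p, low = chi_square_education(np.array([[10, 0], [0, 10]]))
        assert x2 == pytest.approx(20.0)
        assert df == 1
        assert not low  # expected counts are exactly 5, not below

    def test_proportional_rows_independent(self):
        x2, _, p, _ = chi_square_education(np.array([[4, 6], [2, 3]]))
        assert x2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_zero_column_dropped_reducing_df(self):
        x2_full, df_full, _, _ = chi_square_education(
            np.array([[5, 0, 5, 5], [5, 0, 5, 5]]))
        assert df_full == 2  # level 2 unused by both groups

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            table = rng.integers(1, 20, size=(2, int(rng.integers(2, 5))))
            x2, df, _, _ = chi_square_education(table)
            x2_ref, df_ref = chi_square_oracle(table)
            assert x2 == pytest.approx(x2_ref, abs=1e-10)
            assert df == df_ref

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError):
            chi_square_education(np.array([[0, 0], [3, 4]]))


class TestCovariateTests:
    def test_full_report_on_default_cohort(self, default_cohort):
        table, labels = default_cohort
        codes = pd.Categorical(labels).codes
        out = covariate_tests(table.data, codes)
        assert set(out["anova"]) == {"mmse", "hads_anxiety", "hads_depression",
                                     "iq_crystallized", "iq_fluid", "digit_symbol"}
        for cov, res in out["anova"].items():
            assert res["df"] == [5, 149]
            assert len(res["pairwise"]) == 15  # 6 choose 2
        assert len(out["education_chi_square"]) == 15
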