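import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tiltlab import FitResult, ValidationError
from tiltlab.staircase import SURROUNDS
from tiltlab.stats import (
    ABS_SURROUNDS,
    anova_table,
    attraction_tests,
    bias_threshold_correlations,
    bonferroni_alpha,
    condition_contrasts,
    one_sample_t,
    paired_t,
    pearson_r,
    qc_measurement,
    rm_anova_gg,
    summarize_condition,
)

from conftest import make_summary_table


def make_fits(mus=None, sigmas=None, lapses=None):
    mus = mus or {s: 0.0 for s in SURROUNDS}
    sigmas = sigmas or {s: 2.0 for s in SURROUNDS}
    lapses = lapses or {s: 0.05 for s in SURROUNDS}
    return [
        FitResult(
            mu_hat=mus[s], sigma_hat=sigmas[s], lapse_hat=lapses[s],
            mu_sd=0.3, sigma_sd=0.4, lapse_sd=0.02, n_trials=80, surround_deg=s,
        )
        for s in SURROUNDS
    ]


class TestSummarizeCondition:
    def test_antisymmetric_biases_give_halfdiff(self):
        fits = make_fits(mus={0: 0, 15: 2, -15: -2, 30: 0, -30: 0, 75: 0, -75: 0})
        summ = summarize_condition(fits).set_index("abs_surround")
        assert summ.loc[15, "bias"] == 2.0

    def test_common_offset_cancels(self):
        fits = make_fits(mus={0: 0, 15: 0, -15: 0, 30: 1, -30: 1, 75: 0, -75: 0})
        summ = summarize_condition(fits).set_index("abs_surround")
        assert summ.loc[30, "bias"] == 0.0

    def test_threshold_is_symmetric_mean(self):
        sig = {s: 2.0 for s in SURROUNDS}
        sig[75], sig[-75] = 2.0, 4.0
        summ = summarize_condition(make_fits(sigmas=sig)).set_index("abs_surround")
        assert summ.loc[75, "threshold"] == 3.0

    def test_zero_surround_uses_single_fit(self):
        fits = make_fits(mus={0: 0.7, 15: 0, -15: 0, 30: 0, -30: 0, 75: 0, -75: 0})
        summ = summarize_condition(fits).set_index("abs_surround")
        assert summ.loc[0, "bias"] == 0.7

    def test_lapse_summary_is_mean_log10(self):
        lap = {s: 0.05 for s in SURROUNDS}
        lap[15], lap[-15] = 0.01, 0.1
        summ = summarize_condition(make_fits(lapses=lap)).set_index("abs_surround")
        assert summ.loc[15, "log10_lapse"] == pytest.approx((-2 + -1) / 2)

    def test_four_levels_and_missing_surround_rejected(self):
        summ = summarize_condition(make_fits())
        assert list(summ["abs_surround"]) == list(ABS_SURROUNDS)
        with pytest.raises(ValidationError):
            summarize_condition(make_fits()[:6])


class TestRmAnova:
    def test_df_identities_at_study_size(self):
        rng = np.random.default_rng(0)
        table = anova_table(make_summary_table(rng, n_subjects=26), "bias")
        res = {r.effect: r for r in rm_anova_gg(table)}
        assert (res["Condition"].df_num, res["Condition"].df_den) == (2, 50)
        assert (res["Orientation"].df_num, res["Orientation"].df_den) == (3, 75)
        inter = res["Condition x Orientation"]
        assert (inter.df_num, inter.df_den) == (6, 150)

    def test_epsilon_bounds(self, anova_fixture):
        for r in rm_anova_gg(anova_fixture):
            assert 1.0 / r.df_num <= r.ehat <= 1.0 + 1e-12

    def test_compound_symmetry_gives_epsilon_near_one(self):
        """With iid cell noise (sphericity holds) epsilon-hat approaches 1."""
        rng = np.random.default_rng(5)
        rows = [
            {
                "subject_id": f"S{i}",
                "condition": c,
                "orientation": o,
                "value": rng.normal(0, 1),
            }
            for i in range(40)
            for c in "abc"
            for o in (0, 15, 30, 75)
        ]
        for r in rm_anova_gg(pd.DataFrame(rows)):
            assert r.ehat > 0.9 - 0.1

    def test_grand_mean_invariance(self, anova_fixture):
        shifted = anova_fixture.assign(value=anova_fixture["value"] + 100.0)
        for a, b in zip(rm_anova_gg(anova_fixture), rm_anova_gg(shifted)):
            assert a.F == pytest.approx(b.F, abs=1e-8)
            assert a.ehat == pytest.approx(b.ehat, abs=1e-8)

    def test_unbalanced_table_rejected(self, anova_fixture):
        with pytest.raises(ValidationError):
            rm_anova_gg(anova_fixture.iloc[:-1])

    def test_too_few_subjects_rejected(self, anova_fixture):
        two = anova_fixture[anova_fixture["subject_id"].isin(["S0", "S1"])]
        with pytest.raises(ValidationError):
            rm_anova_gg(two)


class TestTTests:
    def test_paired_df_and_oracle(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 26), rng.normal(0.3, 1, 26)
        t, df, p = paired_t(x, y)
        assert df == 25
        ref = sps.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_samples_t_zero(self):
        x = np.arange(5.0)
        assert paired_t(x, x) == (0.0, 4, 1.0)

    def test_zero_variance_nonzero_difference_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ValidationError):
            paired_t(x, x + 1.0)

    def test_one_sample_oracle_and_shift_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(1, 2, 20)
        t, df, p = one_sample_t(x, 0.5)
        ref = sps.ttest_1samp(x, 0.5)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)
        t2, _, _ = one_sample_t(x - 0.5, 0.0)
        assert t == pytest.approx(t2, abs=1e-12)

    def test_one_sample_constant_zero(self):
        assert one_sample_t(np.zeros(6), 0.0) == (0.0, 5, 1.0)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x)
        assert r == 1.0 and p == 0.0

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 26), rng.normal(0, 1, 26)
        r, p = pearson_r(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_vector_undefined(self):
        r, p = pearson_r(np.ones(10), np.arange(10.0))
        assert np.isnan(r) and np.isnan(p)

    def test_null_distribution_at_n26(self):
        """Independent samples of size 26 leave |r| below 0.39 in >= 95%
        of draws (two-sided 5% critical value ~0.388)."""
        rng = np.random.default_rng(12)
        inside = 0
        for _ in range(1000):
            r, _ = pearson_r(rng.normal(size=26), rng.normal(size=26))
            inside += abs(r) < 0.39
        # exact null coverage of |r| < 0.39 at n=26 is 0.9513; allow 3
        # binomial SEs around it
        assert abs(inside / 1000 - 0.9513) <= 3 * np.sqrt(0.9513 * 0.0487 / 1000)


class TestBonferroni:
    def test_study_values(self):
        assert bonferroni_alpha(0.05, 4) == 0.0125
        assert round(bonferroni_alpha(0.05, 12), 4) == 0.0042
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(ValidationError):
            bonferroni_alpha(1.5, 4)


class TestBattery:
    def test_condition_contrasts_detect_injected_effect(self):
        summ = make_summary_table(np.random.default_rng(8), n_subjects=20, effect=1.5)
        res = condition_contrasts(summ, "bias").set_index("abs_surround")
        assert res.loc[15, "significant"] and res.loc[30, "significant"]
        assert not res.loc[0, "significant"] and not res.loc[75, "significant"]
        assert (res["alpha_bonferroni"] == 0.0125).all()
        assert (res["df"] == 19).all()

    def test_attraction_tests_negative_bias(self):
        summ = make_summary_table(np.random.default_rng(9), n_subjects=40)
        res = attraction_tests(summ)
        assert set(res["condition"]) == {"sober", "placebo", "alcohol"}
        assert (res["t"] < 0).all() and (res["p"] < 0.05).all()

    def test_correlation_family_of_twelve(self):
        summ = make_summary_table(np.random.default_rng(10), n_subjects=20)
        res = bias_threshold_correlations(summ)
        assert len(res) == 12
        assert res["alpha_bonferroni"].unique() == pytest.approx([0.05 / 12])
        for _, row in res.iterrows():
            cell = summ[
                (summ["condition"] == row["condition"])
                & (summ["abs_surround"] == row["abs_surround"])
            ]
            ref = sps.pearsonr(cell["bias"], cell["threshold"])
            assert row["r"] == pytest.approx(ref.statistic, abs=1e-10)


class TestQcRule:
    def test_four_of_seven_high_lapses_flagged(self):
        lapses = dict(zip(SURROUNDS, (0.25, 0.30, 0.22, 0.21, 0.05, 0.10, 0.02)))
        flagged, n_high = qc_measurement(make_fits(lapses=lapses))
        assert flagged and n_high == 4

    def test_all_low_passes(self):
        flagged, n_high = qc_measurement(make_fits())
        assert not flagged and n_high == 0

    def test_three_high_is_below_the_rule(self):
        lapses = dict(zip(SURROUNDS, (0.25, 0.30, 0.22, 0.05, 0.05, 0.10, 0.02)))
        flagged, n_high = qc_measurement(make_fits(lapses=lapses))
        assert not flagged and n_high == 3

    def test_wrong_count_rejected(self):
        with pytest.raises(ValidationError):
            qc_measurement(make_fits()[:5])
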