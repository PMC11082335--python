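"""Group statistics: t-tests, Fisher exact, age adjustment, bootstrap, ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest

from csfpulse.stats import (
    GroupComparison,
    SubjectRecord,
    anova_bonferroni,
    bootstrap_pairwise,
    fisher_exact_2x2,
    pearson_corr,
    residualize_age,
    two_sample_t,
)


def enumerate_fisher_p(table):
    """Brute-force two-sided Fisher p: sum the probabilities of all tables
    with the observed margins that are no more probable than the observed."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def hyper(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = hyper(a)
    return sum(
        hyper(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if hyper(x) <= p_obs * (1 + 1e-12)
    )


class TestTwoSampleT:
    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0]
        res = two_sample_t(x, x)
        assert res.p_value == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0)

    def test_symmetric_two_point_samples(self):
        res = two_sample_t([0.0, 1.0], [0.0, 1.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_mmse_summary_statistics_reproduce_printed_p(self):
        res = two_sample_t(
            summary_a=(26.1, 4.0, 16), summary_b=(21.7, 4.0, 19)
        )
        assert round(res.p_value, 3) == 0.003

    def test_raw_data_equals_its_own_summary_statistics(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(0, 1, 14), rng.normal(0.5, 1.2, 17)
        from_raw = two_sample_t(x, y)
        from_summary = two_sample_t(
            summary_a=(x.mean(), x.std(ddof=1), x.size),
            summary_b=(y.mean(), y.std(ddof=1), y.size),
        )
        assert from_raw.statistic == pytest.approx(from_summary.statistic)
        assert from_raw.p_value == pytest.approx(from_summary.p_value)

    def test_zero_variance_conventions(self):
        assert two_sample_t([5.0, 5.0], [5.0, 5.0]).p_value == 1.0
        assert two_sample_t([5.0, 5.0], [9.0, 9.0]).p_value == 0.0

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            two_sample_t([1.0], [2.0, 3.0])


class TestFisherExact:
    def test_study_gender_table_gives_p_one(self):
        # PDD-L 11M/5F vs PDD-H 13M/6F
        res = fisher_exact_2x2([[11, 5], [13, 6]])
        assert res.p_value == pytest.approx(1.0)

    def test_symmetric_table_gives_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [
            [[1, 0], [0, 1]],
            [[11, 5], [13, 6]],
            [[8, 2], [3, 9]],
            [[0, 7], [6, 1]],
            [[10, 10], [5, 15]],
        ],
    )
    def test_agrees_with_hypergeometric_enumeration(self, table):
        res = fisher_exact_2x2(table)
        assert res.p_value == pytest.approx(enumerate_fisher_p(table), abs=1e-10)

    def test_zero_margin_degenerates_to_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero margin"):
            res = fisher_exact_2x2([[0, 3], [0, 5]])
        assert res.p_value == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])


class TestAgeResidualization:
    def make_cohort(self, slope, noise_sd, n=52, seed=0):
        rng = np.random.default_rng(seed)
        age = rng.uniform(55, 85, n)
        measure = 3.0 + slope * age + rng.normal(0, noise_sd, n)
        return pd.DataFrame({"age": age, "measure": measure})

    def test_zero_slope_leaves_measure_unchanged(self):
        df = pd.DataFrame(
            {"age": [60.0, 70.0, 80.0], "measure": [5.0, 5.0, 5.0]}
        )
        adjusted = residualize_age(df, "measure")
        assert np.allclose(adjusted, df.measure)

    def test_perfect_age_dependence_collapses_to_grand_mean(self):
        df = pd.DataFrame({"age": [60.0, 70.0, 80.0, 75.0]})
        df["measure"] = 2.0 * df.age
        adjusted = residualize_age(df, "measure")
        assert np.allclose(adjusted, df.measure.mean())

    def test_pooled_mean_is_preserved_exactly(self):
        df = self.make_cohort(slope=0.5, noise_sd=2.0)
        adjusted = residualize_age(df, "measure")
        assert adjusted.mean() == pytest.approx(df.measure.mean(), abs=1e-10)

    def test_known_slope_recovered_within_two_se(self):
        slope, noise_sd = 0.5, 2.0
        df = self.make_cohort(slope, noise_sd, seed=21)
        age = df.age.to_numpy()
        fitted_slope = np.polyfit(age, df.measure.to_numpy(), 1)[0]
        se = noise_sd / (age.std() * np.sqrt(len(df)))
        assert abs(fitted_slope - slope) < 2 * se
        # after adjustment, no residual age correlation
        adjusted = residualize_age(df, "measure")
        r, _ = pearson_corr(age, adjusted.to_numpy())
        assert abs(r) < 1e-10

    def test_constant_age_warns_and_returns_identity(self):
        df = pd.DataFrame({"age": [70.0] * 5, "measure": [1.0, 2, 3, 4, 5]})
        with pytest.warns(UserWarning, match="constant age"):
            adjusted = residualize_age(df, "measure")
        assert np.allclose(adjusted, df.measure)


class TestBootstrap:
    def test_identical_constant_samples(self):
        res = bootstrap_pairwise([2.0, 2.0, 2.0], [2.0, 2.0, 2.0], seed=1)
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)
        assert res.p_value == 1.0

    def test_separated_groups_exclude_zero(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 20)
        y = rng.normal(5, 1, 20)
        res = bootstrap_pairwise(x, y, B=2000, seed=3)
        assert res.ci_high < 0  # x - y is negative throughout
        assert res.p_value < 0.01

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 15), rng.normal(0.3, 1, 15)
        a = bootstrap_pairwise(x, y, B=1500, seed=77)
        b = bootstrap_pairwise(x, y, B=1500, seed=77)
        assert (a.ci_low, a.ci_high, a.p_value) == (b.ci_low, b.ci_high, b.p_value)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="B must be >= 1000"):
            bootstrap_pairwise([1.0, 2.0], [3.0, 4.0], B=10, seed=1)

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            bootstrap_pairwise([1.0, 2.0], [3.0, 4.0])


class TestAnovaBonferroni:
    def test_identical_groups_are_null(self):
        g = [1.0, 2.0, 3.0, 4.0]
        omnibus, pairwise = anova_bonferroni({"a": g, "b": g, "c": g})
        assert omnibus.statistic == pytest.approx(0.0)
        assert all(c.p_value == 1.0 for c in pairwise)

    def test_single_shifted_group_drives_the_signal(self):
        rng = np.random.default_rng(15)
        groups = {
            "a": rng.normal(0, 1, 10),
            "b": rng.normal(0, 1, 10),
            "c": rng.normal(10, 1, 10),
        }
        omnibus, pairwise = anova_bonferroni(groups)
        assert omnibus.p_value < 0.05
        by_pair = {(c.group_a, c.group_b): c.p_value for c in pairwise}
        assert by_pair[("a", "b")] > 0.05
        assert by_pair[("a", "c")] < 0.05
        assert by_pair[("b", "c")] < 0.05

    def test_bonferroni_never_lowers_a_p_value(self):
        rng = np.random.default_rng(16)
        groups = {k: rng.normal(i * 0.3, 1, 8) for i, k in enumerate("abc")}
        _, pairwise = anova_bonferroni(groups)
        for c in pairwise:
            raw = two_sample_t(groups[c.group_a], groups[c.group_b])
            assert c.p_value >= raw.p_value - 1e-15

    def test_two_groups_are_not_enough(self):
        with pytest.raises(ValueError, match=">= 3 groups"):
            anova_bonferroni({"a": [1.0, 2.0], "b": [3.0, 4.0]})


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_corr(x, x)[0] == pytest.approx(1.0)
        assert pearson_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_independent_normals_at_study_size_are_uncorrelated(self):
        rng = np.random.default_rng(31)
        ps = []
        for _ in range(40):
            r, p = pearson_corr(rng.normal(0, 1, 52), rng.normal(0, 1, 52))
            assert abs(r) < 0.6
            ps.append(p)
        # p roughly uniform: around half above 0.5, none systematically tiny
        assert 0.2 < np.mean(np.asarray(ps) > 0.5) < 0.8

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSubjectRecord:
    def test_unknown_group_label_rejected(self):
        with pytest.raises(ValueError, match="group"):
            SubjectRecord(subject_id="s1", group="XX", age=70.0, gender="F")

    def test_comparison_record_validates_probability(self):
        with pytest.raises(ValueError, match="outside"):
            GroupComparison(
                measure="m", group_a="a", group_b="b", statistic=0.0,
                p_value=1.5, method="t_test", n_a=2, n_b=2,
            )
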