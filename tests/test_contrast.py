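import math

import numpy as np
import pytest
from scipy import stats

import triogrs as tg
from triogrs.contrast import fisher_exact_2x2, odds_ratio_woolf
from triogrs.errors import ValidationError


def fisher_p_enumeration(a, b, c, d):
    """Oracle: exhaustive hypergeometric enumeration over fixed margins."""
    m, n, k = a + b, c + d, a + c
    denom = math.comb(m + n, k)
    def pmf(x):
        return math.comb(m, x) * math.comb(n, k - x) / denom
    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, k - n), min(m, k) + 1):
        px = pmf(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(1.0, total)


class TestMeanContrast:
    def test_identical_groups(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        res = tg.mean_contrast(v, v)
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_matches_textbook_pooled_t(self):
        m = np.array([2.0, 4.0, 6.0, 8.0])
        f = np.array([1.0, 3.0, 5.0, 7.0])
        res = tg.mean_contrast(m, f)
        # hand-computed pooled-variance t: s_p^2 = 20/3, t = 1 / sqrt(20/3 * 1/2)
        t_hand = 1.0 / math.sqrt((20 / 3) * 0.5)
        p_hand = 2 * stats.t.sf(t_hand, df=6)
        assert res.t_statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.p_value == pytest.approx(p_hand, rel=1e-12)
        assert res.degrees_of_freedom == 6
        assert res.transform_applied == "none"

    def test_log_transform_on_skewed_positive_data(self):
        rng = np.random.default_rng(1)
        m = np.exp(rng.normal(0, 1, 200))
        f = np.exp(rng.normal(0, 1, 200))
        res = tg.mean_contrast(m, f)
        assert res.transform_applied == "log"
        # after the transform the t-test runs on the logs
        expected = stats.ttest_ind(np.log(m), np.log(f), equal_var=True)
        assert res.p_value == pytest.approx(float(expected.pvalue))

    def test_transform_skipped_for_nonpositive_values(self):
        rng = np.random.default_rng(2)
        m = np.exp(rng.normal(0, 1, 100)) - 0.5  # skewed but crosses zero
        f = np.exp(rng.normal(0, 1, 100)) - 0.5
        res = tg.mean_contrast(m, f)
        assert res.transform_applied == "none"

    def test_short_vector_rejected(self):
        with pytest.raises(ValidationError):
            tg.mean_contrast([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            tg.mean_contrast([1.0, np.inf, 2.0], [1.0, 2.0, 3.0])


class TestPercentileThreshold:
    def test_nearest_rank_on_1_to_100(self):
        scores = np.arange(1.0, 101.0)
        assert tg.percentile_threshold(scores, 0.95) == 95.0
        assert tg.percentile_threshold(scores, 0.90) == 90.0
        assert tg.percentile_threshold(scores, 0.75) == 75.0

    def test_degenerate_distribution(self):
        scores = np.full(50, 5.0)
        cutoff = tg.percentile_threshold(scores, 0.95)
        assert cutoff == 5.0
        assert (scores > cutoff).sum() == 0

    def test_cutoff_is_an_observed_score(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=37)
        for q in (0.95, 0.9, 0.75, 0.5):
            assert tg.percentile_threshold(scores, q) in scores

    def test_empty_rejected_and_small_sample_warns(self):
        with pytest.raises(ValidationError):
            tg.percentile_threshold([], 0.95)
        with pytest.warns(UserWarning, match="unstable"):
            tg.percentile_threshold(np.arange(10.0), 0.95)

    @pytest.mark.parametrize("n", [100, 466, 721])
    def test_tail_count_near_nominal(self, n):
        rng = np.random.default_rng(n)
        scores = rng.normal(size=n)  # continuous, ties almost surely absent
        cutoff = tg.percentile_threshold(scores, 0.95)
        above = int((scores > cutoff).sum())
        assert abs(above - math.ceil(0.05 * n)) <= 1


class TestDichotomize:
    def test_known_table_or_and_enumerated_p(self):
        mothers = np.r_[np.full(10, 2.0), np.zeros(90)]
        fathers = np.r_[np.full(5, 2.0), np.zeros(95)]
        res = tg.dichotomize_and_test(mothers, fathers, cutoff=1.0)
        assert (res.a, res.b, res.c, res.d) == (10, 90, 5, 95)
        assert res.odds_ratio == pytest.approx(950 / 450)
        assert res.fisher_p == pytest.approx(fisher_p_enumeration(10, 90, 5, 95), abs=1e-12)

    def test_symmetric_table_is_null(self):
        mothers = np.r_[np.full(5, 2.0), np.zeros(95)]
        res = tg.dichotomize_and_test(mothers, mothers, cutoff=1.0)
        assert res.odds_ratio == 1.0 and res.fisher_p == 1.0

    def test_high_means_strictly_greater(self):
        mothers = np.array([1.0, 2.0, 3.0])
        fathers = np.array([1.0, 1.0, 4.0])
        res = tg.dichotomize_and_test(mothers, fathers, cutoff=1.0)
        assert res.a == 2 and res.c == 1  # scores equal to the cutoff are "low"

    def test_label_swap_inverts_odds_ratio(self):
        rng = np.random.default_rng(7)
        m = rng.normal(0.3, 1, 120)
        f = rng.normal(0.0, 1, 130)
        cutoff = tg.percentile_threshold(f, 0.75)
        fwd = tg.dichotomize_and_test(m, f, cutoff)
        rev = tg.dichotomize_and_test(f, m, cutoff)
        assert not fwd.corrected and not rev.corrected
        assert rev.odds_ratio == pytest.approx(1 / fwd.odds_ratio)
        assert rev.fisher_p == pytest.approx(fwd.fisher_p)

    def test_zero_cell_gets_haldane_correction(self):
        mothers = np.full(20, 2.0)  # every mother above the cutoff: b = 0
        fathers = np.r_[np.full(4, 2.0), np.zeros(16)]
        res = tg.dichotomize_and_test(mothers, fathers, cutoff=1.0)
        assert res.corrected
        assert res.ci_low <= res.odds_ratio <= res.ci_high
        expected_or = (20.5 * 16.5) / (0.5 * 4.5)
        assert res.odds_ratio == pytest.approx(expected_or)

    def test_ci_brackets_or_and_matches_woolf(self):
        or_, lo, hi, corrected = odds_ratio_woolf(10, 90, 5, 95)
        assert not corrected
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 5 + 1 / 95)
        z = stats.norm.ppf(0.975)
        assert lo == pytest.approx(or_ * math.exp(-z * se))
        assert hi == pytest.approx(or_ * math.exp(z * se))

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValidationError):
            odds_ratio_woolf(0, 0, 0, 0)


class TestContrastSuite:
    def test_row_cardinality(self, small_cohort):
        cfg, trios, dm, weights, _ = small_cohort
        grs = tg.compute_grs(dm, weights, tg.parent_roles(trios))
        suite = tg.run_contrast_suite(grs, trios, quantile_levels=(0.95, 0.90, 0.75))
        assert len(suite.thresholds) == 12  # 4 conditions x 3 levels
        assert len(suite.means) == 4
        assert set(suite.means["condition"]) == {"combined", "OBESITY", "HTN", "T2D"}

    def test_cutoffs_recomputed_within_subgroup(self, small_cohort):
        cfg, trios, dm, weights, _ = small_cohort
        grs = tg.compute_grs(dm, weights, tg.parent_roles(trios))
        full = tg.run_contrast_suite(grs, trios, quantile_levels=(0.75,))
        chop = tg.run_contrast_suite(grs, trios, tg.SubgroupSpec(cohort="CHOP"),
                                     quantile_levels=(0.75,))
        assert chop.n_trios < full.n_trios
        row_f = full.thresholds.query("condition == 'combined'")["cutoff"].iloc[0]
        row_c = chop.thresholds.query("condition == 'combined'")["cutoff"].iloc[0]
        assert row_f != row_c  # subgroup uses its own fathers' distribution

    def test_overt_phenotype_exclusion_drops_trios(self, small_cohort):
        cfg, trios, dm, weights, _ = small_cohort
        grs = tg.compute_grs(dm, weights, tg.parent_roles(trios))
        excl = tg.run_contrast_suite(grs, trios,
                                     tg.SubgroupSpec(exclude_overt_phenotype=True),
                                     quantile_levels=(0.75,))
        overt = ((trios["maternal_preeclampsia"] == "yes")
                 | (trios["maternal_htn_medication"] == "yes")
                 | (trios["maternal_pregestational_diabetes"] == "yes")).sum()
        assert excl.n_trios == len(trios) - overt

    def test_tiny_subgroup_rejected(self, small_cohort):
        cfg, trios, dm, weights, _ = small_cohort
        grs = tg.compute_grs(dm, weights, tg.parent_roles(trios))
        with pytest.raises(ValidationError, match="<10"):
            tg.run_contrast_suite(grs, trios, tg.SubgroupSpec(ctd_subtype="L-TGA"))
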