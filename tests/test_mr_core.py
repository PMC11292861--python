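"""MR estimators against closed forms, independent oracles and contracts."""

import numpy as np
import pytest
from scipy import stats

from medmr import (
    DegenerateDesignError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    beta_to_or,
    cochran_q,
    ivw,
    leave_one_out,
    mode_estimate,
    mr_egger,
    percent_change,
    wald_ratio,
    weighted_median,
)

from conftest import harmonized_frame


class TestWaldRatio:
    def test_analytic(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        est = wald_ratio(0.1, 0.01, 0.0, 0.01)
        assert est.beta == 0.0 and est.pval == 1.0

    def test_negative_exposure_effect_se_positive(self):
        est = wald_ratio(-0.1, 0.01, 0.05, 0.01)
        assert est.beta == pytest.approx(-0.5) and est.se == pytest.approx(0.1)

    def test_degenerate_instrument(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        h = harmonized_frame([0.1], [0.01], [0.05], [0.02])
        est = ivw(h, effects="fixed")
        wald = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_noise_free_recovers_theta_with_closed_form_se(self):
        bx = np.array([0.1, 0.15, 0.2, 0.3])
        theta = 0.4
        h = harmonized_frame(bx, 0.01, theta * bx, 0.01)
        est = ivw(h, effects="fixed")
        assert est.beta == pytest.approx(theta)
        assert est.se == pytest.approx((np.sum(bx**2) / 0.01**2) ** -0.5)
        q, _, p = cochran_q(h)
        assert q == pytest.approx(0.0, abs=1e-20) and p == pytest.approx(1.0)

    def test_three_snp_fixture_matches_independent_sums(self):
        # spreadsheet-style evaluation of the two weighted sums
        bx = np.array([0.10, 0.15, 0.20])
        by = np.array([0.02, 0.04, 0.05])
        sy = np.full(3, 0.01)
        w = 1 / sy**2
        expected_beta = np.sum(w * bx * by) / np.sum(w * bx * bx)  # = 180/725
        h = harmonized_frame(bx, 0.01, by, sy)
        est = ivw(h, effects="fixed")
        assert est.beta == pytest.approx(expected_beta)
        assert est.beta == pytest.approx(0.2482758620689655)
        assert est.se == pytest.approx(725.0**-0.5)

    def test_random_effects_never_narrower_than_fixed(self):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.05, 0.2, 8)
        by = 0.3 * bx + rng.normal(0, 0.02, 8)
        h = harmonized_frame(bx, 0.01, by, 0.01)
        assert ivw(h).se >= ivw(h, effects="fixed").se

    def test_insufficient_snps(self):
        h = harmonized_frame([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(h, effects="multiplicative_random")


class TestEgger:
    def test_noise_free_slope_and_intercept(self):
        bx = np.array([0.10, 0.15, 0.20, 0.25])
        theta, delta = 0.3, 0.02
        h = harmonized_frame(bx, 0.01, delta + theta * bx, 0.01)
        res = mr_egger(h)
        assert res.slope.beta == pytest.approx(theta)
        assert res.intercept == pytest.approx(delta)

    def test_constant_offset_leaves_slope_unchanged(self):
        # closed-form WLS: adding delta to every beta_out moves only the intercept
        bx = np.array([0.10, 0.15, 0.20, 0.25])
        rng = np.random.default_rng(7)
        by = 0.3 * bx + rng.normal(0, 0.01, 4)
        h0 = mr_egger(harmonized_frame(bx, 0.01, by, 0.01))
        h1 = mr_egger(harmonized_frame(bx, 0.01, by + 0.05, 0.01))
        assert h1.slope.beta == pytest.approx(h0.slope.beta)
        assert h1.intercept == pytest.approx(h0.intercept + 0.05)

    def test_orientation_makes_estimate_sign_convention_free(self):
        # re-coding an instrument's effect allele (flip both betas) is a no-op
        bx = np.array([0.10, -0.15, 0.20, 0.25])
        by = np.array([0.03, -0.05, 0.07, 0.08])
        flipped = mr_egger(harmonized_frame(np.abs(bx), 0.01, np.sign(bx) * by, 0.01))
        oriented = mr_egger(harmonized_frame(bx, 0.01, by, 0.01))
        assert oriented.slope.beta == pytest.approx(flipped.slope.beta)

    def test_collinear_design_raises(self):
        h = harmonized_frame([0.1, 0.1, -0.1], [0.01], [0.03, 0.02, 0.01], [0.01])
        with pytest.raises(DegenerateDesignError):
            mr_egger(h)

    def test_too_few_snps(self):
        h = harmonized_frame([0.1, 0.2], [0.01], [0.03, 0.05], [0.01])
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(h)


class TestWeightedMedian:
    def test_equal_weight_interpolated_median(self):
        # ratios {0.1, 0.5, 0.9} with equal weights -> 0.5 by direct
        # evaluation of the interpolated weighted-percentile definition
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.5, 0.9])
        est = weighted_median(harmonized_frame(bx, 0.01, by, 0.01), seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_identical_ratios_zero_se_limit(self):
        bx = np.array([0.1, 0.2, 0.4])
        est = weighted_median(harmonized_frame(bx, 1e-9, 0.3 * bx, 1e-9), seed=1)
        assert est.beta == pytest.approx(0.3)
        assert est.se < 1e-6

    def test_seeded_bootstrap_is_bit_reproducible(self):
        h = harmonized_frame([0.1, 0.15, 0.2, 0.3], [0.01],
                             [0.03, 0.05, 0.05, 0.1], [0.01])
        a = weighted_median(h, n_boot=200, seed=11)
        b = weighted_median(h, n_boot=200, seed=11)
        assert a.se == b.se and a.beta == b.beta

    def test_requires_seed_and_three_snps(self):
        h = harmonized_frame([0.1, 0.15, 0.2], [0.01], [0.03, 0.05, 0.05], [0.01])
        with pytest.raises(ValueError):
            weighted_median(h)
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(h.iloc[:2], seed=1)


class TestModeEstimators:
    def test_cluster_beats_outlier(self):
        # five ratios near 0.3 plus one at 3.0: the mode stays with the
        # cluster while the mean would not; cross-checked against a dense
        # grid-search argmax of the same kernel sum written independently
        bx = np.ones(6)
        by = np.array([0.28, 0.29, 0.30, 0.31, 0.32, 3.0])
        h = harmonized_frame(bx, 0.01, by, 0.01)
        est = mode_estimate(h, weighted=False, seed=3, n_boot=50)
        assert abs(est.beta - 0.30) < 0.05
        assert abs(est.beta - np.mean(by)) > 0.3

        ratios = by / bx
        mad = np.median(np.abs(ratios - np.median(ratios)))
        bw = 0.9 * (1.4826 * mad) * len(ratios) ** (-0.2)
        grid = np.linspace(-1, 4, 200_001)
        dens = np.exp(-0.5 * ((grid[:, None] - ratios) / bw) ** 2).sum(axis=1)
        oracle = grid[np.argmax(dens)]
        assert est.beta == pytest.approx(oracle, abs=1e-2)

    def test_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.5])
        est = mode_estimate(harmonized_frame(bx, 0.01, 0.25 * bx, 0.01),
                            weighted=True, seed=5, n_boot=20)
        assert est.beta == pytest.approx(0.25)

    def test_weighted_equals_simple_under_equal_weights(self):
        bx = np.ones(5)
        by = np.array([0.1, 0.2, 0.25, 0.3, 0.6])
        h = harmonized_frame(bx, 0.01, by, 0.01)  # equal ratio variances
        simple = mode_estimate(h, weighted=False, seed=9, n_boot=20)
        weighted = mode_estimate(h, weighted=True, seed=9, n_boot=20)
        assert simple.beta == pytest.approx(weighted.beta)


class TestCochranQ:
    def test_identical_ratios_q_zero(self):
        bx = np.array([0.1, 0.2, 0.4])
        q, df, p = cochran_q(harmonized_frame(bx, 0.01, 0.3 * bx, 0.01))
        assert q == pytest.approx(0.0, abs=1e-18)
        assert p == pytest.approx(1.0)

    def test_two_snps_df_one(self):
        _, df, _ = cochran_q(harmonized_frame([0.1, 0.2], [0.01], [0.05, 0.04], [0.01]))
        assert df == 1

    def test_three_snp_term_by_term_sum(self):
        bx = np.array([0.10, 0.15, 0.20])
        by = np.array([0.02, 0.04, 0.05])
        sy = np.full(3, 0.01)
        ratios = by / bx
        w = bx**2 / sy**2
        beta_fixed = np.sum(w * ratios) / np.sum(w)
        expected_q = float(np.sum(w * (ratios - beta_fixed) ** 2))
        q, df, p = cochran_q(harmonized_frame(bx, 0.01, by, sy))
        assert q == pytest.approx(expected_q)
        assert df == 2
        assert p == pytest.approx(stats.chi2.sf(expected_q, 2))


class TestLeaveOneOut:
    def test_homogeneous_set_unflagged(self):
        bx = np.array([0.1, 0.15, 0.2, 0.25])
        loo = leave_one_out(harmonized_frame(bx, 0.001, 0.3 * bx, 0.001))
        assert len(loo) == 4
        assert not loo["influential"].any()
        np.testing.assert_allclose(loo["beta"], 0.3, rtol=1e-9)

    def test_planted_outlier_flagged(self):
        # three instruments with mildly negative ratios plus one strong
        # positive outlier that drags the pooled estimate across zero;
        # removing it flips the sign, so it alone must be flagged
        bx = np.array([0.1, 0.12, 0.15, 0.1])
        by = np.array([-0.001, -0.002, -0.001, 0.01])
        h = harmonized_frame(bx, 0.01, by, 0.01)
        full = ivw(h)
        without = ivw(h.iloc[:3])
        assert np.sign(full.beta) != np.sign(without.beta)  # fixture sanity
        loo = leave_one_out(h)
        assert bool(loo.iloc[3]["influential"])
        assert not loo.iloc[:3]["influential"].any()

    def test_row_count_contract(self):
        bx = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
        loo = leave_one_out(harmonized_frame(bx, 0.01, 0.2 * bx, 0.01))
        assert len(loo) == 5


class TestReportingScales:
    @pytest.mark.parametrize("beta,expected", [(-0.30, 0.74), (-0.21, 0.81),
                                               (-0.14, 0.87), (0.16, 1.17), (0.0, 1.00)])
    def test_beta_to_or(self, beta, expected):
        or_point, lo, hi = beta_to_or(beta, 0.1)
        assert round(or_point, 2) == expected
        assert lo < or_point < hi

    @pytest.mark.parametrize("beta,expected", [(-0.30, -26), (-0.21, -19), (0.16, 17)])
    def test_percent_change(self, beta, expected):
        assert round(percent_change(beta)) == expected

    def test_or_ci_consistency(self):
        est = ivw(harmonized_frame([0.1, 0.2], [0.01], [0.05, 0.09], [0.01]))
        assert est.or_point == pytest.approx(np.exp(est.beta))
        assert est.or_ci_low == pytest.approx(np.exp(est.beta - 1.96 * est.se))
        assert est.or_ci_high == pytest.approx(np.exp(est.beta + 1.96 * est.se))


class TestOrderInvariance:
    @pytest.mark.parametrize("method", ["ivw", "egger", "median", "mode", "q"])
    def test_shuffling_variants_changes_nothing(self, method):
        rng = np.random.default_rng(2024)
        bx = rng.uniform(0.05, 0.25, 10)
        by = 0.3 * bx + rng.normal(0, 0.01, 10)
        h = harmonized_frame(bx, 0.01, by, 0.01)
        hs = h.sample(frac=1, random_state=5).reset_index(drop=True)
        if method == "ivw":
            assert ivw(h).beta == pytest.approx(ivw(hs).beta, rel=1e-12)
        elif method == "egger":
            assert mr_egger(h).slope.beta == pytest.approx(mr_egger(hs).slope.beta, rel=1e-9)
        elif method == "median":
            assert weighted_median(h, seed=1, n_boot=10).beta == pytest.approx(
                weighted_median(hs, seed=1, n_boot=10).beta, rel=1e-12)
        elif method == "mode":
            assert mode_estimate(h, seed=1, n_boot=10).beta == pytest.approx(
                mode_estimate(hs, seed=1, n_boot=10).beta, rel=1e-9)
        else:
            assert cochran_q(h)[0] == pytest.approx(cochran_q(hs)[0], rel=1e-12)
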