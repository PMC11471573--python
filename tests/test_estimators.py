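"""MR estimators: Wald ratio, IVW, weighted median, Egger, dispatch, OR view."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrscreen.estimators import (EstimationError, MRConfig, Z95, beta_to_or,
                                 egger, ivw, run_mr, wald_ratio,
                                 weighted_median)
from mrscreen.harmonize import DROPPED_PALINDROMIC, HarmonizedPair
from conftest import make_pairs


class TestWaldRatio:
    def test_arithmetic(self):
        (p,) = make_pairs([0.1], [0.05], [0.02])
        est = wald_ratio(p)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_sign(self):
        (p,) = make_pairs([-0.2], [0.1], [0.02])
        assert wald_ratio(p).beta == pytest.approx(-0.5)

    def test_identity_when_beta_x_is_one(self):
        (p,) = make_pairs([1.0], [0.37], [0.02])
        assert wald_ratio(p).beta == pytest.approx(0.37)

    def test_zero_exposure_beta_rejected(self):
        (p,) = make_pairs([0.0], [0.1], [0.02])
        with pytest.raises(EstimationError, match="undefined"):
            wald_ratio(p)


class TestIvw:
    def test_single_pair_collapses_to_wald(self):
        pairs = make_pairs([0.1], [0.05], [0.02])
        est = ivw(pairs)
        wr = wald_ratio(pairs[0])
        assert (est.beta, est.se) == (wr.beta, wr.se)

    def test_perfect_fit_q_zero_fixed_equals_random(self, rng):
        bx = np.array([0.1, 0.2, 0.3])
        pairs = make_pairs(bx, 0.5 * bx, rng.uniform(0.01, 0.05, 3))
        fe = ivw(pairs, variant="fixed")
        mre = ivw(pairs, variant="multiplicative_random")
        assert fe.beta == pytest.approx(0.5)
        assert mre.se == pytest.approx(fe.se)

    def test_fixed_se_never_exceeds_random_se(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 15))
            pairs = make_pairs(rng.normal(0.1, 0.05, k),
                               rng.normal(0.0, 0.1, k),
                               rng.uniform(0.01, 0.1, k))
            fe = ivw(pairs, variant="fixed")
            mre = ivw(pairs, variant="multiplicative_random")
            assert fe.se <= mre.se + 1e-15

    def test_sign_equivariance_under_allele_recoding(self, rng):
        k = 12
        bx = rng.normal(0.1, 0.05, k)
        by = rng.normal(0.03, 0.05, k)
        sy = rng.uniform(0.01, 0.1, k)
        a = ivw(make_pairs(bx, by, sy))
        b = ivw(make_pairs(-bx, by, sy))
        assert b.beta == pytest.approx(-a.beta)
        assert b.se == pytest.approx(a.se)

    def test_permutation_invariance(self, rng):
        k = 9
        bx, by, sy = rng.normal(0.1, 0.03, k), rng.normal(0, 0.05, k), \
            rng.uniform(0.01, 0.1, k)
        perm = rng.permutation(k)
        a = ivw(make_pairs(bx, by, sy))
        b = ivw(make_pairs(bx[perm], by[perm], sy[perm]))
        assert b.beta == pytest.approx(a.beta, rel=1e-12)
        assert b.se == pytest.approx(a.se, rel=1e-12)

    def test_dropped_pairs_rejected(self):
        bad = HarmonizedPair("rs1", 0.1, 0.01, 0.05, 0.02, DROPPED_PALINDROMIC)
        with pytest.raises(EstimationError, match="dropped"):
            ivw([bad])


class TestWeightedMedian:
    def test_equal_weights_odd_k_hits_middle_ratio(self):
        bx = np.ones(3)
        est = weighted_median(make_pairs(bx, [0.2, 0.5, 0.9], 1.0), n_boot=50)
        assert est.beta == pytest.approx(0.5)

    def test_equal_weights_even_k_interpolates(self):
        bx = np.ones(4)
        est = weighted_median(make_pairs(bx, [0.1, 0.2, 0.3, 0.4], 1.0), n_boot=50)
        # midpoints 0.125,0.375,0.625,0.875 -> interpolate at 0.5 -> 0.25
        assert est.beta == pytest.approx(0.25)

    def test_estimate_bounded_by_ratio_range(self, rng):
        for _ in range(20):
            k = int(rng.integers(3, 12))
            bx = rng.uniform(0.05, 0.3, k)
            by = rng.normal(0, 0.1, k)
            sy = rng.uniform(0.01, 0.1, k)
            est = weighted_median(make_pairs(bx, by, sy), n_boot=20)
            ratios = by / bx
            assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12

    def test_seeded_bootstrap_reproducible_and_order_invariant(self, rng):
        k = 6
        bx, by, sy = rng.uniform(0.05, 0.3, k), rng.normal(0, 0.1, k), \
            rng.uniform(0.01, 0.1, k)
        pairs = make_pairs(bx, by, sy, se_x=0.01)
        perm = rng.permutation(k)
        shuffled = [pairs[i] for i in perm]
        a = weighted_median(pairs, n_boot=200, seed=42)
        b = weighted_median(shuffled, n_boot=200, seed=42)
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_fewer_than_three_instruments_refused(self):
        with pytest.raises(EstimationError):
            weighted_median(make_pairs([0.1, 0.2], [0.05, 0.1], 0.02))


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.03 + 0.4 * bx
        slope, intercept = egger(make_pairs(bx, by, 0.05))
        assert slope.beta == pytest.approx(0.4, abs=1e-12)
        assert intercept.intercept == pytest.approx(0.03, abs=1e-12)

    def test_negative_exposure_betas_oriented_before_fit(self):
        bx = np.array([0.1, -0.2, 0.3, -0.4])
        by = 0.03 * np.sign(bx) + 0.4 * bx  # consistent after orientation
        slope, intercept = egger(make_pairs(bx, by, 0.05))
        assert slope.beta == pytest.approx(0.4, abs=1e-12)
        assert intercept.intercept == pytest.approx(0.03, abs=1e-12)

    def test_singular_design_rejected(self):
        with pytest.raises(EstimationError, match="singular"):
            egger(make_pairs([0.2, 0.2, 0.2], [0.1, 0.2, 0.3], 0.05))

    def test_null_intercept_pvalues_uniform(self):
        """Balanced pleiotropy => Egger intercept p-values ~ Uniform(0,1)."""
        from scipy import stats as sps
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(400):
            k = 25
            bx = rng.uniform(0.05, 0.3, k)
            sy = np.full(k, 0.05)
            by = 0.3 * bx + rng.normal(0, sy)
            _, icpt = egger(make_pairs(bx, by, sy))
            pvals.append(icpt.pval)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestDispatch:
    def test_k1_reports_single_ivw_estimate(self):
        out = run_mr(make_pairs([0.1], [0.05], [0.02]))
        assert [e.method for e in out] == ["ivw_fe"] and out[0].n_snps == 1

    def test_k2_ivw_only(self):
        out = run_mr(make_pairs([0.1, 0.2], [0.05, 0.1], 0.02))
        assert [e.method for e in out] == ["ivw_fe"]

    @pytest.mark.parametrize("k", [3, 5])
    def test_k3_and_up_adds_weighted_median(self, k, rng):
        pairs = make_pairs(rng.uniform(0.05, 0.3, k), rng.normal(0, 0.05, k),
                           0.02)
        methods = [e.method for e in run_mr(pairs, MRConfig(n_boot=50))]
        assert methods == ["ivw_mre", "weighted_median"]

    def test_null_beta_gives_or_one_ci_spanning_one(self):
        bx = np.ones(3)
        pairs = make_pairs(bx, [0.0, 0.0, 0.0], 0.1)
        est = ivw(pairs)
        assert est.or_point == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high


class TestBetaToOr:
    def test_null_beta(self):
        orp, lo, hi = beta_to_or(0.0, 0.1)
        assert orp == pytest.approx(1.0)
        assert lo == pytest.approx(np.exp(-Z95 * 0.1), abs=1e-6)
        assert (round(lo, 3), round(hi, 3)) == (0.822, 1.217)

    def test_reference_effect_size(self):
        # log-odds 0.265 -> OR ~ 1.303
        assert beta_to_or(0.265, 0.1)[0] == pytest.approx(1.3034, abs=1e-3)

    def test_zero_se_degenerate_ci(self):
        orp, lo, hi = beta_to_or(0.3, 0.0)
        assert orp == lo == hi


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=2, max_value=12), st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_ivw_sign_equivariance_property(k, seed):
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.01, 0.3, k) * rng.choice([-1, 1], k)
    by = rng.normal(0, 0.1, k)
    sy = rng.uniform(0.01, 0.1, k)
    a = ivw(make_pairs(bx, by, sy))
    b = ivw(make_pairs(-bx, by, sy))
    assert b.beta == pytest.approx(-a.beta, rel=1e-10)
    assert b.se == pytest.approx(a.se, rel=1e-10)
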