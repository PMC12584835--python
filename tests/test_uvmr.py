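"""Univariable MR estimators against independent oracles and calibrations."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import optimize, stats

import mrkit as mk
from mrkit import HarmonizedSet
from mrkit.uvmr import _silverman_bandwidth, _weighted_median_point, _weighted_mode_point

from conftest import random_harmonized, wls_oracle


class TestWaldRatios:
    def test_ratio_se_and_zero_exposure_exclusion(self):
        h = HarmonizedSet.from_arrays(
            bx=np.array([0.10, -0.10, 0.0]),
            bx_se=np.full(3, 0.01),
            by=np.array([0.05, 0.05, 0.05]),
            by_se=np.array([0.01, 0.02, 0.01]),
        )
        ratios, ses, ids = mk.wald_ratios(h)
        np.testing.assert_allclose(ratios, [0.5, -0.5])
        np.testing.assert_allclose(ses, [0.1, 0.2])
        assert ids == ["v0", "v1"]


class TestIVW:
    def test_perfect_proportionality(self, proportional_set):
        est = mk.ivw(proportional_set)
        assert est.beta == pytest.approx(0.5)
        assert est.q_stat == pytest.approx(0.0, abs=1e-24)

    def test_matches_wls_oracle_on_fixture(self):
        h = HarmonizedSet.from_arrays(
            bx=np.array([0.2, 0.3, 0.5]),
            bx_se=np.full(3, 0.01),
            by=np.array([0.11, 0.14, 0.26]),
            by_se=np.array([0.05, 0.04, 0.06]),
        )
        est = mk.ivw(h)
        w = 1.0 / h.by_se**2
        coef, se_unscaled, rss = wls_oracle(h.bx[:, None], h.by, w)
        assert est.beta == pytest.approx(coef[0], rel=1e-12)
        scale = max(1.0, np.sqrt(rss / 2))
        assert est.se == pytest.approx(se_unscaled[0] * scale, rel=1e-12)
        assert est.q_stat == pytest.approx(rss, rel=1e-12)

    def test_fixed_effects_se(self, proportional_set):
        est = mk.ivw(proportional_set, effects_model="fixed")
        w = 1 / proportional_set.by_se**2
        assert est.se == pytest.approx(1 / np.sqrt(np.sum(w * proportional_set.bx**2)))

    def test_requires_two_variants(self):
        h = HarmonizedSet.from_arrays([0.1], [0.01], [0.05], [0.01])
        with pytest.raises(mk.AnalysisError):
            mk.ivw(h)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.5])
        h = HarmonizedSet.from_arrays(
            bx, np.full(4, 0.01), 0.02 + 0.4 * bx, np.array([0.03, 0.05, 0.04, 0.06])
        )
        est = mk.egger(h)
        assert est.egger_intercept == pytest.approx(0.02, rel=1e-10)
        assert est.beta == pytest.approx(0.4, rel=1e-10)
        assert est.q_stat == pytest.approx(0.0, abs=1e-20)

    def test_matches_weighted_ols_oracle(self, rng):
        h = random_harmonized(rng, 4)
        # orient exposure effects non-negative, as the estimator does
        flip = h.bx < 0
        bx = np.where(flip, -h.bx, h.bx)
        by = np.where(flip, -h.by, h.by)
        w = 1.0 / h.by_se**2
        X = np.column_stack([np.ones(4), bx])
        coef, se_unscaled, rss = wls_oracle(X, by, w)
        scale = max(1.0, np.sqrt(rss / 2))
        est = mk.egger(h)
        assert est.egger_intercept == pytest.approx(coef[0], rel=1e-10)
        assert est.beta == pytest.approx(coef[1], rel=1e-10)
        assert est.egger_intercept_se == pytest.approx(se_unscaled[0] * scale, rel=1e-10)
        assert est.se == pytest.approx(se_unscaled[1] * scale, rel=1e-10)

    def test_directional_pleiotropy_intercept_recovered(self, rng):
        """With InSIDE holding and mean pleiotropy 0.05, the intercept
        estimate centres on 0.05 and is detected far above the null rate."""
        n, reps = 100, 200
        intercepts, rejections = [], 0
        for _ in range(reps):
            bx = rng.uniform(0.05, 0.3, n)
            alpha = rng.normal(0.05, 0.02, n)
            by_se = np.full(n, 0.01)
            by = alpha + 0.1 * bx + rng.normal(0, by_se)
            h = HarmonizedSet.from_arrays(bx, np.full(n, 0.004), by, by_se)
            est = mk.egger(h)
            intercepts.append(est.egger_intercept)
            rejections += est.egger_intercept_pval < 0.05
        assert np.mean(intercepts) == pytest.approx(0.05, abs=0.005)
        assert rejections / reps > 0.5


class TestWeightedMedian:
    def test_equal_ratios_ignore_weights(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = HarmonizedSet.from_arrays(
            bx, np.full(3, 0.01), 0.7 * bx, np.array([0.01, 0.05, 0.2])
        )
        est = mk.weighted_median(h, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.7)

    def test_matches_cdf_scan_oracle(self, rng):
        """The interpolated weighted median must solve F(m) = 1/2 for the
        piecewise-linear weighted CDF, located here by root bisection."""
        h = random_harmonized(rng, 5, noise=3.0)
        ratios, ses, _ = mk.wald_ratios(h)
        w = 1.0 / ses**2
        order = np.argsort(ratios)
        r, wn = ratios[order], w[order] / w.sum()
        s = np.cumsum(wn) - wn / 2

        def cdf_minus_half(x):
            return np.interp(x, r, s, left=s[0], right=s[-1]) - 0.5

        m = optimize.brentq(cdf_minus_half, r[0], r[-1])
        est = mk.weighted_median(h, n_boot=50, seed=0)
        assert est.beta == pytest.approx(m, rel=1e-10)

    def test_majority_valid_weight_consistency(self, rng):
        """10 valid variants (ratio 0.5) holding ~60% of weight beat 5
        invalid ones at ratio 2.0."""
        bx = np.concatenate([np.full(10, 0.2), np.full(5, 0.2)])
        by = np.concatenate([0.5 * np.full(10, 0.2), 2.0 * np.full(5, 0.2)])
        # equal per-variant weights: valid group carries 10/15 of the weight
        h = HarmonizedSet.from_arrays(
            bx, np.full(15, 1e-5), by, np.full(15, 0.01)
        )
        est = mk.weighted_median(h, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5, abs=1e-6)

    def test_invariant_to_splitting_a_tail_variant(self):
        """Duplicating a variant away from the median while halving its
        weight leaves the interpolated median unchanged.  (Splitting a
        variant adjacent to the median moves the interpolation knots, so
        exact invariance is only expected away from the centre.)"""
        ratios = np.array([0.2, 0.5, 0.9, 1.4])
        weights = np.array([1.0, 2.0, 1.5, 0.5])
        base = _weighted_median_point(ratios, weights)
        split_r = np.array([0.2, 0.5, 0.9, 1.4, 1.4])
        split_w = np.array([1.0, 2.0, 1.5, 0.25, 0.25])
        assert _weighted_median_point(split_r, split_w) == pytest.approx(base)

    def test_bootstrap_se_deterministic_under_seed(self, rng):
        h = random_harmonized(rng, 8)
        a = mk.weighted_median(h, n_boot=100, seed=42)
        b = mk.weighted_median(h, n_boot=100, seed=42)
        assert a.se == b.se


class TestWeightedMode:
    def test_dominant_cluster_wins(self):
        bx = np.full(10, 0.2)
        by = 0.2 * np.concatenate([np.full(8, 0.3), np.full(2, 5.0)])
        h = HarmonizedSet.from_arrays(bx, np.full(10, 0.005), by, np.full(10, 0.02))
        est = mk.weighted_mode(h, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.3, abs=0.05)

    def test_matches_dense_grid_oracle(self, rng):
        h = random_harmonized(rng, 6, noise=2.0)
        ratios, ses, _ = mk.wald_ratios(h)
        w = 1.0 / ses**2
        bw = _silverman_bandwidth(ratios, w)
        lo, hi = ratios.min() - 3 * bw, ratios.max() + 3 * bw
        dense = np.linspace(lo, hi, 100_001)
        dens = np.zeros_like(dense)
        for r_j, w_j in zip(ratios, w):  # explicit brute-force accumulation
            dens += w_j / w.sum() * np.exp(-0.5 * ((dense - r_j) / bw) ** 2)
        oracle = dense[np.argmax(dens)]
        est = mk.weighted_mode(h, n_boot=50, seed=0)
        grid_step = (hi - lo) / 511
        assert abs(est.beta - oracle) <= grid_step

    def test_large_bandwidth_approaches_weighted_mean(self, rng):
        h = random_harmonized(rng, 12, noise=2.0)
        ratios, ses, _ = mk.wald_ratios(h)
        w = 1.0 / ses**2
        wmean = float(np.sum(w * ratios) / w.sum())
        est = mk.weighted_mode(h, bandwidth_factor=200.0, n_boot=10, seed=0)
        bw = 200.0 * _silverman_bandwidth(ratios, w)
        grid_step = (ratios.max() - ratios.min() + 6 * bw) / 511
        assert abs(est.beta - wmean) <= 2 * grid_step


class TestCochranQ:
    def test_perfect_fit_gives_zero(self, proportional_set):
        q, p = mk.cochran_q(proportional_set, 0.5)
        assert q == pytest.approx(0.0, abs=1e-24)
        assert p == pytest.approx(1.0)

    def test_hand_computed_sum(self):
        h = HarmonizedSet.from_arrays(
            bx=np.array([0.1, 0.2, 0.3]),
            bx_se=np.full(3, 0.01),
            by=np.array([0.06, 0.09, 0.18]),
            by_se=np.array([0.02, 0.03, 0.04]),
        )
        beta = 0.5
        expected = (
            (0.06 - 0.05) ** 2 / 0.02**2
            + (0.09 - 0.10) ** 2 / 0.03**2
            + (0.18 - 0.15) ** 2 / 0.04**2
        )
        q, p = mk.cochran_q(h, beta)
        assert q == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(expected, 2), rel=1e-12)


class TestEstimateAll:
    def test_zero_noise_all_methods_agree(self):
        bx = np.array([0.1, 0.25, 0.4, 0.6])
        h = HarmonizedSet.from_arrays(
            bx, np.full(4, 0.01), 0.35 * bx, np.full(4, 0.02)
        )
        ests = mk.estimate_all(h, seed=0, n_boot=50)
        for est in ests.values():
            assert est.beta == pytest.approx(0.35, abs=0.01)

    def test_seeded_runs_identical(self, rng):
        h = random_harmonized(rng, 10)
        a = mk.estimate_all(h, seed=9, n_boot=100)
        b = mk.estimate_all(h, seed=9, n_boot=100)
        for m in a:
            assert a[m].__dict__ == b[m].__dict__

    def test_sign_flip_equivariance(self, rng):
        """Jointly negating a variant's exposure and outcome effects
        changes nothing in any estimator."""
        h = random_harmonized(rng, 9)
        df = h.df.copy()
        lab = h.exposure_labels[0]
        flip = np.array([1, -1, 1, -1, 1, -1, 1, -1, 1], float)
        df[f"beta_{lab}"] *= flip
        df["outcome_beta"] *= flip
        h2 = HarmonizedSet(df, h.exposure_labels, h.outcome_label)
        a = mk.estimate_all(h, seed=5, n_boot=100)
        b = mk.estimate_all(h2, seed=5, n_boot=100)
        for m in ("ivw", "egger"):
            assert a[m].beta == pytest.approx(b[m].beta, rel=1e-12)
            assert a[m].se == pytest.approx(b[m].se, rel=1e-12)

    def test_or_fields_consistent_and_monotone(self, rng):
        h = random_harmonized(rng, 7)
        for est in mk.estimate_all(h, seed=2, n_boot=50).values():
            assert est.or_value == pytest.approx(np.exp(est.beta), rel=1e-12)
            assert est.or_low <= est.or_value <= est.or_high
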