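"""MR estimators against closed forms and independent oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from protmr.mr_estimators import (
    egger,
    estimate_all,
    ivw,
    wald_ratio,
    weighted_median,
    weighted_mode,
    _mode_point,
    _weighted_median_point,
)


def random_pairs(rng, n=None, null=False):
    n = n or int(rng.integers(3, 11))
    bx = rng.uniform(0.05, 0.5, n) * rng.choice([-1, 1], n)
    sx = rng.uniform(0.005, 0.02, n)
    sy = rng.uniform(0.01, 0.05, n)
    slope = 0.0 if null else rng.uniform(-0.5, 0.5)
    by = slope * bx + sy * rng.standard_normal(n)
    return bx, sx, by, sy


class TestWaldRatio:
    def test_direct_ratio(self):
        est = wald_ratio((0.5, 0.01, 0.1, 0.05))
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome(self):
        est = wald_ratio((0.5, 0.01, 0.0, 0.05))
        assert est.beta == 0.0
        assert est.pvalue == pytest.approx(1.0)

    def test_sign_flip_of_exposure_leaves_estimate(self):
        a = wald_ratio((0.5, 0.01, 0.1, 0.05))
        b = wald_ratio((-0.5, 0.01, -0.1, 0.05))
        assert a.beta == pytest.approx(b.beta)

    def test_zero_exposure_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio((0.0, 0.01, 0.1, 0.05))


class TestIVW:
    def test_equal_ratio_closed_form(self):
        est = ivw((np.array([0.5, 0.4]), np.array([0.01, 0.01]),
                   np.array([0.1, 0.08]), np.array([0.05, 0.05])))
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx((0.41 / 0.0025) ** -0.5, rel=1e-12)
        assert not est.random_effects  # Q = 0 here

    def test_single_pair_equals_wald(self):
        est = ivw((np.array([0.5]), np.array([0.01]), np.array([0.1]),
                   np.array([0.05])))
        w = wald_ratio((0.5, 0.01, 0.1, 0.05))
        assert est.beta == pytest.approx(w.beta) and est.se == pytest.approx(w.se)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_wls_oracle(self, seed):
        """Zero-intercept WLS via statsmodels reproduces IVW to 1e-10."""
        rng = np.random.default_rng(seed)
        bx, sx, by, sy = random_pairs(rng)
        est = ivw((bx, sx, by, sy), random_effects="fixed")
        fit = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
        # fixed-effect se is the unscaled (X'WX)^{-1/2}
        se_fe = float(np.sum(bx**2 / sy**2)) ** -0.5
        assert est.se == pytest.approx(se_fe, abs=1e-12)

    def test_random_effects_inflation_formula(self, rng):
        bx, sx, by, sy = random_pairs(rng)
        by = by + 0.3 * rng.standard_normal(len(bx))  # force heterogeneity
        est_auto = ivw((bx, sx, by, sy))
        est_fix = ivw((bx, sx, by, sy), random_effects="fixed")
        assert est_auto.Q / (est_auto.n_iv - 1) > 1
        assert est_auto.se == pytest.approx(
            est_fix.se * np.sqrt(est_auto.Q / (est_auto.n_iv - 1)), rel=1e-12)

    def test_all_zero_exposure_raises(self):
        with pytest.raises(ZeroDivisionError):
            ivw((np.zeros(3), np.full(3, 0.01), np.ones(3), np.full(3, 0.05)))

    def test_parameter_recovery_simulation(self):
        """Homogeneous data, true slope 0.3: mean estimate within MC error."""
        betas = []
        for s in range(200):
            rng = np.random.default_rng(1000 + s)
            n = 10
            bx = rng.uniform(0.1, 0.3, n)
            sy = np.full(n, 0.02)
            by = 0.3 * bx + sy * rng.standard_normal(n)
            betas.append(ivw((bx, np.full(n, 0.005), by, sy)).beta)
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert np.mean(betas) == pytest.approx(0.3, abs=3 * mc_se)


class TestEgger:
    def test_exact_linear_fit(self):
        bx = np.array([0.2, 0.4, 0.6])
        by = 0.5 * bx + 0.04
        est = egger((bx, np.full(3, 0.01), by, np.full(3, 0.02)))
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.intercept == pytest.approx(0.04, abs=1e-10)

    def test_through_origin_data_matches_ivw_with_equal_weights(self):
        bx = np.array([0.2, 0.4, 0.6])
        by = 0.5 * bx
        sy = np.full(3, 0.02)
        e = egger((bx, np.full(3, 0.01), by, sy))
        i = ivw((bx, np.full(3, 0.01), by, sy), random_effects="fixed")
        assert e.beta == pytest.approx(i.beta, abs=1e-10)
        assert e.intercept == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_wls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bx, sx, by, sy = random_pairs(rng, n=int(rng.integers(4, 11)))
        est = egger((bx, sx, by, sy))
        flip = np.sign(bx)
        X = sm.add_constant(bx * flip)
        fit = sm.WLS(by * flip, X, weights=1 / sy**2).fit()
        assert est.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert est.pvalue == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_under_three_pairs_not_estimable(self):
        est = egger((np.array([0.1, 0.2]), np.array([0.01, 0.01]),
                     np.array([0.0, 0.1]), np.array([0.02, 0.02])))
        assert not est.estimable

    def test_intercept_test_size_under_balanced_pleiotropy(self):
        """Type-I error of the balance test ≈ 5% over null simulations."""
        hits = 0
        n_rep = 400
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            n = 10
            bx = rng.uniform(0.05, 0.3, n)
            sy = np.full(n, 0.02)
            by = 0.2 * bx + sy * rng.standard_normal(n)
            if egger((bx, np.full(n, 0.005), by, sy)).intercept_p < 0.05:
                hits += 1
        assert hits / n_rep == pytest.approx(0.05, abs=0.03)


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        bx = np.ones(3)
        by = np.array([0.1, 0.2, 0.9])
        est = weighted_median((bx, np.full(3, 0.01), by, np.full(3, 0.02)),
                              n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_weight_concentration_drives_estimate(self):
        # one IV carries almost all weight (huge bx relative to sy)
        bx = np.array([5.0, 0.01, 0.01])
        by = np.array([5.0 * 0.7, 0.001, 0.009])
        est = weighted_median((bx, np.full(3, 0.001), by, np.full(3, 0.02)),
                              n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.7, abs=1e-6)

    def test_outlier_resistance_vs_ivw(self):
        rng = np.random.default_rng(5)
        n = 10
        bx = rng.uniform(0.2, 0.4, n)
        sy = np.full(n, 0.01)
        by = 0.3 * bx + sy * rng.standard_normal(n)
        by[0] += 0.5  # gross outlier
        wm = weighted_median((bx, np.full(n, 0.005), by, sy), n_boot=100, seed=2)
        iv = ivw((bx, np.full(n, 0.005), by, sy))
        assert abs(wm.beta - 0.3) < abs(iv.beta - 0.3)
        assert abs(wm.beta - 0.3) < 0.1

    def test_interpolation_against_order_statistic_oracle(self, rng):
        for _ in range(50):
            m = int(rng.integers(3, 9))
            ratios = np.sort(rng.normal(0, 1, m))
            w = rng.uniform(0.1, 1, m)
            est = _weighted_median_point(ratios, w)
            # oracle: dense grid over the standardized cumulative weight
            order = np.argsort(ratios)
            r, ww = ratios[order], w[order] / w.sum()
            s = np.cumsum(ww) - ww / 2
            expected = np.interp(0.5, s, r)
            assert est == pytest.approx(expected, abs=1e-12)


class TestWeightedMode:
    def test_dominant_cluster(self):
        bx = np.ones(4)
        by = np.array([0.2, 0.2, 0.2, 0.9])
        est = weighted_mode((bx, np.full(4, 0.01), by, np.full(4, 0.02)),
                            n_boot=50, seed=3)
        assert est.beta == pytest.approx(0.2, abs=0.05)

    def test_identical_ratios_exact(self):
        bx = np.array([0.5, 1.0, 2.0])
        by = 0.4 * bx
        est = weighted_mode((bx, np.full(3, 0.01), by, np.full(3, 0.02)),
                            n_boot=10, seed=4)
        assert est.beta == pytest.approx(0.4, abs=1e-12)

    def test_grid_argmax_matches_fine_grid_oracle(self, rng):
        for _ in range(20):
            m = int(rng.integers(4, 10))
            ratios = rng.normal(0.3, 0.2, m)
            w = rng.uniform(0.1, 1, m)
            w = w / w.sum()
            est = _mode_point(ratios, w, 1.0, grid_size=512)
            dense = _mode_point(ratios, w, 1.0, grid_size=50_001)
            span = ratios.max() - ratios.min()
            sd = np.std(ratios, ddof=1)
            iqr = np.subtract(*np.percentile(ratios, [75, 25]))
            disp = min(sd, iqr / 1.349) if iqr > 0 else sd
            h = 0.9 * disp * m ** (-1 / 5)
            grid_step = (span + 6 * h) / 511
            assert abs(est - dense) <= grid_step

    def test_under_three_pairs_not_estimable(self):
        est = weighted_mode((np.array([0.1]), np.array([0.01]),
                             np.array([0.1]), np.array([0.02])))
        assert not est.estimable


class TestInvariances:
    @pytest.mark.parametrize("method", ["ivw", "egger", "weighted_median",
                                        "weighted_mode"])
    def test_outcome_negation_negates_estimate(self, method, rng):
        bx, sx, by, sy = random_pairs(rng, n=8)
        a = estimate_all((bx, sx, by, sy), (method,), n_boot=50, seed=9)[method]
        b = estimate_all((bx, sx, -by, sy), (method,), n_boot=50, seed=9)[method]
        assert a.beta == pytest.approx(-b.beta, abs=1e-9)

    @pytest.mark.parametrize("method", ["ivw", "egger", "weighted_median",
                                        "weighted_mode"])
    def test_exposure_scaling_inverts_estimate(self, method, rng):
        bx, sx, by, sy = random_pairs(rng, n=8)
        c = 2.5
        a = estimate_all((bx, sx, by, sy), (method,), n_boot=50, seed=9)[method]
        b = estimate_all((c * bx, c * sx, by, sy), (method,), n_boot=50,
                         seed=9)[method]
        assert a.beta == pytest.approx(c * b.beta, abs=1e-9)

    def test_bit_reproducible_given_seed(self, rng):
        bx, sx, by, sy = random_pairs(rng, n=6)
        a = weighted_median((bx, sx, by, sy), n_boot=200, seed=42)
        b = weighted_median((bx, sx, by, sy), n_boot=200, seed=42)
        assert (a.beta, a.se) == (b.beta, b.se)
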