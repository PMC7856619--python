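import dataclasses

import numpy as np
import pytest
from scipy import stats

from _helpers import hset_from_arrays, hset_from_study
from mrkit import estimators as est
from mrkit.simulate import SimulationConfig, simulate_two_sample


class TestWaldRatios:
    def test_basic_arithmetic(self):
        hset = hset_from_arrays([0.1], [0.01], [0.2], [0.05])
        (r,) = est.wald_ratios(hset)
        assert r.ratio == pytest.approx(2.0)
        assert r.ratio_se == pytest.approx(0.5)
        assert r.weight == pytest.approx(4.0)

    def test_sign_invariance(self):
        hset = hset_from_arrays([-0.1], [0.01], [-0.2], [0.05])
        (r,) = est.wald_ratios(hset)
        assert r.ratio == pytest.approx(2.0)
        assert r.ratio_se == pytest.approx(0.5)

    def test_matches_elementwise_division(self, rng):
        g = rng.normal(0.1, 0.02, 10)
        G = rng.normal(0.05, 0.02, 10)
        sy = rng.uniform(0.01, 0.05, 10)
        ratios = est.wald_ratios(hset_from_arrays(g, 0.01, G, sy))
        np.testing.assert_allclose([r.ratio for r in ratios], G / g, rtol=1e-14)
        np.testing.assert_allclose([r.ratio_se for r in ratios], sy / np.abs(g), rtol=1e-14)

    def test_weak_instrument_excluded_not_divided(self):
        hset = hset_from_arrays([0.1, 0.0], [0.01, 0.01], [0.2, 0.1], [0.05, 0.05])
        ratios = est.wald_ratios(hset)
        assert len(ratios) == 1
        assert np.isfinite(ratios[0].ratio)


class TestIVW:
    def test_single_instrument_fixed_equals_wald_ratio(self):
        hset = hset_from_arrays([0.1], [0.01], [0.2], [0.05])
        fit = est.ivw(hset, model="fixed")
        assert fit.beta == pytest.approx(2.0)
        assert fit.se == pytest.approx(0.5)
        with pytest.raises(ValueError, match="at least 2"):
            est.ivw(hset)  # random-effects needs J >= 2

    def test_zero_heterogeneity_case(self):
        g = np.array([0.1, 0.2, 0.3])
        hset = hset_from_arrays(g, 0.01, 0.5 * g, 0.02)
        fit = est.ivw(hset)
        assert fit.beta == pytest.approx(0.5, abs=1e-12)
        assert fit.extras["Q"] == pytest.approx(0.0, abs=1e-20)
        assert fit.extras["inflation"] == 1.0

    def test_matches_weighted_regression_through_origin(self):
        import statsmodels.api as sm

        g = np.array([0.10, 0.20, 0.30])
        G = np.array([0.05, 0.12, 0.14])
        sy = np.array([0.01, 0.01, 0.01])
        hset = hset_from_arrays(g, 0.01, G, sy)
        fit = est.ivw(hset)
        oracle = sm.WLS(G, g[:, None], weights=1 / sy**2).fit()
        assert fit.beta == pytest.approx(oracle.params[0], abs=1e-12)
        # multiplicative random effects = WLS's estimated residual scale
        # (this toy has Q/(J-1) > 1, so the inflation floor is inactive)
        assert fit.extras["Q"] / 2 > 1
        assert fit.se == pytest.approx(oracle.bse[0], abs=1e-12)

    def test_equals_inverse_variance_weighted_mean_of_ratios(self, rng):
        """Algebraic identity: fixed-effect IVW is the weighted mean of the
        Wald ratios with weights gamma^2/sigma_Y^2."""
        for _ in range(20):
            J = int(rng.integers(2, 30))
            g = rng.normal(0, 0.05, J)
            g[np.abs(g) < 1e-3] = 1e-3
            G = rng.normal(0, 0.05, J)
            sy = rng.uniform(0.005, 0.05, J)
            fit = est.ivw(hset_from_arrays(g, 0.01, G, sy), model="fixed")
            w = g**2 / sy**2
            assert fit.beta == pytest.approx(np.sum(w * (G / g)) / np.sum(w), abs=1e-10)

    def test_ci_brackets_estimate(self, smoking_like_study):
        fit = est.ivw(hset_from_study(smoking_like_study))
        assert fit.ci_low < fit.beta < fit.ci_high
        assert fit.or_ci_low == pytest.approx(np.exp(fit.ci_low))
        assert 0 < fit.pvalue <= 1


class TestEgger:
    def test_exact_line_recovered(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        hset = hset_from_arrays(g, 0.01, 0.01 + 0.5 * g, 0.02)
        fit = est.egger(hset)
        assert fit.extras["intercept"] == pytest.approx(0.01, abs=1e-12)
        assert fit.beta == pytest.approx(0.5, abs=1e-12)
        assert fit.extras["Q_prime"] == pytest.approx(0.0, abs=1e-18)

    def test_requires_three_instruments(self):
        hset = hset_from_arrays([0.1, 0.2], 0.01, [0.05, 0.1], 0.02)
        with pytest.raises(ValueError, match=">=3"):
            est.egger(hset)

    def test_matches_statsmodels_wls_oracle(self):
        import statsmodels.api as sm

        g = np.array([0.10, 0.15, 0.22, 0.30, 0.41])
        G = np.array([0.08, 0.02, 0.19, 0.11, 0.30])
        sy = np.array([0.02, 0.03, 0.02, 0.04, 0.03])
        fit = est.egger(hset_from_arrays(g, 0.01, G, sy))
        oracle = sm.WLS(G, sm.add_constant(g), weights=1 / sy**2).fit()
        assert fit.extras["intercept"] == pytest.approx(oracle.params[0], abs=1e-10)
        assert fit.beta == pytest.approx(oracle.params[1], abs=1e-10)
        assert fit.extras["Q_prime"] / 3 > 1  # inflation floor inactive here
        assert fit.extras["intercept_se"] == pytest.approx(oracle.bse[0], abs=1e-10)
        assert fit.se == pytest.approx(oracle.bse[1], abs=1e-10)
        assert fit.pvalue == pytest.approx(oracle.pvalues[1], abs=1e-10)

    def test_se_floor_prevents_deflation(self):
        # near-exact line: Q'/(J-2) << 1, so SEs keep the unscaled value
        g = np.array([0.1, 0.2, 0.3, 0.4])
        G = 0.01 + 0.5 * g + np.array([1e-6, -1e-6, 1e-6, -1e-6])
        fit = est.egger(hset_from_arrays(g, 0.01, G, 0.02))
        assert fit.extras["inflation"] == 1.0

    def test_balanced_pleiotropy_null_intercept(self):
        cfg = SimulationConfig(
            J=100, beta_true=0.3, tau=0.02, mu_alpha=0.0, frac_invalid=1.0, seed=42
        )
        fit = est.egger(hset_from_study(simulate_two_sample(cfg)))
        assert abs(fit.extras["intercept"]) < 3 * fit.extras["intercept_se"]


def _median_oracle(b, w):
    """Direct evaluation of the interpolation formula, written independently."""
    order = np.argsort(b)
    b, w = np.asarray(b, float)[order], np.asarray(w, float)[order]
    s = []
    total = w.sum()
    running = 0.0
    for wj in w:
        running += wj
        s.append((running - wj / 2) / total)
    # piecewise-linear inverse CDF at 0.5
    for i in range(len(s) - 1):
        if s[i] <= 0.5 <= s[i + 1]:
            t = (0.5 - s[i]) / (s[i + 1] - s[i])
            return b[i] + t * (b[i + 1] - b[i])
    return b[0] if 0.5 < s[0] else b[-1]


class TestWeightedMedian:
    def test_median_of_odd_equal_weight_set(self):
        assert est.weighted_median_point(np.array([1.0, 2.0, 9.0]), np.ones(3)) == 2.0

    def test_constant_ratios_for_any_weights(self, rng):
        w = rng.uniform(0.1, 5, 7)
        assert est.weighted_median_point(np.full(7, 1.3), w) == pytest.approx(1.3)

    def test_matches_interpolation_oracle(self, rng):
        for _ in range(25):
            b = rng.normal(0, 1, 5)
            w = rng.uniform(0.2, 3.0, 5)
            assert est.weighted_median_point(b, w) == pytest.approx(
                _median_oracle(b, w), abs=1e-10
            )

    def test_full_estimator_contract(self, smoking_like_study):
        hset = hset_from_study(smoking_like_study)
        fit = est.weighted_median(hset, n_boot=200, seed=5)
        assert fit.ci_low < fit.beta < fit.ci_high
        assert fit.n_variants == 150
        again = est.weighted_median(hset, n_boot=200, seed=5)
        assert fit.beta == again.beta and fit.se == again.se  # seeded determinism
        with pytest.raises(ValueError, match="seed"):
            est.weighted_median(hset, n_boot=200)
        with pytest.raises(ValueError, match="n_boot"):
            est.weighted_median(hset, n_boot=50, seed=1)


class TestWeightedMode:
    def test_dominant_cluster_wins(self):
        b = np.array([2.0, 2.0, 2.0, 7.0])
        assert est.weighted_mode_point(b, np.ones(4)) == pytest.approx(2.0, abs=0.05)

    def test_constant_ratios(self):
        assert est.weighted_mode_point(np.full(5, 0.7), np.ones(5)) == 0.7

    def test_requires_three_instruments(self):
        hset = hset_from_arrays([0.1, 0.2], 0.01, [0.05, 0.1], 0.02)
        with pytest.raises(ValueError, match=">=3"):
            est.weighted_mode(hset, seed=1)

    def test_beats_ivw_with_thirty_percent_invalid(self):
        """With a 70% valid cluster, the mode's average error is smaller
        than IVW's (directional pleiotropy drags IVW off target)."""
        errs_mode, errs_ivw = [], []
        for s in range(200):
            cfg = SimulationConfig(
                J=10, beta_true=0.3, rho2_gx=0.10, tau=0.02, mu_alpha=0.3,
                frac_invalid=0.3, seed=6000 + s,
            )
            hset = hset_from_study(simulate_two_sample(cfg))
            g = np.array([i.gamma for i in hset.instruments])
            G = np.array([i.Gamma for i in hset.instruments])
            sy = np.array([i.sigma_y for i in hset.instruments])
            errs_ivw.append(abs(est.ivw(hset).beta - 0.3))
            errs_mode.append(
                abs(est.weighted_mode_point(G / g, (g / sy) ** 2) - 0.3)
            )
        assert np.mean(errs_mode) < np.mean(errs_ivw)


class TestSharedProperties:
    @pytest.fixture()
    def toy(self, rng):
        g = rng.normal(0.15, 0.04, 12)
        G = rng.normal(0.05, 0.03, 12)
        sy = rng.uniform(0.01, 0.04, 12)
        return g, G, sy

    def test_scale_equivariance(self, toy):
        """Multiplying every outcome beta and SE by c scales beta and SE by c."""
        g, G, sy = toy
        c = 3.7
        for method in (est.ivw, est.egger):
            a = method(hset_from_arrays(g, 0.01, G, sy))
            b = method(hset_from_arrays(g, 0.01, c * G, c * sy))
            assert b.beta == pytest.approx(c * a.beta, rel=1e-10)
            assert b.se == pytest.approx(c * a.se, rel=1e-10)
        w = (g / sy) ** 2  # ratio weights are scale-invariant
        assert est.weighted_median_point(c * G / g, w / c**2) == pytest.approx(
            c * est.weighted_median_point(G / g, w), rel=1e-10
        )

    def test_orientation_invariance(self, toy):
        """Sign-flipping any instrument's (gamma, Gamma) pair leaves IVW,
        weighted median and weighted mode untouched."""
        g, G, sy = toy
        flip = np.ones_like(g)
        flip[::3] = -1
        a = hset_from_arrays(g, 0.01, G, sy)
        b = hset_from_arrays(flip * g, 0.01, flip * G, sy)
        assert est.ivw(a).beta == pytest.approx(est.ivw(b).beta, abs=1e-14)
        w = (g / sy) ** 2
        assert est.weighted_median_point(G / g, w) == est.weighted_median_point(
            (flip * G) / (flip * g), w
        )
        assert est.weighted_mode_point(G / g, w) == est.weighted_mode_point(
            (flip * G) / (flip * g), w
        )

    def test_all_estimators_consistent_without_pleiotropy(self):
        """Mean point estimate over 500 clean replicates is within two
        Monte-Carlo SEs of the true effect, for all four estimators."""
        true = 0.3
        res = {"ivw": [], "egger": [], "median": [], "mode": []}
        for s in range(500):
            study = simulate_two_sample(
                SimulationConfig(J=150, beta_true=true, seed=5000 + s)
            )
            hset = hset_from_study(study)
            g = study.exposure["beta"].to_numpy()
            G = study.outcome["beta"].to_numpy()
            sy = study.outcome["se"].to_numpy()
            res["ivw"].append(est.ivw(hset).beta)
            res["egger"].append(est.egger(hset).beta)
            rw = (g / sy) ** 2
            res["median"].append(est.weighted_median_point(G / g, rw))
            res["mode"].append(est.weighted_mode_point(G / g, rw))
        for name, vals in res.items():
            vals = np.array(vals)
            mcse = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - true) < 2 * mcse, name
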