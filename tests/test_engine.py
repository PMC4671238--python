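"""Hierarchical MC: HD distributions, incidence curves, nested population MC."""

import numpy as np
import pytest
from scipy import integrate, stats

import probdose as pb
from probdose._random import substream


def _const(x, n=100):
    return np.full(n, float(x))


class TestHdMedian:
    def test_point_mass_arithmetic(self):
        out = pb.hd_median_samples(_const(10), _const(0.1), _const(2), _const(1))
        assert np.allclose(out, 0.5)

    def test_identity_factors(self):
        ad = np.random.default_rng(0).lognormal(1, 0.3, 200)
        out = pb.hd_median_samples(ad, _const(1, 200), _const(1, 200), _const(1, 200))
        assert np.array_equal(out, ad)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pb.hd_median_samples(_const(1, 5), _const(1, 6), _const(1, 5), _const(1, 5))


class TestHdMi:
    def test_point_mass_chain(self):
        goal = pb.ProtectionGoal(m_star=0.05, i_star=0.01)
        res = pb.hd_mi_samples(_const(10), _const(0.1), _const(2), _const(1),
                               _const(0.746), goal)
        expected = 0.5 * np.exp(pb.z_score(0.01) * 0.746)
        assert np.allclose(res.hd_mi_samples, expected)
        assert expected == pytest.approx(0.0882, abs=2e-4)

    def test_median_incidence_collapses(self):
        rng = np.random.default_rng(1)
        ad = rng.lognormal(1, 0.4, 300)
        sig = rng.lognormal(-0.3, 0.3, 300)
        goal = pb.ProtectionGoal(m_star=0.05, i_star=0.5)
        res = pb.hd_mi_samples(ad, _const(1, 300), _const(1, 300), _const(1, 300),
                               sig, goal)
        assert np.array_equal(res.hd_mi_samples, res.hd_median_samples)

    def test_sensitive_below_median_elementwise(self):
        rng = np.random.default_rng(2)
        ad = rng.lognormal(1, 0.4, 300)
        sig = rng.lognormal(-0.3, 0.3, 300)
        goal = pb.ProtectionGoal(m_star=0.05, i_star=0.05)
        res = pb.hd_mi_samples(ad, _const(0.2, 300), _const(1, 300), _const(1, 300),
                               sig, goal)
        assert np.all(res.hd_mi_samples <= res.hd_median_samples)

    def test_rfd_is_lower_confidence_quantile(self):
        rng = np.random.default_rng(3)
        ad = rng.lognormal(1, 0.4, 5000)
        goal = pb.ProtectionGoal(m_star=0.05, i_star=0.01, confidence=0.95)
        res = pb.hd_mi_samples(ad, _const(1, 5000), _const(1, 5000), _const(1, 5000),
                               _const(0.7, 5000), goal)
        assert res.probabilistic_rfd == pytest.approx(
            np.quantile(res.hd_mi_samples, 0.05)
        )

    def test_goal_validation(self):
        with pytest.raises(pb.errors.ConfigError):
            pb.ProtectionGoal(m_star=0.05, i_star=0.7)


class TestIncidenceCurve:
    def test_half_at_median_dose(self):
        hd = _const(2.0, 50)
        sig = _const(0.5, 50)
        curve = pb.incidence_curve(hd, sig, np.array([2.0]))
        assert curve.p50[0] == pytest.approx(0.5)

    def test_quantile_dose_gives_target_incidence(self):
        rng = np.random.default_rng(4)
        hd = rng.lognormal(0, 0.3, 200)
        sig = rng.lognormal(-0.3, 0.2, 200)
        # per draw, the dose hd*exp(-1.645 sigma) has incidence 5%
        for j in (0, 17, 100):
            d = hd[j] * np.exp(-1.6449 * sig[j])
            z = (np.log(d) - np.log(hd[j])) / sig[j]
            assert stats.norm.cdf(z) == pytest.approx(0.05, abs=1e-4)

    def test_eq9_eq11_round_trip(self):
        # incidence evaluated at HD_M^I returns I* exactly, draw by draw
        rng = np.random.default_rng(5)
        ad = rng.lognormal(1, 0.4, 400)
        daf = rng.lognormal(-1.5, 0.1, 400)
        ahu = rng.lognormal(0, 0.69, 400)
        ou = np.ones(400)
        sig = rng.lognormal(-0.29, 0.46, 400)
        goal = pb.ProtectionGoal(m_star=0.05, i_star=0.01)
        res = pb.hd_mi_samples(ad, daf, ahu, ou, sig, goal)
        z = (np.log(res.hd_mi_samples) - np.log(res.hd_median_samples)) / sig
        inc = stats.norm.cdf(z)
        assert np.allclose(inc, 0.01, atol=1e-12)

    def test_bands_ordered_and_monotone(self):
        rng = np.random.default_rng(6)
        hd = rng.lognormal(0, 0.5, 300)
        sig = rng.lognormal(-0.3, 0.3, 300)
        grid = np.geomspace(0.01, 10, 40)
        c = pb.incidence_curve(hd, sig, grid)
        assert np.all(c.p5 <= c.p50 + 1e-12) and np.all(c.p50 <= c.p95 + 1e-12)
        for band in (c.p5, c.p50, c.p95):
            assert np.all(np.diff(band) >= -1e-12)

    def test_positive_grid_required(self):
        with pytest.raises(ValueError):
            pb.incidence_curve(_const(1), _const(0.5), np.array([0.0, 1.0]))


class TestPopulationIncidence:
    THETA = np.array([0.0, 0.10536, 1.0])

    def _ones(self, n):
        return np.ones(n)

    def test_sigma_zero_equals_median_curve(self):
        n = 20
        doses = np.geomspace(0.1, 10, 8)
        thetas = [self.THETA] * n
        curve = pb.population_incidence_stochastic(
            thetas, "weibull", self._ones(n), self._ones(n), self._ones(n),
            np.zeros(n), doses, n_inner=200, seed=1,
        )
        from probdose.families import extra_risk

        expected = extra_risk("weibull", self.THETA, doses)
        assert np.allclose(curve.p50, expected, rtol=1e-12)
        assert np.allclose(curve.p5, curve.p95)

    def test_zero_dose_zero_extra_risk(self):
        n = 10
        curve = pb.population_incidence_stochastic(
            [self.THETA] * n, "weibull", self._ones(n), self._ones(n),
            self._ones(n), np.full(n, 0.5), np.array([0.0, 1.0]), n_inner=200,
            seed=2,
        )
        assert curve.p5[0] == curve.p95[0] == 0.0

    def test_matches_quadrature_oracle(self):
        # <M_H(HD)> = int f(exp(z sigma) HD) phi(z) dz, via adaptive quadrature
        sigma, hd = 0.693, 1.0
        b, k = 0.10536, 1.0

        oracle, _ = integrate.quad(
            lambda z: (1 - np.exp(-b * (np.exp(z * sigma) * hd) ** k))
            * stats.norm.pdf(z),
            -8, 8,
        )
        n, n_inner = 3, 40_000
        curve = pb.population_incidence_stochastic(
            [self.THETA] * n, "weibull", self._ones(n), self._ones(n),
            self._ones(n), np.full(n, sigma), np.array([hd]), n_inner=n_inner,
            seed=3,
        )
        # MC standard error of the inner average
        z = substream(3, "inner_z").standard_normal(n_inner)
        vals = 1 - np.exp(-b * (np.exp(z * sigma) * hd) ** k)
        se = vals.std() / np.sqrt(n_inner)
        assert abs(curve.p50[0] - oracle) < 3 * se

    def test_inner_guard(self):
        with pytest.raises(ValueError):
            pb.population_incidence_stochastic(
                [self.THETA], "weibull", self._ones(1), self._ones(1),
                self._ones(1), np.zeros(1), np.array([1.0]), n_inner=50, seed=0,
            )

    def test_inner_seed_does_not_touch_uncertainty(self):
        # the variability inner loop must not re-pair uncertainty draws
        rng = np.random.default_rng(7)
        ad = rng.lognormal(0, 0.3, 50)
        goal = pb.ProtectionGoal(m_star=0.1, i_star=0.01)
        args = (ad, self._ones(50), self._ones(50), self._ones(50),
                np.full(50, 0.7), goal)
        r1 = pb.hd_mi_samples(*args)
        _ = pb.population_incidence_stochastic(
            [self.THETA] * 50, "weibull", self._ones(50), self._ones(50),
            self._ones(50), np.full(50, 0.7), np.array([1.0]), n_inner=200,
            seed=99,
        )
        r2 = pb.hd_mi_samples(*args)
        assert np.array_equal(r1.hd_mi_samples, r2.hd_mi_samples)


class TestScaleEquivariance:
    def test_dose_rescaling_scales_hdmi(self):
        # multiplying all doses by c multiplies every HD percentile by c
        spec = pb.EndpointSpec("stochastic_quantal", 0.10)
        goal = pb.ProtectionGoal(m_star=0.10, i_star=0.01)
        results = []
        for c in (1.0, 10.0):
            ds = pb.simulate_quantal_dataset(
                "weibull", [0.02, 0.001 / (c**1.2), 1.2],
                [0, 30 * c, 100 * c, 300 * c], 50, seed=42,
            )
            ad = pb.bootstrap_ad_samples(ds, spec, families=["weibull"],
                                         n_boot=100, seed=5)
            n = ad.samples.size
            cfg = pb.AdjustmentConfig(bw_animal=0.03)
            daf = pb.sample_daf(cfg, n, substream(5, "daf"))
            ahu = pb.sample_ahu(cfg, n, substream(5, "ahu"))
            ou = pb.sample_ou(cfg, n, substream(5, "ou"))
            sig = pb.sample_sigma_h(pb.VariabilitySpec(), n, substream(5, "sigma_h"))
            res = pb.hd_mi_samples(ad.samples, daf, ahu, ou, sig, goal)
            results.append(res.summary)
        for a, b in zip(results[0], results[1]):
            assert b == pytest.approx(10.0 * a, rel=1e-9)
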