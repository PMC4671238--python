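"""Model fitting, goodness of fit, and benchmark-dose computation."""

import numpy as np
import pytest
from scipy import stats

import probdose as pb
from probdose import errors
from probdose.models import GOF_THRESHOLD, ModelFit


def _shell(family, theta, kind, max_dose=10.0):
    theta = np.asarray(theta, dtype=float)
    if kind == "quantal":
        from probdose.families import quantal_probability

        bg = float(quantal_probability(family, theta, 0.0))
    else:
        from probdose.families import continuous_median

        bg = float(continuous_median(family, theta, 0.0))
    return ModelFit(family, theta, 0.0, 1.0, True, kind, bg, len(theta), max_dose)


class TestClosedFormBMD:
    def test_exponential_percent_change(self):
        fit = _shell("exponential", [100.0, 0.01, 1.0], "continuous")
        spec = pb.EndpointSpec("continuous", 0.05)
        assert pb.bmd_from_fit(fit, spec) == pytest.approx(np.log(1.05) / 0.01, rel=1e-9)

    def test_weibull_extra_risk(self):
        fit = _shell("weibull", [0.0, 0.10536, 1.0], "quantal")
        spec = pb.EndpointSpec("stochastic_quantal", 0.10)
        expected = -np.log(0.9) / 0.10536
        assert pb.bmd_from_fit(fit, spec) == pytest.approx(expected, rel=1e-9)

    def test_weibull_ed50(self):
        fit = _shell("weibull", [0.0, 0.10536, 1.0], "quantal")
        spec = pb.EndpointSpec("deterministic_quantal", None)
        assert pb.bmd_from_fit(fit, spec) == pytest.approx(np.log(2) / 0.10536, rel=1e-9)

    def test_extra_risk_invariant_to_background(self):
        # independent background cancels out of the extra-risk BMD
        spec = pb.EndpointSpec("stochastic_quantal", 0.10)
        b0 = pb.bmd_from_fit(_shell("weibull", [0.0, 0.2, 1.3], "quantal"), spec)
        b1 = pb.bmd_from_fit(_shell("weibull", [0.3, 0.2, 1.3], "quantal"), spec)
        assert b0 == pytest.approx(b1, rel=1e-9)

    def test_bmd_beyond_range(self):
        fit = _shell("weibull", [0.0, 1e-9, 1.0], "quantal", max_dose=1.0)
        with pytest.raises(errors.BMDRangeError):
            pb.bmd_from_fit(fit, pb.EndpointSpec("stochastic_quantal", 0.10))

    @pytest.mark.parametrize(
        "family,theta,kind,spec",
        [
            ("weibull", [0.05, 0.03, 1.4], "quantal",
             pb.EndpointSpec("stochastic_quantal", 0.05)),
            ("gamma", [0.02, 0.5, 2.0], "quantal",
             pb.EndpointSpec("stochastic_quantal", 0.10)),
            ("log_probit", [0.01, -3.0, 1.5], "quantal",
             pb.EndpointSpec("deterministic_quantal", None)),
            ("exponential", [200.0, -0.02, 1.0], "continuous",
             pb.EndpointSpec("continuous", 0.05)),
            ("hill", [100.0, 20.0, 1.6, 2.0], "continuous",
             pb.EndpointSpec("continuous", 0.10)),
        ],
    )
    def test_predict_reproduces_bmr_at_bmd(self, family, theta, kind, spec):
        from probdose.families import extra_risk

        fit = _shell(family, theta, kind, max_dose=50.0)
        bmd = pb.bmd_from_fit(fit, spec)
        if spec.endpoint_class is pb.EndpointClass.CONTINUOUS:
            f0 = pb.predict(fit, 0.0)
            rel = abs(pb.predict(fit, bmd) - f0) / f0
            assert rel == pytest.approx(spec.critical_effect_size, rel=1e-8)
        elif spec.endpoint_class is pb.EndpointClass.STOCHASTIC_QUANTAL:
            er = float(extra_risk(family, theta, bmd))
            assert er == pytest.approx(spec.critical_effect_size, rel=1e-8)
        else:
            assert pb.predict(fit, bmd) == pytest.approx(0.5, rel=1e-8)


class TestPredict:
    def test_background_at_zero(self, mouse_tumor_dataset):
        fit = pb.fit_quantal(mouse_tumor_dataset, "weibull")
        assert pb.predict(fit, 0.0) == pytest.approx(fit.background)

    def test_monotone_in_dose(self, mouse_tumor_dataset):
        fit = pb.fit_quantal(mouse_tumor_dataset, "log_logistic")
        doses = np.linspace(0, 300, 50)
        p = pb.predict(fit, doses)
        assert np.all(np.diff(p) >= -1e-12)

    def test_negative_dose_rejected(self, mouse_tumor_dataset):
        fit = pb.fit_quantal(mouse_tumor_dataset, "weibull")
        with pytest.raises(ValueError):
            pb.predict(fit, -1.0)

    def test_weibull_point_value(self):
        fit = _shell("weibull", [0.0, 0.10536, 1.0], "quantal")
        assert pb.predict(fit, 1.0) == pytest.approx(0.100, abs=5e-4)


class TestFitContinuous:
    def test_parameter_recovery_tiny_noise(self):
        ds = pb.simulate_continuous_dataset(
            "exponential", [100.0, 0.01, 1.0], [0, 2, 5, 10, 20], 40, cv=1e-4, seed=11
        )
        fit = pb.fit_continuous(ds, "exponential")
        a, b, g = fit.theta
        assert a == pytest.approx(100.0, rel=0.01)
        assert b * 20**g == pytest.approx(0.01 * 20, rel=0.01)  # effect at top dose

    def test_flat_data_no_effect(self):
        groups = [pb.ContinuousGroup(d, 20, 100.0, 0.5) for d in (0, 5, 10, 20)]
        ds = pb.DoseResponseDataset("flat", groups)
        fit = pb.fit_continuous(ds, "exponential")
        # fitted effect at the top dose is negligible -> BMD out of range
        f0, ftop = pb.predict(fit, 0.0), pb.predict(fit, 20.0)
        assert abs(ftop / f0 - 1) < 0.02
        with pytest.raises(errors.BMDRangeError):
            pb.bmd_from_fit(fit, pb.EndpointSpec("continuous", 0.05))

    def test_true_model_dominates_loglik(self):
        # Hill-generated data: the Hill fit cannot do worse than exponential
        ds = pb.simulate_continuous_dataset(
            "hill", [100.0, 10.0, 1.8, 2.0], [0, 2, 5, 10, 20, 50], 200, cv=0.05,
            seed=12,
        )
        ll_hill = pb.fit_continuous(ds, "hill").loglik
        ll_exp = pb.fit_continuous(ds, "exponential").loglik
        assert ll_hill >= ll_exp - 1e-6

    def test_requires_control(self):
        groups = [pb.ContinuousGroup(d, 10, 100.0, 5.0) for d in (1, 2, 4, 8)]
        ds = pb.DoseResponseDataset("noctrl", groups)
        with pytest.raises(errors.DatasetValidationError):
            pb.fit_continuous(ds, "exponential")

    def test_too_few_groups_for_hill(self):
        groups = [pb.ContinuousGroup(d, 10, 100.0 - d, 5.0) for d in (0, 5, 10)]
        ds = pb.DoseResponseDataset("small", groups)
        with pytest.raises(errors.FitError):
            pb.fit_continuous(ds, "hill")


class TestFitQuantal:
    def test_all_zero_affected(self):
        groups = [pb.QuantalGroup(d, 50, 0) for d in (0, 10, 30)]
        ds = pb.DoseResponseDataset("null", groups)
        fit = pb.fit_quantal(ds, "weibull")
        assert fit.background == pytest.approx(0.0, abs=1e-6)
        assert fit.at_boundary

    def test_weibull_recovery_large_n(self):
        ds = pb.simulate_quantal_dataset(
            "weibull", [0.0, 0.10536, 1.0], [0, 1, 3, 6, 12], 20_000, seed=13
        )
        fit = pb.fit_quantal(ds, "weibull")
        assert fit.theta[1] == pytest.approx(0.10536, rel=0.05)

    def test_saturated_two_parameter_model(self):
        groups = [pb.QuantalGroup(0, 50, 2), pb.QuantalGroup(5, 50, 10),
                  pb.QuantalGroup(20, 50, 30)]
        ds = pb.DoseResponseDataset("threept", groups)
        fit = pb.fit_quantal(ds, "weibull")  # 3 params on 3 groups
        assert fit.gof_p == 1.0
        assert fit.accepted


class TestGofPvalue:
    def test_deviance_to_pvalue(self, mouse_tumor_dataset):
        # chi-square tail oracle: deviance 5.99 on 2 df -> p ~= 0.050
        assert stats.chi2.sf(5.99, 2) == pytest.approx(0.050, abs=5e-4)
        fit = pb.fit_quantal(mouse_tumor_dataset, "weibull")
        df = len(mouse_tumor_dataset.groups) - fit.n_params
        # recompute the p-value from the fit's deviance independently
        y = np.array([g.affected for g in mouse_tumor_dataset.groups], float)
        n = mouse_tumor_dataset.ns.astype(float)
        r = np.clip(y / n, 1e-9, 1 - 1e-9)
        ll_sat = np.sum(y * np.log(r) + (n - y) * np.log1p(-r))
        dev = 2 * (ll_sat - fit.loglik)
        assert fit.gof_p == pytest.approx(float(stats.chi2.sf(dev, df)), rel=1e-9)

    def test_type_one_error_rate(self):
        # fitting the true model: rejection rate at the 0.05 screen ~= 5%
        n_sim = 2000
        rejections = 0
        for r in range(n_sim):
            ds = pb.simulate_quantal_dataset(
                "weibull", [0.05, 0.03, 1.0], [0, 5, 15, 40, 80], 250,
                seed=50_000 + r,
            )
            fit = pb.fit_quantal(ds, "weibull")
            rejections += fit.gof_p <= GOF_THRESHOLD
        rate = rejections / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < 3 * se


class TestQuantizeDuality:
    def test_quantal_ed50_matches_continuous_bmd(self):
        # dichotomizing a monotone continuous response at the M* cut point:
        # the fitted quantal ED50 estimates the continuous BMD at M*
        params = [100.0, 0.012, 1.0]
        mstar = 0.05
        true_bmd = np.log(1 + mstar) / 0.012
        ind = pb.simulate_continuous_individuals(
            "exponential", params, [0.25, 1, 2, 4, 8, 16], 3000, cv=0.10, seed=21
        )
        qds = pb.quantize_continuous(ind, 100.0 * (1 + mstar), "increase")
        fit = pb.fit_quantal(qds, "log_probit")
        ed50 = pb.bmd_from_fit(fit, pb.EndpointSpec("deterministic_quantal", None))
        assert ed50 == pytest.approx(true_bmd, rel=0.10)
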