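import numpy as np
import pytest
from scipy.integrate import quad

import nisurv as nv
from nisurv import KnotSet, flexpar_drmst, flexpar_ds, hr_estimate, ni_test
from nisurv.measures import Estimate

from conftest import make_ds


def exp_reduction_model(lam, beta=0.0, vscale=1e-4):
    """Exponential model embedded in the spline family (no internal knots)."""
    return nv.FlexParModel(
        knots=KnotSet(np.log(0.01), np.log(10.0)),
        gamma=np.array([np.log(lam), 1.0]),
        beta=beta,
        vcov=np.eye(3) * vscale,
        loglik=0.0,
        converged=True,
        n_events=100,
        n_total=100,
    )


class TestHrEstimate:
    def test_null_symmetric_on_log_scale(self, fitted_model):
        est = hr_estimate(fitted_model, alpha=0.025)
        assert est.value == pytest.approx(np.exp(fitted_model.beta))
        assert np.log(est.ci_high) - np.log(est.value) == pytest.approx(
            np.log(est.value) - np.log(est.ci_low)
        )

    def test_arithmetic_on_definition(self):
        model = exp_reduction_model(0.5, beta=np.log(2.0), vscale=0.01)
        est = hr_estimate(model, alpha=0.025)
        z = 1.959963984540054
        assert est.value == pytest.approx(2.0)
        assert est.ci_low == pytest.approx(2 * np.exp(-z * 0.1))
        assert est.ci_high == pytest.approx(2 * np.exp(z * 0.1))

    def test_unconverged_model_refused(self, fitted_model):
        import dataclasses

        bad = dataclasses.replace(fitted_model, converged=False)
        with pytest.raises(nv.ConvergenceError):
            hr_estimate(bad)


class TestFlexparDrmst:
    def test_zero_when_arms_identical(self):
        model = exp_reduction_model(0.7, beta=0.0)
        assert flexpar_drmst(model, 3.0).value == 0.0

    def test_exponential_closed_form_s90(self):
        lam = -np.log(0.9) / 3.0
        model = exp_reduction_model(lam, beta=np.log(2.0))
        want = -nv.match_margins(0.9, 2.0, 3.0).drmst
        assert flexpar_drmst(model, 3.0).value == pytest.approx(want, abs=1e-10)
        assert want == pytest.approx(-0.1424, abs=5e-5)

    def test_quadrature_matches_adaptive_integration(self):
        rng = np.random.default_rng(4)
        knots = KnotSet(np.log(0.05), np.log(8.0), (np.log(0.5), np.log(2.0)))
        for _ in range(20):
            gamma = np.array(
                [rng.normal(-1, 0.5), rng.uniform(0.5, 1.5), rng.normal(0, 0.05),
                 rng.normal(0, 0.05)]
            )
            beta = rng.normal(0, 0.5)
            model = nv.FlexParModel(
                knots=knots, gamma=gamma, beta=beta, vcov=np.eye(5) * 1e-4,
                loglik=0.0, converged=True, n_events=10, n_total=10,
            )
            got = flexpar_drmst(model, 3.0).value

            def diff(t):
                return nv.predict_survival(model, t, 1) - nv.predict_survival(
                    model, t, 0
                )

            want, _ = quad(diff, 0.0, 3.0, limit=200, epsabs=1e-12, epsrel=1e-12)
            assert got == pytest.approx(want, abs=1e-8)

    def test_se_positive_and_finite(self, fitted_model):
        est = flexpar_drmst(fitted_model, 3.0)
        assert np.isfinite(est.se) and est.se > 0


class TestFlexparDs:
    @pytest.mark.parametrize(
        "s, want", [(0.9, -0.09), (0.2, -0.16)]
    )
    def test_exponential_closed_form(self, s, want):
        lam = -np.log(s) / 3.0
        model = exp_reduction_model(lam, beta=np.log(2.0))
        assert flexpar_ds(model, 3.0).value == pytest.approx(want, abs=1e-10)

    def test_zero_when_arms_identical(self):
        model = exp_reduction_model(0.3, beta=0.0)
        assert flexpar_ds(model, 3.0).value == 0.0


class TestArmSwapSymmetry:
    def test_swap_negates_differences_inverts_hr(self, exp_trial_tau):
        swapped = nv.SurvivalDataset(
            exp_trial_tau.time, exp_trial_tau.event, 1 - exp_trial_tau.arm
        )
        m1 = nv.fit_flexpar(exp_trial_tau)
        m2 = nv.fit_flexpar(swapped)
        assert m2.beta == pytest.approx(-m1.beta, abs=1e-5)
        assert m2.se_log_hr == pytest.approx(m1.se_log_hr, rel=1e-4)
        d1, d2 = flexpar_drmst(m1, 3.0), flexpar_drmst(m2, 3.0)
        assert d2.value == pytest.approx(-d1.value, abs=1e-6)
        assert d2.se == pytest.approx(d1.se, rel=1e-3)
        s1, s2 = flexpar_ds(m1, 3.0), flexpar_ds(m2, 3.0)
        assert s2.value == pytest.approx(-s1.value, abs=1e-6)


class TestFlexVsNonparConvergence:
    def test_agree_on_large_ph_data(self):
        design = nv.TrialDesign(s3_control=0.6, n_per_arm=20000, true_hr=1.5)
        ds = nv.censor_at(nv.simulate_trial(nv.SimSpec(design=design, seed=21)), 3.0)
        model = nv.fit_flexpar(ds)
        fd = flexpar_drmst(model, 3.0)
        nd = nv.nonpar_drmst(ds, 3.0)
        assert abs(fd.value - nd.value) < 3 * np.hypot(fd.se, nd.se)
        fs = flexpar_ds(model, 3.0)
        ns = nv.nonpar_ds(ds, 3.0)
        assert abs(fs.value - ns.value) < 3 * np.hypot(fs.se, ns.se)


def _estimate(measure, value, se, scale, alpha=0.025):
    z = 1.959963984540054
    if scale == "log":
        lo, hi = value * np.exp(-z * se), value * np.exp(z * se)
    else:
        lo, hi = value - z * se, value + z * se
    return Estimate(
        measure=measure, method="flexpar", value=value, se=se, scale=scale,
        ci_low=lo, ci_high=hi, alpha=alpha, tau=3.0,
    )


class TestNiTest:
    def test_hr_reject(self):
        res = ni_test(_estimate("HR", 1.0, 0.1, "log"), margin=2.0)
        assert res.z == pytest.approx(np.log(2) / 0.1)
        assert res.reject_null

    def test_drmst_boundary_of_null(self):
        res = ni_test(_estimate("DRMST", -0.143, 0.05, "identity"), margin=0.143)
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert not res.reject_null

    def test_ds_reject(self):
        res = ni_test(_estimate("DS", 0.0, 0.02, "identity"), margin=0.09)
        assert res.z == pytest.approx(4.5)
        assert res.reject_null

    def test_superiority_margins(self):
        assert ni_test(_estimate("HR", 0.5, 0.1, "log"), margin=1.0).reject_null
        assert not ni_test(_estimate("DRMST", 0.01, 0.05, "identity"), margin=0.0).reject_null

    def test_scale_mismatch_rejected(self):
        with pytest.raises(nv.InputError):
            ni_test(_estimate("HR", 1.0, 0.1, "identity"), margin=2.0)
        with pytest.raises(nv.InputError):
            ni_test(_estimate("DS", 0.0, 0.1, "log"), margin=0.05)

    def test_invalid_margins_rejected(self):
        with pytest.raises(nv.InputError):
            ni_test(_estimate("HR", 1.0, 0.1, "log"), margin=0.8)
        with pytest.raises(nv.InputError):
            ni_test(_estimate("DRMST", 0.0, 0.1, "identity"), margin=-0.1)

    def test_degenerate_se_decided_by_sign(self):
        est = Estimate(
            measure="DS", method="nonparametric", value=0.0, se=0.0,
            scale="identity", ci_low=0.0, ci_high=0.0, alpha=0.025, tau=3.0,
        )
        assert ni_test(est, margin=0.05).reject_null
        assert not ni_test(est, margin=0.0).reject_null
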