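import numpy as np
import pytest

import nisurv as nv
from nisurv import (
    ConvergenceError,
    FittingError,
    KnotSet,
    fit_flexpar,
    log_likelihood,
    place_knots,
    predict_survival,
    rcs_basis,
)

from conftest import make_ds


class TestPlaceKnots:
    def test_hand_set(self):
        t = np.exp([0.0, 1.0, 2.0, 3.0])
        ds = make_ds(t, [1, 1, 1, 1], [0, 0, 1, 1])
        ks = place_knots(ds, n_internal=2)
        assert ks.boundary_low == 0.0 and ks.boundary_high == 3.0
        assert ks.internal == pytest.approx((1.0, 2.0))  # 33%/67% quantiles

    def test_no_internal_knots(self):
        ds = make_ds([1.0, 2.0, 3.0], [1, 1, 1], [0, 0, 1])
        ks = place_knots(ds, n_internal=0)
        assert ks.internal == ()

    def test_censored_times_ignored(self):
        ds = make_ds([1, 2, 3, 4, 100.0], [1, 1, 1, 1, 0], [0, 0, 1, 1, 1])
        ks = place_knots(ds)
        assert ks.boundary_high == pytest.approx(np.log(4.0))

    def test_too_few_distinct_event_times(self):
        ds = make_ds([1, 1, 1, 2], [1, 1, 1, 1], [0, 0, 1, 1])
        with pytest.raises(FittingError, match="fewer"):
            place_knots(ds, n_internal=2)

    def test_quantile_collapsing_onto_boundary(self):
        t = np.exp([0, 0, 0, 0, 0, 1, 2, 3.0])
        ds = make_ds(t, [1] * 8, [0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(FittingError):
            place_knots(ds, n_internal=2)


class TestRcsBasis:
    knots = KnotSet(0.0, 3.0, (1.0, 2.0))

    def test_below_boundary_is_linear_only(self):
        B, D = rcs_basis([-1.0], self.knots)
        assert B[0] == pytest.approx([1.0, -1.0, 0.0, 0.0])
        assert D[0] == pytest.approx([0.0, 1.0, 0.0, 0.0])

    def test_linear_beyond_upper_boundary(self):
        # the derivative of every basis column is constant above k_max
        _, d1 = rcs_basis([3.5], self.knots)
        _, d2 = rcs_basis([5.0], self.knots)
        assert d1 == pytest.approx(d2)

    def test_derivative_matches_finite_differences(self):
        xs = np.linspace(-0.5, 3.5, 41)
        h = 1e-5
        Bp, _ = rcs_basis(xs + h, self.knots)
        Bm, _ = rcs_basis(xs - h, self.knots)
        _, D = rcs_basis(xs, self.knots)
        assert np.allclose((Bp - Bm) / (2 * h), D, atol=1e-6)

    def test_continuity_at_knots(self):
        eps = 1e-9
        for k in (0.0, 1.0, 2.0, 3.0):
            Bl, Dl = rcs_basis([k - eps], self.knots)
            Br, Dr = rcs_basis([k + eps], self.knots)
            assert np.allclose(Bl, Br, atol=1e-6)
            assert np.allclose(Dl, Dr, atol=1e-6)


class TestLogLikelihood:
    def test_exponential_closed_form(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(2.0, 30)
        e = rng.integers(0, 2, 30)
        ds = make_ds(t, e, [0] * 15 + [1] * 15)
        knots = KnotSet(np.log(t.min()) - 0.1, np.log(t.max()) + 0.1)
        lam = 0.7
        got = log_likelihood([np.log(lam), 1.0], 0.0, ds, knots)
        want = float(np.sum(e * np.log(lam) - lam * t))
        assert got == pytest.approx(want, rel=1e-12)

    def test_single_subject_unit_value(self):
        ds = make_ds([1.0], [1], [0])
        knots = KnotSet(-1.0, 1.0)
        assert log_likelihood([0.0, 1.0], 0.0, ds, knots) == pytest.approx(-1.0)

    def test_three_subject_hand_oracle(self):
        # gamma=(ln 2, 1), beta=ln 1.5: H(t|arm) = 2 t * 1.5^arm
        ds = make_ds([0.5, 1.0, 2.0], [1, 0, 1], [0, 0, 1])
        knots = KnotSet(np.log(0.5), np.log(2.0))
        lam, hr = 2.0, 1.5
        want = (
            (np.log(lam) - lam * 0.5)  # control event at 0.5
            + (-lam * 1.0)  # control censored at 1
            + (np.log(lam * hr) - lam * hr * 2.0)  # research event at 2
        )
        got = log_likelihood([np.log(lam), 1.0], np.log(hr), ds, knots)
        assert got == pytest.approx(want, rel=1e-12)

    def test_non_monotone_spline_is_minus_inf(self):
        ds = make_ds([1.0], [1], [0])
        knots = KnotSet(-1.0, 1.0)
        assert log_likelihood([0.0, -1.0], 0.0, ds, knots) == -np.inf


class TestFit:
    def test_null_beta_within_three_se(self, fitted_model):
        assert abs(fitted_model.beta) < 3 * fitted_model.se_log_hr

    def test_deterministic_refit(self, exp_trial_tau):
        a = fit_flexpar(exp_trial_tau)
        b = fit_flexpar(exp_trial_tau)
        assert a.theta == pytest.approx(b.theta, abs=0.0)

    def test_control_survival_recovered(self):
        design = nv.TrialDesign(s3_control=0.6, n_per_arm=2000, true_hr=1.0)
        ds = nv.simulate_trial(nv.SimSpec(design=design, seed=42))
        model = fit_flexpar(ds)
        assert predict_survival(model, 3.0, arm=0) == pytest.approx(0.6, abs=0.03)

    def test_weibull_reduction_recovers_shape_scale(self):
        rng = np.random.default_rng(11)
        shape, scale = 1.5, 2.0
        t = scale * rng.weibull(shape, size=3000)
        ds = make_ds(t, [1] * 3000, [0] * 1500 + [1] * 1500)
        model = fit_flexpar(ds, n_internal=0)
        # ln H(t) = gamma0 + gamma1 ln t  <=>  H(t) = (t/scale)^shape
        assert model.gamma[1] == pytest.approx(shape, rel=0.05)
        assert model.gamma[0] == pytest.approx(-shape * np.log(scale), rel=0.05)

    def test_nested_model_dominance(self, exp_trial_tau, fitted_model):
        # the spline fit cannot be beaten by the exponential submodel
        lam = exp_trial_tau.n_events / exp_trial_tau.time.sum()
        gamma_exp = np.array([np.log(lam), 1.0, 0.0, 0.0])
        ll_exp = log_likelihood(gamma_exp, 0.0, exp_trial_tau, fitted_model.knots)
        assert fitted_model.loglik >= ll_exp - 1e-6

    def test_vcov_symmetric_psd(self, fitted_model):
        v = fitted_model.vcov
        assert np.allclose(v, v.T)
        assert np.all(np.linalg.eigvalsh(v) > 0)

    def test_cox_agreement(self):
        import lifelines

        design = nv.TrialDesign(s3_control=0.6, n_per_arm=1000, true_hr=1.3)
        ds = nv.censor_at(nv.simulate_trial(nv.SimSpec(design=design, seed=9)), 3.0)
        model = fit_flexpar(ds)
        cph = lifelines.CoxPHFitter()
        cph.fit(ds.to_frame(), duration_col="time", event_col="event")
        beta_cox = float(cph.params_["arm"])
        se_cox = float(cph.standard_errors_["arm"])
        assert abs(model.beta - beta_cox) < 0.02 * se_cox
        assert abs(model.se_log_hr - se_cox) < 0.02 * se_cox

    def test_single_arm_refused(self):
        ds = make_ds([1, 2, 3], [1, 1, 1], [0, 0, 0])
        with pytest.raises(nv.InputError):
            fit_flexpar(ds)

    def test_no_event_arm_warns(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1.0, 60)
        ds = make_ds(
            np.concatenate([t, np.full(30, 5.0)]),
            [1] * 60 + [0] * 30,
            [0] * 60 + [1] * 30,
        )
        with pytest.warns(UserWarning, match="no events"):
            try:
                fit_flexpar(ds, n_internal=0)
            except ConvergenceError:
                pass  # fine: failing loudly is the contract


class TestPredictSurvival:
    def test_ph_ordering_and_monotonicity(self, fitted_model):
        grid = np.linspace(0.05, 5.0, 80)
        s0 = predict_survival(fitted_model, grid, arm=0)
        s1 = predict_survival(fitted_model, grid, arm=1)
        assert np.all(np.diff(s0) <= 1e-12)
        if fitted_model.beta > 0:
            assert np.all(s1 <= s0)
        else:
            assert np.all(s1 >= s0)

    def test_exponential_closed_form(self):
        lam = 0.5
        model = nv.FlexParModel(
            knots=KnotSet(np.log(0.01), np.log(10.0)),
            gamma=np.array([np.log(lam), 1.0]),
            beta=0.0,
            vcov=np.eye(3) * 1e-4,
            loglik=0.0,
            converged=True,
            n_events=1,
            n_total=1,
        )
        for t in (0.5, 1.0, 3.0):
            assert predict_survival(model, t, 0) == pytest.approx(np.exp(-lam * t))

    def test_nonpositive_time_rejected(self, fitted_model):
        with pytest.raises(nv.InputError):
            predict_survival(fitted_model, 0.0, arm=0)
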