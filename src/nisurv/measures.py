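"""Population-level summary measures with delta-method inference.

Three measures compare the research arm (A) with the control arm (C):

* HR — hazard ratio ``h_A(t) / h_C(t)``, constant under proportional
  hazards; inference on the log scale.
* DRMST(tau) — difference in restricted mean survival time,
  ``int_0^tau S_A - int_0^tau S_C``; identity scale.
* DS(tau) — difference in survival probability at the horizon,
  ``S_A(tau) - S_C(tau)``; identity scale.

All three are simple functionals of a fitted flexible parametric
proportional-hazards model; their standard errors propagate the joint
parameter covariance through the functional by the delta method.
One-sided Wald tests against a non-inferiority margin (margin HR = 1 or
margin loss = 0 recovers a superiority test) complete the module.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .flexpar import ConvergenceError, FlexParModel, rcs_basis
from .survdata import InputError

__all__ = [
    "NumericError",
    "Estimate",
    "TestResult",
    "hr_estimate",
    "flexpar_drmst",
    "flexpar_ds",
    "ni_test",
    "bootstrap_drmst_se",
]


class NumericError(RuntimeError):
    """A numerical post-processing step produced a non-finite result."""


@dataclass(frozen=True)
class Estimate:
    """A summary-measure point estimate with its Wald interval.

    ``se`` lives on ``scale`` ("log" for HR, "identity" otherwise) while
    ``value`` and the confidence limits are always on the natural scale.
    The interval is two-sided at level ``1 - 2*alpha`` so that each tail
    matches the one-sided test level ``alpha``.
    """

    measure: str  # "HR" | "DRMST" | "DS"
    method: str  # "flexpar" | "nonparametric"
    value: float
    se: float
    scale: str  # "log" | "identity"
    ci_low: float
    ci_high: float
    alpha: float
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.measure not in ("HR", "DRMST", "DS"):
            raise InputError(f"unknown measure {self.measure!r}")
        if self.se < 0 or not np.isfinite(self.se):
            raise NumericError(f"invalid standard error {self.se!r}")
        if not self.ci_low <= self.value <= self.ci_high:
            raise NumericError("confidence interval does not bracket the estimate")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a one-sided non-inferiority (or superiority) Wald test."""

    estimate: Estimate
    margin: float
    alpha: float
    z: float
    reject_null: bool


def _wald_ci(value: float, se: float, alpha: float) -> tuple[float, float]:
    z = norm.ppf(1 - alpha)
    return value - z * se, value + z * se


def hr_estimate(model: FlexParModel, alpha: float = 0.025) -> Estimate:
    """Hazard ratio ``exp(beta)`` with a log-scale Wald interval."""
    _require_converged(model)
    se = model.se_log_hr
    lo, hi = _wald_ci(model.beta, se, alpha)
    return Estimate(
        measure="HR",
        method="flexpar",
        value=model.hr,
        se=se,
        scale="log",
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        alpha=alpha,
    )


def _require_converged(model: FlexParModel) -> None:
    if not model.converged:
        raise ConvergenceError("model did not converge; refusing to summarise")


@functools.lru_cache(maxsize=None)
def _gauss_legendre(order: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(order)


def _survival_from_theta(theta: np.ndarray, model: FlexParModel, t: np.ndarray, arm: int):
    B, _ = rcs_basis(np.log(t), model.knots)
    eta = B @ theta[:-1] + theta[-1] * arm
    return np.exp(-np.exp(np.clip(eta, -700.0, 700.0)))


def _drmst_value(theta: np.ndarray, model: FlexParModel, tau: float, order: int) -> float:
    # Fixed-order Gauss-Legendre after substituting t = tau * u^2, which
    # absorbs the t^p behaviour of the survival difference near t = 0 (p is
    # the spline slope in log time and can drop below 1).
    nodes, weights = _gauss_legendre(order)
    u = 0.5 * (nodes + 1.0)
    w = 0.5 * weights * 2.0 * tau * u
    t = tau * u**2
    diff = _survival_from_theta(theta, model, t, 1) - _survival_from_theta(
        theta, model, t, 0
    )
    return float(w @ diff)


def _ds_value(theta: np.ndarray, model: FlexParModel, tau: float) -> float:
    t = np.array([tau])
    return float(
        _survival_from_theta(theta, model, t, 1)[0]
        - _survival_from_theta(theta, model, t, 0)[0]
    )


def _delta_se(fn, theta: np.ndarray, vcov: np.ndarray) -> float:
    """Delta-method SE with central finite-difference gradient.

    Per-parameter step ``max(1e-5, 1e-4 * |theta_j|)``.
    """
    grad = np.empty(theta.size)
    for j in range(theta.size):
        h = max(1e-5, 1e-4 * abs(theta[j]))
        up, dn = theta.copy(), theta.copy()
        up[j] += h
        dn[j] -= h
        grad[j] = (fn(up) - fn(dn)) / (2.0 * h)
    if not np.all(np.isfinite(grad)):
        raise NumericError("non-finite delta-method gradient")
    var = float(grad @ vcov @ grad)
    if not np.isfinite(var) or var < 0:
        raise NumericError(f"invalid delta-method variance {var!r}")
    return float(np.sqrt(var))


def flexpar_drmst(
    model: FlexParModel, tau: float, alpha: float = 0.025, order: int = 64
) -> Estimate:
    """Model-based DRMST(tau) by fixed-order Gauss-Legendre quadrature.

    Order 64 is far beyond what the smooth integrand needs and is kept
    fixed for reproducibility.
    """
    _require_converged(model)
    if not tau > 0:
        raise InputError("tau must be positive")
    theta = model.theta
    value = _drmst_value(theta, model, tau, order)
    if model.beta == 0.0:
        value = 0.0  # identical arms: integrand is exactly zero
    se = _delta_se(lambda th: _drmst_value(th, model, tau, order), theta, model.vcov)
    lo, hi = _wald_ci(value, se, alpha)
    return Estimate(
        measure="DRMST",
        method="flexpar",
        value=value,
        se=se,
        scale="identity",
        ci_low=lo,
        ci_high=hi,
        alpha=alpha,
        tau=tau,
    )


def flexpar_ds(model: FlexParModel, tau: float, alpha: float = 0.025) -> Estimate:
    """Model-based DS(tau) = S(tau|research) - S(tau|control)."""
    _require_converged(model)
    if not tau > 0:
        raise InputError("tau must be positive")
    theta = model.theta
    value = _ds_value(theta, model, tau)
    if model.beta == 0.0:
        value = 0.0
    se = _delta_se(lambda th: _ds_value(th, model, tau), theta, model.vcov)
    lo, hi = _wald_ci(value, se, alpha)
    return Estimate(
        measure="DS",
        method="flexpar",
        value=value,
        se=se,
        scale="identity",
        ci_low=lo,
        ci_high=hi,
        alpha=alpha,
        tau=tau,
    )


def ni_test(est: Estimate, margin: float, alpha: float | None = None) -> TestResult:
    """One-sided Wald test of non-inferiority at level ``alpha``.

    ``margin`` is expressed on the measure's natural scale as a positive
    tolerable loss: a ratio > 1 for HR, an absolute loss >= 0 for DRMST and
    DS (internally the null region for the differences is ``value <=
    -margin``). ``margin = 1`` (HR) or ``0`` (differences) turns the test
    into a superiority test.
    """
    if alpha is None:
        alpha = est.alpha
    if est.measure == "HR":
        if est.scale != "log":
            raise InputError("HR estimate must carry a log-scale SE")
        if margin < 1:
            raise InputError("HR margin must be >= 1 (harm = higher hazard)")
        if est.value <= 0:
            raise InputError("HR estimate must be positive")
        num = np.log(margin) - np.log(est.value)
    else:
        if est.scale != "identity":
            raise InputError(f"{est.measure} estimate must carry an identity-scale SE")
        if margin < 0:
            raise InputError(f"{est.measure} margin must be >= 0 (tolerable loss)")
        num = est.value + margin
    if est.se > 0:
        z = float(num / est.se)
    else:  # degenerate: decided by the sign of the numerator
        z = float(np.inf if num > 0 else (-np.inf if num < 0 else 0.0))
    reject = bool(z > norm.ppf(1 - alpha))
    return TestResult(estimate=est, margin=margin, alpha=alpha, z=z, reject_null=reject)


def bootstrap_drmst_se(
    ds,
    tau: float,
    n_boot: int = 500,
    seed: int = 0,
    n_internal: int = 2,
    alpha: float = 0.025,
) -> float:
    """Non-parametric bootstrap SE of the model-based DRMST (utility only;
    the main analysis path uses the delta method)."""
    from .flexpar import fit_flexpar  # local import to avoid cycles at load

    rng = np.random.default_rng(seed)
    n = len(ds)
    values = []
    attempts = 0
    while len(values) < n_boot:
        attempts += 1
        if attempts > 10 * n_boot:
            raise ConvergenceError("bootstrap: too many non-convergent resamples")
        idx = rng.integers(0, n, size=n)
        from .survdata import SurvivalDataset

        boot = SurvivalDataset(ds.time[idx], ds.event[idx], ds.arm[idx])
        if boot.arms_present != {0, 1} or boot.n_events == 0:
            continue
        try:
            model = fit_flexpar(boot, n_internal=n_internal)
        except ConvergenceError:
            continue
        values.append(flexpar_drmst(model, tau, alpha).value)
    return float(np.std(values, ddof=1))
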