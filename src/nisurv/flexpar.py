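"""Flexible parametric proportional-hazards survival model.

The log cumulative hazard is modelled as a restricted (natural) cubic
spline in log time with a proportional arm effect::

    ln H(t | arm) = s(ln t; gamma) + beta * arm,
    S(t | arm)    = exp(-exp(ln H(t | arm))),

where ``s`` is linear in ``ln t`` beyond its boundary knots. With no
internal knots ``s`` is globally linear and the family reduces to the
Weibull; ``exp(beta)`` is the hazard ratio of research versus control.
Fitting is by full maximum likelihood; the covariance of all parameters
comes from the observed information at the optimum, so every summary
measure derived from the model inherits delta-method standard errors.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .survdata import InputError, SurvivalDataset

__all__ = [
    "FittingError",
    "ConvergenceError",
    "KnotSet",
    "FlexParModel",
    "place_knots",
    "rcs_basis",
    "log_likelihood",
    "fit_flexpar",
    "predict_survival",
]


class FittingError(RuntimeError):
    """Model cannot be set up or fitted on the given data."""


class ConvergenceError(FittingError):
    """The likelihood optimiser failed to converge after all restarts."""


@dataclass(frozen=True)
class KnotSet:
    """Spline knots on the log-time scale."""

    boundary_low: float
    boundary_high: float
    internal: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        ks = self.all_knots
        if not all(a < b for a, b in zip(ks, ks[1:])):
            raise FittingError(
                f"knots must be strictly increasing, got {ks}; "
                "try fewer internal knots"
            )

    @property
    def all_knots(self) -> tuple[float, ...]:
        return (self.boundary_low, *self.internal, self.boundary_high)

    @property
    def n_basis(self) -> int:
        """Number of spline coefficients: intercept, slope, one per internal knot."""
        return 2 + len(self.internal)


def place_knots(ds: SurvivalDataset, n_internal: int = 2) -> KnotSet:
    """Boundary knots at min/max log event time, internal knots at equally
    spaced quantiles (33%/67% for the default two internal knots) of the log
    uncensored times.

    Quantiles use the linear order-statistic interpolation convention
    (numpy's default).
    """
    if n_internal < 0:
        raise InputError("n_internal must be >= 0")
    t = ds.time[ds.event == 1]
    if np.unique(t).size < n_internal + 2:
        raise FittingError(
            f"only {np.unique(t).size} distinct uncensored times; "
            f"need at least {n_internal + 2} — try fewer internal knots"
        )
    x = np.log(t)
    lo, hi = float(x.min()), float(x.max())
    if n_internal == 0:
        return KnotSet(lo, hi)
    probs = np.arange(1, n_internal + 1) / (n_internal + 1)
    internal = tuple(float(q) for q in np.quantile(x, probs))
    return KnotSet(lo, hi, internal)


def rcs_basis(x, knots: KnotSet) -> tuple[np.ndarray, np.ndarray]:
    """Restricted cubic spline basis and its derivative at log-time ``x``.

    Returns ``(B, D)`` of shape ``(n, k)`` where the columns are
    ``(1, x, v_1(x), ..., v_m(x))`` and their derivatives. Each
    ``v_j(x) = (x-k_j)_+^3 - l_j (x-k_min)_+^3 - (1-l_j)(x-k_max)_+^3`` with
    ``l_j = (k_max-k_j)/(k_max-k_min)``, which makes the spline linear
    beyond the boundary knots.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    n, k = x.size, knots.n_basis
    B = np.empty((n, k))
    D = np.empty((n, k))
    B[:, 0] = 1.0
    B[:, 1] = x
    D[:, 0] = 0.0
    D[:, 1] = 1.0
    kmin, kmax = knots.boundary_low, knots.boundary_high
    span = kmax - kmin
    pmin = np.maximum(x - kmin, 0.0)
    pmax = np.maximum(x - kmax, 0.0)
    for j, kj in enumerate(knots.internal):
        lam = (kmax - kj) / span
        pj = np.maximum(x - kj, 0.0)
        B[:, 2 + j] = pj**3 - lam * pmin**3 - (1 - lam) * pmax**3
        D[:, 2 + j] = 3.0 * (pj**2 - lam * pmin**2 - (1 - lam) * pmax**2)
    return B, D


@dataclass
class FlexParModel:
    """A fitted spline-on-log-cumulative-hazard proportional-hazards model."""

    knots: KnotSet
    gamma: np.ndarray
    beta: float
    vcov: np.ndarray
    loglik: float
    converged: bool
    n_events: int
    n_total: int

    @property
    def theta(self) -> np.ndarray:
        """Stacked parameter vector ``(gamma, beta)`` matching ``vcov``."""
        return np.append(self.gamma, self.beta)

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def se_log_hr(self) -> float:
        return float(np.sqrt(self.vcov[-1, -1]))

    def summary(self) -> str:
        names = [f"gamma{j}" for j in range(len(self.gamma))] + ["beta"]
        se = np.sqrt(np.diag(self.vcov))
        lines = [
            f"FlexParModel: n={self.n_total}, events={self.n_events}, "
            f"loglik={self.loglik:.4f}, converged={self.converged}",
            f"{'param':<8}{'estimate':>12}{'se':>12}{'ci95_low':>12}{'ci95_high':>12}",
        ]
        for name, est, s in zip(names, self.theta, se):
            lines.append(
                f"{name:<8}{est:>12.5f}{s:>12.5f}"
                f"{est - 1.959964 * s:>12.5f}{est + 1.959964 * s:>12.5f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# likelihood

_PENALTY = 1e8
_PENALTY_W = 1e8


def _prepare(ds: SurvivalDataset, knots: KnotSet):
    logt = np.log(ds.time)
    B, D = rcs_basis(logt, knots)
    d = ds.event.astype(bool)
    return {
        "B": B,
        "D": D,
        "d": d,
        "arm": ds.arm.astype(float),
        "logt": logt,
        "Bd": B[d],
        "Dd": D[d],
        "logt_d": logt[d],
        "arm_d": ds.arm[d].astype(float),
    }


def _value_grad_hess(theta: np.ndarray, prep: dict):
    """Negative log-likelihood with analytic gradient and Hessian.

    A non-monotone spline (non-positive d ln H / d ln t at an event time) is
    handled by a smooth quadratic barrier whose gradient points back towards
    the feasible region, keeping the optimiser in smooth territory.
    """
    k = prep["B"].shape[1]
    gamma, beta = theta[:k], theta[k]
    sp = prep["Dd"] @ gamma  # spline slope at event times
    eps = 1e-8
    if sp.size and sp.min() <= eps:
        bad = np.maximum(eps - sp, 0.0)
        f = _PENALTY + _PENALTY_W * float(bad @ bad)
        g = np.zeros(k + 1)
        g[:k] = -2.0 * _PENALTY_W * (bad @ prep["Dd"])
        H = np.eye(k + 1)
        H[:k, :k] += 2.0 * _PENALTY_W * (prep["Dd"].T * bad.astype(bool)) @ prep["Dd"]
        return f, g, H

    eta = prep["B"] @ gamma + beta * prep["arm"]
    eta = np.clip(eta, -700.0, 700.0)
    Hcum = np.exp(eta)
    ll = float(
        np.sum(np.log(sp) - prep["logt_d"] + eta[prep["d"]]) - Hcum.sum()
    )
    inv_sp = 1.0 / sp
    g = np.empty(k + 1)
    g[:k] = -(inv_sp @ prep["Dd"] + prep["Bd"].sum(axis=0) - Hcum @ prep["B"])
    g[k] = -(prep["arm_d"].sum() - Hcum @ prep["arm"])
    Hmat = np.empty((k + 1, k + 1))
    WD = prep["Dd"] * (inv_sp**2)[:, None]
    WB = prep["B"] * Hcum[:, None]
    Hmat[:k, :k] = WD.T @ prep["Dd"] + WB.T @ prep["B"]
    hb = (Hcum * prep["arm"]) @ prep["B"]
    Hmat[:k, k] = hb
    Hmat[k, :k] = hb
    Hmat[k, k] = float(Hcum @ (prep["arm"] ** 2))
    return -ll, g, Hmat


def log_likelihood(gamma, beta: float, ds: SurvivalDataset, knots: KnotSet) -> float:
    """Log-likelihood of ``(gamma, beta)``; ``-inf`` when the fitted log
    cumulative hazard is non-increasing at any event time."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.size != knots.n_basis:
        raise InputError(
            f"gamma must have length {knots.n_basis}, got {gamma.size}"
        )
    prep = _prepare(ds, knots)
    sp = prep["Dd"] @ gamma
    if sp.size and sp.min() <= 0:
        return -np.inf
    f, _, _ = _value_grad_hess(np.append(gamma, beta), prep)
    return -f


def fit_flexpar(
    ds: SurvivalDataset,
    n_internal: int = 2,
    max_restarts: int = 3,
) -> FlexParModel:
    """Fit the model by maximum likelihood.

    Starts from the exponential-model solution (``gamma = (ln(events /
    total follow-up), 1, 0, ...)``, ``beta = 0``) and uses a trust-region
    Newton method with the analytic gradient and Hessian; up to
    ``max_restarts`` jittered restarts before raising ``ConvergenceError``.
    """
    ds.require_two_arms()
    for arm in (0, 1):
        if ds.event[ds.arm == arm].sum() == 0:
            warnings.warn(
                f"arm {arm} has no events; estimates may be unstable",
                stacklevel=2,
            )
    knots = place_knots(ds, n_internal)
    prep = _prepare(ds, knots)
    k = knots.n_basis

    lam0 = max(ds.n_events, 1) / float(ds.time.sum())
    start = np.zeros(k + 1)
    start[0] = np.log(lam0)
    start[1] = 1.0

    rng = np.random.default_rng(0)  # deterministic restart jitter
    last_err = "did not converge"
    for attempt in range(max_restarts + 1):
        theta0 = start if attempt == 0 else start + rng.normal(
            scale=0.3, size=k + 1
        ) * (1.0 + np.abs(start))

        def fun(th):
            f, g, _ = _value_grad_hess(th, prep)
            return f, g

        def hess(th):
            return _value_grad_hess(th, prep)[2]

        res = minimize(
            fun,
            theta0,
            jac=True,
            hess=hess,
            method="trust-exact",
            options={"gtol": 1e-8, "maxiter": 300},
        )
        f, g, H = _value_grad_hess(res.x, prep)
        if f >= _PENALTY:  # stuck in the infeasible region
            last_err = "optimum has non-monotone baseline log cumulative hazard"
            continue
        if np.max(np.abs(g)) > 1e-4 * (1.0 + abs(f)):
            last_err = f"gradient norm {np.max(np.abs(g)):.3g} too large"
            continue
        try:
            np.linalg.cholesky(H)
        except np.linalg.LinAlgError:
            last_err = "observed information not positive definite"
            continue
        vcov = np.linalg.inv(H)
        vcov = 0.5 * (vcov + vcov.T)
        return FlexParModel(
            knots=knots,
            gamma=res.x[:k].copy(),
            beta=float(res.x[k]),
            vcov=vcov,
            loglik=-f,
            converged=True,
            n_events=ds.n_events,
            n_total=len(ds),
        )
    raise ConvergenceError(
        f"flexible parametric fit failed after {max_restarts} restarts: {last_err}"
    )


def predict_survival(model: FlexParModel, t, arm: int):
    """Model-based survival probability S(t | arm); vectorised over ``t``.

    Beyond the boundary knots the spline extrapolates linearly in log time.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr <= 0):
        raise InputError("survival prediction requires t > 0")
    if arm not in (0, 1):
        raise InputError("arm must be 0 or 1")
    B, _ = rcs_basis(np.log(t_arr), model.knots)
    eta = B @ model.gamma + model.beta * arm
    out = np.exp(-np.exp(np.clip(eta, -700.0, 700.0)))
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out
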