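"""Non-parametric estimators: Kaplan-Meier, RMST, difference in proportions.

These are the "standard" analyses a trial would run without modelling
assumptions: Kaplan-Meier survival curves with the Greenwood variance, the
restricted mean survival time as the area under the Kaplan-Meier step
function, and the difference in survival proportions at the horizon with a
Wald interval. Because no distributional assumption is made, none of these
estimators is affected by data observed after the horizon once the data
are administratively censored there.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .measures import Estimate
from .survdata import CONTROL, RESEARCH, InputError, SurvivalDataset

__all__ = [
    "KMCurve",
    "kaplan_meier",
    "km_survival_at",
    "km_rmst",
    "nonpar_drmst",
    "nonpar_ds",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier step function for one arm.

    ``survival[i]`` is the product-limit estimate just after
    ``event_times[i]``; ``greenwood_var[i]`` its Greenwood variance.
    ``max_observed_time`` (event or censoring) bounds where the curve is
    identified.
    """

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_subjects: int
    max_observed_time: float


def kaplan_meier(ds_one_arm: SurvivalDataset) -> KMCurve:
    """Product-limit estimator with the Greenwood variance.

    Ties between censorings and events at the same time are resolved
    events-first (the censored subject is still at risk at that time).
    """
    t = ds_one_arm.time
    e = ds_one_arm.event
    order = np.lexsort((1 - e, t))  # by time, events before censorings
    t, e = t[order], e[order]
    n = t.size

    # distinct event times with event counts and numbers at risk
    is_event = e == 1
    ev_times, first_idx, d = np.unique(
        t[is_event], return_index=True, return_counts=True
    )
    # number at risk just before each event time: subjects with time >= that
    # time (censored exactly at an event time counts as at risk)
    n_at_risk = n - np.searchsorted(t, ev_times, side="left")

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - d / n_at_risk
        surv = np.cumprod(frac)
        inc = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf)
        gw = surv**2 * np.cumsum(inc)
    gw = np.where(surv == 0.0, 0.0, gw)  # variance of a degenerate estimate
    return KMCurve(
        event_times=ev_times,
        survival=surv,
        greenwood_var=gw,
        n_at_risk=n_at_risk.astype(np.int64),
        n_events=d.astype(np.int64),
        n_subjects=n,
        max_observed_time=float(t.max()),
    )


def km_survival_at(curve: KMCurve, t: float) -> tuple[float, float]:
    """``(S(t), Var S(t))`` of the step function at time ``t``."""
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        return 1.0, 0.0
    return float(curve.survival[idx]), float(curve.greenwood_var[idx])


def km_rmst(curve: KMCurve, tau: float, alpha: float = 0.025) -> Estimate:
    """Restricted mean survival time to ``tau``: area under the KM curve.

    The variance is the standard product-limit RMST variance
    ``sum_{t_i <= tau} A(t_i)^2 d_i / (n_i (n_i - d_i))`` where
    ``A(t_i) = int_{t_i}^{tau} S(u) du`` is the forward area from each
    event time, i.e. the squared-forward-area weighting of the Greenwood
    increments.
    """
    if not tau > 0:
        raise InputError("tau must be positive")
    reaches_zero = curve.survival.size and curve.survival[-1] == 0.0 and (
        curve.event_times[-1] <= tau
    )
    if curve.max_observed_time < tau and not reaches_zero:
        raise InputError(
            f"RMST to tau={tau} not identifiable: follow-up ends at "
            f"{curve.max_observed_time} with the curve still positive"
        )
    within = curve.event_times <= tau
    times = curve.event_times[within]
    surv = curve.survival[within]
    # step integration of S on [0, tau]
    edges = np.concatenate(([0.0], times, [tau]))
    heights = np.concatenate(([1.0], surv))
    widths = np.diff(edges)
    area = float(heights @ widths)
    # forward areas from each retained event time to tau
    seg = heights * widths
    rev_cum = np.cumsum(seg[::-1])[::-1]
    A = rev_cum[1:] if times.size else np.empty(0)
    d = curve.n_events[within].astype(float)
    nrisk = curve.n_at_risk[within].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(nrisk > d, d / (nrisk * (nrisk - d)), np.inf)
    terms = np.where(A == 0.0, 0.0, A**2 * inc)
    var = float(terms.sum())
    se = float(np.sqrt(var))
    z = norm.ppf(1 - alpha)
    return Estimate(
        measure="DRMST",  # one-arm RMST reuses the container; see callers
        method="nonparametric",
        value=area,
        se=se,
        scale="identity",
        ci_low=area - z * se,
        ci_high=area + z * se,
        alpha=alpha,
        tau=tau,
    )


def nonpar_drmst(ds: SurvivalDataset, tau: float, alpha: float = 0.025) -> Estimate:
    """Kaplan-Meier DRMST(tau): RMST difference, research minus control,
    with independent-arms variance and a plain Wald interval."""
    ra = km_rmst(kaplan_meier(ds.arm_subset(RESEARCH)), tau, alpha)
    rc = km_rmst(kaplan_meier(ds.arm_subset(CONTROL)), tau, alpha)
    value = ra.value - rc.value
    se = float(np.hypot(ra.se, rc.se))
    z = norm.ppf(1 - alpha)
    return Estimate(
        measure="DRMST",
        method="nonparametric",
        value=value,
        se=se,
        scale="identity",
        ci_low=value - z * se,
        ci_high=value + z * se,
        alpha=alpha,
        tau=tau,
    )


def _simple_proportion(ds_arm: SurvivalDataset, tau: float) -> tuple[float, int]:
    # tau-survivor: no event by tau (event exactly at tau counts as failure;
    # censoring exactly at tau counts as a survivor with known status)
    survivor = (ds_arm.time > tau) | ((ds_arm.time == tau) & (ds_arm.event == 0))
    return float(survivor.mean()), len(ds_arm)


def nonpar_ds(ds: SurvivalDataset, tau: float, alpha: float = 0.025) -> Estimate:
    """Difference in tau-survival proportions with a Wald interval.

    When every subject's tau-status is known (no censoring strictly before
    tau) this is the simple difference in binomial proportions. Otherwise
    it falls back to the Kaplan-Meier estimates of S(tau) with Greenwood
    variances and logs a notice.
    """
    if not tau > 0:
        raise InputError("tau must be positive")
    arm_a = ds.arm_subset(RESEARCH)
    arm_c = ds.arm_subset(CONTROL)
    censored_early = (ds.event == 0) & (ds.time < tau)
    if censored_early.any():
        logger.info(
            "nonpar_ds: %d subject(s) censored before tau=%g; "
            "falling back to Kaplan-Meier survival at tau",
            int(censored_early.sum()),
            tau,
        )
        sa, va = km_survival_at(kaplan_meier(arm_a), tau)
        sc, vc = km_survival_at(kaplan_meier(arm_c), tau)
        value, se = sa - sc, float(np.sqrt(va + vc))
    else:
        pa, na = _simple_proportion(arm_a, tau)
        pc, nc = _simple_proportion(arm_c, tau)
        value = pa - pc
        se = float(np.sqrt(pa * (1 - pa) / na + pc * (1 - pc) / nc))
    z = norm.ppf(1 - alpha)
    return Estimate(
        measure="DS",
        method="nonparametric",
        value=value,
        se=se,
        scale="identity",
        ci_low=value - z * se,
        ci_high=value + z * se,
        alpha=alpha,
        tau=tau,
    )
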