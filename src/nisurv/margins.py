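"""Non-inferiority margin matching across summary-measure scales.

A margin expressed as a hazard ratio, a restricted-mean-survival-time loss
or a survival-probability loss describes, for a given control arm, the same
boundary survival curve for the research arm. Under an exponential control
arm with survival ``s`` at the horizon ``tau`` and a proportional-hazards
boundary (research hazard = ``hr_margin`` times control):

    lambda_C = -ln(s) / tau,        lambda_A = hr_margin * lambda_C,
    DS margin     = s - s^hr_margin,
    DRMST margin  = (1 - s)/lambda_C - (1 - s^hr_margin)/lambda_A,

both reported as positive losses when ``hr_margin > 1``. A hook accepts an
arbitrary control survival function, with the research boundary curve
``S_A = S_C^hr`` and the two integrals evaluated numerically.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from scipy.integrate import quad
from scipy.optimize import brentq

from .survdata import InputError

__all__ = ["MatchedMargins", "match_margins", "match_margins_curve", "invert_margin"]


@dataclass(frozen=True)
class MatchedMargins:
    """One non-inferiority margin expressed on all three scales."""

    s_tau_control: float
    tau: float
    hr: float
    drmst: float  # years of restricted mean survival lost (positive = loss)
    ds: float  # absolute survival-probability loss at tau (positive = loss)

    def __str__(self) -> str:
        return (
            f"margins at tau={self.tau:g} (control S(tau)={self.s_tau_control:g}): "
            f"HR {self.hr:g} | DRMST {self.drmst:.4f} years | "
            f"DS {100 * self.ds:.2f} percentage points"
        )


def _check_domain(s_tau_control: float, hr_margin: float, tau: float) -> None:
    if not 0 < s_tau_control < 1:
        raise InputError("control survival at tau must lie strictly in (0, 1)")
    if not hr_margin > 0:
        raise InputError("HR margin must be positive")
    if not tau > 0:
        raise InputError("tau must be positive")


def match_margins(
    s_tau_control: float, hr_margin: float, tau: float = 3.0
) -> MatchedMargins:
    """Match an HR margin onto the DRMST and DS scales (exponential control)."""
    _check_domain(s_tau_control, hr_margin, tau)
    s = s_tau_control
    lam_c = -math.log(s) / tau
    lam_a = hr_margin * lam_c
    # -expm1 keeps the restricted mean accurate down to vanishing hazards
    rmst_c = -math.expm1(-lam_c * tau) / lam_c
    rmst_a = -math.expm1(-lam_a * tau) / lam_a
    return MatchedMargins(
        s_tau_control=s,
        tau=tau,
        hr=hr_margin,
        drmst=rmst_c - rmst_a,
        ds=s - s**hr_margin,
    )


def match_margins_curve(
    control_survival: Callable[[float], float], hr_margin: float, tau: float = 3.0
) -> MatchedMargins:
    """Margin matching for an arbitrary control survival function.

    The boundary research curve is ``S_A(t) = S_C(t)^hr_margin``
    (proportional hazards at the margin); the two restricted means are
    integrated numerically.
    """
    if not hr_margin > 0:
        raise InputError("HR margin must be positive")
    if not tau > 0:
        raise InputError("tau must be positive")
    s_tau = control_survival(tau)
    if not 0 < s_tau < 1:
        raise InputError("control survival at tau must lie strictly in (0, 1)")
    rmst_c, _ = quad(control_survival, 0.0, tau, limit=200)
    rmst_a, _ = quad(lambda t: control_survival(t) ** hr_margin, 0.0, tau, limit=200)
    return MatchedMargins(
        s_tau_control=float(s_tau),
        tau=tau,
        hr=hr_margin,
        drmst=rmst_c - rmst_a,
        ds=float(s_tau - s_tau**hr_margin),
    )


def invert_margin(
    s_tau_control: float, tau: float, target: str, margin_value: float
) -> float:
    """Back-calculate the HR margin whose matched margin on ``target``
    (``"drmst"`` or ``"ds"``) equals ``margin_value``.

    Both matched losses are strictly increasing in the HR margin, so the
    inverse is found by monotone root-finding; the round trip with
    ``match_margins`` is accurate to about 1e-10.
    """
    if target not in ("drmst", "ds"):
        raise InputError("target must be 'drmst' or 'ds'")
    _check_domain(s_tau_control, 1.0, tau)
    s = s_tau_control
    lam_c = -math.log(s) / tau
    if target == "ds":
        lo, hi = s - 1.0, s  # range as hr spans (0, inf)
    else:
        lo, hi = (1.0 - s) / lam_c - tau, (1.0 - s) / lam_c
    if not lo < margin_value < hi:
        raise InputError(
            f"{target} margin {margin_value} unattainable for control "
            f"survival {s} at tau={tau} (range ({lo:.6g}, {hi:.6g}))"
        )

    def f(log_hr: float) -> float:
        m = match_margins(s, math.exp(log_hr), tau)
        return getattr(m, target) - margin_value

    log_hr = brentq(f, -40.0, 40.0, xtol=1e-13, rtol=1e-15, maxiter=200)
    return float(math.exp(log_hr))
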