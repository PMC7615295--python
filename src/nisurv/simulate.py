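"""Trial simulator: uniform accrual, exponential arms, administrative censoring.

Subjects enter uniformly over the accrual period and are analysed at a
fixed calendar date, so the censoring time of a subject entering at ``E``
is ``total_years - E`` — uniform between ``total_years - accrual_years``
and ``total_years`` years of follow-up. Event times are exponential with
the control rate chosen to hit the design's survival at the horizon and
the research rate scaled by the true hazard ratio. The default 3-year
accrual / 6-year analysis design guarantees every subject at least 3 years
of potential follow-up, so no one is censored before the 3-year horizon.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .survdata import InputError, SurvivalDataset, TrialDesign, censor_at

__all__ = [
    "SimSpec",
    "PATCH_DESIGNS",
    "rate_from_survival",
    "expected_event_fraction",
    "simulate_trial",
    "simulate_patch_cohort",
    "patch_design",
]

_VARIANTS = ("all_data", "censor_at_tau")


@dataclass(frozen=True)
class SimSpec:
    """One simulation run: a design, an explicit seed, and the data window.

    ``variant="all_data"`` keeps every observation up to the analysis date;
    ``"censor_at_tau"`` additionally censors at the horizon (the staggered /
    non-staggered pair of analyses).
    """

    design: TrialDesign
    seed: object  # int or numpy SeedSequence
    variant: str = "all_data"

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise InputError(f"variant must be one of {_VARIANTS}")
        if self.seed is None:
            raise InputError("an explicit seed is required for every run")


def rate_from_survival(s: float, t: float) -> float:
    """Exponential hazard rate with survival ``s`` at time ``t``."""
    if not 0 < s < 1:
        raise InputError("survival probability must lie strictly in (0, 1)")
    if not t > 0:
        raise InputError("time must be positive")
    return -math.log(s) / t


def expected_event_fraction(
    design: TrialDesign, arm: int = 0, censor_at_tau: bool = False
) -> float:
    """Probability that a subject's event is observed, in closed form.

    With censoring at the horizon the answer is ``1 - S(tau)``. Otherwise
    the censoring time is uniform on ``(total - accrual, total)`` and the
    observed-event probability is
    ``1 - (exp(-lam*(T-a)) - exp(-lam*T)) / (a*lam)`` for accrual ``a > 0``.
    """
    lam = rate_from_survival(design.s3_control, design.tau)
    if arm == 1:
        lam *= design.true_hr
    if censor_at_tau:
        return 1.0 - math.exp(-lam * design.tau)
    a, total = design.accrual_years, design.total_years
    if a == 0:
        return 1.0 - math.exp(-lam * total)
    return 1.0 - (math.exp(-lam * (total - a)) - math.exp(-lam * total)) / (a * lam)


def _simulate_arms(
    n_control: int,
    n_research: int,
    lam_control: float,
    true_hr: float,
    accrual: float,
    total: float,
    rng: np.random.Generator,
    label: str,
) -> SurvivalDataset:
    sizes = {0: n_control, 1: n_research}
    rates = {0: lam_control, 1: true_hr * lam_control}
    times, events, arms = [], [], []
    for arm in (0, 1):
        n = sizes[arm]
        entry = rng.uniform(0.0, accrual, size=n) if accrual > 0 else np.zeros(n)
        t_event = rng.exponential(scale=1.0 / rates[arm], size=n)
        censor = total - entry
        obs = np.minimum(t_event, censor)
        obs = np.maximum(obs, 1e-12)  # guard against a zero draw
        times.append(obs)
        events.append((t_event <= censor).astype(np.int64))
        arms.append(np.full(n, arm, dtype=np.int64))
    return SurvivalDataset(
        np.concatenate(times),
        np.concatenate(events),
        np.concatenate(arms),
        label=label,
    )


def simulate_trial(spec: SimSpec) -> SurvivalDataset:
    """Simulate one trial dataset under the spec's design.

    The control arm holds ``n_per_arm`` subjects and the research arm
    ``round(n_per_arm * allocation_ratio)``.
    """
    d = spec.design
    rng = np.random.default_rng(spec.seed)
    lam_c = rate_from_survival(d.s3_control, d.tau)
    n_research = int(round(d.n_per_arm * d.allocation_ratio))
    ds = _simulate_arms(
        d.n_per_arm,
        n_research,
        lam_c,
        d.true_hr,
        d.accrual_years,
        d.total_years,
        rng,
        label=f"simulated trial (s_tau={d.s3_control}, hr={d.true_hr})",
    )
    if spec.variant == "censor_at_tau":
        ds = censor_at(ds, d.tau)
    return ds


# --- PATCH trial cohorts ----------------------------------------------------
# Two prostate-cancer non-inferiority cohorts comparing transdermal
# oestradiol with LHRH analogues. Design values: 3-year control-arm survival
# (metastasis-free / overall), total sample size, 1.08:1 research:control
# allocation, 3-year accrual, analysis at 6 years.
PATCH_DESIGNS: dict[str, dict] = {
    "non_metastatic": {"s3_control": 0.83, "n_total": 1345, "hr_margin": 1.27},
    "metastatic": {"s3_control": 0.66, "n_total": 1500, "hr_margin": 1.19},
}
_PATCH_ALLOCATION = 1.08  # research : control


def patch_design(which: str, true_hr: float = 1.0) -> TrialDesign:
    """TrialDesign for a PATCH cohort. The research arm takes
    ``round(n_total * r / (1 + r))`` subjects, remainder to control."""
    try:
        p = PATCH_DESIGNS[which]
    except KeyError:
        raise InputError(
            f"unknown cohort {which!r}; choose from {sorted(PATCH_DESIGNS)}"
        ) from None
    r = _PATCH_ALLOCATION
    n_research = int(round(p["n_total"] * r / (1.0 + r)))
    n_control = p["n_total"] - n_research
    return TrialDesign(
        s3_control=p["s3_control"],
        n_per_arm=n_control,
        true_hr=true_hr,
        allocation_ratio=n_research / n_control,
    )


def simulate_patch_cohort(
    which: str, seed: object, true_hr: float = 1.0, variant: str = "all_data"
) -> SurvivalDataset:
    """Simulate one dataset under a PATCH cohort design."""
    design = patch_design(which, true_hr=true_hr)
    ds = simulate_trial(SimSpec(design=design, seed=seed, variant=variant))
    ds.label = f"PATCH {which} (true_hr={true_hr})"
    return ds
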