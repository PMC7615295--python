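"""Containers and I/O for two-arm survival data and trial designs.

Follow-up times are measured in years since randomisation. Arms are coded
``0`` = control (C) and ``1`` = research (A); every between-arm contrast in
the package is research minus control for differences (DRMST, DS) and
research over control for ratios (HR).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CONTROL",
    "RESEARCH",
    "InputError",
    "SurvivalRecord",
    "SurvivalDataset",
    "TrialDesign",
    "read_survival_csv",
    "censor_at",
]

CONTROL = 0
RESEARCH = 1


class InputError(ValueError):
    """User-supplied data or configuration violate the input contract."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time (years), event indicator, arm label."""

    time: float
    event: int
    arm: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and self.time > 0):
            raise InputError(f"time must be positive and finite, got {self.time!r}")
        if self.event not in (0, 1):
            raise InputError(f"event must be 0 or 1, got {self.event!r}")
        if self.arm not in (CONTROL, RESEARCH):
            raise InputError(f"arm must be 0 (control) or 1 (research), got {self.arm!r}")


class SurvivalDataset:
    """A collection of per-subject survival records, stored columnwise.

    Parameters
    ----------
    time, event, arm
        Equal-length sequences. ``time`` strictly positive and finite,
        ``event`` and ``arm`` in {0, 1}.
    label
        Free-text description carried through transformations.
    """

    def __init__(self, time, event, arm, label: str = "") -> None:
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        arm = np.asarray(arm)
        if time.ndim != 1 or time.size == 0:
            raise InputError("dataset must contain at least one record")
        if event.shape != time.shape or arm.shape != time.shape:
            raise InputError("time, event and arm must have equal length")
        bad = np.flatnonzero(~(np.isfinite(time) & (time > 0)))
        if bad.size:
            raise InputError(f"non-positive or non-finite time in row {bad[0] + 1}")
        bad = np.flatnonzero(~np.isin(event, (0, 1)))
        if bad.size:
            raise InputError(f"event outside {{0,1}} in row {bad[0] + 1}")
        bad = np.flatnonzero(~np.isin(arm, (0, 1)))
        if bad.size:
            raise InputError(f"arm outside {{0,1}} in row {bad[0] + 1}")
        self.time = time
        self.event = event.astype(np.int64)
        self.arm = arm.astype(np.int64)
        self.label = label

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.time.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, SurvivalDataset):
            return NotImplemented
        return (
            np.array_equal(self.time, other.time)
            and np.array_equal(self.event, other.event)
            and np.array_equal(self.arm, other.arm)
        )

    def __repr__(self) -> str:
        return (
            f"SurvivalDataset(n={len(self)}, events={self.n_events}, "
            f"arms={sorted(self.arms_present)}, label={self.label!r})"
        )

    # -- derived quantities ------------------------------------------------
    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def arms_present(self) -> set[int]:
        return set(np.unique(self.arm).tolist())

    def arm_subset(self, arm: int) -> "SurvivalDataset":
        """Records from one arm only (order preserved)."""
        mask = self.arm == arm
        if not mask.any():
            raise InputError(f"arm {arm} has no records")
        return SurvivalDataset(
            self.time[mask], self.event[mask], self.arm[mask], label=self.label
        )

    def require_two_arms(self) -> None:
        """Refuse datasets unusable for two-arm estimation."""
        if self.arms_present != {CONTROL, RESEARCH}:
            raise InputError("two-arm estimation requires records in both arms")
        if self.n_events == 0:
            raise InputError("dataset has no events; nothing to estimate")

    # -- conversion --------------------------------------------------------
    def records(self) -> list[SurvivalRecord]:
        return [
            SurvivalRecord(float(t), int(e), int(a))
            for t, e, a in zip(self.time, self.event, self.arm)
        ]

    @classmethod
    def from_records(
        cls, records: Iterable[SurvivalRecord], label: str = ""
    ) -> "SurvivalDataset":
        recs = list(records)
        return cls(
            [r.time for r in recs],
            [r.event for r in recs],
            [r.arm for r in recs],
            label=label,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event, "arm": self.arm})

    def to_csv(self, path) -> None:
        """Write ``time,event,arm`` CSV at full floating-point precision."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


_DEFAULT_COLUMNS = {"time": "time", "event": "event", "arm": "arm"}


def read_survival_csv(
    path,
    columns: Mapping[str, str] | None = None,
    arm_codes: Mapping[object, int] | None = None,
    label: str | None = None,
) -> SurvivalDataset:
    """Read per-subject records from a delimited text file with a header.

    Parameters
    ----------
    columns
        Optional map from canonical names (``time``, ``event``, ``arm``) to
        the column names used in the file.
    arm_codes
        Optional map translating arm labels in the file (e.g. ``"C"``/``"A"``)
        to the canonical 0/1 coding.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        unknown = set(columns) - set(colmap)
        if unknown:
            raise InputError(f"unknown canonical column name(s): {sorted(unknown)}")
        colmap.update(columns)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise InputError(f"missing column(s) {missing} in {path}")
    time = pd.to_numeric(df[colmap["time"]], errors="coerce").to_numpy(float)
    event = pd.to_numeric(df[colmap["event"]], errors="coerce").to_numpy(float)
    arm_raw = df[colmap["arm"]]
    if arm_codes:
        arm = arm_raw.map(lambda v: arm_codes.get(v, arm_codes.get(str(v), np.nan)))
        arm = pd.to_numeric(arm, errors="coerce").to_numpy(float)
    else:
        arm = pd.to_numeric(arm_raw, errors="coerce").to_numpy(float)
    for name, col in (("time", time), ("event", event), ("arm", arm)):
        bad = np.flatnonzero(~np.isfinite(col))
        if bad.size:
            raise InputError(f"unparseable {name} value in row {bad[0] + 1} of {path}")
    try:
        return SurvivalDataset(
            time,
            event.astype(np.int64),
            arm.astype(np.int64),
            label=label if label is not None else str(path),
        )
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from None


def censor_at(ds: SurvivalDataset, horizon: float) -> SurvivalDataset:
    """Administratively censor every record at ``horizon`` years.

    Records with ``time > horizon`` become ``(horizon, censored)``; records
    with ``time <= horizon`` are untouched, so an event occurring exactly at
    the horizon still counts as an event (closed-interval convention).
    """
    if not (horizon > 0):
        raise InputError(f"censoring horizon must be positive, got {horizon!r}")
    beyond = ds.time > horizon
    time = np.where(beyond, horizon, ds.time)
    event = np.where(beyond, 0, ds.event)
    return SurvivalDataset(time, event, ds.arm, label=ds.label)


@dataclass(frozen=True)
class TrialDesign:
    """Design of a two-arm trial with uniform accrual and a fixed analysis date.

    Attributes
    ----------
    s3_control
        Control-arm survival probability at the horizon ``tau``.
    n_per_arm
        Control-arm sample size; the research arm holds
        ``round(n_per_arm * allocation_ratio)`` subjects.
    true_hr
        Data-generating hazard ratio, research over control.
    accrual_years
        Duration of uniform recruitment.
    total_years
        Time from start of recruitment to the analysis date.
    tau
        Horizon for DRMST and DS. The constraint
        ``tau <= total_years - accrual_years`` guarantees every subject has
        at least ``tau`` years of potential follow-up.
    """

    s3_control: float
    n_per_arm: int
    true_hr: float = 1.0
    accrual_years: float = 3.0
    total_years: float = 6.0
    tau: float = 3.0
    allocation_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.s3_control < 1:
            raise InputError("s3_control must lie strictly between 0 and 1")
        if int(self.n_per_arm) != self.n_per_arm or self.n_per_arm < 2:
            raise InputError("n_per_arm must be an integer >= 2")
        if not 0 <= self.accrual_years < self.total_years:
            raise InputError("need 0 <= accrual_years < total_years")
        if not 0 < self.tau <= self.total_years - self.accrual_years:
            raise InputError("need 0 < tau <= total_years - accrual_years")
        if not self.true_hr > 0:
            raise InputError("true_hr must be positive")
        if not self.allocation_ratio > 0:
            raise InputError("allocation_ratio must be positive")

    def with_true_hr(self, true_hr: float) -> "TrialDesign":
        return replace(self, true_hr=true_hr)

    @classmethod
    def from_yaml(cls, path) -> "TrialDesign":
        """Load the fields from the ``design:`` block of a YAML file."""
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise InputError(f"{path}: expected a mapping at top level")
        block = doc.get("design", doc)
        try:
            return cls(**block)
        except TypeError as exc:
            raise InputError(f"{path}: bad design block ({exc})") from None
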