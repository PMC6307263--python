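"""Treatment calendars and forward simulation across them.

A course is the contiguous run of calendar days from the first delivered
fraction to the last, including untreated weekends and interruption days.
Fractions are 2 Gy each, delivered on weekdays; in-room imaging (from which
the tumor volume is contoured) is flagged on every fraction day by default.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .kinetics import CompartmentState, day_propagator
from .params import KineticParameters

__all__ = [
    "DayRecord",
    "TreatmentCourse",
    "CourseError",
    "standard_course",
    "simulate_course",
    "read_course",
    "write_course",
]

FRACTION_DOSE_GY = 2.0


class CourseError(ValueError):
    """The treatment calendar violates a structural constraint."""


@dataclass(frozen=True)
class DayRecord:
    """One calendar day of the course."""

    date: dt.date
    fraction_delivered: bool
    imaging: bool = False
    measured_volume: float | None = None

    @property
    def dose(self) -> float:
        return FRACTION_DOSE_GY if self.fraction_delivered else 0.0

    def __post_init__(self) -> None:
        if self.measured_volume is not None and not (self.measured_volume > 0.0):
            raise CourseError(
                f"measured volume must be positive, got {self.measured_volume!r} "
                f"on {self.date}"
            )


@dataclass(frozen=True)
class TreatmentCourse:
    """Ordered, contiguous daily records spanning first to last fraction."""

    days: tuple[DayRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.days:
            raise CourseError("a course must contain at least one day")
        if not self.days[0].fraction_delivered or not self.days[-1].fraction_delivered:
            raise CourseError("a course must start and end on fraction days")
        for prev, cur in zip(self.days, self.days[1:]):
            if (cur.date - prev.date).days != 1:
                raise CourseError(
                    f"days must be contiguous; gap between {prev.date} and {cur.date}"
                )

    def __len__(self) -> int:
        return len(self.days)

    @property
    def span_days(self) -> int:
        """Calendar length, first to last fraction inclusive."""
        return (self.days[-1].date - self.days[0].date).days + 1

    @property
    def n_fractions(self) -> int:
        return sum(d.fraction_delivered for d in self.days)

    @property
    def treated_flags(self) -> list[bool]:
        return [d.fraction_delivered for d in self.days]

    @property
    def dates(self) -> list[dt.date]:
        return [d.date for d in self.days]

    def imaging_indices(self) -> list[int]:
        return [i for i, d in enumerate(self.days) if d.imaging]

    def with_volumes(self, volumes_by_date: dict[dt.date, float]) -> "TreatmentCourse":
        """Attach measured volumes (cm^3) to the matching imaging days."""
        unknown = set(volumes_by_date) - {d.date for d in self.days}
        if unknown:
            raise CourseError(f"volume dates not in course: {sorted(unknown)}")
        days = tuple(
            DayRecord(
                date=d.date,
                fraction_delivered=d.fraction_delivered,
                imaging=d.imaging or d.date in volumes_by_date,
                measured_volume=volumes_by_date.get(d.date, d.measured_volume),
            )
            for d in self.days
        )
        return TreatmentCourse(days)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [d.date.isoformat() for d in self.days],
                "fraction": [int(d.fraction_delivered) for d in self.days],
                "volume_cm3": [d.measured_volume for d in self.days],
            }
        )


def standard_course(
    start_date: dt.date,
    n_fractions: int = 33,
    gap_after_fraction: int | None = None,
    gap_days: int = 7,
) -> TreatmentCourse:
    """Weekday-only fractionation calendar, optionally interrupted.

    Fractions fall on consecutive weekdays starting at ``start_date`` (which
    must be a weekday); weekends are untreated rest days.  If
    ``gap_after_fraction`` is given, treatment pauses for ``gap_days``
    calendar days once that many fractions have been delivered, emulating a
    course interruption; remaining fractions resume on the next weekday.
    Imaging is flagged on every fraction day (daily in-room imaging).
    """
    if n_fractions < 1:
        raise CourseError(f"n_fractions must be >= 1, got {n_fractions!r}")
    if start_date.weekday() >= 5:
        raise CourseError(f"start date {start_date} falls on a weekend")
    if gap_after_fraction is not None and not (0 < gap_after_fraction < n_fractions):
        raise CourseError(
            f"gap_after_fraction must be inside the course, got {gap_after_fraction!r}"
        )

    records: list[DayRecord] = []
    delivered = 0
    gap_remaining = 0
    date = start_date
    while delivered < n_fractions:
        in_gap = gap_remaining > 0
        treat = date.weekday() < 5 and not in_gap
        records.append(DayRecord(date=date, fraction_delivered=treat, imaging=treat))
        if treat:
            delivered += 1
            if gap_after_fraction is not None and delivered == gap_after_fraction:
                gap_remaining = gap_days
        if in_gap:
            gap_remaining -= 1
        date += dt.timedelta(days=1)
    return TreatmentCourse(tuple(records))


def simulate_course(
    params: KineticParameters,
    course: TreatmentCourse,
    convention: str = "ode",
) -> np.ndarray:
    """Normalized tumor-burden trajectory ``G_i / G_0`` across the course.

    The state at index ``i`` is the burden at the start of day ``i`` (i.e.
    before that day's fraction, matching when in-room imaging happens); index
    0 is the first fraction day and is 1.0 by construction.  Each day applies
    the exact one-day propagator for that day's treatment status, starting
    from ``(U, V, W) = (p, 1 - p, 0)``.
    """
    props = {
        flag: day_propagator(params, flag, convention=convention)
        for flag in (False, True)
    }
    x = CompartmentState.from_csc_proportion(params.p).as_array()
    g0 = x.sum()
    values = np.empty(len(course), dtype=float)
    values[0] = 1.0
    flags = course.treated_flags
    for i in range(1, len(course)):
        x = props[flags[i - 1]] @ x
        values[i] = x.sum() / g0
    return values


# ---------------------------------------------------------------------------
# File dialect: CSV with header date,fraction,volume_cm3 (ISO dates,
# fraction in {0,1}, volume blank when no imaging); JSON equivalent is a
# list of {"date": ..., "fraction": ..., "volume_cm3": ...} objects.
# ---------------------------------------------------------------------------


def _course_from_records(rows: Iterable[dict]) -> TreatmentCourse:
    days = []
    for row in rows:
        raw_vol = row.get("volume_cm3")
        volume = None
        if raw_vol is not None and raw_vol == raw_vol and raw_vol != "":
            volume = float(raw_vol)
        days.append(
            DayRecord(
                date=dt.date.fromisoformat(str(row["date"])),
                fraction_delivered=bool(int(row["fraction"])),
                imaging=volume is not None,
                measured_volume=volume,
            )
        )
    return TreatmentCourse(tuple(days))


def read_course(path: str | Path) -> TreatmentCourse:
    """Read a course file (CSV or JSON, by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        frame = pd.read_csv(path)
        missing = {"date", "fraction", "volume_cm3"} - set(frame.columns)
        if missing:
            raise CourseError(f"{path}: missing columns {sorted(missing)}")
        rows = frame.to_dict("records")
    return _course_from_records(rows)


def write_course(course: TreatmentCourse, path: str | Path) -> None:
    """Write a course file in the same dialect ``read_course`` accepts."""
    path = Path(path)
    frame = course.to_dataframe()
    if path.suffix.lower() == ".json":
        records = frame.where(pd.notna(frame), None).to_dict("records")
        path.write_text(json.dumps(records, indent=1))
    else:
        frame.to_csv(path, index=False)
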