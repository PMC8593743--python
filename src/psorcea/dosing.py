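"""Dose and dispense calendars for biologic treatment lines.

Each PBS-listed biologic is described by a :class:`DosingSchedule` — the
injection calendar printed on its product information ("Week 0, 4, and every
12 weeks thereafter") — and, separately, by a :class:`DispensePlan`, the
calendar of pharmacy supply events.  The two differ whenever one dispensed
pack covers several injections (etanercept is supplied as four 50 mg
syringes, adalimumab as two 40 mg syringes, maintenance ixekizumab as a
three-pen pack).  Drug acquisition costs accrue per dispense; clinical
dosing questions (how many injections fall in a window) use the dose
calendar.

All week offsets are measured from the start of the treatment line; every
new line restarts its calendar at week 0, mirroring the PBS rule that each
biologic begins with its own induction regimen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator


@dataclass(frozen=True)
class DosingSchedule:
    """Injection calendar: loading doses, then a fixed steady interval.

    Parameters
    ----------
    loading_dose_weeks:
        Strictly increasing week offsets of the loading doses; the first
        must be 0 (treatment starts with a dose).
    steady_interval_weeks:
        Weeks between doses once loading is complete; the first steady-state
        dose falls ``steady_interval_weeks`` after the last loading dose.
    """

    loading_dose_weeks: tuple[int, ...]
    steady_interval_weeks: int

    def __post_init__(self) -> None:
        lw = tuple(self.loading_dose_weeks)
        object.__setattr__(self, "loading_dose_weeks", lw)
        if not lw or lw[0] != 0:
            raise ValueError("loading_dose_weeks must start at week 0")
        if any(b <= a for a, b in zip(lw, lw[1:])):
            raise ValueError("loading_dose_weeks must be strictly increasing")
        if self.steady_interval_weeks < 1:
            raise ValueError("steady_interval_weeks must be >= 1")

    def _iter_doses(self) -> Iterator[int]:
        yield from self.loading_dose_weeks
        t = self.loading_dose_weeks[-1] + self.steady_interval_weeks
        while True:
            yield t
            t += self.steady_interval_weeks


@dataclass(frozen=True)
class DispensePlan:
    """Pharmacy supply calendar: induction dispenses, then periodic packs.

    ``induction_weeks`` lists supply events during the 12-week induction
    phase; from ``maintenance_start_week`` (default 12) onward one dispense
    occurs every ``maintenance_interval_weeks``.
    """

    induction_weeks: tuple[int, ...]
    maintenance_interval_weeks: int
    maintenance_start_week: int = 12

    def __post_init__(self) -> None:
        iw = tuple(self.induction_weeks)
        object.__setattr__(self, "induction_weeks", iw)
        if not iw or iw[0] != 0:
            raise ValueError("induction_weeks must start at week 0")
        if any(b <= a for a, b in zip(iw, iw[1:])):
            raise ValueError("induction_weeks must be strictly increasing")
        if self.maintenance_interval_weeks < 1:
            raise ValueError("maintenance_interval_weeks must be >= 1")

    def dispenses_in_interval(self, start_week: int, end_week: int) -> int:
        """Number of supply events in the half-open window [start, end)."""
        if start_week < 0 or end_week < start_week:
            raise ValueError("require 0 <= start_week <= end_week")
        n = sum(1 for w in self.induction_weeks if start_week <= w < end_week)
        t = self.maintenance_start_week
        while t < end_week:
            if t >= start_week:
                n += 1
            t += self.maintenance_interval_weeks
        return n


def dose_times(schedule: DosingSchedule, duration_weeks: int) -> list[int]:
    """All injection week-offsets ``t`` with ``0 <= t < duration_weeks``.

    >>> adalimumab = DosingSchedule((0, 1), 2)
    >>> dose_times(adalimumab, 12)
    [0, 1, 3, 5, 7, 9, 11]
    """
    if duration_weeks < 0:
        raise ValueError("duration_weeks must be >= 0")
    out: list[int] = []
    for t in schedule._iter_doses():
        if t >= duration_weeks:
            break
        out.append(t)
    return out


def doses_in_interval(schedule: DosingSchedule, start_week: int,
                      end_week: int) -> int:
    """Count injections in the half-open window [start_week, end_week).

    The half-open convention means a dose falling exactly on a review or
    switch boundary belongs to the period that starts there, so nothing is
    double counted; ixekizumab's week-12 dose is its first maintenance dose.
    """
    if start_week < 0:
        raise ValueError("start_week must be >= 0")
    if end_week < start_week:
        raise ValueError("interval is inverted: end_week < start_week")
    return sum(1 for t in dose_times(schedule, end_week) if t >= start_week)
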