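"""Dosing-regimen grammar: named schedules expanded to absolute dose times."""
from __future__ import annotations

from dataclasses import dataclass

from .pbpk import DoseRegimen

__all__ = ["RegimenSpec", "expand_regimen", "SCHEDULES"]

#: Dose days within each 7-day cycle (``None`` marks sub-daily schedules).
SCHEDULES = ("single", "three_weekly", "qd", "bid")


@dataclass
class RegimenSpec:
    """Weight-normalized dose plus a named schedule over a study duration."""

    dose_mg_per_kg: float
    schedule: str = "single"
    duration: float = 1.0  # days
    body_weight: float = 20.0  # g
    ka: float = 3.0  # 1/h
    lag_time: float = 0.17  # h
    fa: float = 1.0

    def __post_init__(self) -> None:
        if self.dose_mg_per_kg <= 0:
            raise ValueError("dose_mg_per_kg must be > 0")
        if self.schedule not in SCHEDULES:
            raise ValueError(
                f"unknown schedule {self.schedule!r}; expected one of {SCHEDULES}"
            )
        if self.schedule != "single" and self.duration < 1:
            raise ValueError("duration must be >= 1 day for repeated schedules")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")


def _dose_hours(schedule: str, duration_days: float) -> list[float]:
    if schedule == "single":
        return [0.0]
    hours: list[float] = []
    if schedule == "three_weekly":
        # every other day, three times a week: days {0, 2, 4} of each cycle
        day = 0
        while day < duration_days:
            if day % 7 in (0, 2, 4):
                hours.append(day * 24.0)
            day += 1
    elif schedule == "qd":
        hours = [d * 24.0 for d in range(int(duration_days))]
    elif schedule == "bid":
        hours = [h for h in range(0, int(duration_days * 24), 12)]
    return [float(h) for h in hours]


def expand_regimen(spec: RegimenSpec) -> DoseRegimen:
    """Expand a named schedule into absolute dose amount (mg) and times (h)."""
    dose_mg = spec.dose_mg_per_kg * spec.body_weight / 1000.0  # g -> kg
    times = _dose_hours(spec.schedule, spec.duration)
    return DoseRegimen(
        dose_amount=dose_mg,
        dose_times=tuple(times),
        ka=spec.ka,
        lag_time=spec.lag_time,
        fa=spec.fa,
        route_label=f"IP {spec.dose_mg_per_kg:g} mg/kg, {spec.schedule}",
    )
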