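"""Solution encoding and objective kernels for both allocation stages.

A :class:`Schedule` fixes, for one realized emergency scenario, which
elective patients are admitted and when.  Current patients always occupy
days ``1..remaining``; emergencies occupy ``arrival_day..arrival_day+los-1``.
Stage-2 evaluation reuses the same encoding with lengths of stay replaced by
their extended values (``elective_los`` / ``current_remaining`` overrides).

Stage-1 objectives: mean bed-occupancy rate f11 (maximize), mean delay index
f12 over admitted electives (minimize), mean emergency admission rate f13
relative to the daily Poisson cap (maximize).  Stage-2 objectives: f21, the
fraction of stage-1 patient-day assignments preserved (maximize), and f22,
the peak number of extra beds needed relative to stage 1 (minimize).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .instance import EmergencyArrival, Instance

__all__ = [
    "Schedule",
    "ObjectiveVector",
    "StageOneReference",
    "carryover_occupancy",
    "total_occupancy",
    "occupancy_vector",
    "elective_current_occupancy",
    "f11_occupancy_rate",
    "f12_delay_index",
    "f13_emergency_rate",
    "f21_similarity",
    "f22_added_beds",
    "is_feasible",
    "occupancy_pmf",
    "stage1_objectives",
    "bed_layout",
    "schedule_to_frame",
]


@dataclass
class Schedule:
    """One candidate allocation.

    ``admission_day`` maps elective patient id to admission day (absent =
    not admitted).  ``elective_los`` and ``current_remaining`` hold the
    lengths of stay in effect; stage 1 populates them from the instance,
    stage 2 with extended values.
    """

    admission_day: dict[int, int]
    emergencies: list[EmergencyArrival]
    elective_los: dict[int, int] = field(default_factory=dict)
    current_remaining: dict[int, int] = field(default_factory=dict)

    @classmethod
    def empty(cls, inst: Instance,
              emergencies: Iterable[EmergencyArrival] = ()) -> "Schedule":
        return cls(
            admission_day={},
            emergencies=list(emergencies),
            elective_los={p.id: p.los for p in inst.electives},
            current_remaining={p.id: p.remaining for p in inst.currents},
        )

    def copy(self) -> "Schedule":
        return Schedule(
            dict(self.admission_day),
            list(self.emergencies),
            dict(self.elective_los),
            dict(self.current_remaining),
        )

    def los_of(self, inst: Instance, pid: int) -> int:
        los = self.elective_los.get(pid)
        return inst.elective(pid).los if los is None else los

    def remaining_of(self, inst: Instance, pid: int) -> int:
        rem = self.current_remaining.get(pid)
        if rem is None:
            rem = next(c.remaining for c in inst.currents if c.id == pid)
        return rem

    def emergency_count(self, day: int) -> int:
        return sum(1 for e in self.emergencies if e.arrival_day == day)

    def occupant_pairs(self, inst: Instance) -> set[tuple[int, int]]:
        """All (patient id, day) bed occupations within the horizon."""
        T = inst.horizon
        pairs: set[tuple[int, int]] = set()
        for c in inst.currents:
            for t in range(1, min(self.remaining_of(inst, c.id), T) + 1):
                pairs.add((c.id, t))
        for e in self.emergencies:
            for t in range(e.arrival_day, min(e.arrival_day + e.los - 1, T) + 1):
                pairs.add((e.id, t))
        for pid, day in self.admission_day.items():
            for t in range(day, min(day + self.los_of(inst, pid) - 1, T) + 1):
                pairs.add((pid, t))
        return pairs


@dataclass(frozen=True)
class ObjectiveVector:
    """Objective values of one schedule in one stage."""

    stage: int
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        expected = 3 if self.stage == 1 else 2
        if self.stage not in (1, 2) or len(self.values) != expected:
            raise ValueError("stage 1 has 3 objectives, stage 2 has 2")

    @property
    def f11(self) -> float:
        return self.values[0]

    @property
    def f12(self) -> float:
        return self.values[1]

    @property
    def f13(self) -> float:
        return self.values[2]

    @property
    def f21(self) -> float:
        return self.values[0]

    @property
    def f22(self) -> float:
        return self.values[1]


@dataclass(frozen=True)
class StageOneReference:
    """The frozen stage-1 schedule and objective values bounding stage 2."""

    schedule: Schedule
    objectives: ObjectiveVector

    def __post_init__(self) -> None:
        if self.objectives.stage != 1:
            raise ValueError("reference objectives must be stage-1 values")


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def _check_day(inst: Instance, t: int) -> None:
    if not 1 <= t <= inst.horizon:
        raise ValueError(f"day {t} outside horizon [1, {inst.horizon}]")


def carryover_occupancy(s: Schedule, inst: Instance, t: int) -> int:
    """Patients already in a bed before day ``t`` who still occupy it on ``t``.

    Counts electives admitted on an earlier day whose stay covers ``t``,
    emergencies that arrived earlier and are still staying, and current
    patients with remaining stay reaching ``t``.
    """
    _check_day(inst, t)
    n = sum(1 for c in inst.currents if s.remaining_of(inst, c.id) >= t)
    n += sum(
        1
        for e in s.emergencies
        if e.arrival_day < t <= e.arrival_day + e.los - 1
    )
    n += sum(
        1
        for pid, day in s.admission_day.items()
        if day < t <= day + s.los_of(inst, pid) - 1
    )
    return n


def total_occupancy(s: Schedule, inst: Instance, t: int) -> int:
    """All patients in a bed on day ``t``: new admissions plus carryover."""
    _check_day(inst, t)
    new_el = sum(1 for day in s.admission_day.values() if day == t)
    return new_el + s.emergency_count(t) + carryover_occupancy(s, inst, t)


def _window_add(occ: list, start: int, los: int) -> None:
    for i in range(start - 1, min(start + los - 1, len(occ))):
        occ[i] += 1


def _occupancy_list(s: Schedule, inst: Instance, include_emergencies: bool) -> list:
    occ = [0] * inst.horizon
    for c in inst.currents:
        _window_add(occ, 1, s.remaining_of(inst, c.id))
    if include_emergencies:
        for e in s.emergencies:
            _window_add(occ, e.arrival_day, e.los)
    for pid, day in s.admission_day.items():
        _window_add(occ, day, s.los_of(inst, pid))
    return occ


def occupancy_vector(s: Schedule, inst: Instance) -> np.ndarray:
    """Total occupancy for every day of the horizon."""
    return np.array(_occupancy_list(s, inst, True), dtype=int)


def elective_current_occupancy(s: Schedule, inst: Instance) -> np.ndarray:
    """Per-day occupancy by elective and current patients only."""
    return np.array(_occupancy_list(s, inst, False), dtype=int)


# ---------------------------------------------------------------------------
# stage-1 objectives
# ---------------------------------------------------------------------------

def f11_occupancy_rate(s: Schedule, inst: Instance) -> float:
    """Mean daily occupancy over capacity; exceeds 1 under emergency overflow."""
    occ = occupancy_vector(s, inst)
    return float(occ.sum() / (inst.beds * inst.horizon))


def f12_delay_index(s: Schedule, inst: Instance) -> float:
    """Mean of (delay days x loss of chance) over admitted electives."""
    if not s.admission_day:
        return 0.0
    total = sum(
        inst.elective(pid).loss_of_chance * (day - inst.elective(pid).expected_day)
        for pid, day in s.admission_day.items()
    )
    return float(total / len(s.admission_day))


def f13_emergency_rate(s: Schedule, inst: Instance) -> float:
    """Mean daily ratio of admitted emergencies to the Poisson cap ``Mp_t``.

    Days with a zero cap carry no information and are excluded from the mean.
    """
    caps = inst.max_per_day
    ratios = [
        s.emergency_count(t) / caps[t - 1]
        for t in range(1, inst.horizon + 1)
        if caps[t - 1] > 0
    ]
    return float(np.mean(ratios)) if ratios else 0.0


def stage1_objectives(s: Schedule, inst: Instance) -> ObjectiveVector:
    return ObjectiveVector(
        1,
        (
            f11_occupancy_rate(s, inst),
            f12_delay_index(s, inst),
            f13_emergency_rate(s, inst),
        ),
    )


def is_feasible(s: Schedule, inst: Instance) -> tuple[bool, list[str]]:
    """Hard stage constraints: capacity, single timely admission, arrival caps.

    Elective-plus-current occupancy must stay within the bed count every day
    (emergencies are allowed to overflow), each elective is admitted at most
    once and never before its expected day, and daily emergency counts never
    exceed the cap ``Mp_t``.
    """
    v: list[str] = []
    occ = elective_current_occupancy(s, inst)
    for t in np.flatnonzero(occ > inst.beds):
        v.append(
            f"day {t + 1}: elective+current occupancy {occ[t]} exceeds "
            f"{inst.beds} beds"
        )
    for pid, day in s.admission_day.items():
        p = inst.elective(pid)
        if day < p.expected_day:
            v.append(
                f"elective {pid}: admitted day {day} before expected "
                f"day {p.expected_day}"
            )
        if not 1 <= day <= inst.horizon:
            v.append(f"elective {pid}: admission day {day} outside horizon")
    caps = inst.max_per_day
    for t in range(1, inst.horizon + 1):
        n = s.emergency_count(t)
        if n > caps[t - 1]:
            v.append(f"day {t}: {n} emergencies exceed cap {caps[t - 1]}")
    return (not v, v)


# ---------------------------------------------------------------------------
# stage-2 objectives
# ---------------------------------------------------------------------------

def f21_similarity(
    stage1: Schedule,
    stage2: Schedule,
    inst: Instance,
    *,
    bed_sensitive: bool = False,
    denominator: str = "stage1",
) -> float:
    """Fraction of stage-1 patient-day assignments preserved by stage 2.

    By default a match means the same patient occupies *a* bed on the same
    day (beds are interchangeable).  With ``bed_sensitive=True`` the match
    additionally requires the same deterministically labeled bed, which is
    stricter under re-layouts.  ``denominator`` picks the normalization:
    stage-1 patient-days (default) or the larger of the two stages'.
    """
    if bed_sensitive:
        p1 = _bed_pairs(stage1, inst)
        p2 = _bed_pairs(stage2, inst)
    else:
        p1 = stage1.occupant_pairs(inst)
        p2 = stage2.occupant_pairs(inst)
    if not p1:
        return 1.0
    if denominator == "stage1":
        denom = len(p1)
    elif denominator == "max":
        denom = max(len(p1), len(p2))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return len(p1 & p2) / denom


def f22_added_beds(
    stage1: Schedule, stage2: Schedule, inst: Instance
) -> int:
    """Peak extra daily bed requirement of stage 2 over stage 1 (>= 0)."""
    q1 = occupancy_vector(stage1, inst)
    q2 = occupancy_vector(stage2, inst)
    return int(max(0, (q2 - q1).max()))


# ---------------------------------------------------------------------------
# occupancy uncertainty
# ---------------------------------------------------------------------------

def occupancy_pmf(s: Schedule, inst: Instance, t: int) -> dict[int, float]:
    """Law of day-``t`` occupancy with the emergency count left random.

    The elective and current occupancy is deterministic; the day's emergency
    admissions follow the truncated Poisson law, shifting the point mass.
    """
    _check_day(inst, t)
    det = int(elective_current_occupancy(s, inst)[t - 1])
    pmf = inst.arrivals.day_pmf(t)
    return {det + k: float(p) for k, p in enumerate(pmf)}


# ---------------------------------------------------------------------------
# bed layout / export
# ---------------------------------------------------------------------------

_CATEGORY = {"current": 0, "emergency": 1, "elective": 2}


def _stays(s: Schedule, inst: Instance):
    """(category, id, first day, last day) for every patient in the schedule."""
    T = inst.horizon
    out = []
    for c in inst.currents:
        rem = s.remaining_of(inst, c.id)
        if rem >= 1:
            out.append(("current", c.id, 1, min(rem, T)))
    for e in s.emergencies:
        out.append(
            ("emergency", e.id, e.arrival_day, min(e.arrival_day + e.los - 1, T))
        )
    for pid, day in s.admission_day.items():
        out.append(
            ("elective", pid, day, min(day + s.los_of(inst, pid) - 1, T))
        )
    return out


def bed_layout(s: Schedule, inst: Instance) -> dict[int, int]:
    """Deterministic patient -> bed-number assignment (first fit).

    Each stay keeps a single bed.  Stays are placed day by day; same-day
    arrivals are ordered current, then emergency, then elective, ascending
    id, and take the lowest bed free over their whole stay.  Bed numbers may
    exceed the nominal capacity when demand overflows.
    """
    stays = sorted(
        _stays(s, inst), key=lambda x: (x[2], _CATEGORY[x[0]], x[1])
    )
    free_from: list[int] = []  # bed index -> first day it is free
    assignment: dict[int, int] = {}
    for _cat, pid, start, end in stays:
        for b, free in enumerate(free_from):
            if free <= start:
                break
        else:
            free_from.append(0)
            b = len(free_from) - 1
        free_from[b] = end + 1
        assignment[pid] = b + 1
    return assignment


def _bed_pairs(s: Schedule, inst: Instance) -> set[tuple[int, int, int]]:
    beds = bed_layout(s, inst)
    return {
        (beds[pid], pid, day) for pid, day in s.occupant_pairs(inst)
    }


def schedule_to_frame(s: Schedule, inst: Instance) -> pd.DataFrame:
    """Long-format (day, bed, patient, category) table of the allocation."""
    beds = bed_layout(s, inst)
    rows = []
    for cat, pid, start, end in _stays(s, inst):
        for day in range(start, end + 1):
            rows.append((day, f"B{beds[pid]}", pid, cat))
    return pd.DataFrame(
        sorted(rows), columns=["day", "bed", "patient_id", "category"]
    )
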