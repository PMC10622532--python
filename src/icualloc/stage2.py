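"""Length-of-stay disturbances and the three second-stage repair strategies.

After the stage-1 allocation is fixed, elective and current patients may
stay longer than planned.  A disturbance (:class:`ExtensionDraw`) samples a
per-patient extension from the configured law — by default extra whole days
with probabilities 40/25/20/10/5 percent for 0..4 days — plus a stream of
new emergency arrivals from the same Poisson model, capped so daily totals
never exceed the admission cap.

Three repairs are compared:

* ``elective-first`` keeps every stage-1 assignment (extended) and admits
  new emergencies only while a nominal bed is free, rejecting the rest;
* ``emergency-first`` admits every emergency and re-admits electives
  greedily into the remaining capacity, postponing those that no longer fit;
* ``recall`` re-runs the evolutionary search on (max similarity, min added
  beds) under no-deterioration constraints on the stage-1 objectives and
  returns the front member with the fewest added beds (ties to higher
  similarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .instance import EmergencyArrival, ExtensionDistribution, Instance
from .nsga2 import (
    GAParams,
    ParetoFront,
    _extended_base,
    _fits,
    _place,
    reinsert,
    run_stage2,
)
from .schedule import (
    Schedule,
    StageOneReference,
    elective_current_occupancy,
    f21_similarity,
    f22_added_beds,
    occupancy_vector,
)

__all__ = [
    "ExtensionDraw",
    "Stage2Result",
    "sample_extensions",
    "apply_extensions",
    "elective_first",
    "emergency_first",
    "recall",
    "STRATEGIES",
]


@dataclass
class ExtensionDraw:
    """One realized stage-2 disturbance.

    ``elective_los`` / ``current_remaining`` hold the extended (in-effect)
    values for every patient; ``new_emergencies`` is the additional arrival
    stream of the repair period.
    """

    elective_los: dict[int, int]
    current_remaining: dict[int, int]
    new_emergencies: list[EmergencyArrival] = field(default_factory=list)


@dataclass
class Stage2Result:
    """Outcome of one repair strategy on one disturbance."""

    strategy: str
    schedule: Schedule
    f21: float
    f22: int
    rejected_emergencies: int
    postponed_electives: int


def sample_extensions(
    inst: Instance,
    dist: ExtensionDistribution | None = None,
    rng: np.random.Generator | int = 0,
    *,
    reference: Schedule | None = None,
    include_new_emergencies: bool = True,
) -> ExtensionDraw:
    """Draw per-patient LOS extensions and a new emergency stream.

    In additive mode the new stay is ``LOS + e``; in multiplicative mode it
    is the unique integer in ``[LOS*(1+R), LOS*(1+R)+1)``.  When a
    ``reference`` schedule is given, new daily emergency counts are capped
    so that stage-1 plus new arrivals stay within ``Mp_t``.
    """
    dist = dist or inst.extension_dist
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    elective_los = {
        p.id: dist.extend(p.los, float(dist.sample(rng)))
        for p in inst.electives
    }
    current_remaining = {
        c.id: dist.extend(c.remaining, float(dist.sample(rng)))
        for c in inst.currents
    }
    new: list[EmergencyArrival] = []
    if include_new_emergencies:
        counts = inst.arrivals.sample_counts(rng)
        caps = inst.max_per_day
        existing_ids = (
            [e.id for e in reference.emergencies] if reference else []
        )
        next_id = max(existing_ids, default=20_000) + 1
        for day, n in enumerate(counts, start=1):
            if reference is not None:
                room = caps[day - 1] - reference.emergency_count(day)
                n = min(n, max(0, room))
            for _ in range(n):
                new.append(
                    EmergencyArrival(
                        id=next_id,
                        arrival_day=day,
                        los=int(inst.emergency_los_dist.sample(rng)),
                    )
                )
                next_id += 1
    return ExtensionDraw(elective_los, current_remaining, new)


def apply_extensions(s: Schedule, draw: ExtensionDraw) -> Schedule:
    """The schedule with every stay lengthened in place (days unchanged).

    The result may violate capacity; the repair strategies deal with that.
    New emergencies are *not* added here — they are an admission decision.
    """
    out = s.copy()
    out.elective_los = dict(draw.elective_los)
    out.current_remaining = dict(draw.current_remaining)
    return out


# ---------------------------------------------------------------------------
# strategies
# ---------------------------------------------------------------------------

def _result(
    name: str,
    stage1: Schedule,
    repaired: Schedule,
    inst: Instance,
    rejected: int,
    postponed: int,
) -> Stage2Result:
    return Stage2Result(
        strategy=name,
        schedule=repaired,
        f21=f21_similarity(stage1, repaired, inst),
        f22=f22_added_beds(stage1, repaired, inst),
        rejected_emergencies=rejected,
        postponed_electives=postponed,
    )


def elective_first(
    s: Schedule, inst: Instance, draw: ExtensionDraw
) -> Stage2Result:
    """Keep every stage-1 assignment verbatim; meet overflow with added beds.

    All stage-1 electives, currents, and already-admitted emergencies are
    served with their extended stays at their stage-1 days, and new
    emergencies are taken in as they arrive, so the daily bed requirement
    (and hence the added-bed count) reflects the full committed demand.  A
    new emergency is counted as rejected when no nominal-capacity bed is
    free for its whole stay — it can only be served in an added bed.
    """
    repaired = apply_extensions(s, draw)
    occ = list(occupancy_vector(repaired, inst))
    rejected = 0
    for e in sorted(draw.new_emergencies, key=lambda e: (e.arrival_day, e.id)):
        if not _fits(occ, e.arrival_day, e.los, inst.beds):
            rejected += 1
        repaired.emergencies.append(e)
        _place(occ, e.arrival_day, e.los)
    return _result("elective-first", s, repaired, inst, rejected, 0)


def emergency_first(
    s: Schedule, inst: Instance, draw: ExtensionDraw
) -> Stage2Result:
    """Serve all emergency and current demand; refit electives greedily.

    No emergency is ever rejected.  Electives are re-admitted greedily in
    two passes, most severe and shortest first: the first pass keeps every
    patient whose stage-1 day still fits at that day, the second places the
    remainder at their earliest feasible day; patients that fit nowhere are
    postponed beyond the horizon.
    """
    repaired = apply_extensions(s, draw)
    stage1_days = dict(repaired.admission_day)
    repaired.admission_day = {}
    repaired.emergencies = list(s.emergencies) + list(draw.new_emergencies)
    occ = list(occupancy_vector(repaired, inst))
    order = sorted(
        stage1_days,
        key=lambda pid: (
            -inst.elective(pid).loss_of_chance,
            repaired.los_of(inst, pid),
            pid,
        ),
    )
    displaced = []
    for pid in order:
        los = repaired.los_of(inst, pid)
        if _fits(occ, stage1_days[pid], los, inst.beds):
            repaired.admission_day[pid] = stage1_days[pid]
            _place(occ, stage1_days[pid], los)
        else:
            displaced.append(pid)
    postponed = 0
    for pid in displaced:
        p = inst.elective(pid)
        los = repaired.los_of(inst, pid)
        for d in range(p.expected_day, inst.horizon + 1):
            if _fits(occ, d, los, inst.beds):
                repaired.admission_day[pid] = d
                _place(occ, d, los)
                break
        else:
            postponed += 1
    return _result("emergency-first", s, repaired, inst, 0, postponed)


def recall(
    s: Schedule,
    inst: Instance,
    draw: ExtensionDraw,
    params: GAParams | None = None,
    reference: StageOneReference | None = None,
) -> Stage2Result:
    """Re-run the evolutionary search and pick the fewest-added-beds solution.

    Wraps the stage-2 NSGA-II (no deterioration of the frozen stage-1
    objectives) and selects, from the returned front, the schedule with
    minimal added beds, breaking ties toward higher similarity.  The full
    front is attached to the result's schedule-independent metadata via
    :func:`recall_front` when needed.
    """
    if reference is None:
        from .schedule import stage1_objectives

        reference = StageOneReference(s, stage1_objectives(s, inst))
    front = run_stage2(inst, reference, draw, params)
    i = min(
        range(len(front)),
        key=lambda k: (front.objectives[k, 1], -front.objectives[k, 0]),
    )
    chosen = front.schedules[i]
    postponed = len(s.admission_day) - len(chosen.admission_day)
    res = _result("recall", s, chosen, inst, 0, max(0, postponed))
    res.front = front  # full front kept for reporting
    return res


STRATEGIES = {
    "elective-first": elective_first,
    "emergency-first": emergency_first,
    "recall": recall,
}
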