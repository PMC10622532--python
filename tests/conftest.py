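"""Shared fixtures and hypothesis settings for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from icualloc.instance import (
    ArrivalModel,
    CurrentPatient,
    ElectivePatient,
    Instance,
)
from icualloc.nsga2 import STAGE1_SENSES, STAGE2_SENSES, _fits, _to_min
from icualloc.schedule import (
    Schedule,
    _occupancy_list,
    elective_current_occupancy,
    stage1_objectives,
)
from icualloc.synthetic import GeneratorConfig, generate_instance

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# instances
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_instance() -> Instance:
    """The generator's defaults: 24 beds, 7 days, 100 electives, 3 currents."""
    return generate_instance(seed=0)


@pytest.fixture(scope="session")
def small_instance() -> Instance:
    """A smaller instance for fast unit-level search tests."""
    return generate_instance(
        GeneratorConfig(
            beds=8, horizon=5, n_electives=20, n_currents=2,
            rate_range=(1.0, 2.0), seed=3,
        )
    )


def no_arrivals(horizon: int) -> ArrivalModel:
    return ArrivalModel(tuple([0.0] * horizon))


@pytest.fixture(scope="session")
def toy_instances() -> dict[str, Instance]:
    """Enumerable stage-1 toys (λ=0) with known exhaustive Pareto fronts."""
    return {
        # three one-day patients competing for one bed: delay/occupancy tradeoff
        "one-bed": Instance(
            beds=1, horizon=3,
            electives=(
                ElectivePatient(1, 1, 1, 0.9),
                ElectivePatient(2, 1, 1, 0.5),
                ElectivePatient(3, 1, 1, 0.1),
            ),
            currents=(), arrivals=no_arrivals(3),
        ),
        # mixed lengths of stay over two beds
        "two-bed": Instance(
            beds=2, horizon=3,
            electives=(
                ElectivePatient(1, 1, 2, 0.5),
                ElectivePatient(2, 1, 1, 0.9),
                ElectivePatient(3, 2, 2, 0.1),
                ElectivePatient(4, 1, 1, 0.1),
                ElectivePatient(5, 2, 1, 0.9),
            ),
            currents=(), arrivals=no_arrivals(3),
        ),
        # a current patient blocking one bed for the first two days
        "with-current": Instance(
            beds=2, horizon=3,
            electives=(
                ElectivePatient(1, 1, 1, 0.5),
                ElectivePatient(2, 1, 2, 0.9),
                ElectivePatient(3, 2, 1, 0.1),
                ElectivePatient(4, 3, 1, 0.9),
            ),
            currents=(CurrentPatient(10001, 3, 2),),
            arrivals=no_arrivals(3),
        ),
    }


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def all_admission_maps(inst: Instance):
    """Every capacity-feasible elective admission map of a λ=0 instance."""
    options = [
        [None] + list(range(p.expected_day, inst.horizon + 1))
        for p in inst.electives
    ]
    for combo in itertools.product(*options):
        s = Schedule.empty(inst)
        for p, day in zip(inst.electives, combo):
            if day is not None:
                s.admission_day[p.id] = day
        if (elective_current_occupancy(s, inst) <= inst.beds).all():
            yield s


def is_maximal(s: Schedule, inst: Instance, include_emergencies: bool = True) -> bool:
    """True iff no waiting elective fits any remaining vacancy."""
    occ = _occupancy_list(s, inst, include_emergencies)
    for p in inst.electives:
        if p.id in s.admission_day:
            continue
        los = s.los_of(inst, p.id)
        for d in range(p.expected_day, inst.horizon + 1):
            if _fits(occ, d, los, inst.beds):
                return False
    return True


def pareto_set(vectors, senses) -> set[tuple]:
    """Non-dominated subset of objective vectors by pairwise comparison."""
    arr = np.array(sorted(set(map(tuple, vectors))), dtype=float)
    F = _to_min(arr, senses)
    out = set()
    for i in range(len(F)):
        dominated = ((F <= F[i]).all(axis=1) & (F < F[i]).any(axis=1)).any()
        if not dominated:
            out.add(tuple(arr[i]))
    return out


def exhaustive_stage1_front(inst: Instance) -> set[tuple]:
    """Exact Pareto front over maximal feasible schedules (λ=0 instances).

    Maximality reflects the algorithm's solution space: every individual
    passes through the re-insertion repair, so schedules leaving a fillable
    vacancy are unreachable by construction.
    """
    vecs = [
        tuple(round(v, 12) for v in stage1_objectives(s, inst).values)
        for s in all_admission_maps(inst)
        if is_maximal(s, inst)
    ]
    return pareto_set(vecs, STAGE1_SENSES)


def brute_force_fronts(F: np.ndarray) -> np.ndarray:
    """O(n²·m) non-domination front indices for a minimization matrix."""
    n = len(F)
    dominated_by = [
        {
            j
            for j in range(n)
            if j != i and (F[j] <= F[i]).all() and (F[j] < F[i]).any()
        }
        for i in range(n)
    ]
    front = np.zeros(n, dtype=int)
    assigned: set[int] = set()
    k = 1
    while len(assigned) < n:
        level = [
            i
            for i in range(n)
            if i not in assigned and dominated_by[i] <= assigned
        ]
        for i in level:
            front[i] = k
        assigned.update(level)
        k += 1
    return front
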