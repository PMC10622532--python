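"""Problem-specific NSGA-II for the two allocation stages.

The encoding is the elective admission map of a :class:`~icualloc.schedule.Schedule`;
current patients and the individual's realized emergency scenario are fixed
genes that the variation operators never touch.  All operators are
feasibility preserving: the crossover exchanges two elective admission dates
and falls back to the parent when the exchange would break capacity or
expected-date rules; the mutation replaces an admitted elective by a waiting
one with no longer stay; the re-insertion pass greedily fills vacant
bed-days with waiting electives, most severe and shortest first.

Stage 1 searches (max f11, min f12, max f13).  Stage 2 searches
(max f21, min f22) subject to no deterioration of the frozen stage-1
objective values, handled by constrained dominance (feasible solutions
always outrank infeasible ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .instance import EmergencyArrival, Instance
from .schedule import (
    ObjectiveVector,
    Schedule,
    StageOneReference,
    elective_current_occupancy,
    f11_occupancy_rate,
    f12_delay_index,
    f13_emergency_rate,
    f21_similarity,
    f22_added_beds,
    occupancy_vector,
    stage1_objectives,
)
from .synthetic import sample_emergency_stream

__all__ = [
    "GAParams",
    "RankedPopulation",
    "ParetoFront",
    "random_individual",
    "initial_population",
    "crossover",
    "mutate",
    "reinsert",
    "rank",
    "run_stage1",
    "run_stage2",
    "hypervolume",
    "STAGE1_SENSES",
    "STAGE2_SENSES",
]

STAGE1_SENSES = ("max", "min", "max")
STAGE2_SENSES = ("max", "min")

_REF_TOL = 1e-9  # slack when comparing against frozen stage-1 objectives


@dataclass
class GAParams:
    """Evolutionary search parameters (population, generations, rates)."""

    population: int = 100
    generations: int = 200
    mutation_rate: float = 0.1
    crossover_rate: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2 or self.population % 2:
            raise ValueError("population must be an even integer >= 2")
        for r in (self.mutation_rate, self.crossover_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# capacity-aware placement helpers
# ---------------------------------------------------------------------------

def _occupancy(s: Schedule, inst: Instance, include_emergencies: bool) -> list:
    from .schedule import _occupancy_list

    return _occupancy_list(s, inst, include_emergencies)


def _fits(occ: list, day: int, los: int, cap: int) -> bool:
    for i in range(day - 1, min(day + los - 1, len(occ))):
        if occ[i] >= cap:
            return False
    return True


def _place(occ: list, day: int, los: int) -> None:
    for i in range(day - 1, min(day + los - 1, len(occ))):
        occ[i] += 1


def _remove(occ: list, day: int, los: int) -> None:
    for i in range(day - 1, min(day + los - 1, len(occ))):
        occ[i] -= 1


def _feasible_days(occ: list, expected: int, los: int, cap: int) -> list[int]:
    return [
        d for d in range(expected, len(occ) + 1) if _fits(occ, d, los, cap)
    ]


def _first_feasible_day(
    occ: list, expected: int, los: int, cap: int
) -> int | None:
    for d in range(expected, len(occ) + 1):
        if _fits(occ, d, los, cap):
            return d
    return None


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def random_individual(
    inst: Instance,
    rng: np.random.Generator,
    emergencies: Sequence[EmergencyArrival] | None = None,
    *,
    include_emergencies: bool = True,
) -> Schedule:
    """One feasible schedule: currents, a sampled emergency scenario, then
    electives placed greedily in random order at random feasible days."""
    if emergencies is None:
        emergencies = sample_emergency_stream(inst, rng)
    s = Schedule.empty(inst, emergencies)
    occ = _occupancy(s, inst, include_emergencies)
    order = rng.permutation([p.id for p in inst.electives])
    for pid in order:
        p = inst.elective(int(pid))
        days = _feasible_days(occ, p.expected_day, p.los, inst.beds)
        if days:
            day = int(days[rng.integers(len(days))])
            s.admission_day[p.id] = day
            _place(occ, day, p.los)
    return reinsert(s, inst, include_emergencies=include_emergencies)


def initial_population(
    inst: Instance, params: GAParams
) -> list[Schedule]:
    """``population`` independent feasible individuals (substream per member)."""
    streams = np.random.SeedSequence(params.seed).spawn(params.population)
    return [
        random_individual(inst, np.random.default_rng(ss)) for ss in streams
    ]


def _swap_two(
    s: Schedule,
    inst: Instance,
    rng: np.random.Generator,
    include_emergencies: bool,
) -> Schedule:
    """Exchange two admitted electives' dates; reject infeasible exchanges."""
    child = s.copy()
    admitted = sorted(child.admission_day)
    if len(admitted) < 2:
        return child
    i, j = (int(x) for x in rng.choice(admitted, size=2, replace=False))
    di, dj = child.admission_day[i], child.admission_day[j]
    pi, pj = inst.elective(i), inst.elective(j)
    if dj < pi.expected_day or di < pj.expected_day:
        return child
    li, lj = child.los_of(inst, i), child.los_of(inst, j)
    occ = _occupancy(child, inst, include_emergencies)
    _remove(occ, di, li)
    _remove(occ, dj, lj)
    if _fits(occ, dj, li, inst.beds):
        _place(occ, dj, li)
        if _fits(occ, di, lj, inst.beds):
            child.admission_day[i] = dj
            child.admission_day[j] = di
            return child
    return s.copy()


def crossover(
    a: Schedule,
    b: Schedule,
    inst: Instance,
    rng: np.random.Generator,
    *,
    include_emergencies: bool = True,
) -> tuple[Schedule, Schedule]:
    """Per-parent exchange of two elective admission dates (capacity guarded)."""
    return (
        _swap_two(a, inst, rng, include_emergencies),
        _swap_two(b, inst, rng, include_emergencies),
    )


def mutate(
    s: Schedule,
    inst: Instance,
    rng: np.random.Generator,
    *,
    include_emergencies: bool = True,
) -> Schedule:
    """Remove one admitted elective; insert a waiting one with LOS no longer.

    The replacement is admitted at its earliest feasible day at or after its
    expected day; if no candidate fits, the removal alone stands.
    """
    child = s.copy()
    admitted = sorted(child.admission_day)
    if not admitted:
        return child
    removed = int(rng.choice(admitted))
    removed_los = child.los_of(inst, removed)
    day = child.admission_day.pop(removed)
    occ = _occupancy(child, inst, include_emergencies)
    candidates = [
        p.id
        for p in inst.electives
        if p.id not in child.admission_day
        and p.id != removed
        and child.los_of(inst, p.id) <= removed_los
    ]
    rng.shuffle(candidates)
    for pid in candidates:
        p = inst.elective(pid)
        los = child.los_of(inst, pid)
        day = _first_feasible_day(occ, p.expected_day, los, inst.beds)
        if day is not None:
            child.admission_day[pid] = day
            return child
    return child


def reinsert(
    s: Schedule, inst: Instance, *, include_emergencies: bool = True
) -> Schedule:
    """Fill vacant bed-days with waiting electives.

    Candidates are taken most severe first (loss of chance descending), then
    shortest stay, then lowest id, each admitted at its earliest feasible day
    at or after its expected day.
    """
    child = s.copy()
    occ = _occupancy(child, inst, include_emergencies)
    waiting = sorted(
        (p for p in inst.electives if p.id not in child.admission_day),
        key=lambda p: (-p.loss_of_chance, child.los_of(inst, p.id), p.id),
    )
    for p in waiting:
        los = child.los_of(inst, p.id)
        day = _first_feasible_day(occ, p.expected_day, los, inst.beds)
        if day is not None:
            child.admission_day[p.id] = day
            _place(occ, day, los)
    return child


# ---------------------------------------------------------------------------
# non-dominated sorting and crowding
# ---------------------------------------------------------------------------

def _to_min(objectives: np.ndarray, senses: Sequence[str]) -> np.ndarray:
    F = np.asarray(objectives, dtype=float).copy()
    for j, sense in enumerate(senses):
        if sense == "max":
            F[:, j] = -F[:, j]
        elif sense != "min":
            raise ValueError(f"unknown sense {sense!r}")
    return F


def _fast_nondominated_sort(F: np.ndarray) -> np.ndarray:
    """Front index (1-based) of each row of the minimization matrix ``F``."""
    n = len(F)
    le = (F[:, None, :] <= F[None, :, :]).all(-1)
    lt = (F[:, None, :] < F[None, :, :]).any(-1)
    dominates = le & lt  # dominates[i, j]: i dominates j
    n_dominators = dominates.sum(axis=0)
    front = np.zeros(n, dtype=int)
    current = np.flatnonzero(n_dominators == 0)
    k = 1
    while current.size:
        front[current] = k
        n_dominators = n_dominators - dominates[current].sum(axis=0)
        n_dominators[front > 0] = -1
        current = np.flatnonzero(n_dominators == 0)
        k += 1
    return front


def _crowding(F: np.ndarray, front: np.ndarray) -> np.ndarray:
    dist = np.zeros(len(F))
    for f in np.unique(front):
        idx = np.flatnonzero(front == f)
        if idx.size <= 2:
            dist[idx] = np.inf
            continue
        for j in range(F.shape[1]):
            order = idx[np.argsort(F[idx, j], kind="stable")]
            span = F[order[-1], j] - F[order[0], j]
            dist[order[0]] = dist[order[-1]] = np.inf
            if span > 0:
                gaps = (F[order[2:], j] - F[order[:-2], j]) / span
                dist[order[1:-1]] += gaps
    return dist


@dataclass
class RankedPopulation:
    """Schedules with non-domination front index (1 = Pareto) and crowding."""

    schedules: list[Schedule]
    objectives: np.ndarray
    senses: tuple[str, ...]
    front_index: np.ndarray
    crowding: np.ndarray

    def front(self, k: int = 1) -> list[int]:
        return list(np.flatnonzero(self.front_index == k))


def rank(
    population: Sequence[Schedule],
    objectives: np.ndarray,
    senses: Sequence[str],
) -> RankedPopulation:
    """Fast non-dominated sort plus crowding distance."""
    F = _to_min(objectives, senses)
    front = _fast_nondominated_sort(F)
    crowd = _crowding(F, front)
    return RankedPopulation(
        list(population), np.asarray(objectives, float), tuple(senses), front, crowd
    )


@dataclass
class ParetoFront:
    """A mutually non-dominated solution set with its objective values."""

    schedules: list[Schedule]
    objectives: np.ndarray
    stage: int
    senses: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.schedules)

    def objective_vectors(self) -> list[ObjectiveVector]:
        return [ObjectiveVector(self.stage, tuple(v)) for v in self.objectives]


def _first_front(
    pop: list[Schedule], objs: np.ndarray, senses: Sequence[str], stage: int
) -> ParetoFront:
    ranked = rank(pop, objs, senses)
    idx = ranked.front(1)
    # drop exact duplicates (same admissions, same objective values)
    seen: set = set()
    keep = []
    for i in idx:
        key = (
            tuple(sorted(pop[i].admission_day.items())),
            tuple(np.round(objs[i], 12)),
        )
        if key not in seen:
            seen.add(key)
            keep.append(i)
    return ParetoFront(
        [pop[i] for i in keep], np.asarray([objs[i] for i in keep]), stage,
        tuple(senses),
    )


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _tournament(
    rng: np.random.Generator, front: np.ndarray, crowd: np.ndarray
) -> int:
    i, j = rng.integers(len(front)), rng.integers(len(front))
    if (front[i], -crowd[i]) <= (front[j], -crowd[j]):
        return int(i)
    return int(j)


def _evolve(
    inst: Instance,
    params: GAParams,
    population: list[Schedule],
    evaluate: Callable[[Schedule], tuple[float, ...]],
    senses: Sequence[str],
    *,
    include_emergencies: bool = True,
    feasible: Callable[[Schedule], bool] | None = None,
    generation_hook: Callable[[int, RankedPopulation], None] | None = None,
) -> tuple[list[Schedule], np.ndarray]:
    """Elitist (mu + lambda) NSGA-II loop shared by both stages.

    ``feasible`` implements constrained dominance: individuals failing it
    are ranked strictly after every feasible one.
    """
    rng = np.random.default_rng(params.seed)
    pop = list(population)
    objs = np.array([evaluate(s) for s in pop], dtype=float)

    def ranked_keys(pop_, objs_):
        ranked = rank(pop_, objs_, senses)
        front = ranked.front_index.astype(float)
        worst = front.max() + 1
        if feasible is not None:
            bad = np.array([not feasible(s) for s in pop_])
            front = front + bad * worst
        # push exact clones behind their first occurrence to keep the
        # population from filling with copies of one schedule
        seen: set = set()
        for i, s in enumerate(pop_):
            key = (
                tuple(sorted(s.admission_day.items())),
                tuple((e.id, e.arrival_day, e.los) for e in s.emergencies),
            )
            if key in seen:
                front[i] += 2 * worst
            else:
                seen.add(key)
        return ranked, front

    ranked, front = ranked_keys(pop, objs)
    for gen in range(params.generations):
        offspring: list[Schedule] = []
        while len(offspring) < params.population:
            a = pop[_tournament(rng, front, ranked.crowding)]
            b = pop[_tournament(rng, front, ranked.crowding)]
            if rng.random() < params.crossover_rate:
                c1, c2 = crossover(
                    a, b, inst, rng, include_emergencies=include_emergencies
                )
            else:
                c1, c2 = a.copy(), b.copy()
            for child in (c1, c2):
                if rng.random() < params.mutation_rate:
                    child = mutate(
                        child, inst, rng,
                        include_emergencies=include_emergencies,
                    )
                child = reinsert(
                    child, inst, include_emergencies=include_emergencies
                )
                offspring.append(child)
        offspring = offspring[: params.population]
        off_objs = np.array([evaluate(s) for s in offspring], dtype=float)
        pool = pop + offspring
        pool_objs = np.vstack([objs, off_objs])
        ranked, front = ranked_keys(pool, pool_objs)
        order = np.lexsort((-ranked.crowding, front))
        keep = order[: params.population]
        pop = [pool[i] for i in keep]
        objs = pool_objs[keep]
        ranked, front = ranked_keys(pop, objs)
        if generation_hook is not None:
            generation_hook(gen, ranked)
    return pop, objs


def run_stage1(
    inst: Instance,
    params: GAParams | None = None,
    *,
    generation_hook: Callable[[int, RankedPopulation], None] | None = None,
) -> ParetoFront:
    """Stage-1 search over (max occupancy, min delay index, max emergency rate).

    Each individual carries its own realized emergency scenario, sampled at
    creation and inherited unchanged by its offspring, so the front can mix
    high- and low-arrival scenarios.
    """
    params = params or GAParams()
    pop = initial_population(inst, params)

    def evaluate(s: Schedule) -> tuple[float, ...]:
        return stage1_objectives(s, inst).values

    pop, objs = _evolve(
        inst, params, pop, evaluate, STAGE1_SENSES,
        generation_hook=generation_hook,
    )
    return _first_front(pop, objs, STAGE1_SENSES, stage=1)


def _extended_base(inst: Instance, ref: StageOneReference, draw) -> Schedule:
    """The stage-1 schedule with the disturbance applied verbatim."""
    s = ref.schedule.copy()
    s.elective_los = dict(draw.elective_los)
    s.current_remaining = dict(draw.current_remaining)
    s.emergencies = list(ref.schedule.emergencies) + list(draw.new_emergencies)
    return s


def _respects_reference(
    s: Schedule, inst: Instance, ref: StageOneReference
) -> bool:
    """No deterioration of the frozen stage-1 objective values."""
    o = ref.objectives
    return (
        f11_occupancy_rate(s, inst) >= o.f11 - _REF_TOL
        and f12_delay_index(s, inst) <= o.f12 + _REF_TOL
        and f13_emergency_rate(s, inst) >= o.f13 - _REF_TOL
    )


def _drop_repair(base: Schedule, inst: Instance) -> Schedule:
    """Restore total capacity by evicting admitted electives.

    Repeatedly removes, among electives occupying an overloaded day, one with
    the largest delay contribution (removing an above-average contributor
    cannot increase the mean delay index).  Days overloaded by fixed genes
    alone (currents and emergencies) are left as they are.
    """
    s = base.copy()
    occ = occupancy_vector(s, inst)
    while (occ > inst.beds).any():
        over = np.flatnonzero(occ > inst.beds)
        on_day = []
        for day0 in over:
            day = int(day0) + 1
            on_day = [
                pid
                for pid, d in s.admission_day.items()
                if d <= day <= d + s.los_of(inst, pid) - 1
            ]
            if on_day:
                break
        if not on_day:
            break  # fixed genes alone overflow: nothing an eviction can do
        contrib = {
            pid: inst.elective(pid).loss_of_chance
            * (s.admission_day[pid] - inst.elective(pid).expected_day)
            for pid in on_day
        }
        victim = max(on_day, key=lambda pid: (contrib[pid], pid))
        _remove(occ, s.admission_day.pop(victim), s.los_of(inst, victim))
    return s


def run_stage2(
    inst: Instance,
    ref: StageOneReference,
    draw,
    params: GAParams | None = None,
) -> ParetoFront:
    """Stage-2 search over (max similarity f21, min added beds f22).

    If the stage-1 schedule, extended and with the new arrivals, still fits
    entirely within the nominal bed count it is returned unchanged.
    Otherwise the elective admission map is re-optimized
    under the extended stays; candidates that would worsen any frozen
    stage-1 objective are ranked as infeasible (constrained dominance) and
    never enter the returned front unless no feasible solution was found, in
    which case the greedy eviction repair is returned and flagged in
    ``metadata['constraints_met']``.
    """
    params = params or GAParams()
    base = _extended_base(inst, ref, draw)

    def evaluate(s: Schedule) -> tuple[float, float]:
        return (
            f21_similarity(ref.schedule, s, inst),
            float(f22_added_beds(ref.schedule, s, inst)),
        )

    if (occupancy_vector(base, inst) <= inst.beds).all():
        objs = np.array([evaluate(base)])
        return ParetoFront(
            [base], objs, stage=2, senses=STAGE2_SENSES,
            metadata={"constraints_met": True, "short_circuit": True},
        )

    rng = np.random.default_rng(params.seed)
    repaired = _drop_repair(base, inst)
    pop = [repaired]
    original_days = dict(ref.schedule.admission_day)
    for _ in range(params.population - 1):
        s = Schedule(
            {}, list(base.emergencies), dict(base.elective_los),
            dict(base.current_remaining),
        )
        occ = list(occupancy_vector(s, inst))
        for pid in rng.permutation(sorted(original_days)):
            pid = int(pid)
            p = inst.elective(pid)
            los = s.los_of(inst, pid)
            d0 = original_days[pid]
            if _fits(occ, d0, los, inst.beds):
                s.admission_day[pid] = d0
                _place(occ, d0, los)
            elif rng.random() < 0.5:
                days = _feasible_days(occ, p.expected_day, los, inst.beds)
                if days:
                    day = int(days[rng.integers(len(days))])
                    s.admission_day[pid] = day
                    _place(occ, day, los)
        pop.append(s)

    def feasible(s: Schedule) -> bool:
        return _respects_reference(s, inst, ref)

    pop, objs = _evolve(
        inst, params, pop, evaluate, STAGE2_SENSES,
        include_emergencies=True, feasible=feasible,
    )
    ok = [i for i, s in enumerate(pop) if feasible(s)]
    if not ok:
        objs = np.array([evaluate(repaired)])
        return ParetoFront(
            [repaired], objs, stage=2, senses=STAGE2_SENSES,
            metadata={"constraints_met": False, "short_circuit": False},
        )
    front = _first_front(
        [pop[i] for i in ok], objs[ok], STAGE2_SENSES, stage=2
    )
    front.metadata.update(constraints_met=True, short_circuit=False)
    return front


# ---------------------------------------------------------------------------
# hypervolume (for marking the best of repeated runs)
# ---------------------------------------------------------------------------

def hypervolume(
    objectives: np.ndarray,
    senses: Sequence[str],
    reference: Sequence[float] | None = None,
) -> float:
    """Dominated hypervolume w.r.t. a reference point (small fronts only).

    Objectives are converted to minimization; the reference defaults to the
    per-objective worst value plus 1.
    """
    F = _to_min(np.atleast_2d(objectives), senses)
    if reference is None:
        ref = F.max(axis=0) + 1.0
    else:
        ref = _to_min(np.atleast_2d(reference), senses)[0]
    F = F[(F <= ref).all(axis=1)]
    if not len(F):
        return 0.0

    def hv(points: np.ndarray, ref: np.ndarray) -> float:
        if points.shape[1] == 1:
            return float(ref[0] - points[:, 0].min())
        total = 0.0
        prev = None
        order = np.argsort(points[:, 0], kind="stable")
        pts = points[order]
        for i, x in enumerate(pts[:, 0]):
            if prev is not None and x == prev:
                continue
            width_end = pts[i + 1 :, 0]
            nxt = width_end[width_end > x].min() if (width_end > x).any() else ref[0]
            slab = pts[pts[:, 0] <= x][:, 1:]
            total += (nxt - x) * hv(slab, ref[1:])
            prev = x
        return total

    return hv(F, ref)
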