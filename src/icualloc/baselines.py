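"""Multi-objective simulated annealing and tabu search baselines.

Both baselines share the NSGA-II encoding, neighborhood moves (the elective
date-exchange and the remove/replace mutation), objectives, and feasibility
rules, so comparisons isolate the search strategy.  Each maintains a bounded
archive of mutually non-dominated schedules which is returned as the front.

A paired one-sided t-test utility supports algorithm comparisons of the form
H1: mu_NSGA-II - mu_other < 0 on a per-run scalar (mean stage-2 added beds
by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .instance import Instance
from .nsga2 import (
    GAParams,
    ParetoFront,
    _crowding,
    _drop_repair,
    _extended_base,
    _respects_reference,
    _to_min,
    mutate,
    random_individual,
    reinsert,
    run_stage1,
    STAGE1_SENSES,
    STAGE2_SENSES,
    _swap_two,
    rank,
)
from .schedule import (
    Schedule,
    StageOneReference,
    f21_similarity,
    f22_added_beds,
    stage1_objectives,
)
from .stage2 import ExtensionDraw, STRATEGIES, sample_extensions, recall

__all__ = [
    "MOSAParams",
    "MOTSParams",
    "Archive",
    "run_mosa",
    "run_mots",
    "paired_t_test",
    "compare_algorithms",
]


@dataclass
class MOSAParams:
    """Simulated-annealing schedule: geometric cooling 1000 -> 1e-3 at 0.95."""

    start_temperature: float = 1000.0
    end_temperature: float = 1e-3
    cooling_rate: float = 0.95
    moves_per_temperature: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling_rate < 1.0:
            raise ValueError("cooling_rate must lie in (0, 1)")
        if self.end_temperature >= self.start_temperature:
            raise ValueError("end temperature must be below start")

    @property
    def n_levels(self) -> int:
        """Temperature levels until start * rate**n <= end."""
        n = 0
        t = self.start_temperature
        while t > self.end_temperature:
            t *= self.cooling_rate
            n += 1
        return n


@dataclass
class MOTSParams:
    """Tabu-search controls: list 50, tenure 5, 10 candidates, 200 iterations."""

    tabu_list_size: int = 50
    tabu_tenure: int = 5
    candidate_set_size: int = 10
    iterations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (
            self.tabu_list_size,
            self.tabu_tenure,
            self.candidate_set_size,
            self.iterations,
        ):
            if v < 1:
                raise ValueError("all tabu-search parameters must be positive")


class Archive:
    """Bounded set of mutually non-dominated schedules."""

    def __init__(self, senses: Sequence[str], capacity: int = 100):
        self.senses = tuple(senses)
        self.capacity = capacity
        self.schedules: list[Schedule] = []
        self._objs: list[tuple[float, ...]] = []

    def __len__(self) -> int:
        return len(self.schedules)

    @property
    def objectives(self) -> np.ndarray:
        return np.asarray(self._objs, dtype=float).reshape(len(self._objs), -1)

    def add(self, s: Schedule, obj: Sequence[float]) -> bool:
        """Insert if non-dominated; evict dominated members; prune crowding."""
        obj = tuple(float(x) for x in obj)
        fnew = _to_min(np.array([obj]), self.senses)[0]
        keep_s, keep_o = [], []
        for sch, o in zip(self.schedules, self._objs):
            fo = _to_min(np.array([o]), self.senses)[0]
            if (fo <= fnew).all() and (fo < fnew).any():
                return False  # dominated by an archive member
            if o == obj:
                return False
            if not ((fnew <= fo).all() and (fnew < fo).any()):
                keep_s.append(sch)
                keep_o.append(o)
        keep_s.append(s)
        keep_o.append(obj)
        self.schedules, self._objs = keep_s, keep_o
        if len(self.schedules) > self.capacity:
            F = _to_min(self.objectives, self.senses)
            crowd = _crowding(F, np.ones(len(F), dtype=int))
            drop = int(np.argmin(crowd))
            del self.schedules[drop], self._objs[drop]
        return True

    def to_front(self, stage: int) -> ParetoFront:
        return ParetoFront(
            list(self.schedules), self.objectives, stage, self.senses
        )


# ---------------------------------------------------------------------------
# shared stage plumbing
# ---------------------------------------------------------------------------

def _stage_context(
    inst: Instance,
    stage: int,
    ref: StageOneReference | None,
    draw: ExtensionDraw | None,
    rng: np.random.Generator,
):
    """(initial solution, evaluate, senses, feasibility, emergency flag)."""
    if stage == 1:
        initial = random_individual(inst, rng)
        evaluate = lambda s: stage1_objectives(s, inst).values
        feasible = lambda s: True
        return initial, evaluate, STAGE1_SENSES, feasible, True
    if ref is None or draw is None:
        raise ValueError("stage 2 requires a stage-1 reference and a draw")
    base = _extended_base(inst, ref, draw)
    initial = reinsert(
        _drop_repair(base, inst), inst, include_emergencies=True
    )
    evaluate = lambda s: (
        f21_similarity(ref.schedule, s, inst),
        float(f22_added_beds(ref.schedule, s, inst)),
    )
    feasible = lambda s: _respects_reference(s, inst, ref)
    return initial, evaluate, STAGE2_SENSES, feasible, True


def _neighbor(
    s: Schedule,
    inst: Instance,
    rng: np.random.Generator,
    include_emergencies: bool,
) -> Schedule:
    """One move: elective date exchange or remove/replace, then re-insertion."""
    if rng.random() < 0.5:
        nb = _swap_two(s, inst, rng, include_emergencies)
    else:
        nb = mutate(s, inst, rng, include_emergencies=include_emergencies)
    return reinsert(nb, inst, include_emergencies=include_emergencies)


def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool((a <= b).all() and (a < b).any())


# ---------------------------------------------------------------------------
# MOSA
# ---------------------------------------------------------------------------

def run_mosa(
    inst: Instance,
    params: MOSAParams | None = None,
    stage: int = 1,
    ref: StageOneReference | None = None,
    draw: ExtensionDraw | None = None,
    archive_capacity: int = 100,
) -> ParetoFront:
    """Multi-objective simulated annealing with a Pareto archive.

    A neighbor that dominates the current solution is always accepted; a
    dominated neighbor is accepted with probability ``exp(-delta/temp)``
    where ``delta`` is the mean min-max-normalized worsening across
    objectives; mutually non-dominated neighbors are accepted.
    """
    params = params or MOSAParams()
    rng = np.random.default_rng(params.seed)
    current, evaluate, senses, feasible, inc_em = _stage_context(
        inst, stage, ref, draw, rng
    )
    archive = Archive(senses, archive_capacity)
    cur_obj = np.array(evaluate(current), dtype=float)
    if feasible(current):
        archive.add(current, cur_obj)
    lo = _to_min(cur_obj[None], senses)[0].copy()
    hi = lo.copy()

    temp = params.start_temperature
    while temp > params.end_temperature:
        for _ in range(params.moves_per_temperature):
            nb = _neighbor(current, inst, rng, inc_em)
            if not feasible(nb):
                continue
            nb_obj = np.array(evaluate(nb), dtype=float)
            fn = _to_min(nb_obj[None], senses)[0]
            fc = _to_min(cur_obj[None], senses)[0]
            lo, hi = np.minimum(lo, fn), np.maximum(hi, fn)
            archive.add(nb, nb_obj)
            if _dominates(fn, fc):
                accept = True
            elif _dominates(fc, fn):
                span = np.where(hi > lo, hi - lo, 1.0)
                delta = float(np.clip((fn - fc) / span, 0, None).mean())
                accept = rng.random() < np.exp(-delta / temp)
            else:
                accept = True
            if accept:
                current, cur_obj = nb, nb_obj
        temp *= params.cooling_rate
    return archive.to_front(stage)


# ---------------------------------------------------------------------------
# MOTS
# ---------------------------------------------------------------------------

def _move_attr(a: Schedule, b: Schedule) -> tuple:
    """The move between two schedules as the admission-map symmetric diff."""
    da, db = a.admission_day, b.admission_day
    diff = {
        (pid, da.get(pid), db.get(pid))
        for pid in set(da) | set(db)
        if da.get(pid) != db.get(pid)
    }
    return tuple(sorted(diff, key=lambda x: (x[0], x[1] or 0, x[2] or 0)))


def run_mots(
    inst: Instance,
    params: MOTSParams | None = None,
    stage: int = 1,
    ref: StageOneReference | None = None,
    draw: ExtensionDraw | None = None,
    archive_capacity: int = 100,
) -> ParetoFront:
    """Multi-objective tabu search with move-attribute tabu and aspiration.

    Each iteration evaluates a candidate set of neighbors; the best
    non-tabu candidate by (non-domination rank, crowding) becomes current.
    A tabu candidate is still accepted if it enters the archive
    (aspiration).  Move attributes stay tabu for ``tabu_tenure`` iterations
    in a list capped at ``tabu_list_size``.
    """
    params = params or MOTSParams()
    rng = np.random.default_rng(params.seed)
    current, evaluate, senses, feasible, inc_em = _stage_context(
        inst, stage, ref, draw, rng
    )
    archive = Archive(senses, archive_capacity)
    cur_obj = np.array(evaluate(current), dtype=float)
    if feasible(current):
        archive.add(current, cur_obj)
    tabu: list[tuple[tuple, int]] = []  # (move attribute, expiry iteration)

    for it in range(params.iterations):
        tabu = [(m, exp) for m, exp in tabu if exp > it][-params.tabu_list_size:]
        active = {m for m, _ in tabu}
        cands, objs, attrs, aspirated = [], [], [], []
        for _ in range(params.candidate_set_size):
            nb = _neighbor(current, inst, rng, inc_em)
            if not feasible(nb):
                continue
            obj = np.array(evaluate(nb), dtype=float)
            cands.append(nb)
            objs.append(obj)
            attrs.append(_move_attr(current, nb))
            aspirated.append(archive.add(nb, obj))
        if not cands:
            continue
        ranked = rank(cands, np.array(objs), senses)
        order = np.lexsort((-ranked.crowding, ranked.front_index))
        chosen = None
        for k in order:
            if attrs[k] not in active or aspirated[k]:
                chosen = int(k)
                break
        if chosen is None:
            chosen = int(order[0])  # all tabu, none aspirated: move anyway
        if attrs[chosen]:
            tabu.append((attrs[chosen], it + 1 + params.tabu_tenure))
            tabu = tabu[-params.tabu_list_size:]
        current, cur_obj = cands[chosen], objs[chosen]
    return archive.to_front(stage)


# ---------------------------------------------------------------------------
# statistical comparison
# ---------------------------------------------------------------------------

def paired_t_test(x: Sequence[float], y: Sequence[float]) -> dict:
    """One-sided paired t-test of H1: mean(x) - mean(y) < 0."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need at least two paired observations")
    res = stats.ttest_rel(x, y, alternative="less")
    return {
        "mean_difference": float((x - y).mean()),
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "n": int(len(x)),
    }


def _representative(front: ParetoFront) -> int:
    """Index of the front member with the best equal-weight normalized score."""
    F = _to_min(front.objectives, front.senses)
    lo, hi = F.min(axis=0), F.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return int(np.argmin(((F - lo) / span).sum(axis=1)))


def compare_algorithms(
    inst: Instance,
    seeds: Sequence[int],
    nsga_params: GAParams | None = None,
    mosa_params: MOSAParams | None = None,
    mots_params: MOTSParams | None = None,
    recall_params: GAParams | None = None,
    metric: str = "f22",
) -> dict:
    """Paired comparison of NSGA-II against MOSA and MOTS.

    For each seed, every algorithm solves stage 1, a representative front
    member is carried into stage 2 under a shared disturbance seed, and the
    three repair strategies are applied.  The per-seed scalar is the mean
    stage-2 added-bed count (``metric='f22'``), the mean similarity
    (``'f21'``), or the number of admitted patients (``'admitted'``).
    One-sided paired t-tests report whether NSGA-II's mean is lower.
    """
    if len(seeds) < 2:
        raise ValueError("need at least two seeds for a paired comparison")
    nsga_params = nsga_params or GAParams()
    mosa_params = mosa_params or MOSAParams()
    mots_params = mots_params or MOTSParams()
    recall_params = recall_params or GAParams(
        population=30, generations=30, seed=0
    )

    scalars: dict[str, list[float]] = {"nsga2": [], "mosa": [], "mots": []}
    admitted: dict[str, list[float]] = {k: [] for k in scalars}
    for seed in seeds:
        fronts = {
            "nsga2": run_stage1(
                inst, GAParams(
                    nsga_params.population, nsga_params.generations,
                    nsga_params.mutation_rate, nsga_params.crossover_rate,
                    seed=seed,
                )
            ),
            "mosa": run_mosa(
                inst, MOSAParams(
                    mosa_params.start_temperature, mosa_params.end_temperature,
                    mosa_params.cooling_rate, mosa_params.moves_per_temperature,
                    seed=seed,
                )
            ),
            "mots": run_mots(
                inst, MOTSParams(
                    mots_params.tabu_list_size, mots_params.tabu_tenure,
                    mots_params.candidate_set_size, mots_params.iterations,
                    seed=seed,
                )
            ),
        }
        for name, front in fronts.items():
            s1 = front.schedules[_representative(front)]
            ref = StageOneReference(s1, stage1_objectives(s1, inst))
            draw = sample_extensions(
                inst, rng=np.random.default_rng((seed + 1) * 7919),
                reference=s1,
            )
            results = [
                elective_first_or(name_, s1, inst, draw, ref, recall_params)
                for name_ in STRATEGIES
            ]
            admitted[name].append(
                float(
                    np.mean(
                        [
                            len(r.schedule.admission_day)
                            + len(r.schedule.emergencies)
                            + len(inst.currents)
                            for r in results
                        ]
                    )
                )
            )
            if metric == "f22":
                scalars[name].append(float(np.mean([r.f22 for r in results])))
            elif metric == "f21":
                scalars[name].append(float(np.mean([r.f21 for r in results])))
            elif metric == "admitted":
                scalars[name].append(admitted[name][-1])
            else:
                raise ValueError(f"unknown metric {metric!r}")

    report = {
        "metric": metric,
        "per_seed": scalars,
        "mean_admitted": {k: float(np.mean(v)) for k, v in admitted.items()},
        "tests": {
            "nsga2_vs_mosa": paired_t_test(scalars["nsga2"], scalars["mosa"]),
            "nsga2_vs_mots": paired_t_test(scalars["nsga2"], scalars["mots"]),
        },
    }
    return report


def elective_first_or(
    name: str,
    s1: Schedule,
    inst: Instance,
    draw: ExtensionDraw,
    ref: StageOneReference,
    recall_params: GAParams,
):
    """Dispatch one repair strategy by name (recall gets its GA budget)."""
    if name == "recall":
        return recall(s1, inst, draw, recall_params, reference=ref)
    return STRATEGIES[name](s1, inst, draw)
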