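"""Front summaries, scenario sweeps, and occupancy reporting.

The five named extension scenarios shift probability mass from "no extra
days" (S1, also the base law) toward "four extra days" (S5), so mean
stage-2 repair load increases from S1 to S5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instance import ExtensionDistribution, Instance
from .nsga2 import GAParams, ParetoFront, hypervolume, run_stage1
from .schedule import (
    Schedule,
    StageOneReference,
    occupancy_pmf,
    stage1_objectives,
)
from .stage2 import ExtensionDraw, STRATEGIES, sample_extensions, recall

__all__ = [
    "SCENARIOS",
    "scenario",
    "FrontSummary",
    "summarize_front",
    "scenario_sweep",
    "occupancy_report",
]

_EXT_DAYS = (0, 1, 2, 3, 4)

#: Named extension laws: probability of 0..4 extra days per scenario.
SCENARIOS: dict[str, ExtensionDistribution] = {
    name: ExtensionDistribution(_EXT_DAYS, probs, "additive")
    for name, probs in {
        "S1": (0.40, 0.25, 0.20, 0.10, 0.05),
        "S2": (0.25, 0.40, 0.20, 0.10, 0.05),
        "S3": (0.05, 0.25, 0.40, 0.20, 0.10),
        "S4": (0.05, 0.10, 0.20, 0.40, 0.25),
        "S5": (0.05, 0.10, 0.20, 0.25, 0.40),
    }.items()
}
SCENARIOS["table5"] = SCENARIOS["S1"]  # the base law coincides with S1


def scenario(name: str) -> ExtensionDistribution:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        ) from None


@dataclass
class FrontSummary:
    """Tabular view of a front: one row per solution plus an average row."""

    table: pd.DataFrame

    @property
    def averages(self) -> pd.Series:
        return self.table.loc["Avg."]


def _counts(s: Schedule, inst: Instance) -> dict:
    return {
        "current": len(inst.currents),
        "emergency": len(s.emergencies),
        "elective": len(s.admission_day),
    }


def summarize_front(
    front: ParetoFront,
    inst: Instance,
    stage2_results: dict[str, list] | None = None,
) -> FrontSummary:
    """Per-solution admitted counts and objectives, with an average row.

    ``stage2_results`` maps strategy name to one
    :class:`~icualloc.stage2.Stage2Result` per front solution; their f21/f22
    become extra columns.
    """
    rows = []
    for i, s in enumerate(front.schedules):
        row = {"solution": i + 1, **_counts(s, inst)}
        if front.stage == 1:
            row.update(
                zip(("f11", "f12", "f13"), np.asarray(front.objectives[i]))
            )
        else:
            row.update(zip(("f21", "f22"), np.asarray(front.objectives[i])))
        if stage2_results:
            for name, results in stage2_results.items():
                row[f"{name}_f21"] = results[i].f21
                row[f"{name}_f22"] = results[i].f22
        rows.append(row)
    table = pd.DataFrame(rows).set_index("solution")
    table.loc["Avg."] = table.mean(axis=0)
    return FrontSummary(table)


def scenario_sweep(
    inst: Instance,
    scenarios: dict[str, ExtensionDistribution] | None = None,
    stage1_params: GAParams | None = None,
    recall_params: GAParams | None = None,
    seeds: tuple[int, ...] = (0,),
    strategies: tuple[str, ...] = ("elective-first", "emergency-first", "recall"),
) -> pd.DataFrame:
    """Mean stage-2 objectives per scenario, stage 1 solved once per seed.

    For each seed, the stage-1 front is computed once; each scenario's
    disturbances are applied to the same representative solution, and every
    requested repair strategy is run.  Returns one row per scenario with the
    mean f21 and f22 across seeds and strategies, the implied total bed
    count (nominal beds plus mean added beds, rounded), and the seed whose
    stage-1 front had the largest dominated hypervolume.
    """
    scenarios = scenarios or {
        k: v for k, v in SCENARIOS.items() if k != "table5"
    }
    stage1_params = stage1_params or GAParams()
    recall_params = recall_params or GAParams(population=30, generations=30)
    prep = []
    hv = {}
    for seed in seeds:
        p = GAParams(
            stage1_params.population, stage1_params.generations,
            stage1_params.mutation_rate, stage1_params.crossover_rate,
            seed=seed,
        )
        front = run_stage1(inst, p)
        hv[seed] = hypervolume(front.objectives, front.senses)
        F = np.asarray(front.objectives, float)
        lo, hi = F.min(0), F.max(0)
        span = np.where(hi > lo, hi - lo, 1.0)
        score = ((F - lo) / span * np.array([-1.0, 1.0, -1.0])).sum(1)
        s1 = front.schedules[int(np.argmin(score))]
        ref = StageOneReference(s1, stage1_objectives(s1, inst))
        prep.append((seed, s1, ref))
    best_seed = max(hv, key=hv.get)

    rows = []
    for name, dist in scenarios.items():
        f21s, f22s = [], []
        for seed, s1, ref in prep:
            draw = sample_extensions(
                inst, dist, np.random.default_rng((seed + 1) * 104_729),
                reference=s1,
            )
            for strat in strategies:
                if strat == "recall":
                    res = recall(s1, inst, draw, recall_params, reference=ref)
                else:
                    res = STRATEGIES[strat](s1, inst, draw)
                f21s.append(res.f21)
                f22s.append(res.f22)
        mean_f22 = float(np.mean(f22s))
        rows.append(
            {
                "scenario": name,
                "mean_f21": float(np.mean(f21s)),
                "mean_f22": mean_f22,
                "total_beds": int(round(inst.beds + mean_f22)),
            }
        )
    out = pd.DataFrame(rows).set_index("scenario")
    out.attrs["hypervolume_best_seed"] = best_seed
    return out


def occupancy_report(front: ParetoFront, inst: Instance) -> pd.DataFrame:
    """Per-solution, per-day occupancy PMFs with expected bed counts."""
    rows = []
    for i, s in enumerate(front.schedules):
        for t in range(1, inst.horizon + 1):
            pmf = occupancy_pmf(s, inst, t)
            expected = sum(k * p for k, p in pmf.items())
            for beds, prob in pmf.items():
                rows.append(
                    {
                        "solution": i + 1,
                        "day": t,
                        "beds": beds,
                        "probability": prob,
                        "expected_beds": expected,
                    }
                )
    return pd.DataFrame(rows)
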