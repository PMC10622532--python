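# icualloc

Two-stage multi-objective ICU bed allocation under arrival and
length-of-stay uncertainty.

An intensive-care unit serves three patient streams at once: patients
already in a bed (*current* patients with a remaining stay), *elective*
patients booked in advance with an expected admission day, and *emergency*
arrivals that follow a Poisson process and cannot be turned away lightly.
`icualloc` plans elective admissions over a short horizon and then repairs
the plan when reality deviates — when stays run longer than booked and new
emergencies keep arriving.

## The model

**Stage 1 (planning).** Choose an admission day for each elective patient
(at or after their expected day, never exceeding the `Q` nominal beds on
any day) to optimize three objectives simultaneously:

- `f11` — maximize the mean bed-occupancy rate over the horizon;
- `f12` — minimize the delay index: the mean over admitted electives of
  `(admission day − expected day) × loss-of-chance weight`, where the
  weight (0.9 / 0.5 / 0.1) encodes clinical severity;
- `f13` — maximize the emergency admission rate: daily emergencies over
  the day's admission cap `Mp_t` (the 0.999 quantile of the day's Poisson
  arrival law), averaged over days with a positive cap.

There is no single best plan — the result is a Pareto front, found with an
elitist NSGA-II whose operators (date-exchange crossover, remove/replace
mutation, severity-first re-insertion) all preserve feasibility, and where
each individual carries its own frozen emergency scenario.

**Stage 2 (repair).** A disturbance extends stays (by 0–4 extra days with
probabilities 40/25/20/10/5 % under the base law) and adds new emergency
arrivals. Three repair policies are compared:

- **elective-first** — keep every stage-1 assignment; overflow is met with
  added (contingency) beds, and a new emergency that fits in no nominal bed
  counts as rejected;
- **emergency-first** — admit every emergency; refit electives greedily
  (most severe, shortest stay first), postponing those that no longer fit;
- **recall** — re-run the evolutionary search on (`f21` maximize
  similarity to the stage-1 plan, `f22` minimize added beds) under hard
  constraints that none of the frozen stage-1 objective values may
  deteriorate.

Simulated-annealing (MOSA) and tabu-search (MOTS) baselines share the same
encoding, moves and objectives so that comparisons isolate the search
strategy; a paired one-sided t-test utility supports the comparison.

## Worked example

Generate an instance at the default study conditions (24 beds, 7 days,
100 electives, 3 current patients, per-day Poisson arrival rates) and
solve stage 1:

```console
$ icualloc gen --seed 7 --out demo.json
wrote demo.json
$ icualloc stage1 --instance demo.json --pop 50 --gens 100 --seed 0 --out front.json
          current  emergency   elective       f11       f12       f13
solution
1             3.0  43.000000  28.000000  0.952381  0.010714  0.475275
2             3.0  51.000000  28.000000  0.994048  0.085714  0.560963
3             3.0  43.000000  29.000000  0.958333  0.062069  0.475275
4             3.0  43.000000  33.000000  0.934524  0.069697  0.479592
5             3.0  43.000000  32.000000  0.940476  0.084375  0.479592
6             3.0  43.000000  32.000000  0.940476  0.084375  0.479592
Avg.          3.0  44.333333  30.333333  0.953373  0.066157  0.491715
```

Each row is one Pareto-front plan: solution 1 admits 28 electives with
almost no delay, solution 4 admits 33 at the cost of more delay, solution
2 rides a heavier emergency scenario to 99 % occupancy. Now disturb the
first plan and repair it three ways:

```console
$ icualloc repair --instance demo.json --strategy elective-first --pop 50 --gens 100 --seed 0
{
  "strategy": "elective-first",
  "f21": 1.0,
  "f22": 23,
  "rejected_emergencies": 32,
  ...
}
$ icualloc repair --instance demo.json --strategy recall --pop 50 --gens 100 --seed 0
{
  "strategy": "recall",
  "f21": 0.7375,
  "f22": 15,
  "rejected_emergencies": 0,
  "postponed_electives": 23,
  ...
}
```

Keeping every commitment (`elective-first`) preserves the plan perfectly
(`f21 = 1.0`) but needs 23 contingency beds and turns away 32 emergencies;
the constrained re-optimization (`recall`) serves every emergency with 15
added beds while preserving 74 % of the original patient-day assignments.

The same pipeline is available as a library:

```python
from icualloc import generate_instance, GAParams, run_stage1

inst = generate_instance(seed=7)
front = run_stage1(inst, GAParams(population=50, generations=100, seed=0))
print(front.objectives)
```

Other subcommands: `icualloc sweep` runs the five extension-severity
scenarios S1–S5 against shared stage-1 fronts; `icualloc compare` runs the
paired NSGA-II / MOSA / MOTS comparison; `icualloc report` writes per-day
bed-occupancy probability tables.

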