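# Methods

This note states the model `icualloc` implements, the algorithmic and
numerical choices made, and their known limitations.

## Problem data

An *instance* is a nominal bed count `Q`, a planning horizon of `T` days,
and three patient populations:

- **current patients** — already in a bed at day 1 with a remaining stay
  `remaining ≤ LOS`; they occupy a bed on days `1 … remaining`;
- **elective patients** — each with an expected admission day
  `Exp ∈ {1..T}`, a booked length of stay `LOS`, and a loss-of-chance
  severity weight `θ ∈ {0.9, 0.5, 0.1}`;
- **emergency arrivals** — a per-day Poisson stream with rate `λ_t`.

Daily emergency admissions are capped at `Mp_t`, the 0.999 quantile of
`Poisson(λ_t)` (so `λ = 4.5` gives `Mp = 12`), and realized counts are
drawn from the Poisson law truncated and renormalized on `{0..Mp_t}`.
Stays are truncated at the horizon: a patient admitted on day `d` with
stay `l` occupies one bed on days `d … min(d+l−1, T)`.

The synthetic generator's defaults — `Q = 24`, `T = 7`, 100 electives,
3 current patients, per-day rates uniform in a band around 4.5, elective
stays uniform on 1–5 days, severity weights drawn 0.9/0.5/0.1 with equal
mass — define the study conditions used throughout the test suite.

## Stage 1: planning

A *schedule* maps a subset of electives to admission days with
`day ≥ Exp`; current patients and one realized emergency scenario are
fixed genes. Feasibility requires elective-plus-current occupancy within
`Q` on every day and emergency counts within `Mp_t` (emergencies
themselves may overflow `Q`; the overflow is what stage 2 prices as added
beds). Objectives:

- `f11 = mean_t Oc_t / Q` (maximize), where `Oc_t` is total occupancy —
  currents, carried-over and newly admitted electives, emergencies;
- `f12 = mean over admitted electives of θ · (day − Exp)` (minimize);
- `f13 = mean over days with Mp_t > 0 of em_t / Mp_t` (maximize).

The search is an elitist (μ+λ) NSGA-II:

- **initialization** — independent feasible schedules: each individual
  samples its own emergency scenario (kept frozen through its lineage),
  then admits electives greedily in random order at random feasible days,
  then re-inserts;
- **crossover** — per-parent exchange of two admitted electives' dates,
  rejected if it violates capacity or an expected-day window;
- **mutation** — remove one admitted elective and insert a waiting one
  with a stay no longer than the removed one, at its earliest feasible
  day;
- **re-insertion repair** — after every variation, waiting electives are
  admitted most-severe-first (ties: shorter stay, lower id) at their
  earliest feasible day, so every individual is maximal: no waiting
  patient fits any remaining vacancy;
- **selection** — fast non-dominated sorting with crowding distance;
  exact clones are pushed behind their first occurrence to keep diversity;
  parents and offspring compete jointly.

The returned front is the first non-domination level with exact duplicates
removed.

## Stage 2: disturbance and repair

A disturbance draws, per patient, extra days from the extension law
(base law: 0–4 extra days with probabilities 0.40/0.25/0.20/0.10/0.05;
scenarios S1–S5 shift mass toward longer extensions; a multiplicative mode
maps `LOS` to the unique integer in `[LOS(1+R), LOS(1+R)+1)`) and a new
emergency stream from the same Poisson model, capped so stage-1 plus new
daily arrivals stay within `Mp_t`.

Stage-2 objectives against the chosen stage-1 schedule:

- `f21` (maximize) — similarity: the fraction of stage-1 (patient, day)
  occupancy pairs still present in the repaired schedule. The measure is
  bed-agnostic (bed labels are a presentation concern) and uses the
  stage-1 pair count as denominator; a `bed_sensitive` variant and a
  `max`-denominator variant are provided for sensitivity analysis.
- `f22` (minimize) — added beds: `max_t max(0, q2_t − q1_t)` over daily
  total occupancies, i.e. the peak extra simultaneous demand relative to
  the stage-1 profile.

The **recall** strategy re-runs the evolutionary search on (`f21`, `f22`)
with constrained dominance: any candidate whose `f11`/`f12`/`f13` values
(recomputed under the extended stays and enlarged emergency stream) are
worse than the frozen stage-1 values is ranked behind every compliant
candidate and never enters the returned front. If the extended stage-1
schedule still fits within `Q` it is returned unchanged (short circuit).
If no compliant schedule is found, a greedy eviction repair is returned
and flagged via `metadata["constraints_met"] = False` — for some
disturbances the constraint system is genuinely unsatisfiable (evicting
enough load to restore capacity can push the occupancy rate below its
frozen value while re-insertion pushes the delay index above its frozen
value). From the front, recall reports the member with the fewest added
beds, breaking ties toward higher similarity.

The two greedy baselines are described in the README; emergency-first
uses a two-pass refit (keep stage-1 days where they still fit, then
earliest-feasible for the displaced) ordered most-severe, shortest-stay
first.

## Baselines and statistics

MOSA cools geometrically from 1000 to 10⁻³ at rate 0.95; a dominated
neighbor is accepted with probability `exp(−Δ/temp)` where `Δ` is the mean
min–max-normalized worsening. MOTS evaluates 10 candidate neighbors per
iteration for 200 iterations with a 50-entry tabu list of move attributes
(tenure 5) and archive-entry aspiration. Both share the NSGA-II moves and
maintain a bounded Pareto archive pruned by crowding distance.

`compare_algorithms` runs all three algorithms on paired seeds, carries a
representative front member (best equal-weight normalized score) into
stage 2 under a shared disturbance, and reports one-sided paired t-tests
(`H1: mean(NSGA-II) − mean(other) < 0`); on identical samples the t
statistic is undefined (`nan`) and only the mean difference is meaningful.
`scenario_sweep` solves stage 1 once per seed, applies each scenario's
disturbance to the same representative, reports mean `f21`/`f22` per
scenario, a rounded implied total bed count `Q + mean f22`, and marks the
seed whose front had the largest dominated hypervolume (computed by
recursive slicing; suitable for small fronts only).

## Numerical choices

- All randomness flows through `numpy.random.Generator`; population
  members draw from spawned `SeedSequence` substreams, so every pipeline
  is bit-reproducible for a fixed seed tuple.
- Poisson quantities are computed from the exact PMF (log-gamma form);
  truncated laws renormalize the PMF on the capped support.
- Occupancy PMFs for reporting shift the day's truncated arrival law by
  the deterministic load; expected values are exact, not simulated.
- Frozen-objective comparisons in stage 2 use an absolute slack of 1e-9
  to absorb floating-point noise only.

## Limitations

- The date-exchange/remove-replace operator set cannot perform some
  coordinated multi-patient rearrangements in one step; on adversarial
  tiny instances the search may need many restarts to recover the full
  exhaustive front (the test suite's recovery oracles use toys where the
  operators are complete).
- The hypervolume implementation is exponential in the number of
  objectives and intended for fronts of at most a few hundred points.
- Emergency rejection in elective-first counts arrivals that fit in no
  nominal bed; it does not model diversion to other wards.
- `f21`'s denominator convention (stage-1 pairs) makes similarity equal
  to 1 when stage 2 only adds occupancy; use `denominator="max"` when a
  symmetric measure is needed.
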