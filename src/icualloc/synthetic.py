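"""Seeded generation of synthetic allocation instances.

The generator emulates the statistical structure of a one-week ICU planning
problem at a mid-sized hospital: 24 beds, a waiting list of about 100
elective patients with expected admission days spread over the week, a
handful of patients already in beds, and Poisson emergency arrivals whose
0.999-quantile daily cap sits around a dozen patients.  All draws come from
independent, purpose-specific RNG streams so that, for example, stage-2
disturbances can be re-drawn without perturbing the instance itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .instance import (
    CURRENT_ID_BASE,
    DEFAULT_EMERGENCY_LOS,
    DEFAULT_EXTENSION,
    EMERGENCY_ID_BASE,
    LOSS_LEVELS,
    ArrivalModel,
    CurrentPatient,
    DiscreteDistribution,
    ElectivePatient,
    EmergencyArrival,
    ExtensionDistribution,
    Instance,
    validate_instance,
)

__all__ = ["GeneratorConfig", "generate_instance", "sample_emergency_stream"]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-instance generator.

    Defaults reproduce the study conditions: 24 beds, a 7-day horizon,
    100 elective and 3 current patients, elective stays of 1-5 days,
    equal mix of mild/moderate/severe loss-of-chance weights, and daily
    Poisson rates in [4, 5.5] (caps ~11-14 at the 0.999 quantile).
    """

    beds: int = 24
    horizon: int = 7
    n_electives: int = 100
    n_currents: int = 3
    rate_range: tuple[float, float] = (4.0, 5.5)
    los_range: tuple[int, int] = (1, 5)
    loss_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    current_los_range: tuple[int, int] = (2, 5)
    emergency_los_range: tuple[int, int] = (1, 5)
    extension: ExtensionDistribution = field(default=DEFAULT_EXTENSION)
    truncation_quantile: float = 0.999
    seed: int = 0

    def validate(self) -> None:
        if self.n_currents > self.beds:
            raise ValueError(
                f"{self.n_currents} current patients cannot fit in "
                f"{self.beds} beds"
            )
        if min(self.beds, self.horizon) < 1 or min(
            self.n_electives, self.n_currents
        ) < 0:
            raise ValueError("counts must be nonnegative, sizes positive")
        for lo, hi in (
            self.rate_range,
            self.los_range,
            self.current_los_range,
            self.emergency_los_range,
        ):
            if hi < lo:
                raise ValueError(f"empty range ({lo}, {hi})")
        if abs(sum(self.loss_weights) - 1.0) > 1e-9:
            raise ValueError("loss_weights must sum to 1")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_instance(cfg: GeneratorConfig | None = None, **kw) -> Instance:
    """Build a validated instance from ``cfg`` (deterministic per seed)."""
    if cfg is None:
        cfg = GeneratorConfig(**kw)
    cfg.validate()
    r_rates, r_elec, r_cur = _streams(cfg.seed, 3)

    rates = tuple(
        float(x)
        for x in np.round(
            r_rates.uniform(cfg.rate_range[0], cfg.rate_range[1], cfg.horizon), 3
        )
    )

    lo, hi = cfg.los_range
    electives = tuple(
        ElectivePatient(
            id=i + 1,
            expected_day=int(r_elec.integers(1, cfg.horizon + 1)),
            los=int(r_elec.integers(lo, hi + 1)),
            loss_of_chance=float(r_elec.choice(LOSS_LEVELS, p=cfg.loss_weights)),
        )
        for i in range(cfg.n_electives)
    )

    clo, chi = cfg.current_los_range
    currents = []
    for i in range(cfg.n_currents):
        los = int(r_cur.integers(clo, chi + 1))
        currents.append(
            CurrentPatient(
                id=CURRENT_ID_BASE + i + 1,
                los=los,
                remaining=int(r_cur.integers(1, los + 1)),
            )
        )

    elo, ehi = cfg.emergency_los_range
    inst = Instance(
        beds=cfg.beds,
        horizon=cfg.horizon,
        electives=electives,
        currents=tuple(currents),
        arrivals=ArrivalModel(rates, cfg.truncation_quantile),
        emergency_los_dist=DiscreteDistribution.uniform(range(elo, ehi + 1)),
        extension_dist=cfg.extension,
    )
    problems = validate_instance(inst)
    if problems:  # pragma: no cover - generator guarantees validity
        raise AssertionError(f"generator produced invalid instance: {problems}")
    return inst


def sample_emergency_stream(
    inst: Instance,
    seed: int | np.random.Generator,
    id_base: int = EMERGENCY_ID_BASE,
) -> list[EmergencyArrival]:
    """One realized emergency scenario over the horizon.

    Daily counts follow the Poisson law truncated at the cap ``Mp_t``; each
    arrival draws a length of stay from the instance's emergency LOS law.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    counts = inst.arrivals.sample_counts(rng)
    arrivals: list[EmergencyArrival] = []
    next_id = id_base + 1
    for day, n in enumerate(counts, start=1):
        for _ in range(n):
            arrivals.append(
                EmergencyArrival(
                    id=next_id,
                    arrival_day=day,
                    los=int(inst.emergency_los_dist.sample(rng)),
                )
            )
            next_id += 1
    return arrivals
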