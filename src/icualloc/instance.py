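"""Problem instances for ICU bed allocation.

An instance describes one planning problem: a ward with ``Q`` identical beds
over a horizon of ``T`` days, three patient populations (elective patients
waiting for a planned admission, patients already occupying a bed at day 1,
and emergency arrivals whose daily counts are Poisson), and the uncertainty
models attached to them (arrival rates, emergency length-of-stay law, and the
length-of-stay extension law used by the second allocation stage).

Day indexing is 1-based: a patient admitted on day ``t`` with length of stay
``L`` occupies a bed on days ``t .. t+L-1`` inclusive; occupancy beyond the
horizon is ignored by the objectives.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ElectivePatient",
    "CurrentPatient",
    "EmergencyArrival",
    "ArrivalModel",
    "DiscreteDistribution",
    "ExtensionDistribution",
    "Instance",
    "poisson_pmf",
    "max_arrivals",
    "truncated_poisson_pmf",
    "validate_instance",
    "estimate_rates",
    "CURRENT_ID_BASE",
    "EMERGENCY_ID_BASE",
    "LOSS_LEVELS",
]

#: Identifier bases: current ICU patients are coded 10000+, emergency arrivals
#: 20000+, elective patients are bare positive integers.
CURRENT_ID_BASE = 10_000
EMERGENCY_ID_BASE = 20_000

#: Admissible "loss of chance if postponed" severity weights
#: (mild / moderate / severe).
LOSS_LEVELS = (0.1, 0.5, 0.9)


# ---------------------------------------------------------------------------
# patient records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectivePatient:
    """A patient scheduled in advance, who may be admitted late (never early).

    ``loss_of_chance`` weights each day of delay in the delay-index objective.
    """

    id: int
    expected_day: int
    los: int
    loss_of_chance: float


@dataclass(frozen=True)
class CurrentPatient:
    """A patient already in a bed at the start of the horizon.

    ``remaining`` days are counted from day 1, so the patient occupies days
    ``1 .. remaining``.
    """

    id: int
    los: int
    remaining: int


@dataclass(frozen=True)
class EmergencyArrival:
    """A realized emergency admission on ``arrival_day`` staying ``los`` days."""

    id: int
    arrival_day: int
    los: int


# ---------------------------------------------------------------------------
# Poisson arrival model
# ---------------------------------------------------------------------------

def poisson_pmf(k: int, rate: float) -> float:
    """Probability of ``k`` arrivals under a Poisson law with mean ``rate``.

    Returns ``rate**k * exp(-rate) / k!``; a zero rate puts all mass on
    ``k = 0``.
    """
    if k < 0:
        raise ValueError(f"k must be nonnegative, got {k}")
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    if rate == 0:
        return 1.0 if k == 0 else 0.0
    return float(stats.poisson.pmf(k, rate))


def max_arrivals(rate: float, quantile: float = 0.999) -> int:
    """Daily cap on admitted emergencies: the ``quantile`` of Poisson(rate).

    The cap ``Mp_t`` is the smallest integer ``k`` with
    ``P(Poisson(rate) <= k) >= quantile``.  It is nondecreasing in both
    arguments.  Counts above the cap have, by construction, low probability.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must lie in (0, 1), got {quantile}")
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    if rate == 0:
        return 0
    return int(stats.poisson.ppf(quantile, rate))


def truncated_poisson_pmf(rate: float, cap: int) -> np.ndarray:
    """PMF of a Poisson(rate) conditioned on being at most ``cap``.

    Returns an array of length ``cap + 1``; the tail mass beyond the cap is
    renormalized away.
    """
    if cap < 0:
        raise ValueError("cap must be nonnegative")
    if rate == 0:
        out = np.zeros(cap + 1)
        out[0] = 1.0
        return out
    p = stats.poisson.pmf(np.arange(cap + 1), rate)
    return p / p.sum()


@dataclass(frozen=True)
class ArrivalModel:
    """Per-day Poisson arrival rates and the derived daily admission caps."""

    rates: tuple[float, ...]
    truncation_quantile: float = 0.999

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rates):
            raise ValueError("arrival rates must be nonnegative")
        if not 0.0 < self.truncation_quantile < 1.0:
            raise ValueError("truncation_quantile must lie in (0, 1)")

    @property
    def horizon(self) -> int:
        return len(self.rates)

    def rate(self, day: int) -> float:
        return self.rates[day - 1]

    @property
    def max_per_day(self) -> tuple[int, ...]:
        """The cap ``Mp_t`` for each day of the horizon."""
        cached = self.__dict__.get("_caps")
        if cached is None:
            cached = tuple(
                max_arrivals(r, self.truncation_quantile) for r in self.rates
            )
            object.__setattr__(self, "_caps", cached)
        return cached

    def day_pmf(self, day: int) -> np.ndarray:
        """Truncated-Poisson PMF of the day's admitted emergency count."""
        cache = self.__dict__.get("_pmfs")
        if cache is None:
            cache = {}
            object.__setattr__(self, "_pmfs", cache)
        if day not in cache:
            cap = self.max_per_day[day - 1]
            cache[day] = truncated_poisson_pmf(self.rate(day), cap)
        return cache[day]

    def sample_counts(self, rng: np.random.Generator) -> list[int]:
        """One realized emergency count per day, each capped at ``Mp_t``."""
        counts = []
        for day in range(1, self.horizon + 1):
            pmf = self.day_pmf(day)
            counts.append(int(rng.choice(len(pmf), p=pmf)))
        return counts


# ---------------------------------------------------------------------------
# discrete distributions (emergency LOS, LOS extension)
# ---------------------------------------------------------------------------

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class DiscreteDistribution:
    """A finite distribution over numeric support values."""

    support: tuple[float, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.support) != len(self.probs) or not self.support:
            raise ValueError("support and probs must be nonempty, equal length")
        if any(p < 0 or p > 1 for p in self.probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.probs) - 1.0) > _PROB_TOL:
            raise ValueError(f"probabilities sum to {sum(self.probs)}, not 1")

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.probs))

    def sample(self, rng: np.random.Generator, size: int | None = None):
        vals = rng.choice(self.support, size=size, p=self.probs)
        if size is None:
            return type(self.support[0])(vals)
        return vals

    @classmethod
    def uniform(cls, values: Iterable[float]) -> "DiscreteDistribution":
        vals = tuple(values)
        return cls(vals, tuple([1.0 / len(vals)] * len(vals)))


@dataclass(frozen=True)
class ExtensionDistribution(DiscreteDistribution):
    """Law of the per-patient length-of-stay extension applied in stage 2.

    Two formulations are supported:

    ``additive``
        support values are extra whole days ``e``; the new stay is
        ``LOS + e``.  This is the default.
    ``multiplicative``
        support values are fractions ``R``; the new stay is the unique
        integer in ``[LOS*(1+R), LOS*(1+R) + 1)``, i.e. ``ceil(LOS*(1+R))``.
    """

    mode: str = "additive"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown extension mode {self.mode!r}")
        if self.mode == "additive" and any(
            v < 0 or v != int(v) for v in self.support
        ):
            raise ValueError("additive extensions must be nonnegative integers")
        if self.mode == "multiplicative" and any(v < 0 for v in self.support):
            raise ValueError("multiplicative extensions must be nonnegative")

    def extend(self, los: int, draw: float) -> int:
        """New length of stay for a base ``los`` and a drawn extension."""
        if self.mode == "additive":
            return los + int(draw)
        return math.ceil(los * (1.0 + draw) - 1e-12)


#: The base extension law: 0..4 extra days with probabilities
#: 40/25/20/10/5 percent.
DEFAULT_EXTENSION = ExtensionDistribution(
    support=(0, 1, 2, 3, 4),
    probs=(0.40, 0.25, 0.20, 0.10, 0.05),
    mode="additive",
)

#: Default emergency length-of-stay law: uniform on 1..5 days.
DEFAULT_EMERGENCY_LOS = DiscreteDistribution.uniform((1, 2, 3, 4, 5))


# ---------------------------------------------------------------------------
# instance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Instance:
    """One bed-allocation problem."""

    beds: int
    horizon: int
    electives: tuple[ElectivePatient, ...]
    currents: tuple[CurrentPatient, ...]
    arrivals: ArrivalModel
    emergency_los_dist: DiscreteDistribution = DEFAULT_EMERGENCY_LOS
    extension_dist: ExtensionDistribution = DEFAULT_EXTENSION

    # -- convenience lookups -------------------------------------------------

    def elective(self, pid: int) -> ElectivePatient:
        return self._elective_index[pid]

    @property
    def _elective_index(self) -> dict[int, ElectivePatient]:
        idx = self.__dict__.get("_elidx")
        if idx is None:
            idx = {p.id: p for p in self.electives}
            object.__setattr__(self, "_elidx", idx)
        return idx

    @property
    def max_per_day(self) -> tuple[int, ...]:
        return self.arrivals.max_per_day

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "beds": self.beds,
            "horizon": self.horizon,
            "rates": list(self.arrivals.rates),
            "truncation_quantile": self.arrivals.truncation_quantile,
            "electives": [
                {
                    "id": p.id,
                    "expected_day": p.expected_day,
                    "los": p.los,
                    "loss_of_chance": p.loss_of_chance,
                }
                for p in self.electives
            ],
            "currents": [
                {"id": p.id, "los": p.los, "remaining": p.remaining}
                for p in self.currents
            ],
            "emergency_los": {
                "support": list(self.emergency_los_dist.support),
                "probs": list(self.emergency_los_dist.probs),
            },
            "extension": {
                "support": list(self.extension_dist.support),
                "probs": list(self.extension_dist.probs),
                "mode": self.extension_dist.mode,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Instance":
        ext = d["extension"]
        emo = d["emergency_los"]
        return cls(
            beds=int(d["beds"]),
            horizon=int(d["horizon"]),
            electives=tuple(
                ElectivePatient(
                    int(p["id"]),
                    int(p["expected_day"]),
                    int(p["los"]),
                    float(p["loss_of_chance"]),
                )
                for p in d["electives"]
            ),
            currents=tuple(
                CurrentPatient(int(p["id"]), int(p["los"]), int(p["remaining"]))
                for p in d["currents"]
            ),
            arrivals=ArrivalModel(
                rates=tuple(float(r) for r in d["rates"]),
                truncation_quantile=float(d.get("truncation_quantile", 0.999)),
            ),
            emergency_los_dist=DiscreteDistribution(
                tuple(emo["support"]), tuple(emo["probs"])
            ),
            extension_dist=ExtensionDistribution(
                tuple(ext["support"]), tuple(ext["probs"]), ext["mode"]
            ),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Instance":
        try:
            p = Path(source)
            is_file = p.exists()
        except OSError:  # raw JSON text can exceed the path-length limit
            is_file = False
        text = p.read_text() if is_file else str(source)
        return cls.from_dict(json.loads(text))

    def to_csv_dir(self, directory: str | Path) -> None:
        """Three-table CSV export (electives / currents / arrival rates).

        Distribution metadata that has no tabular home goes to ``meta.json``
        in the same directory.
        """
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                (p.id, p.expected_day, p.los, p.loss_of_chance)
                for p in self.electives
            ],
            columns=["Code", "Exp", "LOS", "Loss"],
        ).to_csv(d / "electives.csv", index=False)
        pd.DataFrame(
            [(p.id, p.los, p.remaining) for p in self.currents],
            columns=["Code", "LOS", "Rem"],
        ).to_csv(d / "currents.csv", index=False)
        pd.DataFrame(
            {"day": range(1, self.horizon + 1), "lambda": self.arrivals.rates}
        ).to_csv(d / "arrivals.csv", index=False)
        meta = self.to_dict()
        meta = {
            k: meta[k]
            for k in (
                "beds",
                "horizon",
                "truncation_quantile",
                "emergency_los",
                "extension",
            )
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv_dir(cls, directory: str | Path) -> "Instance":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        el = pd.read_csv(d / "electives.csv")
        cu = pd.read_csv(d / "currents.csv")
        ar = pd.read_csv(d / "arrivals.csv").sort_values("day")
        meta.update(
            rates=ar["lambda"].tolist(),
            electives=[
                {
                    "id": r.Code,
                    "expected_day": r.Exp,
                    "los": r.LOS,
                    "loss_of_chance": r.Loss,
                }
                for r in el.itertuples()
            ],
            currents=[
                {"id": r.Code, "los": r.LOS, "remaining": r.Rem}
                for r in cu.itertuples()
            ],
        )
        return cls.from_dict(meta)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_instance(inst: Instance) -> list[str]:
    """All invariant violations in ``inst`` (empty list means well formed)."""
    v: list[str] = []
    if inst.beds < 1:
        v.append(f"beds must be positive, got {inst.beds}")
    if inst.horizon < 1:
        v.append(f"horizon must be positive, got {inst.horizon}")
    if inst.arrivals.horizon != inst.horizon:
        v.append(
            f"arrival model covers {inst.arrivals.horizon} days, "
            f"horizon is {inst.horizon}"
        )
    for p in inst.electives:
        if p.los < 1:
            v.append(f"elective {p.id}: los {p.los} < 1")
        if p.loss_of_chance not in LOSS_LEVELS:
            v.append(
                f"elective {p.id}: loss_of_chance {p.loss_of_chance} "
                f"not in {LOSS_LEVELS}"
            )
        if not 1 <= p.expected_day <= inst.horizon:
            v.append(
                f"elective {p.id}: expected_day {p.expected_day} "
                f"outside [1, {inst.horizon}]"
            )
    for p in inst.currents:
        if p.los < 1:
            v.append(f"current {p.id}: los {p.los} < 1")
        if not 1 <= p.remaining <= p.los:
            v.append(
                f"current {p.id}: remaining {p.remaining} outside [1, {p.los}]"
            )
    if len(inst.currents) > inst.beds:
        v.append(
            f"{len(inst.currents)} current patients exceed {inst.beds} beds"
        )
    ids = [p.id for p in inst.electives] + [p.id for p in inst.currents]
    if len(set(ids)) != len(ids):
        v.append("patient ids are not unique across categories")
    for dist, name in (
        (inst.emergency_los_dist, "emergency_los"),
        (inst.extension_dist, "extension"),
    ):
        total = sum(dist.probs)
        if abs(total - 1.0) > _PROB_TOL:
            v.append(f"{name} distribution sums to {total}, not 1")
    if any(s < 1 for s in inst.emergency_los_dist.support):
        v.append("emergency LOS support must be positive days")
    return v


def estimate_rates(daily_counts: Sequence[Sequence[float]]) -> tuple[float, ...]:
    """Per-day Poisson rate estimates: the mean historical count of each day.

    ``daily_counts`` holds one sequence per historical period, each of length
    ``T`` (e.g. emergency admissions per weekday over several weeks).
    """
    arr = np.asarray(daily_counts, dtype=float)
    if arr.ndim != 2:
        raise ValueError("daily_counts must be a 2-D period x day table")
    return tuple(arr.mean(axis=0))
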