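"""Unit tests for the schedule encoding and the objective kernels."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icualloc.instance import (
    ArrivalModel,
    CurrentPatient,
    ElectivePatient,
    EmergencyArrival,
    Instance,
)
from icualloc.schedule import (
    Schedule,
    ObjectiveVector,
    StageOneReference,
    bed_layout,
    carryover_occupancy,
    elective_current_occupancy,
    f11_occupancy_rate,
    f12_delay_index,
    f13_emergency_rate,
    f21_similarity,
    f22_added_beds,
    is_feasible,
    occupancy_pmf,
    occupancy_vector,
    schedule_to_frame,
    stage1_objectives,
    total_occupancy,
)
from icualloc.synthetic import generate_instance, sample_emergency_stream

from conftest import no_arrivals


def one_day_instance(n_currents=3, n_electives=8, rate=4.5) -> Instance:
    return Instance(
        beds=24, horizon=1,
        electives=tuple(
            ElectivePatient(i + 1, 1, 1, 0.5) for i in range(n_electives)
        ),
        currents=tuple(
            CurrentPatient(10001 + i, 1, 1) for i in range(n_currents)
        ),
        arrivals=ArrivalModel((rate,)),
    )


class TestOccupancy:
    def test_worked_example_thirteen_beds(self):
        # 3 current patients, 8 electives admitted that day, 2 emergencies
        inst = one_day_instance()
        s = Schedule.empty(
            inst,
            [EmergencyArrival(20001, 1, 2), EmergencyArrival(20002, 1, 1)],
        )
        s.admission_day = {p.id: 1 for p in inst.electives}
        assert total_occupancy(s, inst, 1) == 13

    def test_worked_example_twelve_beds(self):
        inst = one_day_instance()
        s = Schedule.empty(inst, [EmergencyArrival(20001, 1, 1)])
        s.admission_day = {p.id: 1 for p in inst.electives}
        assert total_occupancy(s, inst, 1) == 12

    def test_empty_schedule(self):
        inst = Instance(
            beds=4, horizon=3, electives=(), currents=(),
            arrivals=no_arrivals(3),
        )
        s = Schedule.empty(inst)
        assert total_occupancy(s, inst, 1) == 0
        assert carryover_occupancy(s, inst, 1) == 0

    def test_carryover_window(self):
        # elective admitted day 2 with LOS 3 carries into days 3 and 4 only
        inst = Instance(
            beds=4, horizon=5,
            electives=(ElectivePatient(1, 1, 3, 0.5),),
            currents=(), arrivals=no_arrivals(5),
        )
        s = Schedule.empty(inst)
        s.admission_day[1] = 2
        assert [carryover_occupancy(s, inst, t) for t in (2, 3, 4, 5)] == [
            0, 1, 1, 0,
        ]

    def test_current_remaining_one(self):
        inst = Instance(
            beds=4, horizon=3, electives=(),
            currents=(CurrentPatient(10001, 3, 1),),
            arrivals=no_arrivals(3),
        )
        s = Schedule.empty(inst)
        assert carryover_occupancy(s, inst, 1) == 1
        assert carryover_occupancy(s, inst, 2) == 0

    def test_day_domain_error(self):
        inst = one_day_instance()
        s = Schedule.empty(inst)
        with pytest.raises(ValueError):
            total_occupancy(s, inst, 2)
        with pytest.raises(ValueError):
            carryover_occupancy(s, inst, 0)

    def test_conservation(self, small_instance):
        # Oc_t = new electives + em_t + Cu_t for every day
        inst = small_instance
        rng = np.random.default_rng(0)
        for seed in range(10):
            s = Schedule.empty(inst, sample_emergency_stream(inst, seed))
            for p in inst.electives:
                if rng.random() < 0.5:
                    s.admission_day[p.id] = int(
                        rng.integers(p.expected_day, inst.horizon + 1)
                    )
            occ = occupancy_vector(s, inst)
            for t in range(1, inst.horizon + 1):
                new = sum(1 for d in s.admission_day.values() if d == t)
                assert occ[t - 1] == total_occupancy(s, inst, t)
                assert total_occupancy(s, inst, t) == (
                    new + s.emergency_count(t) + carryover_occupancy(s, inst, t)
                )

    def test_truncation_at_horizon(self):
        inst = Instance(
            beds=4, horizon=2,
            electives=(ElectivePatient(1, 1, 5, 0.5),),
            currents=(), arrivals=no_arrivals(2),
        )
        s = Schedule.empty(inst)
        s.admission_day[1] = 2
        assert list(occupancy_vector(s, inst)) == [0, 1]


class TestStage1Objectives:
    def test_f11_saturated(self):
        inst = Instance(
            beds=1, horizon=2,
            electives=(ElectivePatient(1, 1, 2, 0.5),),
            currents=(), arrivals=no_arrivals(2),
        )
        s = Schedule.empty(inst)
        s.admission_day[1] = 1
        assert f11_occupancy_rate(s, inst) == 1.0

    def test_f11_empty(self):
        inst = one_day_instance(n_currents=0)
        assert f11_occupancy_rate(Schedule.empty(inst), inst) == 0.0
        # current patients occupy beds even with no elective admissions
        with_currents = one_day_instance(n_currents=3)
        assert f11_occupancy_rate(
            Schedule.empty(with_currents), with_currents
        ) == pytest.approx(3 / 24)

    def test_f12_worked_example(self):
        # Exp=1, admitted day 3, loss 0.5 → (3−1)×0.5 = 1.0
        inst = Instance(
            beds=4, horizon=3,
            electives=(ElectivePatient(1, 1, 1, 0.5),),
            currents=(), arrivals=no_arrivals(3),
        )
        s = Schedule.empty(inst)
        s.admission_day[1] = 3
        assert f12_delay_index(s, inst) == pytest.approx(1.0)

    def test_f12_zero_when_on_time_or_empty(self):
        inst = Instance(
            beds=4, horizon=3,
            electives=(
                ElectivePatient(1, 1, 1, 0.9),
                ElectivePatient(2, 2, 1, 0.5),
            ),
            currents=(), arrivals=no_arrivals(3),
        )
        s = Schedule.empty(inst)
        assert f12_delay_index(s, inst) == 0.0
        s.admission_day = {1: 1, 2: 2}
        assert f12_delay_index(s, inst) == 0.0

    def test_f12_hand_average(self):
        # delays (1 day, loss 0.1) and (3 days, loss 0.9) → (0.1+2.7)/2
        inst = Instance(
            beds=4, horizon=4,
            electives=(
                ElectivePatient(1, 1, 1, 0.1),
                ElectivePatient(2, 1, 1, 0.9),
            ),
            currents=(), arrivals=no_arrivals(4),
        )
        s = Schedule.empty(inst)
        s.admission_day = {1: 2, 2: 4}
        assert f12_delay_index(s, inst) == pytest.approx(1.4)

    def test_f13_worked_example_25_percent(self):
        # em=3 against the day cap 12 → 25%
        inst = one_day_instance(rate=4.5)
        assert inst.max_per_day == (12,)
        s = Schedule.empty(
            inst, [EmergencyArrival(20001 + i, 1, 1) for i in range(3)]
        )
        assert f13_emergency_rate(s, inst) == pytest.approx(0.25)

    def test_f13_hand_average(self):
        inst = Instance(
            beds=24, horizon=2, electives=(), currents=(),
            arrivals=ArrivalModel((4.5, 4.5)),
        )
        caps = inst.max_per_day
        n1 = caps[0] // 4  # ratio 0.25
        n2 = 3 * caps[1] // 4  # ratio 0.75
        ems = [EmergencyArrival(20001 + i, 1, 1) for i in range(n1)]
        ems += [EmergencyArrival(21001 + i, 2, 1) for i in range(n2)]
        s = Schedule.empty(inst, ems)
        assert f13_emergency_rate(s, inst) == pytest.approx(0.5)

    def test_f13_saturated_and_zero_cap_days(self):
        inst = Instance(
            beds=24, horizon=2, electives=(), currents=(),
            arrivals=ArrivalModel((4.5, 0.0)),
        )
        cap = inst.max_per_day[0]
        s = Schedule.empty(
            inst, [EmergencyArrival(20001 + i, 1, 1) for i in range(cap)]
        )
        # the zero-cap day carries no information and is excluded
        assert f13_emergency_rate(s, inst) == pytest.approx(1.0)

    def test_monotone_in_admissions(self, small_instance):
        inst = small_instance
        s = Schedule.empty(inst)
        prev = f11_occupancy_rate(s, inst)
        for p in inst.electives[:5]:
            s.admission_day[p.id] = p.expected_day
            cur = f11_occupancy_rate(s, inst)
            assert cur >= prev
            prev = cur

    def test_stage1_objectives_vector(self, small_instance):
        s = Schedule.empty(small_instance)
        v = stage1_objectives(s, small_instance)
        assert v.stage == 1
        assert (v.f11, v.f12, v.f13) == v.values


class TestObjectiveVector:
    def test_shape_validation(self):
        with pytest.raises(ValueError):
            ObjectiveVector(1, (1.0, 2.0))
        with pytest.raises(ValueError):
            ObjectiveVector(2, (1.0, 2.0, 3.0))
        with pytest.raises(ValueError):
            ObjectiveVector(3, (1.0, 2.0))

    def test_reference_requires_stage1(self, small_instance):
        s = Schedule.empty(small_instance)
        with pytest.raises(ValueError):
            StageOneReference(s, ObjectiveVector(2, (1.0, 0.0)))


class TestFeasibility:
    def test_boundary_is_feasible(self):
        inst = Instance(
            beds=2, horizon=1,
            electives=(
                ElectivePatient(1, 1, 1, 0.5),
                ElectivePatient(2, 1, 1, 0.5),
            ),
            currents=(), arrivals=no_arrivals(1),
        )
        s = Schedule.empty(inst)
        s.admission_day = {1: 1, 2: 1}
        ok, v = is_feasible(s, inst)
        assert ok and v == []

    def test_overload_names_day(self):
        inst = Instance(
            beds=1, horizon=2,
            electives=(
                ElectivePatient(1, 1, 2, 0.5),
                ElectivePatient(2, 2, 1, 0.5),
            ),
            currents=(), arrivals=no_arrivals(2),
        )
        s = Schedule.empty(inst)
        s.admission_day = {1: 1, 2: 2}
        ok, v = is_feasible(s, inst)
        assert not ok and any("day 2" in msg for msg in v)

    def test_early_admission_flagged(self):
        inst = Instance(
            beds=2, horizon=3,
            electives=(ElectivePatient(1, 2, 1, 0.5),),
            currents=(), arrivals=no_arrivals(3),
        )
        s = Schedule.empty(inst)
        s.admission_day = {1: 1}
        ok, v = is_feasible(s, inst)
        assert not ok and any("before expected" in msg for msg in v)

    def test_emergency_cap_violation(self):
        inst = one_day_instance(rate=0.5)
        cap = inst.max_per_day[0]
        s = Schedule.empty(
            inst,
            [EmergencyArrival(20001 + i, 1, 1) for i in range(cap + 1)],
        )
        ok, v = is_feasible(s, inst)
        assert not ok and any("exceed cap" in msg for msg in v)

    def test_emergency_overflow_of_beds_allowed(self):
        # emergencies may exceed Q without making the schedule infeasible
        inst = Instance(
            beds=1, horizon=1, electives=(), currents=(),
            arrivals=ArrivalModel((4.5,)),
        )
        s = Schedule.empty(
            inst, [EmergencyArrival(20001 + i, 1, 1) for i in range(3)]
        )
        ok, _ = is_feasible(s, inst)
        assert ok


class TestStage2Objectives:
    def _pair_instance(self):
        return Instance(
            beds=2, horizon=3,
            electives=(
                ElectivePatient(1, 1, 2, 0.5),
                ElectivePatient(2, 1, 1, 0.9),
            ),
            currents=(CurrentPatient(10001, 2, 1),),
            arrivals=no_arrivals(3),
        )

    def test_identity(self, small_instance):
        s = Schedule.empty(
            small_instance, sample_emergency_stream(small_instance, 1)
        )
        for p in small_instance.electives[:4]:
            s.admission_day[p.id] = p.expected_day
        assert f21_similarity(s, s, small_instance) == 1.0
        assert f22_added_beds(s, s, small_instance) == 0

    def test_disjoint_similarity_zero(self):
        inst = self._pair_instance()
        a = Schedule.empty(inst)
        a.admission_day = {2: 1}
        a.current_remaining = {10001: 0}
        b = Schedule.empty(inst)
        b.admission_day = {2: 2}
        b.current_remaining = {10001: 0}
        assert f21_similarity(a, b, inst) == 0.0

    def test_hand_fraction(self):
        inst = self._pair_instance()
        a = Schedule.empty(inst)
        a.admission_day = {1: 1, 2: 2}  # pairs: cur@1, 1@1, 1@2, 2@2 → 4
        b = Schedule.empty(inst)
        b.admission_day = {1: 1}  # keeps cur@1, 1@1, 1@2 → 3 of 4
        assert f21_similarity(a, b, inst) == pytest.approx(0.75)

    def test_denominator_max(self):
        inst = self._pair_instance()
        a = Schedule.empty(inst)
        a.admission_day = {2: 1}  # pairs: cur@1, 2@1 → 2
        b = Schedule.empty(inst)
        b.admission_day = {2: 1, 1: 2}  # adds 1@2, 1@3 → 4 pairs
        assert f21_similarity(a, b, inst) == 1.0
        assert f21_similarity(
            a, b, inst, denominator="max"
        ) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            f21_similarity(a, b, inst, denominator="median")

    def test_empty_stage1_convention(self):
        inst = Instance(
            beds=2, horizon=2, electives=(), currents=(),
            arrivals=no_arrivals(2),
        )
        assert f21_similarity(
            Schedule.empty(inst), Schedule.empty(inst), inst
        ) == 1.0

    def test_f22_hand_max_difference(self):
        inst = Instance(
            beds=2, horizon=2, electives=(), currents=(),
            arrivals=ArrivalModel((4.5, 4.5)),
        )
        s1 = Schedule.empty(inst)
        s2 = Schedule.empty(
            inst,
            [EmergencyArrival(20001 + i, 1, 1) for i in range(6)]
            + [EmergencyArrival(20101 + i, 2, 1) for i in range(4)],
        )
        # q1 = (0, 0), q2 = (6, 4) → 6
        assert f22_added_beds(s1, s2, inst) == 6
        # never negative
        assert f22_added_beds(s2, s1, inst) == 0

    def test_bed_sensitive_variant_is_stricter(self):
        inst = self._pair_instance()
        a = Schedule.empty(inst)
        a.admission_day = {1: 1, 2: 2}
        b = a.copy()
        b.emergencies = [EmergencyArrival(20001, 1, 1)]
        loose = f21_similarity(a, b, inst)
        strict = f21_similarity(a, b, inst, bed_sensitive=True)
        assert strict <= loose


class TestOccupancyPmf:
    def test_shift_structure_and_normalization(self):
        inst = one_day_instance()
        s = Schedule.empty(inst)
        s.admission_day = {p.id: 1 for p in inst.electives}
        det = 8 + 3
        pmf = occupancy_pmf(s, inst, 1)
        assert sum(pmf.values()) == pytest.approx(1.0)
        day_pmf = inst.arrivals.day_pmf(1)
        for k, p in enumerate(day_pmf):
            assert pmf[det + k] == pytest.approx(float(p))
        assert min(pmf) == det
        assert max(pmf) == det + inst.max_per_day[0]

    def test_zero_rate_point_mass(self):
        inst = Instance(
            beds=4, horizon=1,
            electives=(ElectivePatient(1, 1, 1, 0.5),),
            currents=(), arrivals=no_arrivals(1),
        )
        s = Schedule.empty(inst)
        s.admission_day = {1: 1}
        assert occupancy_pmf(s, inst, 1) == {1: 1.0}

    def test_mean_decomposition(self):
        inst = one_day_instance()
        s = Schedule.empty(inst)
        s.admission_day = {p.id: 1 for p in inst.electives}
        pmf = occupancy_pmf(s, inst, 1)
        mean = sum(k * p for k, p in pmf.items())
        day_pmf = inst.arrivals.day_pmf(1)
        trunc_mean = float(np.dot(np.arange(len(day_pmf)), day_pmf))
        assert mean == pytest.approx(11 + trunc_mean)


class TestBedLayout:
    def test_no_double_occupancy(self, small_instance):
        inst = small_instance
        s = Schedule.empty(inst, sample_emergency_stream(inst, 2))
        for p in inst.electives[:8]:
            s.admission_day[p.id] = p.expected_day
        frame = schedule_to_frame(s, inst)
        assert not frame.duplicated(subset=["day", "bed"]).any()

    def test_deterministic(self, small_instance):
        inst = small_instance
        s = Schedule.empty(inst, sample_emergency_stream(inst, 2))
        for p in inst.electives[:8]:
            s.admission_day[p.id] = p.expected_day
        assert bed_layout(s, inst) == bed_layout(s, inst)

    def test_objectives_ignore_bed_labels(self, small_instance):
        # objectives are functions of the schedule only; bed labels are a
        # presentation concern
        inst = small_instance
        s = Schedule.empty(inst, sample_emergency_stream(inst, 2))
        for p in inst.electives[:8]:
            s.admission_day[p.id] = p.expected_day
        v1 = stage1_objectives(s, inst).values
        _ = bed_layout(s, inst)
        assert stage1_objectives(s, inst).values == v1


@given(st.integers(min_value=0, max_value=10_000))
def test_f21_self_similarity_property(seed):
    inst = generate_instance(
        beds=6, horizon=4, n_electives=8, n_currents=1,
        rate_range=(1.0, 2.0), seed=seed % 5,
    )
    rng = np.random.default_rng(seed)
    s = Schedule.empty(inst, sample_emergency_stream(inst, seed % 7))
    for p in inst.electives:
        if rng.random() < 0.6:
            s.admission_day[p.id] = int(
                rng.integers(p.expected_day, inst.horizon + 1)
            )
    assert f21_similarity(s, s, inst) == 1.0
    assert f22_added_beds(s, s, inst) == 0
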