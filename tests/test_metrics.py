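"""Speedup/efficiency arithmetic and the greedy scheduler simulator."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from datumflow import (
    BenchmarkRecord,
    ValidationError,
    WorkloadModel,
    efficiency_table,
    parse_duration,
    round_half_up,
    scaling_efficiency,
    simulate_schedule,
    speedup,
)


def greedy_oracle(durations, n_workers):
    """Independent event-driven re-derivation of the dispatch rule: advance
    time to each completion; idle workers (lowest index first) take the next
    datum in list order."""
    pending = list(durations)
    running = {}  # worker -> completion time
    idle = list(range(n_workers))
    now = 0.0
    makespan = 0.0
    while pending or running:
        while idle and pending:
            worker = min(idle)
            idle.remove(worker)
            running[worker] = now + pending.pop(0)
        now = min(running.values())
        makespan = max(makespan, now)
        for worker in sorted(w for w, end in running.items() if end == now):
            del running[worker]
            idle.append(worker)
    return makespan


class TestDurations:
    @pytest.mark.parametrize(
        "text,minutes",
        [("30.8h", 1848.0), ("37.3min", 37.3), ("90s", 1.5), ("2hr", 120.0), (5, 5.0)],
    )
    def test_unit_conversion(self, text, minutes):
        assert parse_duration(text) == pytest.approx(minutes)

    @pytest.mark.parametrize("bad", ["", "fast", "-3h", "0min", 0, -1.5])
    def test_invalid_durations_rejected(self, bad):
        with pytest.raises(ValidationError):
            parse_duration(bad)


class TestPrintedBenchmarkArithmetic:
    """Reference LC-MS benchmark rows, reproduced from their reported times."""

    def test_feature_finder_row(self):
        s = speedup("30.8h", "37.3min")
        assert round_half_up(s) == 50
        assert round_half_up(scaling_efficiency(s, 80) * 100) == 62

    def test_find_peaks_row(self):
        assert round_half_up(speedup("10.5h", "11.5min")) == 55

    def test_annotation_row_efficiency_from_stated_speedup(self):
        assert scaling_efficiency(63, 80) * 100 == pytest.approx(78.75)
        assert round_half_up(scaling_efficiency(63, 80) * 100) == 79

    def test_benchmark_record_summary(self):
        row = BenchmarkRecord.from_times("FeatureFinderMetabo", "30.8h", "37.3min", 80)
        summary = row.summary()
        assert summary["speedup_rounded"] == 50
        assert summary["efficiency_percent"] == 62

    def test_identities(self):
        assert speedup("7.5h", "7.5h") == 1.0
        assert scaling_efficiency(16.0, 16) == 1.0

    def test_round_half_up_breaks_ties_upward(self):
        assert round_half_up(78.75, 0) == 79
        assert round_half_up(0.5) == 1
        assert round_half_up(2.5) == 3  # banker's rounding would give 2

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            scaling_efficiency(50.0, 0)
        with pytest.raises(ValidationError):
            scaling_efficiency(-1.0, 8)


class TestScheduler:
    def test_identical_durations_closed_form(self):
        # n datums of duration d on N workers finish in ceil(n/N)*d
        for n, n_workers, d in [(8, 4, 3.0), (7, 2, 1.5), (5, 8, 2.0), (9, 4, 1.0)]:
            result = simulate_schedule(WorkloadModel([d] * n), n_workers)
            assert result.makespan == pytest.approx(math.ceil(n / n_workers) * d)

    def test_single_worker_serializes_everything(self):
        workload = WorkloadModel([3.0, 1.0, 4.0, 1.5])
        assert simulate_schedule(workload, 1).makespan == pytest.approx(workload.total)

    def test_long_first_datum_dominates(self):
        assert simulate_schedule(WorkloadModel([5, 1, 1, 1]), 2).makespan == pytest.approx(5.0)

    def test_trace_is_a_valid_schedule(self):
        result = simulate_schedule(WorkloadModel([2, 1, 3, 1, 2]), 2)
        per_worker = {}
        for item in result.trace:
            per_worker.setdefault(item.worker, []).append(item)
        for items in per_worker.values():
            for a, b in zip(items, items[1:]):
                assert b.start >= a.end  # one datum at a time per worker

    def test_invalid_worker_count_rejected(self):
        with pytest.raises(ValidationError):
            simulate_schedule(WorkloadModel([1.0]), 0)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        durations=st.lists(st.sampled_from([1.0, 2.0, 5.0, 10.0]), min_size=1, max_size=8),
        n_workers=st.integers(1, 4),
    )
    def test_simulator_agrees_with_event_driven_oracle(self, durations, n_workers):
        assert simulate_schedule(WorkloadModel(durations), n_workers).makespan == pytest.approx(
            greedy_oracle(durations, n_workers)
        )

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        durations=st.lists(st.floats(0.1, 50.0), min_size=1, max_size=12),
        n_workers=st.integers(1, 6),
    )
    def test_makespan_bounds(self, durations, n_workers):
        makespan = simulate_schedule(WorkloadModel(durations), n_workers).makespan
        assert makespan >= max(durations) - 1e-9
        assert makespan <= sum(durations) + 1e-9


class TestEfficiencyTable:
    def test_perfect_scaling_when_workload_divides_evenly(self):
        rows = efficiency_table(WorkloadModel([2.0] * 8), [1, 2, 4, 8])
        assert all(row["efficiency"] == pytest.approx(1.0) for row in rows)

    def test_efficiency_never_exceeds_one(self):
        workload = WorkloadModel.lognormal(n=60, mean=4.0, sigma=1.0, seed=7)
        for row in efficiency_table(workload, [1, 5, 20, 80]):
            assert row["efficiency"] <= 1.0 + 1e-9

    def test_imbalance_caps_efficiency_as_workers_grow(self):
        # one dominant datum: efficiency at N=80 must fall below N=20,
        # and can never beat total/(N * longest)
        workload = WorkloadModel([100.0] + [1.0] * 99)
        rows = {row["workers"]: row for row in efficiency_table(workload, [20, 80])}
        assert rows[80]["efficiency"] < rows[20]["efficiency"]
        for n_workers, row in rows.items():
            cap = min(1.0, workload.total / (n_workers * max(workload.durations)))
            assert row["efficiency"] <= cap + 1e-9


class TestWorkloadModel:
    def test_generation_reproducible_from_seed(self):
        a = WorkloadModel.lognormal(n=10, mean=3.0, sigma=0.5, seed=11)
        b = WorkloadModel.lognormal(n=10, mean=3.0, sigma=0.5, seed=11)
        c = WorkloadModel.lognormal(n=10, mean=3.0, sigma=0.5, seed=12)
        assert a.durations == b.durations
        assert a.durations != c.durations

    def test_json_round_trip_explicit_and_distribution(self):
        explicit = WorkloadModel.from_json('{"durations": [1.0, 2.5]}')
        assert explicit.durations == [1.0, 2.5]
        sampled = WorkloadModel.from_json(
            '{"distribution": "lognormal", "n": 5, "mean": 2.0, "sigma": 0.3, "seed": 4}'
        )
        assert sampled.durations == WorkloadModel.lognormal(5, 2.0, 0.3, 4).durations

    def test_empty_or_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            WorkloadModel([])
        with pytest.raises(ValidationError):
            WorkloadModel([1.0, 0.0])
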