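"""Parallel-scaling arithmetic and a greedy datum scheduler simulator.

Two standard metrics quantify how well a datum-parallel stage scales:

* **speedup**  S(N) = T1 / TN — serial running time over the parallel
  running time on N workers;
* **scaling efficiency**  E(N) = S(N) / N — the fraction of perfect linear
  scaling actually achieved (1.0 means N workers are N times faster).

Durations carry explicit units at the interface (hours, minutes, seconds)
and are converted to minutes internally, since benchmark tables habitually
mix hours for serial runs with minutes for parallel ones.  Reported
integers and percentages use round-half-up, matching how such tables are
conventionally printed; the raw ratios are always available unrounded.

The simulator models the engine's dispatch rule — an idle worker takes the
next datum in list order, each worker processes one datum at a time — and
exposes the makespan and per-worker trace.  It models pure processing time
only (no container start-up or transfer costs), which is enough to show the
qualitative effect that matters: imbalanced datum durations cap efficiency
as the worker count grows, because the whole job can never finish faster
than its single longest datum.
"""

from __future__ import annotations

import heapq
import json
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .errors import ValidationError

_DURATION_RE = re.compile(r"^\s*([0-9]+(?:\.[0-9]+)?)\s*(h|hr|hours?|m|min|minutes?|s|sec|seconds?)\s*$")

_TO_MINUTES = {"h": 60.0, "m": 1.0, "s": 1.0 / 60.0}


def parse_duration(text: str | float | int) -> float:
    """Parse '30.8h' / '37.3min' / '12s' (or a bare number of minutes) to minutes."""
    if isinstance(text, (int, float)):
        value = float(text)
        if value <= 0:
            raise ValidationError(f"duration must be positive, got {value}")
        return value
    match = _DURATION_RE.match(text)
    if not match:
        raise ValidationError(f"cannot parse duration {text!r} (use e.g. '30.8h', '37.3min')")
    value = float(match.group(1))
    if value <= 0:
        raise ValidationError(f"duration must be positive, got {text!r}")
    return value * _TO_MINUTES[match.group(2)[0]]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero — the convention of printed benchmark tables."""
    quantum = Decimal(1).scaleb(-ndigits)
    result = float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
    return result if ndigits > 0 else int(result)


def speedup(t1: str | float, tn: str | float) -> float:
    """S(N) = T1/TN for positive durations in any mix of units."""
    return parse_duration(t1) / parse_duration(tn)


def scaling_efficiency(s: float, n_workers: int) -> float:
    """E(N) = S(N)/N; 1.0 is perfect linear scaling."""
    if s <= 0:
        raise ValidationError(f"speedup must be positive, got {s}")
    if not isinstance(n_workers, int) or n_workers < 1:
        raise ValidationError(f"worker count must be an integer >= 1, got {n_workers!r}")
    return s / n_workers


@dataclass(frozen=True)
class BenchmarkRecord:
    """One benchmark row: serial vs N-worker running time for a stage."""

    label: str
    n_workers: int
    serial_time: float  # minutes
    parallel_time: float  # minutes

    def __post_init__(self) -> None:
        if self.serial_time <= 0 or self.parallel_time <= 0:
            raise ValidationError("benchmark times must be positive")
        if self.n_workers < 1:
            raise ValidationError("worker count must be >= 1")

    @classmethod
    def from_times(
        cls, label: str, t1: str | float, tn: str | float, n_workers: int
    ) -> "BenchmarkRecord":
        return cls(
            label=label,
            n_workers=n_workers,
            serial_time=parse_duration(t1),
            parallel_time=parse_duration(tn),
        )

    @property
    def speedup(self) -> float:
        return self.serial_time / self.parallel_time

    @property
    def efficiency(self) -> float:
        return self.speedup / self.n_workers

    def summary(self) -> dict:
        """The row as a printed table would show it: rounded speedup and percent."""
        return {
            "label": self.label,
            "workers": self.n_workers,
            "speedup": self.speedup,
            "speedup_rounded": round_half_up(self.speedup),
            "efficiency": self.efficiency,
            "efficiency_percent": round_half_up(self.efficiency * 100),
        }


class WorkloadModel:
    """Per-datum processing durations, explicit or sampled reproducibly."""

    def __init__(self, durations: Sequence[float]):
        durations = [float(d) for d in durations]
        if not durations or any(d <= 0 for d in durations):
            raise ValidationError("workload durations must be a non-empty positive sequence")
        self.durations = durations

    @classmethod
    def lognormal(cls, n: int, mean: float, sigma: float, seed: int) -> "WorkloadModel":
        """Heavy-tailed workload: the realistic shape for per-sample runtimes."""
        rng = np.random.default_rng(seed)
        return cls(np.exp(rng.normal(np.log(mean), sigma, size=n)).tolist())

    @classmethod
    def uniform(cls, n: int, low: float, high: float, seed: int) -> "WorkloadModel":
        rng = np.random.default_rng(seed)
        return cls(rng.uniform(low, high, size=n).tolist())

    @classmethod
    def from_json(cls, text: str) -> "WorkloadModel":
        """Load either {"durations": [...]} or
        {"distribution": "lognormal", "n": ..., "mean": ..., "sigma": ..., "seed": ...}."""
        doc = json.loads(text)
        if "durations" in doc:
            return cls(doc["durations"])
        dist = doc.get("distribution")
        if dist == "lognormal":
            return cls.lognormal(doc["n"], doc["mean"], doc["sigma"], doc["seed"])
        if dist == "uniform":
            return cls.uniform(doc["n"], doc["low"], doc["high"], doc["seed"])
        raise ValidationError(f"unknown workload distribution {dist!r}")

    @property
    def total(self) -> float:
        return sum(self.durations)


@dataclass(frozen=True)
class ScheduledDatum:
    index: int
    worker: int
    start: float
    end: float


@dataclass(frozen=True)
class ScheduleResult:
    makespan: float
    trace: tuple[ScheduledDatum, ...]


def simulate_schedule(workload: WorkloadModel, n_workers: int) -> ScheduleResult:
    """Greedy list scheduling: the next datum goes to the earliest-free worker.

    Ties between simultaneously free workers break toward the lowest worker
    index, making the trace fully deterministic.
    """
    if not isinstance(n_workers, int) or n_workers < 1:
        raise ValidationError(f"worker count must be an integer >= 1, got {n_workers!r}")
    free_at = [(0.0, w) for w in range(n_workers)]  # (time free, worker index)
    heapq.heapify(free_at)
    trace = []
    makespan = 0.0
    for index, duration in enumerate(workload.durations):
        start, worker = heapq.heappop(free_at)
        end = start + duration
        trace.append(ScheduledDatum(index=index, worker=worker, start=start, end=end))
        heapq.heappush(free_at, (end, worker))
        makespan = max(makespan, end)
    return ScheduleResult(makespan=makespan, trace=tuple(trace))


def efficiency_table(workload: WorkloadModel, worker_counts: Sequence[int]) -> list[dict]:
    """Simulated speedup and efficiency for each worker count.

    The simulated serial time is the sum of datum durations, so the speedup
    at N workers is total/makespan(N) and the efficiency is speedup/N.
    """
    rows = []
    for n in worker_counts:
        makespan = simulate_schedule(workload, n).makespan
        s = workload.total / makespan
        rows.append(
            {
                "workers": n,
                "makespan": makespan,
                "speedup": s,
                "efficiency": s / n,
                "efficiency_percent": round_half_up(s / n * 100),
            }
        )
    return rows
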