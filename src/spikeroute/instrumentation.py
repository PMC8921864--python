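"""Hardware-independent operation counters and per-phase timers.

Abstract counters replace hardware profiling: the number of receive
buffer entries read (including rejected foreign entries), entries
skipped, target segments walked, synapses activated, and ring-buffer
writes.  These capture the structural cost difference between the
delivery kernels — the original algorithm reads every entry on every
thread (``T * E`` reads per cycle), the register-sorting redesign reads
each entry exactly twice (once while sorting, once while delivering)
independent of the thread count.  Wall-clock phase times are recorded
for information only; they are never part of any correctness contract.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["CycleCounters", "RunInstrumentation"]


@dataclass
class CycleCounters:
    """Operation counts for one communication cycle (or one run)."""

    entries_read: int = 0
    entries_skipped: int = 0
    segments_walked: int = 0
    synapses_activated: int = 0
    rb_writes: int = 0
    phase_times: dict = field(default_factory=dict)

    def reset(self) -> None:
        self.entries_read = 0
        self.entries_skipped = 0
        self.segments_walked = 0
        self.synapses_activated = 0
        self.rb_writes = 0
        self.phase_times = {}

    def add(self, other: "CycleCounters") -> None:
        self.entries_read += other.entries_read
        self.entries_skipped += other.entries_skipped
        self.segments_walked += other.segments_walked
        self.synapses_activated += other.synapses_activated
        self.rb_writes += other.rb_writes
        for k, v in other.phase_times.items():
            self.phase_times[k] = self.phase_times.get(k, 0.0) + v

    def validate(self) -> None:
        if self.entries_skipped > self.entries_read:
            raise AssertionError("entries_skipped exceeds entries_read")
        if self.synapses_activated != self.rb_writes:
            raise AssertionError("every synapse activation must write a ring buffer")

    def as_dict(self) -> dict:
        d = {
            "entries_read": self.entries_read,
            "entries_skipped": self.entries_skipped,
            "segments_walked": self.segments_walked,
            "synapses_activated": self.synapses_activated,
            "rb_writes": self.rb_writes,
        }
        d.update({f"t_{k}_s": v for k, v in sorted(self.phase_times.items())})
        return d


class RunInstrumentation:
    """Per-cycle counter history plus cumulative totals for a run."""

    def __init__(self) -> None:
        self.records: list[dict] = []
        self.totals = CycleCounters()

    def record_cycle(
        self, cycle: int, algorithm: str, E: int, T: int, counters: CycleCounters
    ) -> None:
        counters.validate()
        row = {"cycle": cycle, "algorithm": algorithm, "E": E, "T": T}
        row.update(counters.as_dict())
        self.records.append(row)
        self.totals.add(counters)

    def time_phase(self, counters: CycleCounters, phase: str):
        """Context manager adding wall time of a block to ``phase``."""
        return _PhaseTimer(counters, phase)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class _PhaseTimer:
    def __init__(self, counters: CycleCounters, phase: str) -> None:
        self.counters = counters
        self.phase = phase

    def __enter__(self):
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, *exc) -> bool:
        dt = time.perf_counter() - self._t0
        self.counters.phase_times[self.phase] = (
            self.counters.phase_times.get(self.phase, 0.0) + dt
        )
        return False
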