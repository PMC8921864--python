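"""Redesigned spike-delivery kernel: parallel sort, then local delivery.

Delivery becomes a two-step process with a single synchronisation point.
First, the threads sort the receive-buffer entries in parallel: thread
``w`` reads the contiguous slice ``[floor(w E / T), floor((w+1) E / T))``
of the buffer and appends each entry to its private domain of the
*spike-receive register*, bucketed by hosting thread and synapse type.
Every buffer element is read exactly once.  After a barrier, each
hosting thread works through just the register cells addressed to it —
grouped by synapse type, so each innermost store array is processed in
one pass — walking each entry's target segment with the synapse's
``Send()`` now returning a direct ring-buffer reference (P2RB) so
``AddValue()`` is called with no neuron-level indirection.  In total
every entry is looked at exactly twice, independent of the thread
count.
"""

from __future__ import annotations

from .exchange import ReceiveBuffer, emission_step
from .instrumentation import CycleCounters

__all__ = ["SpikeReceiveRegister", "sort_into_register", "deliver_from_register"]


class SpikeReceiveRegister:
    """Nested register ``[writing_thread][target_thread][syn_type] -> entries``.

    Each writing thread owns its first-level domain, so the parallel
    sorting phase is free of write conflicts.
    """

    def __init__(self, T: int, n_syn_types: int) -> None:
        self.T = T
        self.n_syn_types = n_syn_types
        self.cells = [
            [[[] for _ in range(n_syn_types)] for _ in range(T)] for _ in range(T)
        ]

    def cell(self, writing_thread: int, target_thread: int, syn_type: int) -> list:
        return self.cells[writing_thread][target_thread][syn_type]

    @property
    def n_entries(self) -> int:
        return sum(
            len(c) for dom in self.cells for row in dom for c in row
        )


def slice_bounds(E: int, T: int, w: int) -> tuple[int, int]:
    """Buffer slice assigned to writing thread ``w``: balanced to within one."""
    return (w * E) // T, ((w + 1) * E) // T


def sort_into_register(
    buffer: ReceiveBuffer,
    T: int,
    counters: CycleCounters,
    n_syn_types: int = 2,
) -> SpikeReceiveRegister:
    """Parallel bucket sort of the receive buffer into the register.

    Thread ``w`` reads its buffer slice in order and appends each entry
    to ``register[w][entry.tid][entry.syn_type]``; slice order is
    preserved within each cell.  Total entry reads equal ``E``.
    """
    E = len(buffer)
    reg = SpikeReceiveRegister(T, n_syn_types)
    for w in range(T):
        lo, hi = slice_bounds(E, T, w)
        domain = reg.cells[w]
        for i in range(lo, hi):
            entry = buffer.entries[i]
            counters.entries_read += 1
            domain[entry.tid][entry.syn_type].append(entry)
    return reg


def deliver_from_register(
    register: SpikeReceiveRegister,
    store,
    thread: int,
    interval_start: int,
    counters: CycleCounters,
) -> None:
    """Deliver one hosting thread's register cells (pointer-mode store).

    Iterates writing-thread domains in ascending order and, within each,
    synapse types in ascending order, so all entries for one innermost
    array are handled in one pass.  Each entry read here is its second
    and final read; the synapse's ``Send()`` returns the target ring
    buffer directly and the kernel calls ``AddValue()`` itself.
    """
    if store.target_mode != "pointer":
        raise ValueError(
            "register delivery requires the store in pointer (P2RB) mode"
        )
    for w in range(register.T):
        for syn_type in range(register.n_syn_types):
            cell = register.cells[w][thread][syn_type]
            if not cell:
                continue
            arr = store.get(thread, syn_type)
            n = len(arr)
            for entry in cell:
                counters.entries_read += 1
                counters.segments_walked += 1
                step = emission_step(interval_start, entry.lag)
                lcid = entry.lcid
                subsq = True
                while subsq:
                    if lcid >= n:
                        raise IndexError(
                            f"segment overruns innermost array "
                            f"(thread {thread}, type {syn_type}, lcid {lcid})"
                        )
                    rb, delay, weight, subsq = arr.send_pointer(lcid)
                    rb.add_value(step, delay, weight)
                    counters.synapses_activated += 1
                    counters.rb_writes += 1
                    lcid += 1
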