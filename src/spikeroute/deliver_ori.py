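"""Original spike-delivery kernel: every thread scans the whole buffer.

Each thread reads through *all* spike entries in the process-local
receive buffer and proceeds only with entries whose hosting thread is
its own — all others are skipped after the read.  For a relevant entry
the thread walks the addressed target segment synapse by synapse via
the ``subsq`` flag; each synapse's ``Send()`` hands delay and weight to
the target neuron's ``Receive()``, which selects the appropriate ring
buffer and calls ``AddValue()``.  The per-entry scanning overhead is
the structural inefficiency the redesigned kernel removes: per cycle
the threads together perform ``T * E`` entry reads for ``E`` entries.
"""

from __future__ import annotations

from .exchange import ReceiveBuffer, emission_step
from .instrumentation import CycleCounters

__all__ = ["deliver_ori"]


def deliver_ori(
    buffer: ReceiveBuffer,
    store,
    neurons,
    thread: int,
    interval_start: int,
    counters: CycleCounters,
) -> None:
    """Deliver one thread's share of a receive buffer, original algorithm.

    ``neurons[tid][lidx]`` must expose ``receive(step, delay_steps,
    weight)`` (index mode) — the neuron-level indirection that selects
    the ring buffer.  In pointer mode the synapse's direct ring-buffer
    reference is used instead, skipping that indirection while keeping
    the scan-all-entries structure.

    Counters: ``entries_read`` for every entry (hit or miss),
    ``entries_skipped`` for foreign entries, ``segments_walked`` and
    ``synapses_activated``/``rb_writes`` for the deliveries performed.
    """
    pointer_mode = store.target_mode == "pointer"
    for entry in buffer.entries:
        counters.entries_read += 1
        if entry.tid != thread:
            counters.entries_skipped += 1
            continue
        counters.segments_walked += 1
        step = emission_step(interval_start, entry.lag)
        arr = store.get(entry.tid, entry.syn_type)
        n = len(arr)
        lcid = entry.lcid
        subsq = True
        while subsq:
            if lcid >= n:
                raise IndexError(
                    f"segment overruns innermost array "
                    f"(thread {entry.tid}, type {entry.syn_type}, lcid {lcid})"
                )
            if pointer_mode:
                rb, delay, weight, subsq = arr.send_pointer(lcid)
                rb.add_value(step, delay, weight)
            else:
                delay, weight, lidx, subsq = arr.send_index(lcid)
                neurons[entry.tid][lidx].receive(step, delay, weight)
            counters.synapses_activated += 1
            counters.rb_writes += 1
            lcid += 1
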