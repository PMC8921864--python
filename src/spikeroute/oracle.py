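"""Naive event-list reference for spike delivery.

Brute-force predictor used to cross-check the delivery kernels: it
iterates the flat edge list per emission — no synapse store, no target
segments, no receive buffers — and accumulates each weight directly
into a predicted ring-buffer image at ``(emission_step + delay) mod L``,
emulating the per-step read-and-clear of quiescent neurons.  Because it
shares no data structures with the kernels, agreement of the ring
buffers is an end-to-end check that every weight arrives exactly at
emission time plus synaptic delay.
"""

from __future__ import annotations

import numpy as np

from .grid import SimGrid
from .partition import EdgeList, PlacementMap

__all__ = ["naive_delivery_ring_buffers", "delivery_multiset"]


def naive_delivery_ring_buffers(
    edges: EdgeList,
    placement: PlacementMap,
    grid: SimGrid,
    emissions_by_cycle: list[list[tuple[int, int]]],
) -> dict:
    """Predicted ring-buffer state after the given cycles of forced emissions.

    ``emissions_by_cycle[c]`` holds ``(gid, absolute_step)`` spikes of
    cycle ``c`` (steps within ``(c*n, (c+1)*n]`` for interval length
    ``n``).  Neurons are assumed quiescent: every slot a neuron update
    would read is cleared, then the cycle's arrivals are accumulated.
    Returns ``{(process, thread): (rb_ex, rb_in)}`` matrices matching
    :meth:`spikeroute.network.Network.ring_buffer_state`.
    """
    L = grid.ring_buffer_length
    n = grid.min_delay_steps
    state = {
        (p, t): (
            np.zeros((placement.n_local(p, t), L)),
            np.zeros((placement.n_local(p, t), L)),
        )
        for p in range(placement.M)
        for t in range(placement.T)
    }
    by_source: dict[int, list[int]] = {}
    for i, s in enumerate(edges.source):
        by_source.setdefault(int(s), []).append(i)

    for c, emissions in enumerate(emissions_by_cycle):
        t0 = c * n
        # neuron updates read (and clear) slots t0 .. t0+n-1 first
        for rb_ex, rb_in in state.values():
            for k in range(n):
                slot = (t0 + k) % L
                rb_ex[:, slot] = 0.0
                rb_in[:, slot] = 0.0
        for gid, step in emissions:
            for i in by_source.get(gid, ()):
                tgt = int(edges.target[i])
                _, p, t = placement.locate(tgt)
                lidx = placement.local_index(tgt)
                w = float(edges.weight[i])
                slot = (step + int(edges.delay_steps[i])) % L
                rb = state[(p, t)][0] if w >= 0 else state[(p, t)][1]
                rb[lidx, slot] += w
    return state


def delivery_multiset(
    edges: EdgeList,
    emissions: list[tuple[int, int]],
) -> dict:
    """Multiset of expected deliveries ``(target, arrival_step, weight) -> count``.

    Order-free summary of what any correct delivery kernel must produce
    for the given emissions.
    """
    out: dict[tuple[int, int, float], int] = {}
    by_source: dict[int, list[int]] = {}
    for i, s in enumerate(edges.source):
        by_source.setdefault(int(s), []).append(i)
    for gid, step in emissions:
        for i in by_source.get(gid, ()):
            key = (
                int(edges.target[i]),
                step + int(edges.delay_steps[i]),
                float(edges.weight[i]),
            )
            out[key] = out.get(key, 0) + 1
    return out
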