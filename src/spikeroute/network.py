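"""Desk-scale emulation of a distributed spiking-network simulation.

A :class:`Network` holds the full state of ``M`` emulated processes with
``T`` threads each: per-thread neuron populations (struct-of-arrays LIF
state), per-neuron excitatory and inhibitory spike ring buffers backed
by per-thread matrices, the per-process 3-D synapse stores, and the
sender-side routing table.  Thread roles execute sequentially with a
barrier between the update, exchange, and delivery phases; the
observable outcome is independent of the order in which thread roles
run within a phase, which is asserted by tests rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .deliver_ori import deliver_ori
from .deliver_srr import deliver_from_register, sort_into_register
from .exchange import all_to_all_exchange, route_emitted_spikes
from .grid import SimGrid
from .instrumentation import CycleCounters, RunInstrumentation
from .neuron import (
    LIFParams,
    PopulationState,
    make_propagators,
    refractory_steps,
    update_population,
)
from .partition import EdgeList, PlacementMap, build_synapse_store
from .ringbuffer import SpikeRingBuffer

__all__ = ["Network", "NeuronHandle", "write_gdf", "read_gdf"]


class NeuronHandle:
    """Per-neuron facade used by the original (index-mode) delivery chain.

    ``receive`` is the neuron-level indirection: it decides which of the
    neuron's ring buffers takes the spike (inhibitory for negative
    weights) and delegates to ``AddValue``.  The pointer-mode kernels
    bypass this object entirely.
    """

    __slots__ = ("rb_ex", "rb_in")

    def __init__(self, rb_ex: SpikeRingBuffer, rb_in: SpikeRingBuffer) -> None:
        self.rb_ex = rb_ex
        self.rb_in = rb_in

    def receive(self, step: int, delay_steps: int, weight: float) -> None:
        rb = self.rb_ex if weight >= 0 else self.rb_in
        rb.add_value(step, delay_steps, weight)


@dataclass
class _ThreadDomain:
    """All state owned by one emulated (process, thread)."""

    gids: np.ndarray
    pop: PopulationState
    rb_ex: np.ndarray  # (n_local, L) ring-buffer matrix, excitatory channel
    rb_in: np.ndarray
    neurons: list  # NeuronHandle per local neuron


class Network:
    """Fully wired network ready for cycle-by-cycle simulation.

    Parameters
    ----------
    edges
        Connectivity; delays in grid steps within the grid's bounds.
    placement
        Round-robin neuron placement (defines ``M``, ``T``, ``N``).
    params
        Homogeneous LIF/alpha-synapse parameters.
    grid
        Time grid; its min-delay interval is the communication interval.
    target_mode
        ``"index"`` (2 B local-index identifier, neuron-level dispatch)
        or ``"pointer"`` (8 B direct ring-buffer reference, P2RB).
    ssg
        Attach sender gids to spike entries (recording-device payload);
        never read during delivery.
    poisson_rate_hz, poisson_weight
        Optional independent Poisson drive per neuron, seeded per
        virtual process so drive is identical for any thread schedule
        and either delivery kernel.
    """

    def __init__(
        self,
        edges: EdgeList,
        placement: PlacementMap,
        params: LIFParams,
        grid: SimGrid,
        target_mode: str = "index",
        ssg: bool = False,
        poisson_rate_hz: float = 0.0,
        poisson_weight: float = 0.0,
        drive_seed: int = 0,
        n_syn_types: int = 2,
    ) -> None:
        if len(edges):
            lo, hi = int(edges.delay_steps.min()), int(edges.delay_steps.max())
            if lo < grid.min_delay_steps or hi > grid.max_delay_steps:
                raise ValueError(
                    f"synaptic delays [{lo}, {hi}] outside grid bounds "
                    f"[{grid.min_delay_steps}, {grid.max_delay_steps}]"
                )
        self.placement = placement
        self.params = params
        self.grid = grid
        self.target_mode = target_mode
        self.ssg = ssg
        self.prop = make_propagators(params, grid.h)
        self.ref_steps = refractory_steps(params, grid.h)
        self.n_syn_types = n_syn_types

        L = grid.ring_buffer_length
        self.domains: dict[tuple[int, int], _ThreadDomain] = {}
        for p in range(placement.M):
            for t in range(placement.T):
                gids = placement.thread_gids(p, t)
                n = len(gids)
                rb_ex = np.zeros((n, L))
                rb_in = np.zeros((n, L))
                neurons = [
                    NeuronHandle(
                        SpikeRingBuffer(grid.min_delay_steps, grid.max_delay_steps,
                                        rb_ex[i]),
                        SpikeRingBuffer(grid.min_delay_steps, grid.max_delay_steps,
                                        rb_in[i]),
                    )
                    for i in range(n)
                ]
                self.domains[(p, t)] = _ThreadDomain(
                    gids=gids, pop=PopulationState.zeros(n),
                    rb_ex=rb_ex, rb_in=rb_in, neurons=neurons,
                )
                self.domains[(p, t)].pop.X[:, 4] = 0.0  # V at E_L

        self.stores, self.routing = build_synapse_store(
            edges, placement, target_mode=target_mode, n_syn_types=n_syn_types
        )
        if target_mode == "pointer":
            self._bind_ring_buffers()

        self.poisson_rate_hz = poisson_rate_hz
        self.poisson_weight = poisson_weight
        self._drive_rngs = {
            vp: np.random.default_rng((drive_seed, vp))
            for vp in range(placement.n_vp)
        }
        self._forced: dict[int, list[int]] = {}  # step -> [gids]
        self.instrumentation = RunInstrumentation()
        self.cycle_index = 0

    # -- construction helpers ------------------------------------------------

    def _bind_ring_buffers(self) -> None:
        """P2RB: resolve each synapse's target to its ring buffer once,
        at network construction; no per-delivery dispatch remains."""
        for p in range(self.placement.M):
            store = self.stores[p]
            for t in range(self.placement.T):
                neurons = self.domains[(p, t)].neurons
                for s in range(self.n_syn_types):
                    arr = store.get(t, s)
                    arr.target_rb = [
                        (neurons[lidx].rb_ex if w >= 0 else neurons[lidx].rb_in)
                        for lidx, w in zip(arr.target_lidx, arr.weight)
                    ]

    # -- fixtures / drive ----------------------------------------------------

    def force_emission(self, gid: int, step: int) -> None:
        """Queue a spike of ``gid`` at absolute grid step ``step``,
        independent of its membrane dynamics (fixture machinery)."""
        self._forced.setdefault(step, []).append(gid)

    def _drive(self, domain: _ThreadDomain, vp: int, n_steps: int) -> np.ndarray | None:
        if self.poisson_rate_hz <= 0.0:
            return None
        lam = self.poisson_rate_hz * self.grid.h * 1e-3
        rng = self._drive_rngs[vp]
        counts = rng.poisson(lam, size=(n_steps, domain.pop.n))
        return counts * self.poisson_weight

    # -- the three-phase cycle -----------------------------------------------

    def run_cycle(self, algorithm: str = "ori", thread_order=None):
        """One communication interval: update, exchange, deliver.

        Returns emitted spikes as ``(gid, step)`` pairs, sorted by step
        then gid.  Counter snapshots are appended to
        ``self.instrumentation``.
        """
        if algorithm not in ("ori", "srr"):
            raise ValueError(f"unknown delivery algorithm {algorithm!r}")
        if algorithm == "srr" and self.target_mode != "pointer":
            raise ValueError("the srr kernel requires target_mode='pointer'")
        M, T = self.placement.M, self.placement.T
        grid = self.grid
        t0 = grid.current_step
        n_steps = grid.min_delay_steps
        if thread_order is None:
            thread_order = [(p, t) for p in range(M) for t in range(T)]
        counters = CycleCounters()
        timer = self.instrumentation.time_phase

        # phase 1: update all neurons, thread by thread, collecting emissions
        emitted: list[tuple[int, int]] = []
        with timer(counters, "update"):
            for (p, t) in thread_order:
                dom = self.domains[(p, t)]
                vp = t * M + p
                drive = self._drive(dom, vp, n_steps)
                if drive is not None:
                    spikes = _update_with_drive(
                        dom, self.params, self.prop, t0, n_steps,
                        self.ref_steps, drive,
                    )
                else:
                    spikes = update_population(
                        dom.pop, self.params, self.prop, dom.rb_ex, dom.rb_in,
                        t0, n_steps, self.ref_steps,
                    )
                emitted.extend((int(dom.gids[i]), s) for i, s in spikes)
        for step in range(t0 + 1, t0 + n_steps + 1):
            for gid in self._forced.pop(step, ()):
                emitted.append((gid, step))
        emitted.sort(key=lambda e: (e[1], e[0]))
        grid.current_step = t0 + n_steps

        # phase 2: route per sending process and exchange all-to-all
        with timer(counters, "communicate"):
            per_sender = [[] for _ in range(M)]
            for gid, step in emitted:
                per_sender[self.placement.locate(gid)[1]].append(
                    (gid, step - t0 - 1)
                )
            outboxes = [
                route_emitted_spikes(ems, self.routing, M, ssg=self.ssg)
                for ems in per_sender
            ]
            buffers = all_to_all_exchange(outboxes)

        # phase 3: deliver with the selected kernel
        E_total = sum(len(b) for b in buffers)
        with timer(counters, "deliver"):
            if algorithm == "ori":
                for (p, t) in thread_order:
                    deliver_ori(
                        buffers[p], self.stores[p],
                        [self.domains[(p, tt)].neurons for tt in range(T)],
                        t, t0, counters,
                    )
            else:
                registers = {}
                for p in range(M):  # sorting phase, all threads of each process
                    registers[p] = sort_into_register(
                        buffers[p], T, counters, self.n_syn_types
                    )
                # barrier: delivery starts only after sorting completes
                for (p, t) in thread_order:
                    deliver_from_register(
                        registers[p], self.stores[p], t, t0, counters
                    )

        self.instrumentation.record_cycle(
            self.cycle_index, algorithm, E_total, T, counters
        )
        self.cycle_index += 1
        return emitted

    def run(self, duration_ms: float, algorithm: str = "ori", thread_order=None):
        """Simulate ``duration_ms`` of biological time (whole cycles).

        The duration must be a multiple of the communication interval.
        Returns all spikes as ``(gid, step)`` pairs.
        """
        interval = self.grid.communication_interval_ms
        n_cycles = round(duration_ms / interval)
        if abs(n_cycles * interval - duration_ms) > 1e-9:
            raise ValueError(
                f"duration {duration_ms} ms is not a multiple of the "
                f"communication interval {interval} ms"
            )
        spikes: list[tuple[int, int]] = []
        for _ in range(n_cycles):
            spikes.extend(self.run_cycle(algorithm=algorithm,
                                         thread_order=thread_order))
        return spikes

    # -- observers -----------------------------------------------------------

    def ring_buffer_state(self) -> dict:
        """Copy of all ring-buffer matrices, keyed ``(process, thread)``."""
        return {
            key: (dom.rb_ex.copy(), dom.rb_in.copy())
            for key, dom in self.domains.items()
        }

    def membrane_potentials(self) -> dict:
        return {
            key: dom.pop.v_m(self.params).copy()
            for key, dom in self.domains.items()
        }


def _update_with_drive(dom, params, prop, t0, n_steps, ref_steps, drive):
    """Update with external Poisson drive injected step by step.

    Drive weights enter the excitatory channel exactly like ring-buffer
    input; drawn per virtual process up front so the result does not
    depend on thread scheduling.
    """
    spikes = []
    for k in range(n_steps):
        slot = (t0 + k) % dom.rb_ex.shape[1]
        dom.rb_ex[:, slot] += drive[k]
        spikes.extend(
            update_population(
                dom.pop, params, prop, dom.rb_ex, dom.rb_in,
                t0 + k, 1, ref_steps,
            )
        )
    return spikes


def write_gdf(spikes, path, h: float) -> None:
    """Write spikes in GDF style: ``gid<TAB>time_ms``, sorted by time then gid."""
    rows = sorted(((step, gid) for gid, step in spikes))
    with open(path, "w") as fh:
        for step, gid in rows:
            fh.write(f"{gid}\t{step * h:.3f}\n")


def read_gdf(path, h: float):
    """Read a GDF-style spike file back into ``(gid, step)`` pairs."""
    spikes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            gid_s, t_s = line.split()
            spikes.append((int(gid_s), round(float(t_s) / h)))
    return spikes
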