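"""Neuron placement, random wiring, and the 3-D synapse store.

Neurons are placed round-robin over all ``M * T`` virtual processes
(one per process/thread pair): neuron ``gid`` lives on virtual process
``gid mod (M*T)``, which maps to process ``vp mod M`` and thread
``vp div M``.  Synapses are hosted on the same thread as their target
neuron and stored per process in a three-level structure indexed by
``[thread][synapse_type][lcid]``.  Within each innermost array the
synapses are grouped into *target segments*: all synapses sharing a
source neuron are contiguous, segments are ordered by ascending source
gid, and every synapse except the last of its segment carries the
``subsq`` (segment-continues) flag.  A spike entry addresses a segment
by the lcid of its first synapse; the sender-side routing table built at
wiring time records exactly one such address per (source, process,
thread, synapse type) with at least one synapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlacementMap",
    "locate_gid",
    "EdgeList",
    "connect_fixed_indegree",
    "InnermostArray",
    "SynapseStore",
    "RoutingTable",
    "build_synapse_store",
    "edges_to_csv",
    "edges_from_csv",
]


def locate_gid(gid: int, M: int, T: int) -> tuple[int, int, int]:
    """Round-robin placement of a neuron: ``(virtual process, process, thread)``.

    ``vp = gid mod (M*T)``, ``process = vp mod M``, ``thread = vp div M``;
    consecutive gids land on distinct virtual processes until wrap-around.
    """
    if gid < 0:
        raise ValueError("gid must be >= 0")
    vp = gid % (M * T)
    return vp, vp % M, vp // M


@dataclass(frozen=True)
class PlacementMap:
    """Round-robin assignment of ``N`` neurons to ``M`` processes x ``T`` threads."""

    M: int
    T: int
    N: int

    def __post_init__(self) -> None:
        if self.M < 1 or self.T < 1 or self.N < 1:
            raise ValueError("M, T, N must all be >= 1")

    @property
    def n_vp(self) -> int:
        return self.M * self.T

    def locate(self, gid: int) -> tuple[int, int, int]:
        if gid >= self.N:
            raise ValueError(f"gid {gid} out of range for N={self.N}")
        return locate_gid(gid, self.M, self.T)

    def local_index(self, gid: int) -> int:
        """Position of ``gid`` within its thread's neuron array."""
        return gid // self.n_vp

    def thread_gids(self, process: int, thread: int) -> np.ndarray:
        """All gids hosted by one (process, thread), ascending."""
        vp = thread * self.M + process
        return np.arange(vp, self.N, self.n_vp)

    def n_local(self, process: int, thread: int) -> int:
        return len(self.thread_gids(process, thread))


@dataclass
class EdgeList:
    """Flat connectivity: parallel arrays, one entry per synapse."""

    source: np.ndarray
    target: np.ndarray
    weight: np.ndarray
    delay_steps: np.ndarray
    syn_type: np.ndarray

    def __len__(self) -> int:
        return len(self.source)

    @classmethod
    def empty(cls) -> "EdgeList":
        return cls(
            source=np.empty(0, dtype=np.int64),
            target=np.empty(0, dtype=np.int64),
            weight=np.empty(0),
            delay_steps=np.empty(0, dtype=np.int64),
            syn_type=np.empty(0, dtype=np.int64),
        )


def connect_fixed_indegree(
    exc_gids: np.ndarray,
    inh_gids: np.ndarray,
    targets: np.ndarray,
    K_exc: int,
    K_inh: int,
    w_exc: float,
    w_inh: float,
    delay_steps: int,
    seed: int,
    allow_autapses: bool = True,
) -> EdgeList:
    """Fixed in-degree random wiring with sources drawn with replacement.

    Every target neuron receives exactly ``K_exc`` synapses with sources
    drawn uniformly from ``exc_gids`` (synapse type 0, weight ``w_exc``)
    and ``K_inh`` from ``inh_gids`` (type 1, weight ``w_inh``).
    Multapses are always possible; autapses (source == target) are
    redrawn only if ``allow_autapses`` is False.  Deterministic for a
    fixed seed; edges are ordered by target, excitatory before
    inhibitory.
    """
    exc_gids = np.asarray(exc_gids, dtype=np.int64)
    inh_gids = np.asarray(inh_gids, dtype=np.int64)
    targets = np.asarray(targets, dtype=np.int64)
    if K_exc > 0 and len(exc_gids) == 0:
        raise ValueError("K_exc > 0 but excitatory source population is empty")
    if K_inh > 0 and len(inh_gids) == 0:
        raise ValueError("K_inh > 0 but inhibitory source population is empty")
    rng = np.random.default_rng(seed)
    n_t = len(targets)

    def draw(pool: np.ndarray, K: int) -> np.ndarray:
        if K == 0 or n_t == 0:
            return np.empty((n_t, 0), dtype=np.int64)
        src = pool[rng.integers(0, len(pool), size=(n_t, K))]
        if not allow_autapses:
            if len(pool) == 1 and np.any(np.isin(targets, pool)):
                raise ValueError("cannot forbid autapses with a single-neuron pool")
            bad = src == targets[:, None]
            while np.any(bad):
                src[bad] = pool[rng.integers(0, len(pool), size=int(bad.sum()))]
                bad = src == targets[:, None]
        return src

    src_e = draw(exc_gids, K_exc)
    src_i = draw(inh_gids, K_inh)
    src = np.concatenate([src_e, src_i], axis=1)  # (n_t, K_exc+K_inh)
    K = K_exc + K_inh
    tgt = np.repeat(targets, K)
    weight = np.tile(
        np.concatenate([np.full(K_exc, w_exc), np.full(K_inh, w_inh)]), n_t
    )
    styp = np.tile(
        np.concatenate([np.zeros(K_exc, dtype=np.int64),
                        np.ones(K_inh, dtype=np.int64)]), n_t
    )
    return EdgeList(
        source=src.ravel(),
        target=tgt,
        weight=weight,
        delay_steps=np.full(n_t * K, delay_steps, dtype=np.int64),
        syn_type=styp,
    )


@dataclass
class InnermostArray:
    """Synapses of one (thread, synapse type): source-sorted target segments.

    ``target_lidx`` is the target's local neuron index on the hosting
    thread (2-byte-index mode); in pointer mode ``target_rb`` is
    populated with direct references to the targets' ring buffers.
    ``subsq[lcid]`` is True iff the segment continues at ``lcid + 1``.
    """

    source: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    weight: np.ndarray = field(default_factory=lambda: np.empty(0))
    delay_steps: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    target_lidx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    subsq: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    target_rb: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.source)

    def send_index(self, lcid: int) -> tuple[int, float, int, bool]:
        """Synapse ``Send()`` in index mode.

        Returns ``(delay_steps, weight, target_lidx, subsq)``; the
        caller must route the spike through the target *neuron*, which
        selects the ring buffer (one extra indirection).
        """
        return (
            int(self.delay_steps[lcid]),
            float(self.weight[lcid]),
            int(self.target_lidx[lcid]),
            bool(self.subsq[lcid]),
        )

    def send_pointer(self, lcid: int):
        """Synapse ``Send()`` in pointer mode (direct ring-buffer reference).

        Returns ``(ring_buffer, delay_steps, weight, subsq)``; the
        caller adds the weight to the buffer itself, with no
        neuron-level dispatch.
        """
        return (
            self.target_rb[lcid],
            int(self.delay_steps[lcid]),
            float(self.weight[lcid]),
            bool(self.subsq[lcid]),
        )


@dataclass
class SynapseStore:
    """Per-process three-dimensional synapse store ``[thread][syn_type]``."""

    arrays: list  # arrays[thread][syn_type] -> InnermostArray
    target_mode: str = "index"

    @property
    def T(self) -> int:
        return len(self.arrays)

    @property
    def n_syn_types(self) -> int:
        return len(self.arrays[0]) if self.arrays else 0

    def get(self, thread: int, syn_type: int) -> InnermostArray:
        return self.arrays[thread][syn_type]

    @property
    def n_synapses(self) -> int:
        return sum(len(a) for row in self.arrays for a in row)

    def memory_bytes(self) -> int:
        from .sparsity import synapse_memory_bytes
        return synapse_memory_bytes(self.n_synapses, self.target_mode)


@dataclass
class RoutingTable:
    """Sender-side map: source gid -> target-segment addresses.

    Each record ``(process, thread, syn_type, lcid)`` addresses the
    first synapse of one target segment; following ``subsq`` from that
    lcid enumerates the whole segment.  Built at wiring time — with all
    emulated processes in one program the wiring directly yields each
    source's segment list.
    """

    segments: dict  # source_gid -> list[(process, thread, syn_type, lcid)]

    def targets_of(self, source_gid: int) -> list:
        return self.segments.get(source_gid, [])

    @property
    def n_segments(self) -> int:
        return sum(len(v) for v in self.segments.values())


def build_synapse_store(
    edges: EdgeList,
    placement: PlacementMap,
    target_mode: str = "index",
    n_syn_types: int = 2,
) -> tuple[list[SynapseStore], RoutingTable]:
    """Sort an edge list into per-process synapse stores plus routing table.

    Returns one :class:`SynapseStore` per emulated process (indexed by
    rank) and the global sender-side :class:`RoutingTable`.  Within each
    innermost array, synapses are stably sorted by source gid, forming
    ascending source-contiguous target segments with ``subsq`` set on
    all but the last synapse of each segment.  In pointer mode the
    ``target_rb`` references are bound later, when the neurons (and
    hence their ring buffers) exist — see
    :meth:`spikeroute.network.Network`.
    """
    if target_mode not in ("index", "pointer"):
        raise ValueError(f"unknown target_mode {target_mode!r}")
    M, T = placement.M, placement.T
    stores = [
        SynapseStore(
            arrays=[[InnermostArray() for _ in range(n_syn_types)] for _ in range(T)],
            target_mode=target_mode,
        )
        for _ in range(M)
    ]
    segments: dict[int, list[tuple[int, int, int, int]]] = {}
    if len(edges):
        tgt = edges.target
        vp = tgt % placement.n_vp
        proc = vp % M
        thread = vp // M
        # bucket edges by (process, thread, syn_type), then source-sort
        order = np.lexsort((edges.source, edges.syn_type, thread, proc))
        for (p, t, s), idx in _group_runs(proc[order], thread[order],
                                          edges.syn_type[order], order):
            arr = stores[p].arrays[t][s]
            arr.source = edges.source[idx].copy()
            arr.weight = edges.weight[idx].copy()
            arr.delay_steps = edges.delay_steps[idx].copy()
            arr.target_lidx = edges.target[idx] // placement.n_vp
            n = len(idx)
            subsq = np.zeros(n, dtype=bool)
            subsq[:-1] = arr.source[1:] == arr.source[:-1]
            arr.subsq = subsq
            starts = np.flatnonzero(
                np.concatenate(([True], arr.source[1:] != arr.source[:-1]))
            )
            for lcid in starts:
                segments.setdefault(int(arr.source[lcid]), []).append(
                    (int(p), int(t), int(s), int(lcid))
                )
    # deterministic per-source record order: process, thread, syn_type
    for recs in segments.values():
        recs.sort(key=lambda r: (r[0], r[1], r[2]))
    return stores, RoutingTable(segments=segments)


def _group_runs(proc, thread, styp, order):
    """Yield ((p, t, s), original-edge indices) per contiguous sorted group."""
    n = len(order)
    if n == 0:
        return
    key = np.stack([proc, thread, styp], axis=1)
    boundaries = np.flatnonzero(np.any(key[1:] != key[:-1], axis=1)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    for a, b in zip(starts, ends):
        yield (int(proc[a]), int(thread[a]), int(styp[a])), order[a:b]


def edges_to_csv(edges: EdgeList, path, h: float) -> None:
    """Write connectivity as CSV: ``source,target,weight,delay_ms,syn_type``."""
    pd.DataFrame({
        "source": edges.source,
        "target": edges.target,
        "weight": edges.weight,
        "delay_ms": edges.delay_steps * h,
        "syn_type": edges.syn_type,
    }).to_csv(path, index=False)


def edges_from_csv(path, h: float) -> EdgeList:
    """Read connectivity from CSV written by :func:`edges_to_csv`."""
    df = pd.read_csv(path)
    delay_steps = np.rint(df["delay_ms"].to_numpy() / h).astype(np.int64)
    if not np.allclose(delay_steps * h, df["delay_ms"].to_numpy(), atol=1e-9):
        raise ValueError("delays in CSV are not multiples of the grid step")
    return EdgeList(
        source=df["source"].to_numpy(np.int64),
        target=df["target"].to_numpy(np.int64),
        weight=df["weight"].to_numpy(float),
        delay_steps=delay_steps,
        syn_type=df["syn_type"].to_numpy(np.int64),
    )
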