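"""Benchmark-network construction, run orchestration, and fixtures.

The benchmark model is a balanced random network: 80% excitatory and
20% inhibitory leaky integrate-and-fire neurons with alpha-shaped
postsynaptic currents, homogeneous parameters, a fixed number of
excitatory and inhibitory afferents per neuron drawn uniformly from the
respective population, uniform delay (1.5 ms by default, which is also
the communication interval), and inhibitory synapses stronger than
excitatory ones by a factor ``g > 1``.  All quantitative parameters are
user-supplied configuration; the module ships a downscaled desk
profile and accepts a full-scale profile (e.g. in-degree 11 250) from
a config file.  A run consists of an init phase (10 ms of biological
time by default) followed by the timed simulation phase (1 s).
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field, asdict

import numpy as np

from .exchange import ReceiveBuffer, SpikeEntry
from .grid import SimGrid
from .instrumentation import CycleCounters
from .network import Network, write_gdf
from .neuron import LIFParams
from .oracle import naive_delivery_ring_buffers
from .partition import PlacementMap, connect_fixed_indegree

__all__ = [
    "BenchmarkConfig",
    "load_config",
    "build_benchmark_network",
    "run_benchmark",
    "generate_fixture_network",
    "synthetic_traffic",
    "TrafficCase",
]


@dataclass
class BenchmarkConfig:
    """Full run configuration with a downscaled desk-scale default.

    The default in-degree and network size are deliberately small so a
    run finishes in seconds on one core; a full-scale profile is set
    purely through these fields (e.g. ``N=125000 * M``, ``K_exc=9000``,
    ``K_inh=2250``) without touching code.
    """

    # [grid]
    h: float = 0.1
    delay_ms: float = 1.5
    # [populations]
    N: int = 500
    exc_fraction: float = 0.8
    # [connectivity]
    K_exc: int = 40
    K_inh: int = 10
    w_exc: float = 50.0          # pA; dyadic so accumulation order cannot matter
    g: float = 5.0               # inhibitory weight = -g * w_exc
    allow_autapses: bool = True
    # [neuron]
    tau_m: float = 10.0
    C_m: float = 250.0
    E_L: float = 0.0
    V_th: float = 20.0
    V_reset: float = 0.0
    t_ref: float = 2.0
    tau_syn: float = 0.5
    I_e: float = 0.0
    # [drive]
    # external Poisson drive just below rheobase (mean drive current
    # ~0.87 x threshold current): fluctuation-driven, irregular firing
    # at cortex-like single-digit rates
    drive: str = "poisson"       # "poisson" | "dc" | "none"
    poisson_rate_hz: float = 6400.0
    poisson_weight: float = 50.0
    # [run]
    M: int = 2
    T: int = 2
    seed: int = 12345
    init_ms: float = 10.0
    sim_ms: float = 1000.0
    algorithm: str = "ori"       # "ori" | "srr"
    target_mode: str = "index"   # "index" | "pointer"
    ssg: bool = False

    def validate(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 < self.exc_fraction < 1.0:
            raise ValueError("exc_fraction must lie in (0, 1)")
        if self.K_exc < 0 or self.K_inh < 0:
            raise ValueError("in-degrees must be >= 0")
        if self.g <= 0:
            raise ValueError("g must be > 0")
        if self.algorithm == "srr" and self.target_mode != "pointer":
            raise ValueError(
                "algorithm 'srr' requires target_mode 'pointer' (P2RB)"
            )
        steps = self.delay_ms / self.h
        if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
            raise ValueError(
                f"delay {self.delay_ms} ms must be a positive multiple of "
                f"h={self.h} ms"
            )

    @property
    def delay_steps(self) -> int:
        return round(self.delay_ms / self.h)

    @property
    def n_exc(self) -> int:
        return round(self.N * self.exc_fraction)

    @property
    def n_inh(self) -> int:
        return self.N - self.n_exc

    def lif_params(self) -> LIFParams:
        return LIFParams(
            tau_m=self.tau_m, C_m=self.C_m, E_L=self.E_L, V_th=self.V_th,
            V_reset=self.V_reset, t_ref=self.t_ref, tau_syn=self.tau_syn,
            I_e=self.I_e,
        )

    def as_dict(self) -> dict:
        return asdict(self)


_SECTION_FIELDS = {
    "grid": ("h", "delay_ms"),
    "populations": ("N", "exc_fraction"),
    "connectivity": ("K_exc", "K_inh", "w_exc", "g", "allow_autapses"),
    "neuron": ("tau_m", "C_m", "E_L", "V_th", "V_reset", "t_ref",
               "tau_syn", "I_e"),
    "drive": ("drive", "poisson_rate_hz", "poisson_weight"),
    "run": ("M", "T", "seed", "init_ms", "sim_ms", "algorithm",
            "target_mode", "ssg"),
}


def load_config(path) -> BenchmarkConfig:
    """Load a TOML (sections ``[grid] [populations] [connectivity]
    [neuron] [drive] [run]``) or JSON run configuration."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            raw = json.load(fh)
    else:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    kwargs = {}
    for section, fields in _SECTION_FIELDS.items():
        sub = raw.get(section, {})
        for key, value in sub.items():
            if key not in fields:
                raise ValueError(f"unknown key {key!r} in section [{section}]")
            kwargs[key] = value
    cfg = BenchmarkConfig(**kwargs)
    cfg.validate()
    return cfg


def build_benchmark_network(config: BenchmarkConfig) -> Network:
    """Wire the balanced random network described by ``config``."""
    config.validate()
    n_exc, n_inh = config.n_exc, config.n_inh
    if n_exc < 1 and config.K_exc > 0:
        raise ValueError("excitatory population is empty but K_exc > 0")
    if n_inh < 1 and config.K_inh > 0:
        raise ValueError("inhibitory population is empty but K_inh > 0")
    exc_gids = np.arange(0, n_exc)
    inh_gids = np.arange(n_exc, config.N)
    placement = PlacementMap(M=config.M, T=config.T, N=config.N)
    grid = SimGrid(
        h=config.h,
        min_delay_steps=config.delay_steps,
        max_delay_steps=config.delay_steps,
    )
    edges = connect_fixed_indegree(
        exc_gids, inh_gids, np.arange(config.N),
        config.K_exc, config.K_inh,
        w_exc=config.w_exc, w_inh=-config.g * config.w_exc,
        delay_steps=config.delay_steps,
        seed=config.seed,
        allow_autapses=config.allow_autapses,
    )
    params = config.lif_params()
    poisson_rate = config.poisson_rate_hz if config.drive == "poisson" else 0.0
    return Network(
        edges, placement, params, grid,
        target_mode=config.target_mode,
        ssg=config.ssg,
        poisson_rate_hz=poisson_rate,
        poisson_weight=config.poisson_weight,
        drive_seed=config.seed + 1,
    )


def run_benchmark(config: BenchmarkConfig, gdf_path=None, counters_path=None) -> dict:
    """Init phase, then timed simulation phase; returns the run report.

    The report contains the mean and SD of the per-neuron firing rate
    over the simulation phase, per-phase cumulative wall times, the
    cumulative operation counters, and the seeds — everything needed to
    reproduce and recount the run.  With ``gdf_path`` set, the
    simulation-phase spikes are written as GDF text (identical seed
    implies a byte-identical file).
    """
    net = build_benchmark_network(config)
    interval = net.grid.communication_interval_ms
    # whole communication cycles covering each requested phase duration
    n_init = math.ceil(round(config.init_ms / interval, 9))
    n_sim = math.ceil(round(config.sim_ms / interval, 9))
    for _ in range(n_init):
        net.run_cycle(algorithm=config.algorithm)
    init_cycles = net.cycle_index
    spikes = []
    for _ in range(n_sim):
        spikes.extend(net.run_cycle(algorithm=config.algorithm))
    sim_ms_actual = n_sim * interval

    counts = np.zeros(config.N, dtype=np.int64)
    for gid, _ in spikes:
        counts[gid] += 1
    duration_s = sim_ms_actual / 1000.0
    rates = counts / duration_s
    sim_records = net.instrumentation.records[init_cycles:]
    phase_totals: dict[str, float] = {}
    counter_totals = {
        k: 0 for k in ("entries_read", "entries_skipped", "segments_walked",
                       "synapses_activated", "rb_writes")
    }
    E_total = 0
    for rec in sim_records:
        E_total += rec["E"]
        for k in counter_totals:
            counter_totals[k] += rec[k]
        for k, v in rec.items():
            if k.startswith("t_") and k.endswith("_s"):
                phase_totals[k[2:-2]] = phase_totals.get(k[2:-2], 0.0) + v
    if gdf_path is not None:
        write_gdf(spikes, gdf_path, config.h)
    if counters_path is not None:
        net.instrumentation.to_csv(counters_path)
    report = {
        "config": config.as_dict(),
        "seed": config.seed,
        "algorithm": config.algorithm,
        "n_spikes": int(counts.sum()),
        "rate_mean_hz": float(rates.mean()),
        "rate_sd_hz": float(rates.std(ddof=1)) if config.N > 1 else 0.0,
        "E_total": int(E_total),
        "counters": counter_totals,
        "phase_times_s": phase_totals,
        "n_cycles_sim": len(sim_records),
        "sim_ms_actual": sim_ms_actual,
    }
    return report


# ---------------------------------------------------------------------------
# fixtures


def generate_fixture_network(kind: str, seed: int = 0):
    """Deterministic tiny networks with hand-traceable delivery.

    ``two-neuron-chain``
        Two neurons, one synapse with a 15-step delay; a forced spike at
        step ``s`` must land in the target's ring-buffer slot for step
        ``s + 15``.
    ``three-thread-toy``
        One process, three threads, one neuron each, wired so a single
        source fans out to segments on two threads.
    ``random-small``
        Seeded random network (quiescent neurons, forced emissions);
        returned together with the naive event-list oracle's expected
        ring-buffer image after one cycle of random forced emissions.

    Returns ``(network, aux)`` where ``aux`` is kind-specific
    (``None``, the edge list, or the oracle prediction with emissions).
    """
    quiet = LIFParams(V_th=1e9)  # threshold far away: delivery-only dynamics
    if kind == "two-neuron-chain":
        from .partition import EdgeList
        placement = PlacementMap(M=1, T=1, N=2)
        grid = SimGrid(h=0.1, min_delay_steps=15, max_delay_steps=15)
        edges = EdgeList(
            source=np.array([0]), target=np.array([1]),
            weight=np.array([1.0]), delay_steps=np.array([15]),
            syn_type=np.array([0]),
        )
        return Network(edges, placement, quiet, grid), None

    if kind == "three-thread-toy":
        from .partition import EdgeList
        placement = PlacementMap(M=1, T=3, N=3)  # gid g on thread g
        grid = SimGrid(h=0.1, min_delay_steps=15, max_delay_steps=15)
        # source 0 targets neurons on threads 1 and 2; source 1 targets thread 0
        edges = EdgeList(
            source=np.array([0, 0, 1]),
            target=np.array([1, 2, 0]),
            weight=np.array([1.0, 0.5, 0.25]),
            delay_steps=np.array([15, 15, 15]),
            syn_type=np.array([0, 0, 0]),
        )
        return Network(edges, placement, quiet, grid), edges

    if kind == "random-small":
        rng = np.random.default_rng(seed)
        N, K = 24, 4
        M, T = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        placement = PlacementMap(M=M, T=T, N=N)
        grid = SimGrid(h=0.1, min_delay_steps=5, max_delay_steps=8)
        from .partition import EdgeList
        n_edges = N * K
        # dyadic weights so any accumulation order is exact
        weights = rng.choice([0.25, 0.5, 1.0, -0.5, -1.0], size=n_edges)
        edges = EdgeList(
            source=rng.integers(0, N, n_edges),
            target=np.repeat(np.arange(N), K),
            weight=weights,
            delay_steps=rng.integers(5, 9, n_edges),
            syn_type=(weights < 0).astype(np.int64),
        )
        net = Network(edges, placement, quiet, grid)
        n_spk = int(rng.integers(1, 8))
        emissions = sorted(
            (int(g), int(s))
            for g, s in zip(rng.integers(0, N, n_spk), rng.integers(1, 6, n_spk))
        )
        expected = naive_delivery_ring_buffers(
            edges, placement, grid, [emissions]
        )
        return net, {"emissions": emissions, "expected_ring_buffers": expected}

    raise ValueError(f"unknown fixture kind {kind!r}")


@dataclass
class TrafficCase:
    """A synthetic-traffic microbenchmark case (no neuron dynamics).

    Holds one receive buffer of ``E`` entries over two consistently
    wired networks — one in index mode for the original kernel, one in
    pointer mode for the register kernel — so both kernels are runnable
    on identical traffic.
    """

    net_index: Network
    net_pointer: Network
    buffer: ReceiveBuffer
    T: int
    E: int

    def run_ori(self) -> CycleCounters:
        counters = CycleCounters()
        net = self.net_index
        T = net.placement.T
        neurons = [net.domains[(0, t)].neurons for t in range(T)]
        from .deliver_ori import deliver_ori
        for t in range(T):
            deliver_ori(self.buffer, net.stores[0], neurons, t, 0, counters)
        counters.validate()
        return counters

    def run_srr(self) -> CycleCounters:
        counters = CycleCounters()
        net = self.net_pointer
        from .deliver_srr import deliver_from_register, sort_into_register
        reg = sort_into_register(self.buffer, self.T, counters,
                                 net.n_syn_types)
        for t in range(self.T):
            deliver_from_register(reg, net.stores[0], t, 0, counters)
        counters.validate()
        return counters


def synthetic_traffic(
    E: int,
    T: int,
    tid_distribution="uniform",
    seed: int = 0,
    neurons_per_thread: int = 4,
    K: int = 3,
) -> TrafficCase:
    """Generate a receive buffer of ``E`` entries over a stub network.

    A small single-process network with ``T`` threads is wired randomly;
    entries are drawn from its valid segment starts with hosting threads
    following ``tid_distribution`` (``"uniform"`` or a length-``T``
    probability vector, e.g. all mass on thread 0 for a skewed mix) and
    lags uniform over the communication interval.
    """
    if E < 0:
        raise ValueError("E must be >= 0")
    rng = np.random.default_rng(seed)
    N = T * neurons_per_thread
    placement = PlacementMap(M=1, T=T, N=N)
    grid = SimGrid(h=0.1, min_delay_steps=5, max_delay_steps=5)
    from .partition import EdgeList
    n_edges = N * K
    weights = rng.choice([0.5, 1.0, -1.0], size=n_edges)
    edges = EdgeList(
        source=rng.integers(0, N, n_edges),
        target=np.repeat(np.arange(N), K),
        weight=weights,
        delay_steps=np.full(n_edges, 5, dtype=np.int64),
        syn_type=(weights < 0).astype(np.int64),
    )
    quiet = LIFParams(V_th=1e9)
    net_index = Network(edges, placement, quiet, grid, target_mode="index")
    net_pointer = Network(edges, placement, quiet, grid, target_mode="pointer")

    # segment starts per hosting thread, identical in both stores
    starts: list[list[tuple[int, int, int]]] = [[] for _ in range(T)]
    store = net_index.stores[0]
    for t in range(T):
        for s in range(store.n_syn_types):
            arr = store.get(t, s)
            for lcid in range(len(arr)):
                if lcid == 0 or not arr.subsq[lcid - 1]:
                    starts[t].append((t, s, lcid))
    if isinstance(tid_distribution, str):
        if tid_distribution != "uniform":
            raise ValueError(f"unknown tid distribution {tid_distribution!r}")
        probs = np.full(T, 1.0 / T)
    else:
        probs = np.asarray(tid_distribution, float)
        if probs.shape != (T,) or not math.isclose(probs.sum(), 1.0):
            raise ValueError("tid distribution must be T probabilities summing to 1")
    entries = []
    for _ in range(E):
        t = int(rng.choice(T, p=probs))
        while not starts[t]:  # hosting thread without segments: redraw
            t = int(rng.choice(T, p=probs))
        tid, syn_type, lcid = starts[t][int(rng.integers(len(starts[t])))]
        entries.append(SpikeEntry(tid=tid, syn_type=syn_type, lcid=lcid,
                                  lag=int(rng.integers(grid.min_delay_steps))))
    return TrafficCase(
        net_index=net_index, net_pointer=net_pointer,
        buffer=ReceiveBuffer(entries=entries), T=T, E=E,
    )
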