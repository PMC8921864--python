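"""Sparsity analytics for distributed spiking-network connectivity.

A network of ``N`` neurons is distributed round-robin over ``M``
processes with ``T`` threads each, and every neuron draws ``K`` incoming
synapses with sources chosen uniformly (with replacement, probability
``1/N`` per source).  Under weak scaling the number of thread-local
synapses

    S = N * K / (M * T)

is held fixed while ``N`` grows with ``M * T``.  The expected number of
*unique* source neurons feeding a thread is then

    N_u = (1 - (1 - 1/N)**S) * N

which for large ``N`` approaches the limit form

    N_u_tilde = (1 - exp(-S / N)) * N.

As the network is distributed more widely, ``N_u`` rises toward ``S``:
in the limit every thread-local synapse has its own unique source, so
spike delivery degenerates into single-synapse target segments at random
memory locations.  The characteristic network size at which a fraction
``zeta`` of ``S`` is unique follows from a quadratic expansion of the
limit form,

    N_zeta = S / (2 * (1 - zeta)),

so at ``N = S`` already half of the sources are unique.  The mean target
segment length ``S_u = S / N_u`` measures the remaining per-source
locality.

All quantities here are expectations over the random wiring; the
:mod:`~spikeroute.partition` module realises exact per-thread counts on
concrete networks, and :func:`monte_carlo_unique_sources` serves as an
independent sampling check of the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ScalingConfig",
    "SparsityPrediction",
    "thread_local_synapses",
    "expected_unique_sources",
    "unique_sources_exact",
    "unique_sources_limit",
    "characteristic_size",
    "characteristic_size_numeric",
    "monte_carlo_unique_sources",
    "synapse_memory_bytes",
    "predict",
    "weak_scaling_curve",
]


@dataclass(frozen=True)
class ScalingConfig:
    """Distribution parameters of a weak- or strong-scaling scenario.

    Attributes
    ----------
    N : int
        Total number of neurons in the network (>= 1).
    K : int
        In-degree: number of incoming synapses per neuron (>= 0).
    M : int
        Number of (emulated) processes (>= 1).
    T : int
        Threads per process (>= 1).
    """

    N: int
    K: int
    M: int
    T: int

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.K < 0:
            raise ValueError(f"K must be >= 0, got {self.K}")
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")


@dataclass(frozen=True)
class SparsityPrediction:
    """Derived sparsity quantities for one :class:`ScalingConfig`.

    ``S`` is the thread-local synapse count, ``p_empty`` the probability
    that a given neuron sources none of the thread-local synapses, ``p``
    its complement, ``N_u`` the expected number of unique sources,
    ``N_u_limit`` the exponential-limit approximation, ``S_u`` the mean
    number of thread-local synapses per unique source, and ``N_zeta``
    the characteristic network size at which half of the sources are
    unique.
    """

    S: float
    p_empty: float
    p: float
    N_u: float
    N_u_limit: float
    S_u: float
    N_zeta: float


def thread_local_synapses(cfg: ScalingConfig) -> float:
    """Number of synapses hosted by one thread, ``S = N K / (M T)``.

    Returned as an exact real number; it need not be an integer for
    arbitrary parameter combinations (it is an expectation-level
    workload measure, not a realised count).
    """
    return cfg.N * cfg.K / (cfg.M * cfg.T)


def unique_sources_exact(S: float, N: float) -> float:
    """Expected unique sources of ``S`` uniform draws from ``N`` neurons.

    Evaluates ``(1 - (1 - 1/N)**S) * N``.  ``S`` may be real-valued.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if S < 0:
        raise ValueError("S must be >= 0")
    if N == 1:
        return 0.0 if S == 0 else 1.0
    # exp/log1p form keeps precision for large S, N
    p_empty = np.exp(S * np.log1p(-1.0 / N))
    return float((1.0 - p_empty) * N)


def expected_unique_sources(cfg: ScalingConfig) -> float:
    """Expected number of unique source neurons of the thread-local synapses."""
    return unique_sources_exact(thread_local_synapses(cfg), cfg.N)


def source_empty_probability(cfg: ScalingConfig) -> float:
    """Probability ``p_empty = (1 - 1/N)**S`` that a given neuron sources
    none of the thread-local synapses."""
    if cfg.N == 1:
        return 1.0 if thread_local_synapses(cfg) == 0 else 0.0
    return float(np.exp(thread_local_synapses(cfg) * np.log1p(-1.0 / cfg.N)))


def unique_sources_limit(S: float, N: float) -> float:
    """Large-``N`` limit form ``(1 - exp(-S/N)) * N`` of the unique-source count."""
    if N <= 0:
        raise ValueError("N must be > 0")
    if S < 0:
        raise ValueError("S must be >= 0")
    # expm1 avoids cancellation when S/N is tiny
    return float(-np.expm1(-S / N) * N)


def characteristic_size(S: float, zeta: float) -> float:
    """Network size at which a fraction ``zeta`` of ``S`` sources is unique.

    Quadratic-approximation result ``N_zeta = S / (2 (1 - zeta))``; at
    ``zeta = 1/2`` this gives ``N_zeta = S`` exactly.
    """
    if S <= 0:
        raise ValueError("S must be > 0")
    if not 0.0 <= zeta < 1.0:
        raise ValueError("zeta must lie in [0, 1); the fraction is never "
                         "reached for zeta >= 1 under the approximation")
    return S / (2.0 * (1.0 - zeta))


def characteristic_size_numeric(S: float, zeta: float) -> float:
    """Numerically invert the limit form ``N_u_tilde(N) = zeta * S``.

    Solves ``(1 - exp(-S/N)) * N = zeta * S`` for ``N``, providing a
    check of the quadratic approximation in :func:`characteristic_size`
    (the two agree closely only for ``zeta`` near 1/2 and below).
    """
    if S <= 0:
        raise ValueError("S must be > 0")
    if not 0.0 < zeta < 1.0:
        raise ValueError("zeta must lie in (0, 1)")

    def f(N: float) -> float:
        return unique_sources_limit(S, N) - zeta * S

    # the limit form rises monotonically from 0 toward S as N grows,
    # so a wide bracket always contains the unique root
    lo, hi = 1e-12 * S + 1e-30, 1e12 * S
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def monte_carlo_unique_sources(
    cfg: ScalingConfig, reps: int, seed: int
) -> tuple[float, float]:
    """Sampling estimate of the unique-source count.

    Draws ``S = round(N K / (M T))`` sources uniformly with replacement
    (self-connections included, matching the ``1/N`` probability model),
    counts distinct values, and averages over ``reps`` repetitions.

    Returns
    -------
    (mean, stderr)
        Sample mean of the distinct-source count and its standard error.
        Identical ``seed`` yields identical output.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    S = int(round(thread_local_synapses(cfg)))
    rng = np.random.default_rng(seed)
    counts = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        if S == 0:
            counts[r] = 0
        else:
            draws = rng.integers(0, cfg.N, size=S)
            counts[r] = np.unique(draws).size
    mean = float(counts.mean())
    stderr = float(counts.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return mean, stderr


def synapse_memory_bytes(n_synapses: int, target_mode: str) -> int:
    """Per-synapse target-identifier memory overhead.

    ``index`` mode stores a 2-byte local neuron index per synapse,
    ``pointer`` mode an 8-byte direct reference to the target's ring
    buffer.  Only this overhead is modelled; the rest of the synapse
    object is identical between modes.
    """
    if n_synapses < 0:
        raise ValueError("n_synapses must be >= 0")
    per = {"index": 2, "pointer": 8}
    if target_mode not in per:
        raise ValueError(f"unknown target_mode {target_mode!r}; "
                         "expected 'index' or 'pointer'")
    return per[target_mode] * n_synapses


def predict(cfg: ScalingConfig) -> SparsityPrediction:
    """Evaluate all sparsity quantities for one configuration."""
    S = thread_local_synapses(cfg)
    p_empty = source_empty_probability(cfg)
    N_u = unique_sources_exact(S, cfg.N)
    N_u_lim = unique_sources_limit(S, cfg.N)
    S_u = S / N_u if N_u > 0 else float("nan")
    N_zeta = characteristic_size(S, 0.5) if S > 0 else float("nan")
    return SparsityPrediction(
        S=S, p_empty=p_empty, p=1.0 - p_empty,
        N_u=N_u, N_u_limit=N_u_lim, S_u=S_u, N_zeta=N_zeta,
    )


def weak_scaling_curve(
    neurons_per_process: int, K: int, T: int, M_values
) -> pd.DataFrame:
    """Sparsity curve for a weak-scaling sweep over process counts.

    Each process contributes ``neurons_per_process`` neurons, so
    ``N = M * neurons_per_process`` while ``S`` stays fixed.  Returns a
    DataFrame with columns ``M, N, S, N_u, N_u_limit, S_u`` suitable for
    CSV export and log-log plotting.
    """
    rows = []
    for M in M_values:
        cfg = ScalingConfig(N=int(M) * neurons_per_process, K=K, M=int(M), T=T)
        pred = predict(cfg)
        rows.append({
            "M": int(M), "N": cfg.N, "S": pred.S,
            "N_u": pred.N_u, "N_u_limit": pred.N_u_limit, "S_u": pred.S_u,
        })
    return pd.DataFrame(rows)
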