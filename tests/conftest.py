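"""Shared fixtures: small random networks generated programmatically."""

import numpy as np
import pytest

from spikeroute.grid import SimGrid
from spikeroute.network import Network
from spikeroute.neuron import LIFParams
from spikeroute.partition import EdgeList, PlacementMap


def make_random_edges(rng, N, K, min_delay=5, max_delay=8):
    """Random fixed-in-degree wiring with dyadic weights (exact sums)."""
    n_edges = N * K
    weights = rng.choice([0.25, 0.5, 1.0, 2.0, -0.5, -1.0], size=n_edges)
    return EdgeList(
        source=rng.integers(0, N, n_edges),
        target=np.repeat(np.arange(N), K),
        weight=weights,
        delay_steps=rng.integers(min_delay, max_delay + 1, n_edges),
        syn_type=(weights < 0).astype(np.int64),
    )


def make_small_network(
    seed,
    target_mode="index",
    N=24,
    K=4,
    M=2,
    T=3,
    spiking=False,
):
    """Small network for delivery tests.

    ``spiking=False`` uses an unreachable threshold (pure delivery
    machinery); ``spiking=True`` adds Poisson drive so neurons actually
    fire and the full cycle is exercised.
    """
    rng = np.random.default_rng(seed)
    grid = SimGrid(h=0.1, min_delay_steps=5, max_delay_steps=8)
    edges = make_random_edges(rng, N, K)
    placement = PlacementMap(M=M, T=T, N=N)
    if spiking:
        params = LIFParams(V_th=20.0, I_e=0.0)
        net = Network(
            edges, placement, params, grid, target_mode=target_mode,
            poisson_rate_hz=4000.0, poisson_weight=64.0, drive_seed=seed,
        )
    else:
        params = LIFParams(V_th=1e9)
        net = Network(edges, placement, params, grid, target_mode=target_mode)
    return net, edges


@pytest.fixture
def rng():
    return np.random.default_rng(424242)
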