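"""Leaky integrate-and-fire neuron with alpha-shaped postsynaptic currents.

Subthreshold dynamics are linear,

    tau_m dV/dt = -(V - E_L) + R_m (I_syn(t) + I_e),      R_m = tau_m / C_m,

with the synaptic current of each input channel (excitatory and
inhibitory) generated by an alpha kernel: an incoming spike of weight
``w`` contributes a current ``w * e * (t/tau_syn) * exp(-t/tau_syn)``
that peaks with amplitude ``w`` at ``t = tau_syn`` after arrival.  Each
channel is a pair of first-order states ``(y1, y2)`` with

    dy1/dt = -y1/tau_syn,   dy2/dt = y1 - y2/tau_syn,   I_chan = y2,

and a spike increments ``y1`` by ``w * e / tau_syn``.

The update over one grid step ``h`` is *exact integration*: the linear
system is advanced by its matrix exponential, computed once at
construction with :func:`scipy.linalg.expm`.  This handles the
degenerate case ``tau_m == tau_syn`` (a defective system matrix) without
special-casing.  Threshold crossings are detected after the full step —
no interpolation — and the spike is bound to the end-of-step grid point;
the neuron is then clamped to ``V_reset`` for the refractory period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = [
    "LIFParams",
    "NeuronState",
    "Propagators",
    "make_propagators",
    "PopulationState",
    "update_population",
    "neuron_update_interval",
]

# state vector layout: (y1_ex, y2_ex, y1_in, y2_in, V - E_L)
_Y1E, _Y2E, _Y1I, _Y2I, _V = range(5)


@dataclass(frozen=True)
class LIFParams:
    """Membrane and synapse parameters (times in ms, capacitance in pF,
    potentials in mV, currents in pA).

    The shipped defaults form a user-supplied benchmark profile for a
    balanced random network; they are configuration, not ground truth —
    any homogeneous parameter set can be passed in.
    """

    tau_m: float = 10.0
    C_m: float = 250.0
    E_L: float = 0.0
    V_th: float = 20.0
    V_reset: float = 0.0
    t_ref: float = 2.0
    tau_syn: float = 0.5
    I_e: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.tau_syn <= 0:
            raise ValueError("time constants must be > 0")
        if self.C_m <= 0:
            raise ValueError("C_m must be > 0")
        if self.t_ref < 0:
            raise ValueError("t_ref must be >= 0")
        if not self.V_th > self.V_reset:
            raise ValueError("V_th must exceed V_reset")


@dataclass
class NeuronState:
    """Dynamical state of one neuron."""

    V_m: float = 0.0
    y1_ex: float = 0.0
    y2_ex: float = 0.0
    y1_in: float = 0.0
    y2_in: float = 0.0
    ref_count: int = 0


@dataclass(frozen=True)
class Propagators:
    """Exact-integration coefficients for one step of size ``h``.

    ``P`` advances ``(y1_ex, y2_ex, y1_in, y2_in, V - E_L)``; ``q_ie``
    is the constant-current input vector (multiplied by ``I_e`` each
    step); ``spike_input_factor = e / tau_syn`` converts an accumulated
    ring-buffer weight into a ``y1`` increment so that the resulting
    current peaks at the weight.
    """

    P: np.ndarray
    q_ie: np.ndarray
    spike_input_factor: float
    h: float

    @property
    def membrane_decay(self) -> float:
        """exp(-h / tau_m), the pure-leak coefficient."""
        return float(self.P[_V, _V])


def make_propagators(params: LIFParams, h: float) -> Propagators:
    """Build the exact one-step propagator for the subthreshold dynamics.

    ``tau_m = inf`` is accepted (no leak; membrane decay coefficient 1).
    """
    if h <= 0:
        raise ValueError("h must be > 0")
    leak = 0.0 if math.isinf(params.tau_m) else 1.0 / params.tau_m
    ks = 1.0 / params.tau_syn
    inv_C = 1.0 / params.C_m
    # augmented system: last coordinate is the constant 1 driving I_e/C_m
    A = np.zeros((6, 6))
    A[_Y1E, _Y1E] = -ks
    A[_Y2E, _Y1E] = 1.0
    A[_Y2E, _Y2E] = -ks
    A[_Y1I, _Y1I] = -ks
    A[_Y2I, _Y1I] = 1.0
    A[_Y2I, _Y2I] = -ks
    A[_V, _Y2E] = inv_C
    A[_V, _Y2I] = inv_C
    A[_V, _V] = -leak
    A[_V, 5] = inv_C  # I_e enters like a constant current of 1 pA, scaled later
    E = expm(A * h)
    P = E[:5, :5]
    q_ie = E[:5, 5]
    return Propagators(P=P, q_ie=q_ie, spike_input_factor=math.e / params.tau_syn, h=h)


@dataclass
class PopulationState:
    """Struct-of-arrays state for ``n`` neurons updated together.

    ``X`` has shape ``(n, 5)`` holding ``(y1_ex, y2_ex, y1_in, y2_in,
    V - E_L)``; ``ref`` the remaining refractory steps per neuron.
    """

    X: np.ndarray
    ref: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "PopulationState":
        return cls(X=np.zeros((n, 5)), ref=np.zeros(n, dtype=np.int64))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def v_m(self, params: LIFParams) -> np.ndarray:
        return self.X[:, _V] + params.E_L


def update_population(
    pop: PopulationState,
    params: LIFParams,
    prop: Propagators,
    rb_ex: np.ndarray,
    rb_in: np.ndarray,
    start_step: int,
    n_steps: int,
    ref_steps: int,
) -> list[tuple[int, int]]:
    """Advance ``n`` neurons by ``n_steps`` grid steps, vectorised.

    ``rb_ex`` / ``rb_in`` are the per-thread ring-buffer matrices of
    shape ``(n, L)``; the slot for each step is read and cleared exactly
    once.  Returns the emitted spikes as ``(local_index, spike_step)``
    pairs with the spike bound to the end-of-step grid point, ordered by
    step then local index.
    """
    X, ref = pop.X, pop.ref
    if not np.all(np.isfinite(X)):
        raise FloatingPointError("non-finite neuron state before update")
    L = rb_ex.shape[1]
    P_T = prop.P.T
    q = prop.q_ie * params.I_e
    v_th_rel = params.V_th - params.E_L
    v_reset_rel = params.V_reset - params.E_L
    fac = prop.spike_input_factor
    spikes: list[tuple[int, int]] = []
    for k in range(n_steps):
        step = start_step + k
        slot = step % L
        in_ex = rb_ex[:, slot].copy()
        rb_ex[:, slot] = 0.0
        in_in = rb_in[:, slot].copy()
        rb_in[:, slot] = 0.0

        refractory = ref > 0
        X[:] = X @ P_T
        X[:, _V] += q[_V]
        # clamp during refractoriness; synaptic states keep evolving
        X[refractory, _V] = v_reset_rel
        ref[refractory] -= 1

        # input read this step drives the current from the next step on
        X[:, _Y1E] += fac * in_ex
        X[:, _Y1I] += fac * in_in

        crossed = np.flatnonzero(~refractory & (X[:, _V] >= v_th_rel))
        if crossed.size:
            X[crossed, _V] = v_reset_rel
            ref[crossed] = ref_steps
            spike_step = step + 1
            spikes.extend((int(i), spike_step) for i in crossed)
    if not np.all(np.isfinite(X)):
        raise FloatingPointError("non-finite neuron state after update")
    return spikes


def refractory_steps(params: LIFParams, h: float) -> int:
    steps = round(params.t_ref / h)
    if abs(steps * h - params.t_ref) > 1e-9:
        raise ValueError(f"t_ref={params.t_ref} ms is not a multiple of h={h} ms")
    return steps


def neuron_update_interval(
    state: NeuronState,
    params: LIFParams,
    rb_ex,
    rb_in,
    grid,
    n_steps: int,
) -> tuple[NeuronState, list[int]]:
    """Advance a single neuron over one communication interval.

    Single-neuron convenience wrapper around :func:`update_population`;
    ``rb_ex`` / ``rb_in`` are :class:`~spikeroute.ringbuffer.SpikeRingBuffer`
    instances.  Returns the new state and the spike grid steps.
    """
    pop = PopulationState.zeros(1)
    pop.X[0] = [state.y1_ex, state.y2_ex, state.y1_in, state.y2_in,
                state.V_m - params.E_L]
    pop.ref[0] = state.ref_count
    prop = make_propagators(params, grid.h)
    spikes = update_population(
        pop, params, prop,
        rb_ex.slots[np.newaxis, :], rb_in.slots[np.newaxis, :],
        grid.current_step, n_steps, refractory_steps(params, grid.h),
    )
    new = NeuronState(
        V_m=float(pop.X[0, _V] + params.E_L),
        y1_ex=float(pop.X[0, _Y1E]), y2_ex=float(pop.X[0, _Y2E]),
        y1_in=float(pop.X[0, _Y1I]), y2_in=float(pop.X[0, _Y2I]),
        ref_count=int(pop.ref[0]),
    )
    return new, [s for _, s in spikes]
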