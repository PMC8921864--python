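# Methods

## What the package models

`spikeroute` is a desk-scale emulation of the intra-node spike-routing
machinery of a distributed, time-driven spiking-network simulator. The
simulation loop is the classic three-phase min-delay cycle: because every
synaptic delay is at least `min_delay`, spikes generated during one interval
of that length cannot affect any neuron before the next interval, so
(1) neurons are propagated for `min_delay` worth of grid steps, (2) the
accumulated spikes are exchanged between processes in one collective step,
and (3) a delivery kernel routes each spike into the ring buffers of its
target neurons, where the per-synapse residual delay is realised as the
write offset. `M` processes and `T` threads per process are *emulated*:
all thread roles run sequentially inside one program with an explicit
barrier between phases. This is a deliberate design choice — the claims
under study are about algorithmic structure (how many times an entry is
touched, who may write where), not about a threading runtime — and it makes
every run exactly reproducible and schedule-independent, which the tests
assert rather than assume.

Two delivery kernels are implemented over the same 3-D synapse store
(`[thread][synapse_type][lcid]`, innermost arrays grouped into
source-contiguous target segments in ascending source order, continuation
marked per synapse by the `subsq` flag):

- **Original (`ori`)** — every thread scans the entire process-local receive
  buffer and skips entries hosted by other threads; a hit walks the segment
  through synapse → neuron → ring buffer (the neuron chooses between its
  excitatory and inhibitory buffer). Total entry reads per cycle: `T · E`.
- **Register-sorting (`srr`)** — each thread reads the buffer slice
  `[⌊wE/T⌋, ⌊(w+1)E/T⌋)` once and buckets entries into its private domain of
  the spike-receive register by (hosting thread, synapse type); after the
  single barrier, each thread drains exactly the cells addressed to it, and
  each synapse's `Send()` returns a direct ring-buffer reference bound at
  wiring time (the pointer-to-ring-buffer design), so delivery calls
  `AddValue()` with no neuron-level dispatch. Total entry reads: `2E`,
  independent of `T`.

Cost is measured with hardware-independent operation counters
(`entries_read`, `entries_skipped`, `segments_walked`, `synapses_activated`,
`rb_writes`); wall-clock phase times are recorded for information only and
never asserted, since they are machine-bound.

## Sparsity analytics

With `N` neurons placed round-robin over `M·T` virtual processes and each
neuron drawing `K` sources uniformly with replacement (probability `1/N`
each, autapses and multapses included so the probability model is exact),
a thread hosts `S = NK/(MT)` synapses, and the expected number of distinct
sources among them is `N_u = (1 − (1 − 1/N)^S)·N`, with the large-`N` limit
`Ñ_u = (1 − e^{−S/N})·N`. `S` is kept real-valued (it is an expectation);
the Monte-Carlo oracle rounds it to the nearest integer, and the wiring
module realises exact per-thread counts on concrete networks. The
characteristic size at which a fraction ζ of sources is unique follows from
the quadratic expansion of the limit form, `N_ζ = S/(2(1−ζ))`, exact in the
sense that ζ = 1/2 at `N_ζ = S`. That expansion is coarse away from its
anchor: solving `(1 − e^{−x})/x = ζ` numerically at ζ = 1/2 gives
`x ≈ 1.594`, i.e. `N ≈ 0.63·S`. Both forms are exposed
(`characteristic_size`, `characteristic_size_numeric`) so users can compare;
tests check that the numeric root actually solves the limit form rather
than pretending the two agree.

## Neuron model and numerics

Single-compartment leaky integrate-and-fire with alpha-shaped postsynaptic
currents, two input channels (excitatory/inhibitory; negative weights route
to the inhibitory channel, a convention the pointer binding freezes at
construction). An input of weight `w` produces a current
`w·e·(t/τ_syn)·e^{−t/τ_syn}` peaking at exactly `w` at `t = τ_syn` — the
peak-amplitude normalisation is our chosen convention, stated because other
codes normalise charge instead. The subthreshold system is linear, so the
one-step update uses the exact matrix exponential of the (augmented) system
computed once with `scipy.linalg.expm`; this also covers the defective case
`τ_m = τ_syn` without a special-cased limit formula. Threshold crossings
are detected after the full step with no interpolation; the spike is bound
to the end-of-step grid point, the membrane is clamped to `V_reset` for
`round(t_ref/h)` steps. An independent high-accuracy `solve_ivp` reference
confirms subthreshold trajectories to < 1e-6 mV, and the constant-current
inter-spike interval matches
`t_ref + τ_m·ln((V_∞ − V_reset)/(V_∞ − V_th))` rounded up to the grid.

Ring buffers have `L = max_delay + min_delay` slots: with delivery once per
min-delay interval, the farthest write (`lag + delay` ahead) is always
strictly in the future of the reader, so accumulate-never-overwrite holds by
construction; a weight-conservation property test exercises random schedules.
Each buffer object wraps a row view of a per-thread matrix, so a synapse can
hold a direct per-neuron reference while the population update reads whole
columns vectorised.

Spike timing convention: a spike detected during the step `t → t+1` is
recorded at grid point `t+1`; its entry carries
`lag = spike_step − interval_start − 1 ∈ [0, min_delay)`, and delivery
reconstructs the emission step as `interval_start + 1 + lag`, preserving
`arrival = emission + delay` exactly (the contract the event-list oracle
checks end to end).

## Benchmark network and synthetic data

The benchmark generator wires the standard balanced random network: 80 %
excitatory / 20 % inhibitory, homogeneous parameters, fixed in-degree per
neuron drawn with replacement from each population, uniform 1.5 ms delay
(which then equals the communication interval), inhibitory weight
`−g·w_exc` with `g > 1`. All quantitative parameters are configuration
(TOML/JSON, every value echoed into the run log); the full-scale profile
(125 000 neurons per process, in-degree 11 250) is expressible but the
shipped default is a desk profile — `N = 500`, `K = 50`, `M = T = 2`,
dyadic weights — chosen so a 1 s run finishes in about a second on one
core. External drive is an independent Poisson source per neuron, seeded
per virtual process and injected into the excitatory ring-buffer channel;
the default rate (6 400 Hz at weight 50 pA) places the mean drive at
roughly 0.87× rheobase, the fluctuation-driven regime in which the network
fires irregularly at cortex-like single-digit rates. A run is an init phase
(10 ms) followed by the timed simulation phase (1 s by default), both
rounded up to whole communication cycles, with the actually simulated span
reported.

What the synthetic conditions do *not* emulate: plasticity (all synapses
static by design), hardware memory behaviour (cache misses, latency — the
counters count operations, not cycles), real MPI transport and its buffer
protocols, and the full-scale connectivity density. Passing tests therefore
demonstrate algorithmic correctness and the structural counter laws, not
wall-clock speedups on any particular machine.

## Design choices where the design was open

- **Dyadic weights in equivalence fixtures.** The two kernels accumulate
  ring-buffer slots in different orders. With weights that are exact binary
  fractions, floating-point addition over the realised magnitudes is exact
  and order-free, so "bit-identical ring buffers and spike files" is a
  meaningful cross-kernel contract rather than a tolerance game.
- **Sender-side routing table.** The reference design composes spike entries
  through a build-time target exchange between processes; with all emulated
  processes in one address space, wiring directly yields each source's
  segment list `(process, thread, syn_type, lcid)`, ordered
  deterministically. One record per non-empty (source, thread, type) group —
  verified against a brute-force grouping.
- **Register iteration order** (ascending writing thread, then synapse type)
  is fixed for determinism; outcomes are order-free by the dyadic-weight
  argument, which the schedule-independence tests confirm.
- **Slice remainders** in the parallel sort use `⌊wE/T⌋` bounds — balanced
  to within one entry for any `E`, `T`.
- **SSG toggle.** Sender identity is an optional entry field used only by
  recording paths; tests assert the toggle changes payload, never outcomes.

## Problem sizes

The default test suite and the acceptance script use small ensembles —
100 seeded networks of 20 neurons over 2×2 virtual processes for kernel
equivalence, 12 Monte-Carlo configurations at 2 500 repetitions, a 500-neuron
desk benchmark over 300 ms — sizes chosen as the smallest that still
exercise multi-process, multi-thread routing, both synapse types, delay
heterogeneity, and ring-buffer wrap-around. The whole suite completes in
well under a minute on one core.

## Known limitations

- Emulated concurrency only; no attempt to measure real parallel speedup.
- Homogeneous neuron parameters and exactly two static synapse types (the
  type axis is exercised, its cardinality effects are not studied).
- The full-scale benchmark profile is configurable but not runnable at desk
  scale (≈1.4×10⁸ synapses per process); its published operating point
  additionally depends on externally tabulated parameters not shipped here.
- Delays are realised on the fixed grid; continuous-time spike precision is
  out of scope.
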