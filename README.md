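# spikeroute

A desk-scale simulation kernel for studying **spike delivery** — the phase
of distributed spiking-neural-network simulation in which spikes that
arrived at a compute node must be routed to their synaptic and neuronal
targets. In time-driven simulators of networks of point neurons this phase,
not neuronal integration or inter-node communication, dominates simulation
time over the practically relevant range of network sizes, because spike
entries arrive unsorted with respect to target thread and synapse type and
their delivery touches essentially random memory.

The package is for simulator developers and computational neuroscientists
who want to study routing algorithms and their operation counts without a
cluster: `M` MPI-like processes with `T` threads each are *emulated*
deterministically inside one program, with the data structures of a
production simulator — a three-dimensional synapse store
`[thread][synapse_type][lcid]` whose innermost arrays are sorted by source
neuron into contiguous *target segments*, per-neuron spike ring buffers,
and per-process receive buffers — and two delivery kernels over them:

- **`ori`** — the original algorithm: every thread scans *all* `E` entries
  of the receive buffer and skips foreign ones (`T·E` entry reads per
  cycle); a hit walks the target segment via the `subsq` continuation flag
  and delivers through synapse → neuron → ring buffer.
- **`srr`** — the redesign: the threads first bucket-sort the buffer in
  parallel (each reads a `⌊wE/T⌋` slice once) into a *spike-receive
  register* indexed by hosting thread and synapse type; after a single
  barrier each thread drains only its own cells, and each synapse holds a
  direct reference to its target's ring buffer (pointer-to-ring-buffer), so
  no neuron-level dispatch remains. Every entry is read exactly **twice**,
  independent of `T`.

Alongside the kernels, closed-form **sparsity analytics** describe how the
routing workload changes as a network is distributed: with `S = NK/(MT)`
thread-local synapses, the expected number of unique spike sources is
`N_u = (1 − (1 − 1/N)^S)·N → (1 − e^{−S/N})·N`, approaching `S` — one
unique source per synapse — with characteristic size
`N_ζ = S/(2(1−ζ))`, so half of the sources are already unique at `N = S`.
The mean target-segment length `S_u = S/N_u` falls toward 1 accordingly.

Neurons are leaky integrate-and-fire with alpha-shaped postsynaptic
currents, advanced by exact integration (matrix-exponential propagators)
on a 0.1 ms grid; the benchmark network is the standard balanced random
model (80 % excitatory / 20 % inhibitory, fixed in-degree, inhibition
stronger by a factor `g`, uniform 1.5 ms delay = communication interval).

## Worked example

Sparsity of the full-scale weak-scaling workload (125 000 neurons per
process, in-degree 11 250, 12 threads):

```
$ spikeroute predict --neurons-per-process 125000 --indegree 11250 --threads 12 --max-m 32
M,N,S,N_u,N_u_limit,S_u
1,125000,117187500.0,125000.0,125000.0,937.5
2,250000,117187500.0,250000.0,250000.0,468.75
4,500000,117187500.0,500000.0,500000.0,234.375
8,1000000,117187500.0,1000000.0,1000000.0,117.1875
16,2000000,117187500.0,2000000.0,2000000.0,58.59375
32,4000000,117187500.0,3999999.9999992438,3999999.9999992438,29.29687500000554
```

`S` stays fixed (weak scaling) while almost every one of the `N` neurons is
still a unique source (`N_u ≈ N` in this regime), and the mean segment
length `S_u` halves with every doubling of `M` — each spike entry finds
fewer and fewer thread-local targets.

Counter laws on synthetic receive-buffer traffic (no neuron dynamics):

```
$ spikeroute traffic -e 1000 -t 12 --seed 1
E=1000 entries, T=12 threads
ori: entries_read=12000 (= T*E), skipped=11000, synapses_activated=1071
srr: entries_read=2000 (= 2*E), synapses_activated=1071
```

The original kernel reads each of the 1 000 entries on all 12 threads
(11 000 reads are immediate rejections); the register kernel reads each
entry once while sorting and once while delivering. The delivery work
itself (1 071 synapse activations) is identical — only scanning overhead
differs.

A full desk-scale run of the balanced random network (N = 500, K = 50,
1 s of biological time, default fluctuation-driven Poisson drive):

```
$ spikeroute run --seed 7 --out spikes.gdf
rate: 7.292 Hz (SD over neurons 2.051 Hz), 3648 spikes in 1000.0 ms
counters: {'entries_read': 29184, 'entries_skipped': 14592, 'segments_walked': 14592,
           'synapses_activated': 182269, 'rb_writes': 182269}
```

The spike file is GDF-style text (`gid<TAB>time_ms`, grid-aligned, sorted
by time then gid); identical configuration and seed reproduce it byte for
byte, and it is byte-identical between `--algorithm ori` and
`--algorithm srr` — the delivery redesign changes operation counts, never
the science output. Configuration is a TOML/JSON file with sections
`[grid] [populations] [connectivity] [neuron] [drive] [run]`
(`--config run.toml`); the full-scale profile is expressed the same way.

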