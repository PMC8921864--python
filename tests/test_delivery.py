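"""The two delivery kernels: hand traces, counter laws, equivalence."""

import numpy as np
import pytest

from spikeroute.benchmark import generate_fixture_network, synthetic_traffic
from spikeroute.deliver_ori import deliver_ori
from spikeroute.deliver_srr import (
    deliver_from_register,
    slice_bounds,
    sort_into_register,
)
from spikeroute.exchange import ReceiveBuffer, SpikeEntry
from spikeroute.instrumentation import CycleCounters

from conftest import make_small_network


class TestDeliverOri:
    def test_three_entry_two_thread_hand_trace(self):
        """Entry tids [0, 1, 0]: thread 0 reads 3 and skips 1, thread 1
        reads 3 and skips 2."""
        net, _ = generate_fixture_network("three-thread-toy")
        store = net.stores[0]
        neurons = [net.domains[(0, t)].neurons for t in range(3)]
        buffer = ReceiveBuffer(entries=[
            SpikeEntry(tid=0, syn_type=0, lcid=0, lag=0),
            SpikeEntry(tid=1, syn_type=0, lcid=0, lag=0),
            SpikeEntry(tid=0, syn_type=0, lcid=0, lag=0),
        ])
        c0, c1 = CycleCounters(), CycleCounters()
        deliver_ori(buffer, store, neurons, 0, 0, c0)
        deliver_ori(buffer, store, neurons, 1, 0, c1)
        assert (c0.entries_read, c0.entries_skipped) == (3, 1)
        assert (c1.entries_read, c1.entries_skipped) == (3, 2)

    def test_single_thread_hosts_everything(self):
        net, _ = make_small_network(seed=2, M=1, T=1)
        case_net = net
        rng = np.random.default_rng(0)
        for g in rng.integers(0, 24, 6):
            case_net.force_emission(int(g), 1)
        case_net.run_cycle("ori")
        rec = case_net.instrumentation.records[-1]
        assert rec["entries_skipped"] == 0
        assert rec["entries_read"] == rec["E"]

    def test_segments_walked_once_each(self):
        """Every segment addressed by the buffer is walked exactly once
        across all threads, and activations sum segment lengths."""
        net, _ = make_small_network(seed=3)
        rng = np.random.default_rng(1)
        emitted = [int(g) for g in rng.integers(0, 24, 8)]
        for g in emitted:
            net.force_emission(g, 2)
        net.run_cycle("ori")
        rec = net.instrumentation.records[-1]
        store_len = {}
        expected_segments = 0
        expected_synapses = 0
        for g in emitted:
            for (p, t, s, lcid) in net.routing.targets_of(g):
                expected_segments += 1
                arr = net.stores[p].get(t, s)
                expected_synapses += 1
                while arr.subsq[lcid]:
                    lcid += 1
                    expected_synapses += 1
        assert rec["segments_walked"] == expected_segments
        assert rec["synapses_activated"] == expected_synapses

    def test_malformed_segment_raises(self):
        net, _ = generate_fixture_network("three-thread-toy")
        store = net.stores[0]
        arr = store.get(0, 0)
        arr.subsq[:] = True  # chain runs past the array end
        buffer = ReceiveBuffer(entries=[SpikeEntry(0, 0, 0, 0)])
        neurons = [net.domains[(0, t)].neurons for t in range(3)]
        with pytest.raises(IndexError):
            deliver_ori(buffer, store, neurons, 0, 0, CycleCounters())


class TestSortIntoRegister:
    def test_slice_rule_partitions_buffer(self):
        entries = [SpikeEntry(tid=i % 2, syn_type=0, lcid=0, lag=0)
                   for i in range(4)]
        counters = CycleCounters()
        reg = sort_into_register(ReceiveBuffer(entries=entries), T=2,
                                 counters=counters)
        # thread 0 sorted entries 0-1, thread 1 entries 2-3
        assert len(reg.cell(0, 0, 0)) == 1 and len(reg.cell(0, 1, 0)) == 1
        assert len(reg.cell(1, 0, 0)) == 1 and len(reg.cell(1, 1, 0)) == 1
        assert reg.n_entries == 4
        assert counters.entries_read == 4  # each element read only once

    @pytest.mark.parametrize("E,T", [(0, 3), (7, 3), (10, 4), (3, 8)])
    def test_slice_bounds_balanced(self, E, T):
        sizes = [slice_bounds(E, T, w)[1] - slice_bounds(E, T, w)[0]
                 for w in range(T)]
        assert sum(sizes) == E
        assert max(sizes) - min(sizes) <= 1
        assert slice_bounds(E, T, 0)[0] == 0
        assert slice_bounds(E, T, T - 1)[1] == E

    def test_empty_buffer(self):
        reg = sort_into_register(ReceiveBuffer(), T=3, counters=CycleCounters())
        assert reg.n_entries == 0

    def test_cells_respect_tid_and_type(self, rng):
        entries = [
            SpikeEntry(tid=int(rng.integers(3)), syn_type=int(rng.integers(2)),
                       lcid=0, lag=0)
            for _ in range(50)
        ]
        reg = sort_into_register(ReceiveBuffer(entries=entries), T=3,
                                 counters=CycleCounters())
        for w in range(3):
            for t in range(3):
                for s in range(2):
                    assert all(e.tid == t and e.syn_type == s
                               for e in reg.cell(w, t, s))
        assert reg.n_entries == 50


class TestCounterLaws:
    @pytest.mark.parametrize("E,T", [(100, 1), (100, 2), (100, 4), (64, 8)])
    def test_srr_reads_twice_ori_reads_T_times(self, E, T):
        case = synthetic_traffic(E, T, seed=E + T)
        c_ori = case.run_ori()
        c_srr = case.run_srr()
        assert c_ori.entries_read == T * E
        assert c_srr.entries_read == 2 * E
        # delivery work itself is identical
        assert c_srr.synapses_activated == c_ori.synapses_activated
        assert c_srr.segments_walked == c_ori.segments_walked
        assert c_srr.entries_skipped == 0

    def test_strict_improvement_for_three_plus_threads(self):
        for T in (3, 4, 6):
            case = synthetic_traffic(30, T, seed=T)
            assert case.run_srr().entries_read < case.run_ori().entries_read

    def test_skewed_mix_keeps_laws(self):
        T = 4
        skewed = [1.0, 0.0, 0.0, 0.0]
        case = synthetic_traffic(40, T, tid_distribution=skewed, seed=5)
        c_ori = case.run_ori()
        c_srr = case.run_srr()
        assert c_ori.entries_read == T * 40
        assert c_srr.entries_read == 2 * 40
        # all deliveries concentrate on thread 0
        assert all(e.tid == 0 for e in case.buffer.entries)
        assert c_ori.entries_skipped == (T - 1) * 40

    def test_zero_entries_noop(self):
        case = synthetic_traffic(0, 4, seed=0)
        assert case.run_ori().entries_read == 0
        assert case.run_srr().entries_read == 0


class TestKernelEquivalence:
    def test_identical_deliveries_on_synthetic_traffic(self):
        """The multiset of (slot, weight) ring-buffer writes matches
        between the kernels on the same traffic."""
        case = synthetic_traffic(60, 3, seed=9)
        case.run_ori()
        case.run_srr()
        for t in range(3):
            di = case.net_index.domains[(0, t)]
            dp = case.net_pointer.domains[(0, t)]
            assert np.array_equal(di.rb_ex, dp.rb_ex)
            assert np.array_equal(di.rb_in, dp.rb_in)

    @pytest.mark.parametrize("seed", range(25))
    def test_bit_identical_ring_buffers_and_spikes(self, seed):
        """Full dynamic networks, dyadic weights: original and
        register-sorting kernels give bit-identical ring buffers and
        spike trains over several cycles."""
        net_o, _ = make_small_network(seed, target_mode="index", spiking=True)
        net_s, _ = make_small_network(seed, target_mode="pointer", spiking=True)
        spikes_o, spikes_s = [], []
        for _ in range(6):
            spikes_o.extend(net_o.run_cycle("ori"))
            spikes_s.extend(net_s.run_cycle("srr"))
        assert spikes_o == spikes_s
        state_o, state_s = net_o.ring_buffer_state(), net_s.ring_buffer_state()
        for key in state_o:
            assert np.array_equal(state_o[key][0], state_s[key][0])
            assert np.array_equal(state_o[key][1], state_s[key][1])
        for key in net_o.domains:
            assert np.array_equal(net_o.domains[key].pop.X,
                                  net_s.domains[key].pop.X)

    def test_ssg_toggle_changes_payload_not_outcome(self):
        """Sender gids enlarge the entry payload; ring buffers and
        spikes are unchanged."""
        nets = []
        for ssg in (False, True):
            net, _ = make_small_network(7, target_mode="pointer", spiking=True)
            net.ssg = ssg
            nets.append(net)
        spikes = [
            [s for _ in range(4) for s in net.run_cycle("srr")] for net in nets
        ]
        assert spikes[0] == spikes[1]
        s0, s1 = nets[0].ring_buffer_state(), nets[1].ring_buffer_state()
        for key in s0:
            assert np.array_equal(s0[key][0], s1[key][0])

    def test_register_delivery_requires_pointer_mode(self):
        net, _ = make_small_network(1, target_mode="index")
        with pytest.raises(ValueError):
            net.run_cycle("srr")
        reg = sort_into_register(ReceiveBuffer(), 3, CycleCounters())
        with pytest.raises(ValueError):
            deliver_from_register(reg, net.stores[0], 0, 0, CycleCounters())


class TestScheduleIndependence:
    @pytest.mark.parametrize("algorithm,mode", [("ori", "index"),
                                                ("srr", "pointer")])
    def test_thread_order_permutation_invariance(self, algorithm, mode):
        rng = np.random.default_rng(31)
        base, _ = make_small_network(13, target_mode=mode, spiking=True)
        roles = [(p, t) for p in range(2) for t in range(3)]
        spikes_ref = [s for _ in range(4) for s in base.run_cycle(algorithm)]
        for trial in range(3):
            net, _ = make_small_network(13, target_mode=mode, spiking=True)
            spikes = []
            for _ in range(4):
                order = [roles[i] for i in rng.permutation(len(roles))]
                spikes.extend(net.run_cycle(algorithm, thread_order=order))
            assert spikes == spikes_ref
            ref_state = base.ring_buffer_state()
            got_state = net.ring_buffer_state()
            for key in ref_state:
                assert np.array_equal(ref_state[key][0], got_state[key][0])
                assert np.array_equal(ref_state[key][1], got_state[key][1])
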