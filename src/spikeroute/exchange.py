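"""Spike collection, emulated all-to-all exchange, and the three-phase cycle.

One communication cycle covers ``min_delay_steps`` grid steps: all
neurons are updated thread by thread and their emissions collected;
each emission fans out into one :class:`SpikeEntry` per target segment
of its source; the entries are exchanged all-to-all between the
emulated processes; and a delivery kernel (original scan-all or
register-sorting redesign) routes every entry's segment into the target
neurons' ring buffers.  The emulation executes thread roles
sequentially with an explicit barrier between phases, so results are
exactly reproducible and independent of the order in which thread roles
run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

__all__ = [
    "SpikeEntry",
    "ReceiveBuffer",
    "route_emitted_spikes",
    "all_to_all_exchange",
    "emission_step",
    "run_cycle",
]


class SpikeEntry(NamedTuple):
    """One routing record in a receive buffer.

    Addresses the target segment starting at ``lcid`` of innermost array
    ``[tid][syn_type]`` on the receiving process.  ``lag`` is the
    emission offset within the communication interval (``0 <= lag <
    min_delay_steps``); the absolute emission step is reconstructed at
    delivery time as ``interval_start + 1 + lag`` (spikes are bound to
    end-of-step grid points).  ``sender_gid`` is carried only in SSG
    mode, for recording devices; delivery never reads it.
    """

    tid: int
    syn_type: int
    lcid: int
    lag: int
    sender_gid: Optional[int] = None


@dataclass
class ReceiveBuffer:
    """Per-process receive buffer: entries concatenated over sending ranks."""

    entries: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def emission_step(interval_start: int, lag: int) -> int:
    """Absolute grid step of a spike from its in-interval lag."""
    return interval_start + 1 + lag


def route_emitted_spikes(
    emissions: Sequence[tuple[int, int]],
    routing,
    M: int,
    ssg: bool = False,
) -> list[list[SpikeEntry]]:
    """Fan emissions out into per-destination-process spike entries.

    ``emissions`` are ``(source_gid, lag)`` pairs from one sending
    process.  Each emission yields one entry per target segment of its
    source (none for processes hosting no targets).  Unknown gids —
    sources absent from the routing table that were never wired — are
    permitted only if they have no targets at all; a malformed gid
    (negative) raises.
    """
    out: list[list[SpikeEntry]] = [[] for _ in range(M)]
    for source_gid, lag in emissions:
        if source_gid < 0:
            raise ValueError(f"invalid source gid {source_gid}")
        for proc, tid, syn_type, lcid in routing.targets_of(source_gid):
            out[proc].append(
                SpikeEntry(
                    tid=tid, syn_type=syn_type, lcid=lcid, lag=lag,
                    sender_gid=source_gid if ssg else None,
                )
            )
    return out


def all_to_all_exchange(
    outboxes: Sequence[Sequence[list]],
) -> list[ReceiveBuffer]:
    """Emulate the synchronous all-to-all spike exchange.

    ``outboxes[sender][dest]`` is the entry list process ``sender``
    addressed to process ``dest``.  Each destination receives the
    concatenation over senders in rank order (emission order preserved
    within each sender); entry totals are conserved.
    """
    M = len(outboxes)
    buffers = []
    for dest in range(M):
        buf = ReceiveBuffer()
        for sender in range(M):
            buf.entries.extend(outboxes[sender][dest])
        buffers.append(buf)
    return buffers


def run_cycle(net, algorithm: str = "ori", thread_order=None):
    """Advance a network by one full communication interval.

    Phases: update all neurons for ``min_delay_steps`` steps collecting
    emissions, route and exchange the spike entries, then deliver with
    the selected kernel (``"ori"`` or ``"srr"``).  Returns the spikes
    emitted during the interval as ``(gid, step)`` pairs.

    ``thread_order`` optionally permutes the order in which the emulated
    (process, thread) roles execute within each phase; the observable
    outcome is independent of it.
    """
    return net.run_cycle(algorithm=algorithm, thread_order=thread_order)
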