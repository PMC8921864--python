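"""Per-neuron spike ring buffer: temporary storage and delay scheduler.

Each neuron input channel owns a circular array of ``L`` slots indexed
by ``step mod L``.  A spike emitted at grid step ``s`` through a synapse
with delay ``d`` accumulates its weight into slot ``(s + d) mod L``; the
neuron update at step ``t`` reads and clears slot ``t mod L``.  With
``L = max_delay + min_delay`` and delivery once per min-delay interval,
every write lands strictly in the future of the reader, so a slot is
never overwritten before it is consumed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SpikeRingBuffer"]


class SpikeRingBuffer:
    """Circular accumulator of weighted spike input for one neuron channel.

    May either own its storage or wrap a row view of a shared per-thread
    matrix, so that a synapse can hold a direct reference to its target's
    buffer while the neuron update reads whole columns vectorised.
    """

    __slots__ = ("slots", "min_delay_steps", "max_delay_steps")

    def __init__(
        self,
        min_delay_steps: int,
        max_delay_steps: int,
        slots: np.ndarray | None = None,
    ) -> None:
        if min_delay_steps < 1 or max_delay_steps < min_delay_steps:
            raise ValueError("require 1 <= min_delay_steps <= max_delay_steps")
        L = max_delay_steps + min_delay_steps
        if slots is None:
            slots = np.zeros(L)
        elif slots.shape != (L,):
            raise ValueError(f"slots must have shape ({L},)")
        self.slots = slots
        self.min_delay_steps = min_delay_steps
        self.max_delay_steps = max_delay_steps

    @property
    def L(self) -> int:
        return len(self.slots)

    def add_value(self, current_step: int, delay_steps: int, weight: float) -> None:
        """Accumulate ``weight`` into the slot for ``current_step + delay_steps``.

        ``current_step`` is the grid step of spike emission.  Delays
        outside ``[min_delay_steps, max_delay_steps]`` violate the
        ring-buffer safety argument and raise.
        """
        if not self.min_delay_steps <= delay_steps <= self.max_delay_steps:
            raise ValueError(
                f"delay {delay_steps} outside "
                f"[{self.min_delay_steps}, {self.max_delay_steps}]"
            )
        self.slots[(current_step + delay_steps) % self.L] += weight

    def read_and_clear(self, step: int) -> float:
        """Consume the accumulated weight for grid step ``step``.

        Must be called exactly once per neuron per step during update;
        the slot is zeroed so it can be reused ``L`` steps later.
        """
        idx = step % self.L
        value = float(self.slots[idx])
        self.slots[idx] = 0.0
        return value
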