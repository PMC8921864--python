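"""Simulation time grid and delay bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class SimGrid:
    """Fixed time grid of the simulation.

    Neurons are updated every ``h`` milliseconds and spike times are
    constrained to this grid.  Spikes are exchanged between emulated
    processes every ``min_delay_steps`` grid steps (the communication
    interval); all synaptic delays must lie in
    ``[min_delay_steps, max_delay_steps]``.
    """

    h: float = 0.1
    min_delay_steps: int = 15
    max_delay_steps: int = 15
    current_step: int = 0

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if self.min_delay_steps < 1:
            raise ValueError("min_delay_steps must be >= 1")
        if self.max_delay_steps < self.min_delay_steps:
            raise ValueError("max_delay_steps must be >= min_delay_steps")
        if self.current_step < 0:
            raise ValueError("current_step must be >= 0")

    @property
    def communication_interval_ms(self) -> float:
        return self.min_delay_steps * self.h

    @property
    def ring_buffer_length(self) -> int:
        """Slot count guaranteeing writes never land on unread slots.

        With delays in ``[min_delay, max_delay]`` steps and delivery once
        per ``min_delay`` interval, ``max_delay + min_delay`` slots keep
        every write strictly ahead of the reader.
        """
        return self.max_delay_steps + self.min_delay_steps

    def steps_to_ms(self, step: int) -> float:
        return step * self.h

    def ms_to_steps(self, t_ms: float) -> int:
        steps = round(t_ms / self.h)
        if abs(steps * self.h - t_ms) > 1e-9:
            raise ValueError(f"{t_ms} ms is not a multiple of h={self.h} ms")
        return steps
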