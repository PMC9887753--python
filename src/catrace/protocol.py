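"""Pacing/caffeine protocol descriptors shared by the detection and kinetics stages."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ProtocolError

__all__ = ["ProtocolDescriptor", "ProtocolPhases"]


@dataclass
class ProtocolDescriptor:
    """What the experimenter did: field-stimulation frequency and phase times.

    ``caffeine_s`` may be omitted when the caffeine-addition time was not
    logged; it is then detected from the trace (largest-prominence transient
    after the pacing stop).
    """

    pacing_freq_hz: float
    pacing_stop_s: float
    pacing_start_s: float = 0.0
    caffeine_s: float | None = None
    iso_condition: bool = False

    def __post_init__(self) -> None:
        if not self.pacing_freq_hz > 0:
            raise ProtocolError(f"pacing_freq_hz must be > 0, got {self.pacing_freq_hz}")
        if not self.pacing_stop_s > self.pacing_start_s:
            raise ProtocolError("pacing_stop_s must exceed pacing_start_s")
        if self.caffeine_s is not None and self.caffeine_s < self.pacing_stop_s:
            raise ProtocolError("caffeine_s precedes pacing_stop_s")

    def stimulus_times(self) -> list[float]:
        """Field-stimulus times at 1/pacing_freq intervals over the paced phase."""
        times = []
        t = self.pacing_start_s
        period = 1.0 / self.pacing_freq_hz
        while t < self.pacing_stop_s:
            times.append(t)
            t += period
        return times


@dataclass
class ProtocolPhases:
    """Contiguous half-open phases of a caffeine-protocol recording, in seconds."""

    paced: tuple[float, float]
    pause: tuple[float, float]
    caffeine: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.paced[0] < self.paced[1] <= self.pause[0] < self.pause[1]
                <= self.caffeine[0] < self.caffeine[1]):
            raise ProtocolError(f"phases must be ordered and non-empty, got {self}")
        if self.paced[1] != self.pause[0] or self.pause[1] != self.caffeine[0]:
            raise ProtocolError("phases must be contiguous")
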