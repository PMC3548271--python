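"""Time base, multichannel buffering, and the event datatypes shared by all modules.

Time is kept as an integer absolute sample index everywhere; seconds are
derived views through :class:`TimeBase`.  All window ranges are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TimeBase",
    "MultiChannelWindow",
    "RingBuffer",
    "SpikeEvent",
    "StimulusCommand",
    "StimulusEvent",
    "DigitalEvent",
    "merge_events",
    "DEFAULT_RAW_RATE",
    "DEFAULT_LFP_RATE",
]

#: Default sampling rate of raw / spike-band streams (samples per second).
DEFAULT_RAW_RATE = 25_000.0
#: Default sampling rate of the LFP stream (500 us sampling period).
DEFAULT_LFP_RATE = 2_000.0


@dataclass(frozen=True)
class TimeBase:
    """Sample-clocked time base.

    Parameters
    ----------
    sample_rate
        Samples per second; must be positive.
    origin
        Absolute sample index corresponding to ``t = 0`` seconds.
    """

    sample_rate: float = DEFAULT_RAW_RATE
    origin: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")

    def to_seconds(self, sample: int | np.ndarray) -> float | np.ndarray:
        return (np.asarray(sample) - self.origin) / self.sample_rate

    def to_sample(self, seconds: float | np.ndarray) -> int | np.ndarray:
        """Nearest sample index for a time in seconds (exact inverse on integers)."""
        s = np.rint(np.asarray(seconds) * self.sample_rate).astype(np.int64) + self.origin
        return int(s) if s.ndim == 0 else s


@dataclass
class MultiChannelWindow:
    """A contiguous block of multichannel voltage data.

    ``values`` is channel-major: shape ``(n_channels, n_samples)``, volts.
    """

    start_sample: int
    values: np.ndarray
    time_base: TimeBase = field(default_factory=TimeBase)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_channels, n_samples)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def end_sample(self) -> int:
        """One past the last sample (half-open convention)."""
        return self.start_sample + self.n_samples

    def times(self) -> np.ndarray:
        return self.time_base.to_seconds(
            np.arange(self.start_sample, self.end_sample)
        )


class RingBuffer:
    """Fixed-capacity circular buffer over a multichannel stream.

    Appending ``N`` samples advances ``head`` by exactly ``N``; reads outside
    the retained range ``[head - capacity, head)`` are rejected.
    """

    def __init__(self, n_channels: int, capacity: int,
                 time_base: TimeBase | None = None, start_sample: int = 0):
        if capacity <= 0:
            raise ValueError("capacity must be positive")
        self.n_channels = int(n_channels)
        self.capacity = int(capacity)
        self.time_base = time_base or TimeBase()
        self._store = np.zeros((self.n_channels, self.capacity))
        self.head = int(start_sample)       # next absolute index to write
        self._written = 0                   # total samples ever appended

    @property
    def oldest(self) -> int:
        """Oldest retained absolute sample index."""
        return self.head - min(self._written, self.capacity)

    def append(self, window: MultiChannelWindow) -> "RingBuffer":
        if window.n_channels != self.n_channels:
            raise ValueError(
                f"channel-count mismatch: buffer has {self.n_channels}, "
                f"window has {window.n_channels}"
            )
        if window.start_sample != self.head:
            raise ValueError(
                f"non-contiguous append: expected start_sample {self.head}, "
                f"got {window.start_sample}"
            )
        vals = window.values
        n = vals.shape[1]
        if n >= self.capacity:
            # only the newest `capacity` samples survive
            tail = vals[:, n - self.capacity:]
            idx = np.arange(self.head + n - self.capacity, self.head + n) % self.capacity
            self._store[:, idx] = tail
        else:
            idx = np.arange(self.head, self.head + n) % self.capacity
            self._store[:, idx] = vals
        self.head += n
        self._written += n
        return self

    def read_window(self, start_sample: int, end_sample: int) -> MultiChannelWindow:
        if end_sample < start_sample:
            raise ValueError("end_sample < start_sample")
        if start_sample < self.oldest or end_sample > self.head:
            raise ValueError(
                f"requested [{start_sample}, {end_sample}) outside retained "
                f"range [{self.oldest}, {self.head})"
            )
        idx = np.arange(start_sample, end_sample) % self.capacity
        vals = self._store[:, idx].reshape(self.n_channels, end_sample - start_sample)
        return MultiChannelWindow(start_sample, vals, self.time_base)


@dataclass
class SpikeEvent:
    """A detected action potential.

    ``time`` is the absolute sample index of the waveform peak.  ``unit`` is
    -1 while unassigned.  ``waveform`` may be ``None`` for count-only streams
    (e.g. spikes emitted by the synthetic plant).
    """

    time: int
    channel: int
    unit: int = -1
    waveform: np.ndarray | None = None
    threshold_at_detection: float = 0.0

    def __post_init__(self) -> None:
        if self.channel < 0:
            raise ValueError("channel must be >= 0")

    def with_unit(self, unit: int) -> "SpikeEvent":
        return replace(self, unit=int(unit))


@dataclass(frozen=True)
class StimulusCommand:
    """A requested stimulation pulse (not yet executed)."""

    time: int
    channel: int
    amplitude: float
    phase_width: float = 400e-6
    shape: str = "biphasic_square"

    def __post_init__(self) -> None:
        if self.phase_width <= 0:
            raise ValueError("phase_width must be positive")
        if self.shape not in ("biphasic_square", "monophasic_square"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")


@dataclass(frozen=True)
class StimulusEvent:
    """An executed stimulation pulse, clock-stamped at its onset sample."""

    time: int
    channel: int
    amplitude: float
    phase_width: float = 400e-6
    shape: str = "biphasic_square"
    max_amplitude: float = 10.0  # safety bound, volts

    def __post_init__(self) -> None:
        if self.phase_width <= 0:
            raise ValueError("phase_width must be positive")
        if abs(self.amplitude) > self.max_amplitude:
            raise ValueError(
                f"amplitude {self.amplitude} V exceeds safety bound "
                f"{self.max_amplitude} V"
            )


@dataclass(frozen=True)
class DigitalEvent:
    """A digital output word change (32-bit port state)."""

    time: int
    port_state: int

    def __post_init__(self) -> None:
        if not (0 <= self.port_state < 2 ** 32):
            raise ValueError("port_state must fit in 32 bits")


def _check_sorted(events: Sequence) -> None:
    times = [e.time for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("event list is not sorted by time")


def merge_events(a: Sequence, b: Sequence) -> list:
    """Merge two time-sorted event lists.

    Output is sorted by ``(time, channel)``; remaining ties keep input order
    (a before b).  Multiplicity is preserved: ``len(out) == len(a) + len(b)``.
    """
    _check_sorted(a)
    _check_sorted(b)
    tagged = [(e.time, getattr(e, "channel", 0), 0, i) for i, e in enumerate(a)]
    tagged += [(e.time, getattr(e, "channel", 0), 1, i) for i, e in enumerate(b)]
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))
    pools = (a, b)
    return [pools[src][i] for _, _, src, i in tagged]
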