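"""Core containers shared across the pipeline stages.

These are re-exported by the public modules (`io_core`, `spike_detection`)
and kept here only to avoid circular imports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelMeta", "Recording", "SpikeTrain", "Waveform"]


@dataclass(frozen=True)
class ChannelMeta:
    """Identity and 3D position of one electrode.

    ``x``/``y`` are the planar coordinates of the pillar base and
    ``height`` its z-extent (all micrometres); the recording site sits at
    the pillar tip, i.e. at ``(x, y, height)``.
    """

    id: int
    x: float = 0.0
    y: float = 0.0
    height: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError(f"channel {self.id}: height must be >= 0")


@dataclass
class Recording:
    """Multi-channel extracellular voltage recording.

    ``signal`` is channels x samples in microvolts, ``fs`` the sampling
    frequency in Hz.  Channel metadata rows correspond to signal rows.
    """

    signal: np.ndarray
    fs: float
    channels: list[ChannelMeta]

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal))
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.signal.ndim != 2:
            raise ValueError("signal must be a channels x samples matrix")
        if len(self.channels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel entries for "
                f"{self.signal.shape[0]} signal rows"
            )
        ids = [c.id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("channel ids must be unique")
        if self.signal.shape[1] == 0:
            raise ValueError("recording must contain at least one sample")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds (= samples / fs)."""
        return self.n_samples / self.fs


@dataclass
class SpikeTrain:
    """Sorted spike (event) times of one channel on ``[0, duration]`` seconds."""

    channel: int
    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.duration <= 0:
            raise ValueError("spike train duration must be positive")
        if self.times.size:
            if np.any(np.diff(self.times) < 0):
                raise ValueError("spike times must be sorted ascending")
            if self.times[0] < 0 or self.times[-1] > self.duration:
                raise ValueError(
                    f"channel {self.channel}: spike times must lie in "
                    f"[0, {self.duration}]"
                )

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class Waveform:
    """Fixed-window voltage snippet centred on a detected spike peak.

    ``samples`` has odd length with the (negative-going) peak at the
    centre sample; ``time`` is the peak time in seconds.
    """

    samples: np.ndarray
    fs: float
    channel: int
    time: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size % 2 != 1:
            raise ValueError("waveform length must be odd (peak at centre)")
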