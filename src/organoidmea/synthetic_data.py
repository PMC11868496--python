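"""Synthetic MEA recordings with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be verified without recording hardware:

- per-channel firing at maturation-stage rates: a homogeneous Poisson
  background plus burst episodes (windows of elevated renewal firing
  whose expected length matches the preset burst duration), with the
  overall expected rate equal to the preset rate;
- community-structured synchrony by mother-train thinning: within a
  community a fraction ``sync_strength`` of events is copied from a
  shared mother train with Gaussian jitter, which leaves each channel's
  expected rate unchanged while making within-community timing
  correlated;
- extracellular waveforms: each spike is assigned to one of 2-3 units
  per channel, each with a parametric biphasic template (dominant
  negative lobe, smaller positive after-lobe, total width under 2 ms),
  inserted into Gaussian background noise of configurable RMS
  (default 13 uV) at the recording sampling rate (default 24414 Hz);
- tilt events: after a switch time, affected channels swap to a disjoint
  unit set, emulating a magnetically tilted electrode contacting a new
  neuron group.

Maturation presets carry the 2- and 6-month summary statistics (mean
rate 0.330 / 8.90 Hz, mean ISI 3.832 / 0.755 s, 1.5 / 9 bursts per
300 s recording, burst duration 0.991 / 1.490 s); the 4-month preset is
a geometric interpolation and the 1-month preset nominal sparse firing,
both placeholders rather than measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._types import ChannelMeta, Recording, SpikeTrain

__all__ = [
    "MaturationPreset",
    "SynthSpec",
    "UnitTemplate",
    "GroundTruth",
    "PRESETS",
    "generate_spike_trains",
    "render_recording",
    "tilt_event",
    "default_channel_layout",
]

#: Recording length (s) over which preset burst counts are defined.
REFERENCE_RECORDING_S = 300.0

#: Within-burst firing rate (Hz): high enough that a ~1 s episode holds
#: well over the 10-spike burst minimum, with ISIs ~40 ms << 300 ms.
BURST_RATE_HZ = 25.0

#: Per-unit absolute refractory period within bursts (s).
REFRACTORY_S = 0.003

#: Shape of the gamma-distributed burst episode length (SD = mean / 3).
BURST_LEN_SHAPE = 9.0


@dataclass(frozen=True)
class MaturationPreset:
    """Firing statistics of one organoid maturation stage."""

    label: str
    rate: float                  # mean spiking rate, Hz
    mean_isi: float              # mean interspike interval, s
    bursts_per_recording: float  # expected bursts per 300 s recording
    burst_duration: float        # mean burst episode length, s

    def __post_init__(self) -> None:
        if self.rate < 0 or self.mean_isi <= 0 or self.burst_duration <= 0:
            raise ValueError(f"invalid preset {self.label}")


def _geomean(a: float, b: float) -> float:
    return float(np.sqrt(a * b))


PRESETS: dict[str, MaturationPreset] = {
    "1mo": MaturationPreset("1mo", rate=0.1, mean_isi=10.0,
                            bursts_per_recording=0.0, burst_duration=0.5),
    "2mo": MaturationPreset("2mo", rate=0.330, mean_isi=3.832,
                            bursts_per_recording=1.5, burst_duration=0.991),
    "4mo": MaturationPreset("4mo", rate=_geomean(0.330, 8.90),
                            mean_isi=_geomean(3.832, 0.755),
                            bursts_per_recording=_geomean(1.5, 9.0),
                            burst_duration=_geomean(0.991, 1.490)),
    "6mo": MaturationPreset("6mo", rate=8.90, mean_isi=0.755,
                            bursts_per_recording=9.0, burst_duration=1.490),
}


@dataclass(frozen=True)
class UnitTemplate:
    """Parametric biphasic extracellular spike template.

    A dominant negative lobe of width ``neg_width`` followed after
    ``pos_delay`` by a positive lobe of relative height ``pos_frac``;
    rendered templates are rescaled so the minimum equals ``-amplitude``
    exactly at the centre sample.
    """

    amplitude: float        # uV, magnitude of the negative peak
    neg_width: float = 2.5e-4   # s (Gaussian sigma)
    pos_width: float = 4.0e-4   # s
    pos_delay: float = 5.0e-4   # s
    pos_frac: float = 0.3
    support: float = 0.002      # s, total template length

    def render(self, fs: float) -> np.ndarray:
        """Sampled template at rate ``fs`` (odd length, minimum at centre).

        The biphasic shape is evaluated on a padded grid and sliced
        centred on its sampled minimum, so the negative peak lands
        exactly on the centre sample regardless of how the positive
        after-lobe skews the profile.
        """
        if self.support > 0.004:
            raise ValueError("template longer than 4 ms")
        half = int(round(self.support / 2 * fs))
        pad = max(4, half // 4)
        t = np.arange(-(half + pad), half + pad + 1) / fs
        w = (-np.exp(-t**2 / (2 * self.neg_width**2))
             + self.pos_frac * np.exp(-(t - self.pos_delay)**2
                                      / (2 * self.pos_width**2)))
        c = int(np.argmin(w))
        w = w[c - half: c + half + 1]
        return w * (self.amplitude / -w.min())


@dataclass
class SynthSpec:
    """Full specification of one synthetic recording."""

    n_channels: int = 60
    duration: float = 300.0
    preset: MaturationPreset = field(default_factory=lambda: PRESETS["4mo"])
    communities: list[list[int]] | None = None  # channel-index groups
    sync_strength: float = 0.0
    jitter: float = 0.002          # s, SD of shared-event jitter
    units_per_channel: int = 2
    amplitude: float = 100.0       # uV, largest unit's negative peak
    noise_rms: float = 13.0        # uV
    fs: float = 24414.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sync_strength <= 1.0:
            raise ValueError("sync_strength must lie in [0, 1]")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be non-negative")
        if self.units_per_channel not in (1, 2, 3):
            raise ValueError("units_per_channel must be 1, 2 or 3")
        if self.communities is not None:
            flat = [c for grp in self.communities for c in grp]
            if sorted(flat) != list(range(self.n_channels)):
                raise ValueError("communities must partition the channel set")

    def community_partition(self) -> list[list[int]]:
        if self.communities is None:
            return [[i] for i in range(self.n_channels)]
        return self.communities


@dataclass
class GroundTruth:
    """Per-spike and per-channel labels behind a generated recording."""

    unit_labels: dict[int, np.ndarray]          # channel -> unit per spike
    community_labels: dict[int, int]            # channel -> community id
    burst_windows: dict[int, list[tuple[float, float]]]  # community -> windows
    templates: dict[int, list[UnitTemplate]]    # channel -> unit templates


def default_channel_layout(n_channels: int, pitch: float = 200.0,
                           heights: tuple[float, ...] = (50.0, 100.0, 200.0),
                           ) -> list[ChannelMeta]:
    """Grid of pillar electrodes cycling through the given heights."""
    side = int(np.ceil(np.sqrt(n_channels)))
    return [
        ChannelMeta(id=i, x=(i % side) * pitch, y=(i // side) * pitch,
                    height=heights[i % len(heights)])
        for i in range(n_channels)
    ]


def _unit_templates(spec: SynthSpec, rng: np.random.Generator
                    ) -> list[UnitTemplate]:
    """Templates for one channel: amplitudes tapering off across units."""
    amps = spec.amplitude * np.array([1.0, 0.75, 0.55])[: spec.units_per_channel]
    return [
        UnitTemplate(
            amplitude=float(a),
            neg_width=float(rng.uniform(2.0e-4, 3.0e-4)),
            pos_width=float(rng.uniform(3.0e-4, 5.0e-4)),
            pos_delay=float(rng.uniform(4.0e-4, 6.0e-4)),
            pos_frac=float(rng.uniform(0.2, 0.4)),
        )
        for a in amps
    ]


def _burst_windows(spec: SynthSpec, rng: np.random.Generator
                   ) -> list[tuple[float, float]]:
    """Random burst episodes; expected count scales with duration."""
    mean_count = (spec.preset.bursts_per_recording
                  * spec.duration / REFERENCE_RECORDING_S)
    if mean_count <= 0:
        return []
    k = rng.poisson(mean_count)
    windows = []
    for _ in range(k):
        length = rng.gamma(BURST_LEN_SHAPE,
                           spec.preset.burst_duration / BURST_LEN_SHAPE)
        start = rng.uniform(0.0, max(spec.duration - length, 0.0))
        windows.append((start, min(start + length, spec.duration)))
    return sorted(windows)


def _renewal_in_window(start: float, end: float, rate: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Refractory-plus-exponential renewal spikes inside one window."""
    if rate <= 0 or end <= start:
        return np.empty(0)
    mean_isi = 1.0 / rate
    exp_mean = max(mean_isi - REFRACTORY_S, 1e-4)
    out = []
    t = start + rng.exponential(exp_mean)
    while t < end:
        out.append(t)
        t += REFRACTORY_S + rng.exponential(exp_mean)
    return np.asarray(out)


def _poisson_events(T: float, rate: float, rng: np.random.Generator
                    ) -> np.ndarray:
    if rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * T)
    return np.sort(rng.uniform(0.0, T, n))


def _background_rate(spec: SynthSpec) -> float:
    """Poisson background rate so the total expected rate hits the preset."""
    p = spec.preset
    burst_rate_contrib = (p.bursts_per_recording * p.burst_duration
                          * BURST_RATE_HZ / REFERENCE_RECORDING_S)
    return max(p.rate - burst_rate_contrib, 0.0)


def _community_events(spec: SynthSpec, windows, scale: float,
                      rng: np.random.Generator) -> np.ndarray:
    """One realization of the community rate profile, scaled by ``scale``."""
    bg = _poisson_events(spec.duration, scale * _background_rate(spec), rng)
    parts = [bg]
    for (a, b) in windows:
        parts.append(_renewal_in_window(a, b, scale * BURST_RATE_HZ, rng))
    return np.sort(np.concatenate(parts))


def generate_spike_trains(spec: SynthSpec
                          ) -> tuple[list[SpikeTrain], GroundTruth]:
    """Generate community-structured spike trains with full ground truth.

    Per community, burst windows and a mother train are shared; each
    channel receives an independent background realization at fraction
    ``1 - sync_strength`` of the rate profile plus mother-train events
    thinned at probability ``sync_strength`` and jittered with Gaussian
    SD ``spec.jitter``.  Expected per-channel rate equals the preset rate
    regardless of ``sync_strength``.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng([spec.seed, 0])
    s = spec.sync_strength
    trains: list[SpikeTrain] = []
    truth = GroundTruth(unit_labels={}, community_labels={},
                        burst_windows={}, templates={})
    per_channel: dict[int, np.ndarray] = {}
    for cid, members in enumerate(spec.community_partition()):
        windows = _burst_windows(spec, rng)
        truth.burst_windows[cid] = windows
        mother = _community_events(spec, windows, 1.0, rng)
        keep = rng.uniform(size=mother.size) < s if mother.size else np.empty(0, bool)
        for ch in members:
            own = _community_events(spec, windows, 1.0 - s, rng)
            shared = mother[keep]
            if shared.size and spec.jitter > 0:
                shared = shared + rng.normal(0.0, spec.jitter, shared.size)
            times = np.concatenate([own, shared])
            times = np.clip(times, 0.0, spec.duration)
            order = np.argsort(times, kind="stable")
            times = times[order]
            per_channel[ch] = times
            truth.community_labels[ch] = cid
    for ch in sorted(per_channel):
        times = per_channel[ch]
        units = np.random.default_rng([spec.seed, 1, ch]).integers(
            0, spec.units_per_channel, times.size
        )
        truth.unit_labels[ch] = units
        truth.templates[ch] = _unit_templates(
            spec, np.random.default_rng([spec.seed, 2, ch])
        )
        trains.append(SpikeTrain(channel=ch, times=times,
                                 duration=spec.duration))
    return trains, truth


def render_recording(trains: list[SpikeTrain], spec: SynthSpec,
                     truth: GroundTruth | None = None,
                     channels: list[ChannelMeta] | None = None) -> Recording:
    """Render spike trains into a noisy multi-channel voltage recording.

    Each spike inserts its unit's biphasic template at the nearest sample;
    additive white Gaussian noise with RMS ``spec.noise_rms`` is then
    added.  Without ground truth every spike uses a default template of
    amplitude ``spec.amplitude``.
    """
    n_samples = int(round(spec.duration * spec.fs))
    rng = np.random.default_rng([spec.seed, 3])
    if channels is None:
        channels = default_channel_layout(max(len(trains), 1))[: len(trains)]
    signal = np.zeros((len(trains), n_samples), dtype=np.float32)
    for row, train in enumerate(trains):
        ch = train.channel
        if truth is not None:
            templates = truth.templates[ch]
            labels = truth.unit_labels[ch]
        else:
            templates = [UnitTemplate(amplitude=spec.amplitude)]
            labels = np.zeros(train.n_spikes, dtype=int)
        rendered = [np.asarray(t.render(spec.fs), dtype=np.float32)
                    for t in templates]
        x = signal[row]
        for t, lab in zip(train.times, labels):
            w = rendered[int(lab) % len(rendered)]
            half = w.size // 2
            c = int(round(t * spec.fs))
            a, b = c - half, c + half + 1
            wa = max(0, -a)
            wb = w.size - max(0, b - n_samples)
            if wa < wb:
                x[max(a, 0): min(b, n_samples)] += w[wa:wb]
        if spec.noise_rms > 0:
            x += rng.normal(0.0, spec.noise_rms, n_samples).astype(np.float32)
        else:
            rng.normal(0.0, 1.0, 1)  # keep the stream position stable
    return Recording(signal=signal, fs=spec.fs, channels=channels[: len(trains)])


def tilt_event(trains: list[SpikeTrain], truth: GroundTruth, spec: SynthSpec,
               t_switch: float, affected: list[int] | None = None,
               new_templates: dict[int, list[UnitTemplate]] | None = None,
               ) -> tuple[list[SpikeTrain], GroundTruth]:
    """Emulate a magnetic tilt: affected channels contact a new neuron group.

    Spikes after ``t_switch`` on affected channels are reassigned to a
    disjoint unit set with fresh templates (or the supplied
    ``new_templates``); spike times are unchanged.  Returns the trains
    (unchanged) and an updated ground truth whose template lists hold the
    pre-tilt units first and the post-tilt units after them.
    """
    if not 0.0 < t_switch < spec.duration:
        raise ValueError(f"t_switch must lie in (0, {spec.duration})")
    affected = list(truth.templates) if affected is None else affected
    new_truth = GroundTruth(
        unit_labels=dict(truth.unit_labels),
        community_labels=dict(truth.community_labels),
        burst_windows=dict(truth.burst_windows),
        templates={ch: list(tpls) for ch, tpls in truth.templates.items()},
    )
    for ch in affected:
        if ch not in new_truth.templates:
            raise KeyError(f"channel {ch} not in ground truth")
        k = len(new_truth.templates[ch])
        if new_templates is not None:
            fresh = new_templates[ch]
        else:
            rng = np.random.default_rng([spec.seed, 4, ch])
            fresh = _unit_templates(spec, rng)
        new_truth.templates[ch] = new_truth.templates[ch] + list(fresh)
        train = next(tr for tr in trains if tr.channel == ch)
        labels = new_truth.unit_labels[ch].copy()
        post = train.times >= t_switch
        labels[post] = (labels[post] % len(fresh)) + k
        new_truth.unit_labels[ch] = labels
    return trains, new_truth
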