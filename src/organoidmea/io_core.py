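"""File formats, configuration and the end-to-end pipeline driver.

A recording lives in a single self-describing HDF5 container::

    /signal    float32, channels x samples, attribute units="uV"
    /channels  table (id, x, y, height, label)
    attrs      fs (Hz)

Spike trains and configs are JSON; metric tables are CSV; networks are
GraphML.  ``run_pipeline`` chains filtering, detection, sorting, burst
detection, synchrony scoring and network mapping, writing every artifact
plus a checksum manifest.  All stage randomness derives from one root
seed split per stage name, so a run is a pure function of (input bytes,
config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from ._types import ChannelMeta, Recording, SpikeTrain
from .activity_metrics import (
    BurstParams, ORGANOID_50MS_BURST_PARAMS, detect_bursts, isi_stats,
    spiking_rate,
)
from .spike_detection import (
    DetectionParams, bandpass, detect_spikes, extract_waveforms,
)
from .spike_sorting import SortingParams, sort_channel
from .synchrony_network import (
    SyncMatrix, SyncParams, assign_communities, build_network,
    louvain_communities, network_metrics, sync_matrix, export_network_map,
)

__all__ = [
    "FormatError",
    "PipelineConfig",
    "Recording",
    "ChannelMeta",
    "stage_seed",
    "read_recording",
    "write_recording",
    "read_spike_trains",
    "write_spike_trains",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not follow the documented container layout."""


def stage_seed(root: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2**31)."""
    ss = np.random.SeedSequence([int(root), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All stage parameters plus the root seed."""

    detection: DetectionParams = field(default_factory=DetectionParams)
    sorting: SortingParams = field(default_factory=SortingParams)
    bursts: BurstParams = field(
        default_factory=lambda: ORGANOID_50MS_BURST_PARAMS)
    synchrony: SyncParams = field(default_factory=SyncParams)
    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        return cls(
            detection=DetectionParams(**{
                **raw.get("detection", {}),
                **{k: tuple(v) for k, v in raw.get("detection", {}).items()
                   if isinstance(v, list)},
            }),
            sorting=SortingParams(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw.get("sorting", {}).items()
            }),
            bursts=BurstParams(**raw.get("bursts", {})),
            synchrony=SyncParams(**raw.get("synchrony", {})),
            seed=int(raw.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# Recording container

_CHANNEL_DTYPE = np.dtype([
    ("id", np.int64), ("x", np.float64), ("y", np.float64),
    ("height", np.float64), ("label", h5py.string_dtype()),
])


def write_recording(rec: Recording, path) -> None:
    """Write a recording to its HDF5 container."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset(
            "signal", data=np.asarray(rec.signal, dtype=np.float32))
        ds.attrs["units"] = "uV"
        table = np.empty(len(rec.channels), dtype=_CHANNEL_DTYPE)
        for i, c in enumerate(rec.channels):
            table[i] = (c.id, c.x, c.y, c.height, c.label)
        f.create_dataset("channels", data=table)
        f.attrs["fs"] = float(rec.fs)


def read_recording(path) -> Recording:
    """Read a recording container; raises :class:`FormatError` on layout errors."""
    with h5py.File(path, "r") as f:
        for name in ("signal", "channels"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset '/{name}'")
        if "fs" not in f.attrs:
            raise FormatError(f"{path}: missing attribute 'fs'")
        fs = float(f.attrs["fs"])
        if fs <= 0:
            raise FormatError(f"{path}: fs must be positive, got {fs}")
        signal = f["signal"][...]
        table = f["channels"][...]
        channels = [
            ChannelMeta(
                id=int(row["id"]), x=float(row["x"]), y=float(row["y"]),
                height=float(row["height"]),
                label=(row["label"].decode()
                       if isinstance(row["label"], bytes) else str(row["label"])),
            )
            for row in table
        ]
    return Recording(signal=signal, fs=fs, channels=channels)


# ---------------------------------------------------------------------------
# Spike-train JSON

def write_spike_trains(trains: list[SpikeTrain], path) -> None:
    """Serialize spike trains as inspectable JSON (lossless at double precision)."""
    if trains:
        T = trains[0].duration
        if any(not np.isclose(tr.duration, T) for tr in trains):
            raise ValueError("all trains must share one duration")
        for tr in trains:
            if tr.times.size and (tr.times[0] < 0 or tr.times[-1] > T):
                raise ValueError(
                    f"channel {tr.channel}: times outside [0, {T}]")
    else:
        T = None
    payload = {
        "duration": T,
        "trains": [
            {"channel": int(tr.channel), "times": tr.times.tolist()}
            for tr in trains
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_spike_trains(path) -> list[SpikeTrain]:
    raw = json.loads(Path(path).read_text())
    if "trains" not in raw:
        raise FormatError(f"{path}: missing 'trains' list")
    T = raw.get("duration")
    return [
        SpikeTrain(channel=int(tr["channel"]),
                   times=np.asarray(tr["times"], dtype=float),
                   duration=float(T))
        for tr in raw["trains"]
    ]


# ---------------------------------------------------------------------------
# Pipeline driver

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(recording_path, config: PipelineConfig, out_dir) -> dict:
    """Run filter -> detect -> sort -> bursts -> synchrony -> network.

    Writes six artifacts (spike trains, waveform clusters, burst table,
    sync matrix, network graph, per-channel metrics) under ``out_dir``
    and returns the manifest (also written as ``manifest.json``) listing
    each artifact with its SHA-256 checksum.  Deterministic given the
    config seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = read_recording(recording_path)
    logger.info("pipeline: %d channels, %.1f s at %g Hz",
                rec.n_channels, rec.duration, rec.fs)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            logger.error("pipeline stage '%s' failed: %s", name, exc)
            raise RuntimeError(f"pipeline stage '{name}' failed") from exc

    p = config.detection
    filtered = _stage("filter", bandpass, rec, p.su_band, p.notch)
    trains = _stage("detect", detect_spikes, filtered, p)
    logger.info("detect: %d spikes on %d channels",
                sum(t.n_spikes for t in trains), len(trains))

    waveforms, dropped = _stage("extract", extract_waveforms, filtered, trains, p)
    sort_params = dataclasses.replace(
        config.sorting, seed=stage_seed(config.seed, "sort"))
    by_channel: dict[int, list] = {}
    for w in waveforms:
        by_channel.setdefault(w.channel, []).append(w)
    clusters = {
        ch: _stage("sort", sort_channel, ws, sort_params)
        for ch, ws in sorted(by_channel.items())
    }

    bursts = {tr.channel: _stage("bursts", detect_bursts, tr, config.bursts)
              for tr in trains}

    sync_params = dataclasses.replace(
        config.synchrony, seed=stage_seed(config.seed, "synchrony"))
    sync = _stage("synchrony", sync_matrix, trains, sync_params)

    g = _stage("network", build_network, sync, rec.channels, sync_params)
    louv = _stage("network", louvain_communities, g,
                  stage_seed(config.seed, "louvain"))
    assign_communities(g, louv)
    net_metrics = network_metrics(g)
    g.graph.update(dataclasses.asdict(net_metrics))
    if louv.modularity is not None:
        g.graph["modularity"] = louv.modularity

    # ----- artifacts
    artifacts: dict[str, Path] = {}

    artifacts["spike_trains"] = out / "spike_trains.json"
    write_spike_trains(trains, artifacts["spike_trains"])

    artifacts["clusters"] = out / "clusters.json"
    artifacts["clusters"].write_text(json.dumps({
        str(ch): [
            {"label": c.label, "n_members": int(c.member_indices.size),
             "mean_waveform": c.mean_waveform.tolist()}
            for c in cl
        ]
        for ch, cl in clusters.items()
    }))

    artifacts["bursts"] = out / "bursts.csv"
    pd.DataFrame(
        [{"channel": b.channel, "start": b.start, "end": b.end,
          "n_spikes": b.n_spikes, "duration": b.duration}
         for bl in bursts.values() for b in bl],
        columns=["channel", "start", "end", "n_spikes", "duration"],
    ).to_csv(artifacts["bursts"], index=False)

    artifacts["sync_matrix"] = out / "sync_matrix.csv"
    pd.DataFrame(sync.scores, index=sync.active, columns=sync.active
                 ).to_csv(artifacts["sync_matrix"])

    artifacts["network"] = out / "network.graphml"
    export_network_map(g, artifacts["network"])

    artifacts["metrics"] = out / "metrics.csv"
    rows = []
    for tr in trains:
        try:
            mean_isi = isi_stats(tr)["mean"]
        except ValueError:
            mean_isi = float("nan")
        rows.append({
            "channel": tr.channel,
            "n_spikes": tr.n_spikes,
            "rate_hz": spiking_rate(tr),
            "mean_isi_s": mean_isi,
            "n_bursts": len(bursts[tr.channel]),
            "n_clusters": len(clusters.get(tr.channel, [])),
        })
    pd.DataFrame(rows).to_csv(artifacts["metrics"], index=False)

    manifest = {
        "seed": config.seed,
        "recording": str(recording_path),
        "edge_spikes_dropped": dropped,
        "network_metrics": dataclasses.asdict(net_metrics),
        "artifacts": {
            name: {"path": p.name, "sha256": _sha256(p)}
            for name, p in artifacts.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline: wrote %d artifacts to %s", len(artifacts), out)
    return manifest
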