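"""Firing-rate, interspike-interval and burst statistics.

Bursts are detected with the MaxInterval rule: a burst opens at an
interspike interval (ISI) no longer than ``max_isi_start``, extends while
ISIs stay within ``max_isi_in``, bursts separated by less than
``min_ibi`` merge, and bursts shorter than ``min_duration`` or with fewer
than ``min_spikes`` spikes are discarded.

Two parameter presets ship: ``DEFAULT_BURST_PARAMS`` carries the five
printed threshold values (300, 301, 10, 50, 200) as-is, while
``ORGANOID_50MS_BURST_PARAMS`` (300 ms, 301 ms, 50 ms, 50 ms, 10 spikes)
uses a 50 ms minimum duration and a spike minimum attainable at organoid
firing rates below ~10 Hz.  The first four parameters are interpreted as
milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._types import ChannelMeta, SpikeTrain

__all__ = [
    "BurstParams",
    "Burst",
    "DEFAULT_BURST_PARAMS",
    "ORGANOID_50MS_BURST_PARAMS",
    "spiking_rate",
    "isi_stats",
    "detect_bursts",
    "activity_by_height",
    "condition_response",
]


@dataclass(frozen=True)
class BurstParams:
    """Five MaxInterval thresholds; time parameters in milliseconds."""

    max_isi_start: float = 300.0
    max_isi_in: float = 301.0
    min_duration: float = 10.0
    min_ibi: float = 50.0
    min_spikes: int = 200

    def __post_init__(self) -> None:
        for name in ("max_isi_start", "max_isi_in", "min_duration", "min_ibi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_spikes < 1:
            raise ValueError("min_spikes must be at least 1")


DEFAULT_BURST_PARAMS = BurstParams()
ORGANOID_50MS_BURST_PARAMS = BurstParams(
    max_isi_start=300.0, max_isi_in=301.0, min_duration=50.0,
    min_ibi=50.0, min_spikes=10,
)


@dataclass(frozen=True)
class Burst:
    """A contiguous run of spikes satisfying all five thresholds."""

    channel: int
    start: float
    end: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.end - self.start


def spiking_rate(train: SpikeTrain) -> float:
    """Mean firing rate: spike count over recording duration, Hz."""
    return train.n_spikes / train.duration


def isi_stats(train: SpikeTrain) -> dict:
    """Interspike-interval summary: mean, median, SD and count (seconds).

    Raises
    ------
    ValueError
        With fewer than two spikes the ISI is undefined.
    """
    if train.n_spikes < 2:
        raise ValueError(
            f"channel {train.channel}: ISI undefined with "
            f"{train.n_spikes} spike(s)"
        )
    isis = np.diff(train.times)
    return {
        "mean": float(np.mean(isis)),
        "median": float(np.median(isis)),
        "std": float(np.std(isis, ddof=1)) if isis.size > 1 else 0.0,
        "n": int(isis.size),
    }


def detect_bursts(
    train: SpikeTrain, p: BurstParams = ORGANOID_50MS_BURST_PARAMS
) -> list[Burst]:
    """MaxInterval burst detection on one spike train.

    Returns disjoint, time-ordered bursts whose span is the first-to-last
    spike of the run.  Merged bursts (gap below ``min_ibi``) absorb any
    spikes lying between them.
    """
    t = train.times
    if t.size < 2:
        return []
    s_start = p.max_isi_start / 1000.0
    s_in = p.max_isi_in / 1000.0
    s_dur = p.min_duration / 1000.0
    s_ibi = p.min_ibi / 1000.0
    isi = np.diff(t)

    # phase 1: open at ISI <= max_isi_start, extend while ISI <= max_isi_in
    runs: list[tuple[int, int]] = []  # inclusive spike-index ranges
    i = 0
    n = t.size
    while i < n - 1:
        if isi[i] <= s_start:
            j = i + 1
            while j < n - 1 and isi[j] <= s_in:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    # phase 2: merge runs separated by less than min_ibi (intervening
    # spikes, if any, are absorbed into the merged burst)
    merged: list[tuple[int, int]] = []
    for a, b in runs:
        if merged and t[a] - t[merged[-1][1]] < s_ibi:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    # phase 3: threshold filters
    bursts = []
    for a, b in merged:
        dur = t[b] - t[a]
        n_sp = b - a + 1
        if dur >= s_dur and n_sp >= p.min_spikes:
            bursts.append(
                Burst(channel=train.channel, start=float(t[a]),
                      end=float(t[b]), n_spikes=n_sp)
            )
    return bursts


def activity_by_height(
    trains: list[SpikeTrain],
    channels: list[ChannelMeta],
    bursts: dict[int, list[Burst]] | None = None,
    burst_params: BurstParams = ORGANOID_50MS_BURST_PARAMS,
) -> pd.DataFrame:
    """Mean +/- s.e.m. spiking rate and burst count per electrode height.

    Returns a DataFrame indexed by height (um) with columns
    ``rate_mean``, ``rate_sem``, ``burst_mean``, ``burst_sem`` and ``n``
    (channels per height group).
    """
    meta = {c.id: c for c in channels}
    missing = [tr.channel for tr in trains if tr.channel not in meta]
    if missing:
        raise KeyError(f"no channel metadata for channels {missing}")
    if bursts is None:
        bursts = {tr.channel: detect_bursts(tr, burst_params) for tr in trains}
    rows = [
        {
            "height": meta[tr.channel].height,
            "rate": spiking_rate(tr),
            "n_bursts": len(bursts.get(tr.channel, [])),
        }
        for tr in trains
    ]
    df = pd.DataFrame(rows)
    out = df.groupby("height").agg(
        rate_mean=("rate", "mean"),
        rate_sem=("rate", "sem"),
        burst_mean=("n_bursts", "mean"),
        burst_sem=("n_bursts", "sem"),
        n=("rate", "size"),
    )
    return out.fillna({"rate_sem": 0.0, "burst_sem": 0.0})


def condition_response(train_pre: SpikeTrain, train_post: SpikeTrain) -> float:
    """Rate fold-change after a treatment (e.g. KCl or TTX wash-in).

    Returns ``rate_post / rate_pre``; an empty pre-treatment train gives
    ``inf`` (signalled as such rather than raising, so sweeps over many
    channels keep running).
    """
    r_pre = spiking_rate(train_pre)
    r_post = spiking_rate(train_post)
    if r_pre == 0.0:
        return float("inf")
    return r_post / r_pre
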