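"""Per-channel burst detection, well-level network bursts, network metrics.

Burst rule: maximal runs of spikes whose consecutive inter-spike intervals
do not exceed ``max_isi``; runs separated by less than the minimal
inter-burst interval (100 ms) are merged; runs with fewer than 5 spikes are
discarded. A network burst is an epoch during which at least 50% of the
well's channels have a burst open simultaneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mea import SpikeTrainSet, mean_firing_rate

__all__ = [
    "Burst",
    "NetworkBurst",
    "NetworkMetrics",
    "detect_bursts",
    "detect_bursts_all",
    "bursting_channels",
    "detect_network_bursts",
    "network_metrics",
]


@dataclass(frozen=True)
class Burst:
    channel: str
    start: float
    end: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def spike_rate(self) -> float:
        return self.n_spikes / self.duration if self.duration > 0 else math.nan


@dataclass(frozen=True)
class NetworkBurst:
    start: float
    end: float
    participating_channels: frozenset
    participation: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class NetworkMetrics:
    """Well-level network readouts. ``inter_nb_interval`` is None when
    fewer than two network bursts were observed (undefined, not zero)."""

    mfr: float
    network_burst_rate: float            # per minute
    network_burst_duration: float | None # s, mean
    inter_nb_interval: float | None      # s, mean end -> next start
    burst_spike_rate: float | None       # Hz, mean over channel bursts
    n_bursting_channels: int
    n_network_bursts: int
    duration: float
    extras: dict = field(default_factory=dict)


def detect_bursts(
    times: np.ndarray,
    channel: str = "ch",
    max_isi_ms: float = 50.0,
    min_spikes: int = 5,
    min_ibi_ms: float = 100.0,
) -> list[Burst]:
    """Group one channel's sorted spike times into bursts.

    Runs are split where an inter-spike interval exceeds ``max_isi_ms``,
    adjacent runs with a gap below ``min_ibi_ms`` are merged back, and
    groups with fewer than ``min_spikes`` spikes are dropped. Burst span is
    first-to-last member spike."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        return []
    max_isi = max_isi_ms * 1e-3
    min_ibi = min_ibi_ms * 1e-3

    breaks = np.flatnonzero(np.diff(t) > max_isi)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, t.size - 1]

    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for a, b in zip(starts[1:], ends[1:]):
        if t[a] - t[merged[-1][1]] < min_ibi:
            merged[-1][1] = int(b)
        else:
            merged.append([int(a), int(b)])

    out = []
    for a, b in merged:
        n = b - a + 1
        if n >= min_spikes:
            out.append(Burst(channel, float(t[a]), float(t[b]), n))
    return out


def detect_bursts_all(
    trains: SpikeTrainSet,
    max_isi_ms: float = 50.0,
    min_spikes: int = 5,
    min_ibi_ms: float = 100.0,
) -> dict:
    """detect_bursts applied per channel; returns {channel: [Burst]}."""
    return {
        ch: detect_bursts(t, ch, max_isi_ms, min_spikes, min_ibi_ms)
        for ch, t in trains.trains.items()
    }


def bursting_channels(
    bursts_by_channel: dict, duration: float, rate_threshold: float = 0.4
) -> set:
    """Channels whose burst rate exceeds ``rate_threshold`` (bursts/s)."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return {
        ch for ch, bl in bursts_by_channel.items() if len(bl) / duration > rate_threshold
    }


def detect_network_bursts(
    bursts_by_channel: dict,
    n_channels: int | None = None,
    participation_threshold: float = 0.5,
    merge_gap_ms: float = 100.0,
) -> list[NetworkBurst]:
    """Epochs during which at least ``participation_threshold`` of the
    well's channels have a burst open, computed by exact interval-overlap
    sweep. Epochs closer than ``merge_gap_ms`` are merged. Participating
    channels are those whose bursts intersect the epoch."""
    if n_channels is None:
        n_channels = len(bursts_by_channel)
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if not (0.0 < participation_threshold <= 1.0):
        raise ValueError("participation_threshold must be in (0, 1]")
    need = math.ceil(participation_threshold * n_channels)
    merge_gap = merge_gap_ms * 1e-3

    events: list[tuple[float, int]] = []
    for bl in bursts_by_channel.values():
        for b in bl:
            events.append((b.start, +1))
            events.append((b.end, -1))
    if not events:
        return []
    # starts before ends at identical times: abutting bursts stay "open"
    events.sort(key=lambda e: (e[0], -e[1]))

    epochs: list[list[float]] = []
    count = 0
    open_start = None
    for time, delta in events:
        count += delta
        if count >= need and open_start is None:
            open_start = time
        elif count < need and open_start is not None:
            epochs.append([open_start, time])
            open_start = None
    if open_start is not None:
        epochs.append([open_start, events[-1][0]])

    merged: list[list[float]] = []
    for a, b in epochs:
        if merged and a - merged[-1][1] < merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    out = []
    for a, b in merged:
        members = frozenset(
            ch
            for ch, bl in bursts_by_channel.items()
            if any(x.start <= b and x.end >= a for x in bl)
        )
        out.append(NetworkBurst(a, b, members, len(members) / n_channels))
    return out


def network_metrics(
    trains: SpikeTrainSet,
    bursts_by_channel: dict | None = None,
    network_bursts: list | None = None,
    rate_threshold: float = 0.4,
    **burst_kwargs,
) -> NetworkMetrics:
    """Compute the well's network readouts. If bursts / network bursts are
    not supplied they are detected with the default rules."""
    if bursts_by_channel is None:
        bursts_by_channel = detect_bursts_all(trains, **burst_kwargs)
    if network_bursts is None:
        network_bursts = detect_network_bursts(bursts_by_channel, trains.n_channels)
    duration = trains.duration

    _, mfr = mean_firing_rate(trains)
    n_nb = len(network_bursts)
    nb_rate = n_nb / (duration / 60.0)
    nb_dur = float(np.mean([nb.duration for nb in network_bursts])) if n_nb else None
    if n_nb >= 2:
        inb = float(
            np.mean([network_bursts[i + 1].start - network_bursts[i].end
                     for i in range(n_nb - 1)])
        )
    else:
        inb = None
    all_bursts = [b for bl in bursts_by_channel.values() for b in bl]
    bsr = float(np.mean([b.spike_rate for b in all_bursts])) if all_bursts else None
    return NetworkMetrics(
        mfr=mfr,
        network_burst_rate=nb_rate,
        network_burst_duration=nb_dur,
        inter_nb_interval=inb,
        burst_spike_rate=bsr,
        n_bursting_channels=len(bursting_channels(bursts_by_channel, duration,
                                                  rate_threshold)),
        n_network_bursts=n_nb,
        duration=duration,
    )
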