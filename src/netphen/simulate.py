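"""Seeded synthetic generators for every input modality of the pipeline.

Each generator returns both the simulated measurement and a ground-truth
annotation object, so detection and metric code can be validated by
round-trip: plant structure, analyse, compare. The MEA generator plants the
statistical signature of the disease-model study this package targets —
control-like and mutant-like wells with equal mean firing rate but different
network-burst statistics.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .mea import MEARecording, SpikeTrainSet

__all__ = [
    "MEASimConfig",
    "PhenotypePreset",
    "PRESETS",
    "GroundTruth",
    "CurrentSimConfig",
    "APTrainConfig",
    "FluorescenceSimConfig",
    "MorphologySimConfig",
    "generate_spike_trains",
    "generate_raw_mea",
    "generate_current_trace",
    "generate_ap_train",
    "generate_fluorescence",
    "generate_morphology",
    "spike_template",
]


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass
class MEASimConfig:
    """Parameters of the well-level spike-train simulator.

    Rates are per second; durations in seconds; amplitudes in microvolts.
    ``within_burst_rate`` is the firing rate of a participating channel
    while a burst epoch is open; background firing is Poisson over the
    whole recording. ``channel_burst_rate`` controls single-channel bursts
    that occur outside network-burst epochs.
    """

    n_channels: int = 12
    duration: float = 600.0
    sampling_rate: float = 10_000.0
    background_rate: float = 0.5
    nb_rate: float = 0.05
    nb_duration_mean: float = 1.0
    nb_duration_sd: float = 0.2
    nb_participation: float = 0.75
    within_burst_rate: float = 60.0
    channel_burst_rate: float = 0.02
    raw_waveform: bool = False
    spike_amplitude: float = 30.0
    noise_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "background_rate": self.background_rate,
            "nb_rate": self.nb_rate,
            "within_burst_rate": self.within_burst_rate,
            "channel_burst_rate": self.channel_burst_rate,
        }
        for name, value in rates.items():
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
        if not (0.0 <= self.nb_participation <= 1.0):
            raise ValueError("nb_participation must be in [0, 1]")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.nb_duration_mean <= 0:
            raise ValueError("nb_duration_mean must be > 0")

    def replace(self, **overrides) -> "MEASimConfig":
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ValueError(f"unknown MEASimConfig fields: {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)


@dataclass(frozen=True)
class PhenotypePreset:
    """Named parameter overrides encoding a network phenotype.

    The ``mutant_like`` preset raises the network-burst rate and lowers
    network-burst duration and within-burst firing, while the expected
    total per-channel firing rate is kept identical to ``control`` — the
    qualitative signature of the disease model (more frequent, shorter,
    sparser network bursts at unchanged global activity).
    """

    name: str
    overrides: dict = field(default_factory=dict)

    def apply(self, config: MEASimConfig) -> MEASimConfig:
        return config.replace(**self.overrides)


# Expected per-channel rate = background
#   + nb_rate * nb_duration * participation * within_rate   (network bursts)
#   + channel_burst_rate * nb_duration * within_rate        (lone bursts)
# control: 0.5 + 0.05*1.0*0.75*60 + 0.02*1.0*60  = 3.95 Hz
# mutant : 0.5 + 0.10*0.6*0.75*50 + 0.04*0.6*50  = 3.95 Hz
PRESETS: dict[str, PhenotypePreset] = {
    "control": PhenotypePreset("control", {}),
    "mutant_like": PhenotypePreset(
        "mutant_like",
        {
            "nb_rate": 0.10,
            "nb_duration_mean": 0.6,
            "nb_duration_sd": 0.12,
            "within_burst_rate": 50.0,
            "channel_burst_rate": 0.04,
        },
    ),
}


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic dataset (one generator each)."""

    spike_times: dict | None = None          # channel -> array of s
    nb_intervals: list | None = None         # [(start_s, end_s)]
    synaptic_events: list | None = None      # [(time_s, amplitude_pA)]
    burst_epochs: list | None = None         # [(start_s, end_s)] clustered events
    transient_times: dict | None = None      # roi -> array of s
    network_event_times: np.ndarray | None = None
    bleach_tau: float | None = None
    ap_peaks: np.ndarray | None = None       # s
    ap_threshold_crossings: np.ndarray | None = None
    ap_ahp_times: np.ndarray | None = None
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# MEA spike trains
# ---------------------------------------------------------------------------

def _poisson_times(rng: np.random.Generator, rate: float, start: float, end: float) -> np.ndarray:
    span = end - start
    if rate <= 0 or span <= 0:
        return np.empty(0)
    n = rng.poisson(rate * span)
    return np.sort(rng.uniform(start, end, size=n))


def _draw_nb_epochs(rng, rate, dur_mean, dur_sd, duration,
                    min_gap: float = 0.11) -> list[tuple[float, float]]:
    """Epoch starts form a Poisson process; an epoch arriving before the
    previous one has closed is pushed back to ``min_gap`` after it.
    The gap sits just above the 100 ms burst-merge rule, so every planted
    epoch is individually resolvable by the detection side."""
    if rate <= 0:
        return []
    epochs: list[tuple[float, float]] = []
    t = rng.exponential(1.0 / rate)
    while t < duration:
        start = t
        if epochs and start < epochs[-1][1] + min_gap:
            start = epochs[-1][1] + min_gap
        dur = max(rng.normal(dur_mean, dur_sd), 0.05)
        end = min(start + dur, duration)
        if end > start and start < duration:
            epochs.append((start, end))
        t += rng.exponential(1.0 / rate)
    return epochs


def generate_spike_trains(
    config: MEASimConfig,
    preset: PhenotypePreset | str | None = None,
    seed: int | None = None,
) -> tuple[SpikeTrainSet, GroundTruth]:
    """Simulate one MEA well as per-channel spike-time arrays.

    Network-burst epochs are drawn as an exponential-gap renewal process at
    ``nb_rate``; within each epoch a random subset of
    ``ceil(nb_participation * n_channels)`` channels fires Poisson at
    ``within_burst_rate``. Independent single-channel bursts occur at
    ``channel_burst_rate`` per channel, and Poisson background at
    ``background_rate`` runs throughout.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if preset is not None:
        config = preset.apply(config)
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    channels = [f"ch{i + 1:02d}" for i in range(config.n_channels)]
    epochs = _draw_nb_epochs(
        rng, config.nb_rate, config.nb_duration_mean, config.nb_duration_sd, config.duration
    )
    per_channel: dict[str, list[np.ndarray]] = {c: [] for c in channels}

    k = math.ceil(config.nb_participation * config.n_channels)
    for start, end in epochs:
        chosen = rng.choice(config.n_channels, size=k, replace=False)
        for idx in chosen:
            per_channel[channels[idx]].append(
                _poisson_times(rng, config.within_burst_rate, start, end)
            )

    for c in channels:
        # lone channel bursts outside the network epochs
        for b_start in _poisson_times(rng, config.channel_burst_rate, 0.0, config.duration):
            b_dur = max(rng.normal(config.nb_duration_mean, config.nb_duration_sd), 0.05)
            per_channel[c].append(
                _poisson_times(rng, config.within_burst_rate, b_start,
                               min(b_start + b_dur, config.duration))
            )
        per_channel[c].append(_poisson_times(rng, config.background_rate, 0.0, config.duration))

    trains = {}
    for c in channels:
        merged = np.sort(np.concatenate(per_channel[c])) if per_channel[c] else np.empty(0)
        trains[c] = np.unique(merged)

    train_set = SpikeTrainSet(
        trains=trains,
        duration=config.duration,
        provenance={"generator": "generate_spike_trains",
                    "preset": preset.name if preset else None,
                    **dataclasses.asdict(config)},
    )
    truth = GroundTruth(
        spike_times={c: t.copy() for c, t in trains.items()},
        nb_intervals=epochs,
        params=dataclasses.asdict(config),
    )
    return train_set, truth


# ---------------------------------------------------------------------------
# raw extracellular waveform
# ---------------------------------------------------------------------------

def spike_template(sampling_rate: float, amplitude: float, width_ms: float = 1.5) -> np.ndarray:
    """Fixed biphasic extracellular spike shape: a negative lobe followed by
    a smaller positive lobe, total width ``width_ms``, negative peak equal
    to ``-amplitude``."""
    n = max(int(round(width_ms * 1e-3 * sampling_rate)), 3)
    n_neg = max(n // 2, 1)
    t_neg = np.linspace(0.0, np.pi, n_neg, endpoint=False)
    t_pos = np.linspace(0.0, np.pi, n - n_neg)
    tpl = np.concatenate([-np.sin(t_neg), 0.4 * np.sin(t_pos)])
    return tpl * (amplitude / -tpl.min())


def generate_raw_mea(
    config: MEASimConfig,
    trains: SpikeTrainSet,
    seed: int | None = None,
) -> MEARecording:
    """Render spike trains as a raw multichannel voltage recording:
    Gaussian noise plus a fixed biphasic template at each spike time (the
    template's negative trough lands on the planted spike time)."""
    if config.spike_amplitude <= 0:
        raise ValueError("spike_amplitude must be > 0")
    rng = np.random.default_rng((config.seed + 1) if seed is None else seed)
    fs = config.sampling_rate
    n_samples = int(round(config.duration * fs))
    channels = list(trains.trains)
    signal = rng.normal(0.0, config.noise_sd, size=(len(channels), n_samples))

    tpl = spike_template(fs, config.spike_amplitude)
    trough = int(np.argmin(tpl))
    for ci, c in enumerate(channels):
        for t in trains.trains[c]:
            i0 = int(round(t * fs)) - trough
            a, b = max(i0, 0), min(i0 + tpl.size, n_samples)
            if b > a:
                signal[ci, a:b] += tpl[a - i0:b - i0]

    return MEARecording(
        signal=signal.astype(np.float32),
        sampling_rate=fs,
        channel_ids=channels,
        well_id="sim",
        metadata={"generator": "generate_raw_mea", "noise_sd": config.noise_sd,
                  "spike_amplitude": config.spike_amplitude},
    )


# ---------------------------------------------------------------------------
# synaptic current traces
# ---------------------------------------------------------------------------

@dataclass
class CurrentSimConfig:
    """Voltage-clamp current-trace simulator (inward events are negative).

    Events are a Poisson process with log-normal amplitudes convolved with
    a normalized double-exponential kernel; clustered epochs plant runs of
    >= 3 events with gaps <= 50 ms, at least one exceeding 100 pA."""

    duration: float = 60.0
    sampling_rate: float = 10_000.0
    event_rate: float = 1.0
    amp_median: float = 30.0
    amp_sigma: float = 0.5
    rise_ms: float = 0.5
    decay_ms: float = 3.0
    burst_rate: float = 0.05
    burst_n_events: int = 4
    burst_gap_ms: tuple = (5.0, 45.0)
    burst_big_amp: float = 130.0
    noise_sd: float = 2.0
    baseline: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.decay_ms <= self.rise_ms:
            raise ValueError("decay_ms must exceed rise_ms")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be > 0")
        for name in ("event_rate", "burst_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def epsc_kernel(sampling_rate: float, rise_ms: float, decay_ms: float) -> np.ndarray:
    """Double-exponential kernel normalized to unit peak."""
    tau_r, tau_d = rise_ms * 1e-3, decay_ms * 1e-3
    t = np.arange(0.0, 8.0 * tau_d, 1.0 / sampling_rate)
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    return k / k.max()


def generate_current_trace(
    config: CurrentSimConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Return (time_s, current_pA, ground truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs

    events: list[tuple[float, float]] = []
    for et in _poisson_times(rng, config.event_rate, 0.0, config.duration):
        events.append((et, rng.lognormal(np.log(config.amp_median), config.amp_sigma)))

    epochs: list[tuple[float, float]] = []
    for b0 in _poisson_times(rng, config.burst_rate, 0.0, config.duration - 1.0):
        gaps = rng.uniform(*config.burst_gap_ms, size=config.burst_n_events - 1) * 1e-3
        times = b0 + np.concatenate([[0.0], np.cumsum(gaps)])
        amps = rng.lognormal(np.log(config.amp_median), config.amp_sigma,
                             size=config.burst_n_events)
        amps[rng.integers(config.burst_n_events)] = config.burst_big_amp
        events.extend(zip(times.tolist(), amps.tolist()))
        epochs.append((float(times[0]), float(times[-1])))

    events.sort()
    trace = np.full(n, config.baseline, dtype=float)
    kernel = epsc_kernel(fs, config.rise_ms, config.decay_ms)
    for et, amp in events:
        i0 = int(round(et * fs))
        if i0 >= n:
            continue
        b = min(i0 + kernel.size, n)
        trace[i0:b] -= amp * kernel[: b - i0]
    if config.noise_sd > 0:
        trace += rng.normal(0.0, config.noise_sd, size=n)

    truth = GroundTruth(synaptic_events=events, burst_epochs=epochs,
                        params=dataclasses.asdict(config))
    return t, trace, truth


# ---------------------------------------------------------------------------
# action-potential trains
# ---------------------------------------------------------------------------

@dataclass
class APTrainConfig:
    """Parametric current-clamp sweep: resting segment, then a train of
    stylized action potentials at the given inter-spike intervals, riding
    on a depolarized baseline (as during step current injection)."""

    isi_ms: tuple = tuple([20.0] * 9)       # 9 ISIs -> 10 APs
    sampling_rate: float = 20_000.0
    v_rest: float = -65.0
    v_base: float = -45.0                   # inter-spike baseline during the step
    threshold: float = -40.0
    peak: float = 30.0
    ahp: float = -55.0                      # most hyperpolarized post-spike value
    rise_ms: float = 1.0
    fall_ms: float = 1.5
    ahp_tau_ms: float = 5.0
    pre_s: float = 0.2                      # resting segment before the step
    post_s: float = 0.1

    def validate(self) -> None:
        if self.peak <= self.threshold:
            raise ValueError("peak must exceed threshold")
        if self.ahp >= self.threshold:
            raise ValueError("ahp must lie below threshold")
        if any(isi <= self.rise_ms + self.fall_ms for isi in self.isi_ms):
            raise ValueError("ISIs must exceed the AP rise+fall time")


def generate_ap_train(
    config: APTrainConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Return (time_s, voltage_mV, ground truth with AP annotations).

    Each AP: linear rise threshold->peak over ``rise_ms``, linear fall
    peak->ahp over ``fall_ms``, exponential recovery ahp->v_base. The
    generator is deterministic; ``seed`` is accepted for API symmetry."""
    config.validate()
    fs = config.sampling_rate
    peaks_s = config.pre_s + config.rise_ms * 1e-3 + np.concatenate(
        [[0.0], np.cumsum(np.asarray(config.isi_ms) * 1e-3)]
    )
    total = peaks_s[-1] + config.post_s
    n = int(round(total * fs))
    t = np.arange(n) / fs
    v = np.full(n, config.v_base)
    v[t < config.pre_s] = config.v_rest

    rise, fall = config.rise_ms * 1e-3, config.fall_ms * 1e-3
    tau = config.ahp_tau_ms * 1e-3
    thr_times, ahp_times = [], []
    for pk in peaks_s:
        thr_times.append(pk - rise)
        ahp_times.append(pk + fall)
        m = t >= pk + fall
        v[m] = config.v_base + (config.ahp - config.v_base) * np.exp(
            -(t[m] - (pk + fall)) / tau
        )
    # rise/fall segments last, so the recovery of AP i never overwrites AP i+1
    for pk in peaks_s:
        m = (t >= pk - rise) & (t < pk)
        v[m] = config.threshold + (config.peak - config.threshold) * (t[m] - (pk - rise)) / rise
        m = (t >= pk) & (t < pk + fall)
        v[m] = config.peak + (config.ahp - config.peak) * (t[m] - pk) / fall

    truth = GroundTruth(
        ap_peaks=peaks_s,
        ap_threshold_crossings=np.asarray(thr_times),
        ap_ahp_times=np.asarray(ahp_times),
        params=dataclasses.asdict(config),
    )
    return t, v, truth


# ---------------------------------------------------------------------------
# ROI fluorescence
# ---------------------------------------------------------------------------

@dataclass
class FluorescenceSimConfig:
    """Somatic calcium-fluorescence simulator.

    F(t) = [F0 + sum of transients] * exp(-t / bleach_tau) + noise,
    sampled at ``frame_rate``. Network events are shared across a random
    ``participation`` fraction of ROIs; each ROI may also fire alone."""

    n_rois: int = 20
    duration: float = 120.0
    frame_rate: float = 10.0
    f0: float = 100.0
    transient_amp: float = 50.0
    transient_decay_s: float = 1.0
    network_rate: float = 0.1
    participation: float = 1.0
    roi_rate: float = 0.0
    min_event_gap: float = 5.0   # s; ~5 decay constants so transients fully
                                 # separate — closer events are unresolvable
                                 # by a level-crossing detector by design
    bleach_tau: float = 60.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.bleach_tau <= 0:
            raise ValueError("bleach_tau must be > 0")
        if self.f0 <= 0:
            raise ValueError("f0 must be > 0")
        if not (0.0 <= self.participation <= 1.0):
            raise ValueError("participation must be in [0, 1]")


def generate_fluorescence(
    config: FluorescenceSimConfig, seed: int | None = None
) -> tuple[np.ndarray, "np.ndarray", GroundTruth]:
    """Return (time_s, F array of shape (n_rois, n_frames), ground truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_frames = int(round(config.duration * config.frame_rate))
    t = np.arange(n_frames) / config.frame_rate

    net_times = _poisson_times(rng, config.network_rate, 0.0, config.duration)
    if net_times.size and config.min_event_gap > 0:
        kept = [net_times[0]]
        for et in net_times[1:]:
            if et - kept[-1] >= config.min_event_gap:
                kept.append(et)
        net_times = np.asarray(kept)
    k = math.ceil(config.participation * config.n_rois)
    roi_events: dict[str, list[float]] = {f"roi{i + 1}": [] for i in range(config.n_rois)}
    for et in net_times:
        for idx in rng.choice(config.n_rois, size=k, replace=False):
            roi_events[f"roi{idx + 1}"].append(float(et))
    for name in roi_events:
        roi_events[name].extend(
            _poisson_times(rng, config.roi_rate, 0.0, config.duration).tolist()
        )

    F = np.empty((config.n_rois, n_frames))
    bleach = np.exp(-t / config.bleach_tau)
    for i, name in enumerate(roi_events):
        roi_events[name] = sorted(roi_events[name])
        f = np.full(n_frames, config.f0)
        for et in roi_events[name]:
            m = t >= et
            f[m] += config.transient_amp * np.exp(-(t[m] - et) / config.transient_decay_s)
        F[i] = f * bleach
    if config.noise_sd > 0:
        F += rng.normal(0.0, config.noise_sd, size=F.shape)

    truth = GroundTruth(
        transient_times={k2: np.asarray(v) for k2, v in roi_events.items()},
        network_event_times=net_times,
        bleach_tau=config.bleach_tau,
        params=dataclasses.asdict(config),
    )
    return t, F, truth


# ---------------------------------------------------------------------------
# morphology (SWC trees)
# ---------------------------------------------------------------------------

@dataclass
class MorphologySimConfig:
    """Random binary dendritic tree with an exact total-length budget."""

    n_primary: int = 3
    total_length: float = 1000.0
    branch_prob: float = 0.35
    step: float = 10.0
    wiggle: float = 0.15          # radians of per-step direction jitter; 0 = straight
    soma_radius: float = 6.0
    min_branch_length: float = 25.0
    seed: int = 0

    def validate(self) -> None:
        if self.total_length <= 0:
            raise ValueError("total_length must be > 0")
        if self.n_primary < 1:
            raise ValueError("n_primary must be >= 1")


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perturb(rng, direction: np.ndarray, angle: float) -> np.ndarray:
    if angle <= 0:
        return direction
    v = direction + rng.normal(scale=angle, size=3)
    return v / np.linalg.norm(v)


def generate_morphology(config: MorphologySimConfig, seed: int | None = None) -> str:
    """Generate a random neuron as SWC text (single soma root, dendrites
    typed 3). Path length along the tree equals ``total_length`` up to
    floating-point rounding; geometry is piecewise straight with per-step
    jitter of ``wiggle`` radians."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    rows: list[tuple[int, int, float, float, float, float, int]] = [
        (1, 1, 0.0, 0.0, 0.0, config.soma_radius, -1)
    ]
    next_id = [2]

    def grow(budget: float, origin: np.ndarray, direction: np.ndarray, parent: int) -> None:
        # length of the stem before a potential branch point
        if budget >= 2 * config.min_branch_length and rng.random() < config.branch_prob:
            stem = budget * rng.uniform(0.25, 0.5)
        else:
            stem = budget
        n_steps = max(int(math.ceil(stem / config.step)), 1)
        step_len = stem / n_steps
        pos, d, par = origin.copy(), direction.copy(), parent
        for _ in range(n_steps):
            d = _perturb(rng, d, config.wiggle)
            pos = pos + step_len * d
            rows.append((next_id[0], 3, pos[0], pos[1], pos[2], 0.5, par))
            par = next_id[0]
            next_id[0] += 1
        rest = budget - stem
        if rest > 0:
            frac = rng.uniform(0.3, 0.7)
            for child_budget in (rest * frac, rest * (1 - frac)):
                cd = _perturb(rng, d, max(config.wiggle, 0.5))
                grow(child_budget, pos, cd, par)

    if config.n_primary == 1:
        shares = np.array([1.0])
    else:
        shares = rng.dirichlet(np.full(config.n_primary, 8.0))
    for share in shares:
        grow(config.total_length * share, np.zeros(3), _random_unit(rng), 1)

    lines = ["# synthetic neuron reconstruction", "# id type x y z radius parent"]
    for r in rows:
        lines.append(f"{r[0]} {r[1]} {r[2]:.4f} {r[3]:.4f} {r[4]:.4f} {r[5]:.4f} {r[6]}")
    return "\n".join(lines) + "\n"
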