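"""Patch-clamp analysis: synaptic-event detection, burst classification of
correlated synaptic inputs, intrinsic membrane / action-potential
properties, and recording quality control.

Synaptic events are inward (negative) postsynaptic currents recorded in
voltage clamp at a nominal holding potential of -60 mV; amplitudes are
reported as positive magnitudes. An event burst is a run of at least 3
consecutive events with inter-onset gaps of at most 50 ms, of which at
least one exceeds 100 pA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal as sps

__all__ = [
    "CurrentTrace",
    "SynapticEvent",
    "EventBurst",
    "IntrinsicProperties",
    "QCResult",
    "detect_events",
    "group_event_bursts",
    "event_statistics",
    "adaptation_ratio",
    "ap_features",
    "input_resistance",
    "membrane_tau",
    "intrinsic_properties",
    "qc_filter",
]


@dataclass
class CurrentTrace:
    """Uniformly sampled membrane current (pA)."""

    samples: np.ndarray
    sampling_rate: float
    holding_potential: float = -60.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class SynapticEvent:
    onset: float     # s, threshold crossing
    peak: float      # s, trough time
    amplitude: float # pA, positive magnitude of the inward deflection

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.peak < self.onset:
            raise ValueError("peak must not precede onset")


@dataclass(frozen=True)
class EventBurst:
    events: tuple
    start: float
    end: float
    max_amplitude: float

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class IntrinsicProperties:
    vrmp: float | None = None             # mV
    input_resistance: float | None = None # MOhm
    membrane_tau: float | None = None     # ms
    adaptation_ratio: float | None = None
    ahp_time: float | None = None         # ms
    ap_half_time: float | None = None     # ms
    series_resistance: float | None = None


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: str | None = None


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Median-filter baseline with reflection padding; computed on a
    decimated copy for long traces."""
    window = max(window | 1, 3)
    step = max(window // 41, 1)
    sub = x[::step]
    w = min(max((window // step) | 1, 3), (sub.size - 1) | 1 if sub.size > 1 else 3)
    pad = w // 2
    med = sps.medfilt(np.pad(sub, pad, mode="reflect"), kernel_size=w)
    med = med[pad:pad + sub.size]
    if step == 1:
        return med
    return np.interp(np.arange(x.size), np.arange(0, x.size, step), med)


def detect_events(
    trace: CurrentTrace,
    min_amplitude_pA: float,
    smoothing_ms: float = 200.0,
    noise_k: float = 3.0,
) -> list[SynapticEvent]:
    """Detect inward postsynaptic-current events.

    The baseline is tracked with a running median of width ``smoothing_ms``;
    deflections below baseline exceeding max(``min_amplitude_pA``,
    ``noise_k`` x robust noise SD) become events. Onset is the threshold
    crossing, amplitude the baseline-to-trough magnitude.
    """
    if min_amplitude_pA <= 0:
        raise ValueError("min_amplitude_pA must be > 0")
    fs = trace.sampling_rate
    window = int(round(smoothing_ms * 1e-3 * fs))
    if window < 3:
        raise ValueError("smoothing window shorter than 3 samples at this sampling rate")
    v = trace.samples
    baseline = _running_median(v, window)
    resid = v - baseline
    noise_sd = float(np.median(np.abs(resid)) / 0.6745)
    threshold = max(min_amplitude_pA, noise_k * noise_sd)

    # light low-pass for the crossing detector only; amplitudes are read
    # from the raw trace so they stay unbiased
    lp = max(int(round(0.3e-3 * fs)), 1)
    det = np.convolve(resid, np.ones(lp) / lp, mode="same") if lp > 1 else resid

    below = det < -threshold
    if not below.any():
        return []
    idx = np.flatnonzero(below)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.r_[idx[0], idx[breaks + 1]]
    run_ends = np.r_[idx[breaks], idx[-1]]
    # noise re-crossings around one event: merge runs separated by < 1 ms
    min_gap = int(round(1e-3 * fs))
    merged = [[int(run_starts[0]), int(run_ends[0])]]
    for a, b in zip(run_starts[1:], run_ends[1:]):
        if a - merged[-1][1] < min_gap:
            merged[-1][1] = int(b)
        else:
            merged.append([int(a), int(b)])
    events = []
    for a, b in merged:
        trough = a + int(np.argmin(det[a:b + 1]))
        amp = float(-det[trough])
        events.append(SynapticEvent(onset=a / fs, peak=trough / fs, amplitude=amp))
    return events


def group_event_bursts(
    events: list,
    n_min: int = 3,
    max_gap_ms: float = 50.0,
    amp_threshold_pA: float = 100.0,
) -> list[EventBurst]:
    """Group time-sorted synaptic events into bursts: maximal runs with
    consecutive onset gaps <= ``max_gap_ms``, keeping runs with at least
    ``n_min`` events of which at least one exceeds ``amp_threshold_pA``."""
    if not events:
        return []
    onsets = np.asarray([e.onset for e in events])
    if np.any(np.diff(onsets) < 0):
        raise ValueError("events must be time-sorted")
    max_gap = max_gap_ms * 1e-3
    breaks = np.flatnonzero(np.diff(onsets) > max_gap)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, len(events) - 1]
    out = []
    for a, b in zip(starts, ends):
        run = tuple(events[a:b + 1])
        max_amp = max(e.amplitude for e in run)
        if len(run) >= n_min and max_amp > amp_threshold_pA:
            out.append(EventBurst(run, run[0].onset, run[-1].onset, max_amp))
    return out


def event_statistics(events: list, duration: float) -> dict:
    """Event frequency (Hz), mean amplitude (pA) and the sorted amplitude
    sample for cumulative-distribution comparisons."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    amps = np.asarray([e.amplitude for e in events])
    return {
        "frequency_hz": len(events) / duration,
        "mean_amplitude_pA": float(amps.mean()) if amps.size else None,
        "amplitudes_pA": np.sort(amps),
    }


# ---------------------------------------------------------------------------
# intrinsic properties
# ---------------------------------------------------------------------------

def ap_features(
    time: np.ndarray,
    voltage: np.ndarray,
    dvdt_threshold: float = 10.0,
    min_peak_mV: float = 0.0,
) -> dict:
    """Locate action potentials in a current-clamp sweep.

    Returns peak times/values, per-AP threshold (potential where dV/dt
    first exceeds ``dvdt_threshold`` mV/ms before the peak) and the AHP
    minimum between successive APs (and after the last)."""
    t = np.asarray(time, dtype=float)
    v = np.asarray(voltage, dtype=float)
    dt_ms = (t[1] - t[0]) * 1e3
    peaks, _ = sps.find_peaks(v, height=min_peak_mV)
    dvdt = np.gradient(v) / dt_ms
    thr_idx, thr_val = [], []
    prev_peak = 0
    for pk in peaks:
        seg = np.flatnonzero(dvdt[prev_peak:pk] > dvdt_threshold)
        i = prev_peak + seg[0] if seg.size else pk
        thr_idx.append(i)
        thr_val.append(v[i])
        prev_peak = pk
    ahp_idx = []
    for j, pk in enumerate(peaks):
        nxt = peaks[j + 1] if j + 1 < len(peaks) else v.size
        seg = v[pk:nxt]
        ahp_idx.append(pk + int(np.argmin(seg)))
    return {
        "peak_times": t[peaks],
        "peak_values": v[peaks],
        "threshold_times": t[np.asarray(thr_idx, dtype=int)] if len(thr_idx) else np.empty(0),
        "threshold_values": np.asarray(thr_val),
        "ahp_times": t[np.asarray(ahp_idx, dtype=int)] if len(ahp_idx) else np.empty(0),
        "ahp_values": v[np.asarray(ahp_idx, dtype=int)] if len(ahp_idx) else np.empty(0),
    }


def adaptation_ratio(peak_times: np.ndarray) -> float | None:
    """Spike-frequency adaptation as (t9 - t8) / (t3 - t2) with 1-based AP
    numbering; None (missing) when fewer than 9 APs are present."""
    pt = np.asarray(peak_times, dtype=float)
    if pt.size < 9:
        return None
    return float((pt[8] - pt[7]) / (pt[2] - pt[1]))


def input_resistance(delta_v_mV: float, delta_i_pA: float) -> float:
    """R_in = dV/dI in MOhm (mV / nA); e.g. a -10 mV step evoking
    -100 pA gives 100 MOhm."""
    if delta_i_pA == 0:
        raise ValueError("delta_i_pA must be non-zero")
    return float(delta_v_mV / (delta_i_pA * 1e-3))


def membrane_tau(
    time: np.ndarray, trace: np.ndarray, step_onset: float, fit_span: float = 0.1
) -> float | None:
    """Membrane time constant (ms) from a mono-exponential fit of the step
    transient starting at ``step_onset``."""
    t = np.asarray(time, dtype=float)
    y = np.asarray(trace, dtype=float)
    m = (t >= step_onset) & (t <= step_onset + fit_span)
    ts, ys = t[m] - step_onset, y[m]
    if ts.size < 5:
        return None
    y_inf = float(np.mean(ys[-max(ts.size // 10, 1):]))
    a0 = float(ys[0] - y_inf)
    if a0 == 0:
        return None
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, tau, c: a * np.exp(-x / tau) + c,
            ts, ys, p0=(a0, fit_span / 5, y_inf), maxfev=5000,
        )
    except RuntimeError:
        warnings.warn("membrane tau fit did not converge")
        return None
    return float(abs(popt[1]) * 1e3)


def intrinsic_properties(
    ap_time: np.ndarray | None = None,
    ap_voltage: np.ndarray | None = None,
    pre_stim_s: float = 0.0,
    passive_step_mV: float = -10.0,
    passive_delta_i_pA: float | None = None,
    passive_time: np.ndarray | None = None,
    passive_trace: np.ndarray | None = None,
    passive_step_onset: float | None = None,
    series_resistance: float | None = None,
) -> IntrinsicProperties:
    """Assemble the intrinsic-property panel from a current-clamp AP sweep
    and a -10 mV passive voltage step.

    Vrmp is the mean pre-stimulus potential; R_in = dV/dI from the passive
    step; the adaptation ratio needs >= 9 APs (else missing); AHP time runs
    from the repolarization's crossing of the AP threshold potential to the
    AHP minimum; AP half-time from the peak to 50% of the peak-to-AHP drop.
    AHP-derived metrics are averaged over APs with a resolvable AHP.
    """
    props = IntrinsicProperties(series_resistance=series_resistance)

    if passive_delta_i_pA is not None:
        props.input_resistance = input_resistance(passive_step_mV, passive_delta_i_pA)
    if passive_time is not None and passive_trace is not None and passive_step_onset is not None:
        props.membrane_tau = membrane_tau(passive_time, passive_trace, passive_step_onset)

    if ap_time is None or ap_voltage is None:
        return props
    t = np.asarray(ap_time, dtype=float)
    v = np.asarray(ap_voltage, dtype=float)
    if pre_stim_s > 0:
        props.vrmp = float(np.mean(v[t < pre_stim_s]))
    feats = ap_features(t, v)
    peaks = feats["peak_times"]
    props.adaptation_ratio = adaptation_ratio(peaks)

    ahp_times_ms, half_times_ms = [], []
    fs = 1.0 / (t[1] - t[0])
    for j, pk_t in enumerate(peaks):
        pk_i = int(round(pk_t * fs))
        ahp_t = feats["ahp_times"][j]
        ahp_i = int(round(ahp_t * fs))
        if ahp_i <= pk_i:
            continue
        thr_v = feats["threshold_values"][j]
        seg = v[pk_i:ahp_i + 1]
        cross = np.flatnonzero(seg <= thr_v)
        if cross.size:
            ahp_times_ms.append((ahp_t - t[pk_i + cross[0]]) * 1e3)
        half_level = feats["peak_values"][j] - 0.5 * (feats["peak_values"][j]
                                                     - feats["ahp_values"][j])
        half = np.flatnonzero(seg <= half_level)
        if half.size:
            half_times_ms.append((t[pk_i + half[0]] - pk_t) * 1e3)
    props.ahp_time = float(np.mean(ahp_times_ms)) if ahp_times_ms else None
    props.ap_half_time = float(np.mean(half_times_ms)) if half_times_ms else None
    return props


def qc_filter(series_resistance: float, membrane_resistance: float) -> QCResult:
    """Recording quality control: fail when series resistance exceeds
    25 MOhm or the membrane-to-series resistance ratio drops below 10.

    The source protocol prints the ratio criterion as "10:0", which is
    arithmetically degenerate; it is implemented as the 10:1 reading."""
    if series_resistance <= 0 or membrane_resistance <= 0:
        raise ValueError("resistances must be > 0")
    if series_resistance > 25.0:
        return QCResult(False, f"series resistance {series_resistance:.1f} MOhm > 25 MOhm")
    ratio = membrane_resistance / series_resistance
    if ratio < 10.0:
        return QCResult(False, f"membrane/series resistance ratio {ratio:.2f} < 10")
    return QCResult(True, None)
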