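"""Calcium-imaging analysis: bleach correction, ΔF/F, transient detection
and ROI synchrony.

The processing order is fixed: correct photobleaching first (divide by the
normalized mono-exponential baseline fit), then define F0 on the corrected
trace and form ΔF/F = (F − F0)/F0. The multiplicative correction keeps
ΔF/F invariant to any positive rescaling of the raw fluorescence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal as sps

__all__ = [
    "ROITraceSet",
    "BleachFit",
    "correct_bleaching",
    "delta_f_over_f",
    "detect_transients",
    "synchrony",
    "analyze_roi_set",
]


@dataclass
class ROITraceSet:
    """Fluorescence time series of hand-placed somatic ROIs (a.u.)."""

    traces: np.ndarray            # (n_rois, n_frames)
    frame_rate: float = 10.0
    roi_ids: list | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("fluorescence traces must be finite")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.roi_ids is None:
            self.roi_ids = [f"roi{i + 1}" for i in range(self.traces.shape[0])]

    @property
    def n_rois(self) -> int:
        return self.traces.shape[0]

    @property
    def duration(self) -> float:
        return self.traces.shape[1] / self.frame_rate


@dataclass(frozen=True)
class BleachFit:
    tau: float          # s; inf when no decay was correctable
    amplitude: float
    offset: float
    corrected: bool


def _medfilt_reflect(x: np.ndarray, w: int) -> np.ndarray:
    """Running median with reflection padding (plain medfilt zero-pads,
    which corrupts estimates near the trace boundaries)."""
    w = min(max(w | 1, 3), (x.size - 1) | 1 if x.size > 1 else 3)
    pad = w // 2
    xp = np.pad(x, pad, mode="reflect")
    return sps.medfilt(xp, kernel_size=w)[pad:xp.size - pad]


def _baseline_mask(f: np.ndarray, frame_rate: float, window_s: float = 10.0) -> np.ndarray:
    """Frames at or below the running 50th percentile — transient-poor
    samples used for the bleach fit."""
    med = _medfilt_reflect(f, int(round(window_s * frame_rate)))
    return f <= med


def correct_bleaching(
    trace: np.ndarray,
    frame_rate: float,
    min_frames: int = 100,
) -> tuple[np.ndarray, BleachFit]:
    """Fit a·exp(−t/τ)+c to baseline frames and divide the trace by the
    fit normalized to its initial value, flattening the baseline.

    Degenerate cases (constant trace, <1% fitted decay over the record,
    non-convergent fit) fall back to no correction with τ = inf."""
    f = np.asarray(trace, dtype=float)
    if f.size < min_frames:
        raise ValueError(f"need at least {min_frames} frames, got {f.size}")
    t = np.arange(f.size) / frame_rate
    mask = _baseline_mask(f, frame_rate)
    tb, fb = t[mask], f[mask]

    span = t[-1]
    if np.ptp(fb) == 0.0:
        return f.copy(), BleachFit(math.inf, 0.0, float(fb[0]), False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                lambda x, a, tau, c: a * np.exp(-x / tau) + c,
                tb, fb,
                p0=(float(fb[0] - fb[-1]), span / 2.0, float(fb[-1])),
                maxfev=10000,
            )
    except (RuntimeError, ValueError):
        warnings.warn("bleach fit did not converge; trace left uncorrected")
        return f.copy(), BleachFit(math.inf, 0.0, float(np.median(fb)), False)
    a, tau, c = float(popt[0]), float(abs(popt[1])), float(popt[2])
    fit0 = a + c
    fit_end = a * math.exp(-span / tau) + c
    if fit0 <= 0 or abs(fit_end / fit0 - 1.0) < 0.01:
        return f.copy(), BleachFit(math.inf, a, c, False)
    g = (a * np.exp(-t / tau) + c) / fit0
    return f / g, BleachFit(tau, a, c, True)


def delta_f_over_f(
    corrected: np.ndarray, f0: float | None = None, f0_percentile: float = 10.0
) -> tuple[np.ndarray, float]:
    """ΔF/F = (F − F0)/F0 with F0 the lower ``f0_percentile`` of the
    corrected trace unless given explicitly."""
    f = np.asarray(corrected, dtype=float)
    if f0 is None:
        f0 = float(np.percentile(f, f0_percentile))
    if f0 <= 0:
        raise ValueError(f"F0 must be > 0, got {f0}")
    return (f - f0) / f0, f0


def detect_transients(
    dff: np.ndarray,
    frame_rate: float,
    k_sd: float = 3.0,
    refractory_s: float = 0.5,
    sd_floor: float = 0.01,
    local_window_s: float = 15.0,
) -> np.ndarray:
    """Onset times (s) of calcium transients.

    The trace is referenced to a running median (which tracks slow decay
    tails and any residual baseline drift — bleach-corrected noise grows
    toward the end of a recording); onsets are upward crossings of
    k_sd × the time-local robust noise SD (floored at ``sd_floor`` ΔF/F
    for noiseless traces), with a refractory period and hysteresis against
    re-triggering."""
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    x = np.asarray(dff, dtype=float)
    w = int(round(local_window_s * frame_rate))
    resid = x - _medfilt_reflect(x, w)
    local_sd = _medfilt_reflect(np.abs(resid), w) / 0.6745
    thr = k_sd * np.maximum(local_sd, sd_floor)

    onsets = []
    last = -math.inf
    armed = True
    for i, val in enumerate(resid):
        if armed and val > thr[i]:
            t = i / frame_rate
            if t - last >= refractory_s:
                onsets.append(t)
                last = t
            armed = False
        elif not armed and val < thr[i] / 3.0:
            armed = True
    return np.asarray(onsets)


def synchrony(
    events_by_roi: dict,
    frame_rate: float,
    duration: float,
    participation: float = 0.5,
    window_frames: int = 1,
) -> dict:
    """Coincidence-based network synchrony across ROIs.

    A frame where at least ``ceil(participation × n_rois)`` ROIs have an
    onset within ±``window_frames`` counts toward one synchronous event
    (consecutive qualifying frames collapse into one). Returns the rate
    per minute, event times and per-event participation. With fewer than
    two ROIs synchrony is undefined (rate None)."""
    n_rois = len(events_by_roi)
    if n_rois < 2:
        return {"rate_per_min": None, "event_times": np.empty(0),
                "participation": np.empty(0)}
    n_frames = int(round(duration * frame_rate))
    need = math.ceil(participation * n_rois)

    counts = np.zeros(n_frames, dtype=int)
    marks = np.zeros((n_rois, n_frames), dtype=bool)
    for i, (_, onsets) in enumerate(sorted(events_by_roi.items())):
        for t in np.asarray(onsets):
            fr = int(round(t * frame_rate))
            a = max(fr - window_frames, 0)
            b = min(fr + window_frames + 1, n_frames)
            marks[i, a:b] = True
    counts = marks.sum(axis=0)

    qualifying = counts >= need
    if not qualifying.any():
        return {"rate_per_min": 0.0, "event_times": np.empty(0),
                "participation": np.empty(0)}
    idx = np.flatnonzero(qualifying)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    times = starts / frame_rate
    parts = np.array([counts[a:b + 1].max() / n_rois for a, b in zip(starts, ends)])
    rate = len(starts) / (duration / 60.0)
    return {"rate_per_min": rate, "event_times": times, "participation": parts}


def analyze_roi_set(
    rois: ROITraceSet,
    f0_percentile: float = 10.0,
    k_sd: float = 3.0,
    participation: float = 0.5,
    window_frames: int = 1,
) -> dict:
    """Full chain per ROI set: bleach-correct → ΔF/F → transients →
    synchrony. Returns dict with dff array, fits, events and synchrony."""
    dff = np.empty_like(rois.traces)
    fits, f0s, events = [], [], {}
    for i, roi in enumerate(rois.roi_ids):
        corrected, fit = correct_bleaching(rois.traces[i], rois.frame_rate)
        d, f0 = delta_f_over_f(corrected, f0_percentile=f0_percentile)
        dff[i] = d
        fits.append(fit)
        f0s.append(f0)
        events[roi] = detect_transients(d, rois.frame_rate, k_sd=k_sd)
    sync = synchrony(events, rois.frame_rate, rois.duration,
                     participation=participation, window_frames=window_frames)
    return {"dff": dff, "bleach_fits": fits, "f0": f0s, "events": events,
            "synchrony": sync}
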