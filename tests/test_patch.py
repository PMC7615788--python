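"""Synaptic event detection, burst classification, intrinsic properties
and recording QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import oracle_event_bursts
from netphen.patch import (
    CurrentTrace,
    SynapticEvent,
    adaptation_ratio,
    detect_events,
    event_statistics,
    group_event_bursts,
    input_resistance,
    intrinsic_properties,
    membrane_tau,
    qc_filter,
)
from netphen.simulate import (
    APTrainConfig,
    CurrentSimConfig,
    epsc_kernel,
    generate_ap_train,
    generate_current_trace,
)

FS = 10_000.0


def make_events(onsets_ms, amps):
    return [SynapticEvent(o * 1e-3, o * 1e-3 + 1e-3, a)
            for o, a in zip(onsets_ms, amps)]


class TestDetectEvents:
    def _trace_with_events(self, times, amps, dur=10.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(dur * FS)
        v = rng.normal(0.0, noise, n) if noise else np.zeros(n)
        kernel = epsc_kernel(FS, 0.5, 3.0)
        for t, a in zip(times, amps):
            i0 = int(t * FS)
            v[i0:i0 + kernel.size] -= a * kernel[: n - i0]
        return CurrentTrace(v, FS)

    def test_noiseless_planted_events_recovered(self):
        times = [1.0, 2.5, 4.0, 6.0, 8.0]
        trace = self._trace_with_events(times, [50.0] * 5)
        ev = detect_events(trace, min_amplitude_pA=20.0)
        assert len(ev) == 5
        for e, t in zip(ev, times):
            assert e.amplitude == pytest.approx(50.0, rel=0.05)
            assert e.onset == pytest.approx(t, abs=2e-3)

    def test_flat_trace_has_no_events(self):
        assert detect_events(CurrentTrace(np.zeros(50000), FS), 10.0) == []

    def test_sub_threshold_event_not_reported(self):
        trace = self._trace_with_events([2.0, 5.0], [50.0, 8.0])
        ev = detect_events(trace, min_amplitude_pA=20.0)
        assert len(ev) == 1

    def test_recall_and_amplitude_bias_at_high_snr(self):
        cfg = CurrentSimConfig(seed=3, noise_sd=2.0)  # median event 30 pA, SNR >= 5
        _, trace, truth = generate_current_trace(cfg)
        ev = detect_events(CurrentTrace(trace, cfg.sampling_rate), 10.0)
        onsets = np.array([e.onset for e in ev])
        amps = np.array([e.amplitude for e in ev])
        planted = [(t, a) for t, a in truth.synaptic_events if a >= 12.0]
        hits, bias = 0, []
        for t, a in planted:
            d = np.abs(onsets - t)
            if d.size and d.min() < 5e-3:
                hits += 1
                bias.append((amps[d.argmin()] - a) / a)
        assert hits / len(planted) >= 0.9
        assert abs(np.mean(bias)) < 0.1


class TestGroupEventBursts:
    def test_qualifying_run(self):
        ev = make_events([0, 30, 60], [50, 120, 60])
        (b,) = group_event_bursts(ev)
        assert b.n_events == 3 and b.max_amplitude == 120

    def test_run_without_large_event_rejected(self):
        assert group_event_bursts(make_events([0, 30, 60], [50, 60, 70])) == []

    def test_short_run_rejected(self):
        assert group_event_bursts(make_events([0, 30], [150, 150])) == []

    def test_amplitude_threshold_is_strict(self):
        assert group_event_bursts(make_events([0, 30, 60], [100, 100, 100])) == []

    @given(
        st.lists(st.tuples(st.floats(0, 0.6), st.floats(5, 200)),
                 min_size=0, max_size=15)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_exhaustive_oracle(self, raw):
        raw.sort()
        onsets = [round(t, 4) for t, _ in raw]
        if len(set(onsets)) != len(onsets):
            onsets = list(np.cumsum(np.abs(np.diff([0] + onsets)) + 1e-4))
        amps = [a for _, a in raw]
        ev = [SynapticEvent(o, o + 1e-3, a) for o, a in zip(onsets, amps)]
        index_of = {id(e): i for i, e in enumerate(ev)}
        got = [(index_of[id(b.events[0])], index_of[id(b.events[-1])])
               for b in group_event_bursts(ev)]
        assert got == oracle_event_bursts(onsets, amps)


class TestEventStatistics:
    def test_frequency_and_mean(self):
        ev = make_events([0, 100, 200], [10, 20, 30])
        s = event_statistics(ev, 600.0)
        assert s["frequency_hz"] == pytest.approx(3 / 600)
        assert s["mean_amplitude_pA"] == pytest.approx(20.0)

    def test_no_events(self):
        s = event_statistics([], 600.0)
        assert s["frequency_hz"] == 0.0
        assert s["mean_amplitude_pA"] is None


class TestIntrinsic:
    def test_adaptation_ratio_constant_isi_is_one(self):
        peaks = np.arange(10) * 0.020
        assert adaptation_ratio(peaks) == pytest.approx(1.0)

    def test_adaptation_ratio_formula(self):
        isis = np.arange(10, 19) * 1e-3
        peaks = np.concatenate([[0.0], np.cumsum(isis)])
        assert adaptation_ratio(peaks) == pytest.approx(17.0 / 11.0)

    def test_adaptation_ratio_shift_and_scale_invariance(self):
        peaks = np.concatenate([[0.0], np.cumsum(np.linspace(0.01, 0.03, 9))])
        base = adaptation_ratio(peaks)
        assert adaptation_ratio(peaks + 5.0) == pytest.approx(base)
        assert adaptation_ratio(peaks * 2.0) == pytest.approx(base)

    def test_fewer_than_nine_aps_is_missing(self):
        assert adaptation_ratio(np.arange(8) * 0.02) is None

    def test_input_resistance_ohms_law(self):
        assert input_resistance(-10.0, -100.0) == pytest.approx(100.0)

    def test_membrane_tau_recovered_from_exponential(self):
        t = np.arange(0, 0.5, 1 / 20000.0)
        v = -60.0 - 10.0 * (1 - np.exp(-(t - 0.1) / 0.015)) * (t >= 0.1)
        tau = membrane_tau(t, v, step_onset=0.1)
        assert tau == pytest.approx(15.0, rel=0.05)

    def test_full_panel_on_parametric_sweep(self):
        cfg = APTrainConfig(isi_ms=tuple(float(x) for x in range(10, 19)))
        t, v, truth = generate_ap_train(cfg)
        props = intrinsic_properties(ap_time=t, ap_voltage=v,
                                     pre_stim_s=cfg.pre_s,
                                     passive_delta_i_pA=-100.0)
        assert props.vrmp == pytest.approx(cfg.v_rest, abs=0.5)
        assert props.input_resistance == pytest.approx(100.0)
        assert props.adaptation_ratio == pytest.approx(17.0 / 11.0, abs=0.01)
        # ideal values from the parametric waveform: repolarization crosses
        # threshold (-40) at 70/85 of the 1.5 ms fall -> 0.265 ms before the
        # AHP minimum; half repolarization (to -12.5 mV) at 0.75 ms
        assert props.ahp_time == pytest.approx(0.265, abs=0.15)
        assert props.ap_half_time == pytest.approx(0.75, abs=0.1)

    def test_too_few_aps_reported_missing(self):
        cfg = APTrainConfig(isi_ms=tuple([20.0] * 5))
        t, v, _ = generate_ap_train(cfg)
        props = intrinsic_properties(ap_time=t, ap_voltage=v, pre_stim_s=cfg.pre_s)
        assert props.adaptation_ratio is None


class TestQC:
    def test_high_series_resistance_fails(self):
        res = qc_filter(30.0, 400.0)
        assert not res.passed and "series resistance" in res.reason

    def test_low_ratio_fails(self):
        res = qc_filter(20.0, 150.0)
        assert not res.passed and "ratio" in res.reason

    def test_good_recording_passes(self):
        assert qc_filter(10.0, 200.0).passed

    def test_monotone_in_series_resistance(self):
        rm = 260.0
        passed = [qc_filter(rs, rm).passed for rs in np.linspace(1.0, 40.0, 40)]
        # once failing, never passes again as Rs rises
        assert passed == sorted(passed, reverse=True)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            qc_filter(0.0, 100.0)
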