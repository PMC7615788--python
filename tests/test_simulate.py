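"""Synthetic generators: determinism, planted-rate consistency, and the
closed-form properties of each modality."""

import numpy as np
import pytest

from netphen import calcium as ca
from netphen import morphology as mo
from netphen import patch as pc
from netphen.mea import bandpass_filter, detect_spikes, mean_firing_rate
from netphen.simulate import (
    APTrainConfig,
    CurrentSimConfig,
    FluorescenceSimConfig,
    MEASimConfig,
    MorphologySimConfig,
    PRESETS,
    epsc_kernel,
    generate_ap_train,
    generate_current_trace,
    generate_fluorescence,
    generate_morphology,
    generate_raw_mea,
    generate_spike_trains,
    spike_template,
)


class TestSpikeTrainGenerator:
    def test_null_process_is_empty(self):
        cfg = MEASimConfig(nb_rate=0.0, background_rate=0.0,
                           channel_burst_rate=0.0, duration=60.0)
        trains, truth = generate_spike_trains(cfg)
        assert trains.total_spikes() == 0
        assert truth.nb_intervals == []

    def test_planted_count_matches_poisson_oracle(self):
        cfg = MEASimConfig(nb_rate=0.2, duration=600.0, seed=5)
        _, truth = generate_spike_trains(cfg)
        lam = 0.2 * 600.0
        assert abs(len(truth.nb_intervals) - lam) <= 3 * np.sqrt(lam)

    def test_full_participation(self):
        cfg = MEASimConfig(nb_participation=1.0, duration=120.0, seed=3,
                           background_rate=0.0, channel_burst_rate=0.0)
        trains, truth = generate_spike_trains(cfg)
        for start, end in truth.nb_intervals:
            active = sum(
                np.any((t >= start) & (t <= end)) for t in trains.trains.values()
            )
            assert active == cfg.n_channels

    def test_determinism(self):
        cfg = MEASimConfig(seed=9, duration=60.0)
        a, _ = generate_spike_trains(cfg, "mutant_like")
        b, _ = generate_spike_trains(cfg, "mutant_like")
        for ch in a.trains:
            assert np.array_equal(a.trains[ch], b.trains[ch])

    def test_planted_rate_consistency_over_seeds(self):
        lam = 0.1 * 300.0
        counts = []
        for seed in range(20):
            _, truth = generate_spike_trains(
                MEASimConfig(nb_rate=0.1, duration=300.0, seed=seed))
            counts.append(len(truth.nb_intervals))
        se = np.sqrt(lam / 20)
        assert abs(np.mean(counts) - lam) <= 3 * se

    def test_intervals_non_overlapping_and_in_range(self):
        cfg = MEASimConfig(nb_rate=0.3, duration=120.0, seed=7)
        _, truth = generate_spike_trains(cfg)
        iv = truth.nb_intervals
        assert all(0 <= a < b <= 120.0 for a, b in iv)
        assert all(iv[i + 1][0] >= iv[i][1] for i in range(len(iv) - 1))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_spike_trains(MEASimConfig(nb_rate=-1.0))
        with pytest.raises(ValueError):
            generate_spike_trains(MEASimConfig(nb_participation=1.5))
        with pytest.raises(ValueError):
            generate_spike_trains(MEASimConfig(background_rate=float("nan")))

    def test_presets_share_expected_mfr_but_differ_in_bursting(self):
        c = PRESETS["control"].apply(MEASimConfig())
        m = PRESETS["mutant_like"].apply(MEASimConfig())
        expected = lambda k: (
            k.background_rate
            + k.nb_rate * k.nb_duration_mean * k.nb_participation * k.within_burst_rate
            + k.channel_burst_rate * k.nb_duration_mean * k.within_burst_rate
        )
        assert expected(c) == pytest.approx(expected(m))
        assert m.nb_rate > c.nb_rate
        assert m.nb_duration_mean < c.nb_duration_mean
        assert m.within_burst_rate < c.within_burst_rate


class TestRawMEA:
    def test_noise_sd_is_reproduced(self):
        cfg = MEASimConfig(duration=10.0, noise_sd=3.0, nb_rate=0.0,
                           background_rate=0.0, channel_burst_rate=0.0,
                           raw_waveform=True, seed=2)
        trains, _ = generate_spike_trains(cfg)
        rec = generate_raw_mea(cfg, trains)
        sds = rec.signal.std(axis=1)
        assert np.all(np.abs(sds - 3.0) / 3.0 < 0.05)

    def test_single_spike_noiseless_equals_template(self):
        cfg = MEASimConfig(duration=1.0, noise_sd=0.0, spike_amplitude=40.0,
                           raw_waveform=True, n_channels=1)
        from netphen.mea import SpikeTrainSet

        trains = SpikeTrainSet({"c0": np.array([0.5])}, 1.0)
        rec = generate_raw_mea(cfg, trains)
        tpl = spike_template(cfg.sampling_rate, 40.0)
        v = np.asarray(rec.signal[0], dtype=float)
        assert v.min() == pytest.approx(-40.0, rel=1e-5)
        assert np.count_nonzero(v) == np.count_nonzero(tpl)

    def test_high_snr_spikes_exceed_detection_threshold(self):
        cfg = MEASimConfig(duration=20.0, noise_sd=3.0, spike_amplitude=30.0,
                           raw_waveform=True, seed=4)
        trains, _ = generate_spike_trains(cfg, "control")
        rec = bandpass_filter(generate_raw_mea(cfg, trains))
        det = detect_spikes(rec)
        # every planted spike has a detected partner within 1 ms
        for ch, planted in trains.trains.items():
            found = det.trains[ch]
            for t in planted:
                assert np.abs(found - t).min() < 1e-3

    def test_nonpositive_amplitude_rejected(self):
        cfg = MEASimConfig(spike_amplitude=0.0, duration=1.0)
        from netphen.mea import SpikeTrainSet

        with pytest.raises(ValueError):
            generate_raw_mea(cfg, SpikeTrainSet({"c0": np.array([0.5])}, 1.0))


class TestCurrentTrace:
    def test_flat_without_events_or_noise(self):
        cfg = CurrentSimConfig(event_rate=0.0, burst_rate=0.0, noise_sd=0.0,
                               duration=5.0)
        _, trace, truth = generate_current_trace(cfg)
        assert np.all(trace == cfg.baseline)
        assert truth.synaptic_events == []

    def test_single_event_peak_is_normalized_amplitude(self):
        cfg = CurrentSimConfig(event_rate=0.0, burst_rate=0.0, noise_sd=0.0,
                               duration=2.0)
        t, trace, _ = generate_current_trace(cfg)
        kernel = epsc_kernel(cfg.sampling_rate, cfg.rise_ms, cfg.decay_ms)
        trace2 = trace.copy()
        i0 = int(1.0 * cfg.sampling_rate)
        trace2[i0:i0 + kernel.size] -= 100.0 * kernel
        assert trace2.min() == pytest.approx(-100.0, rel=1e-3)

    def test_planted_burst_epochs_satisfy_the_rule(self):
        cfg = CurrentSimConfig(seed=8, burst_rate=0.2, event_rate=0.0,
                               noise_sd=0.0, duration=30.0)
        _, _, truth = generate_current_trace(cfg)
        assert truth.burst_epochs
        ev = sorted(truth.synaptic_events)
        for start, end in truth.burst_epochs:
            members = [(t, a) for t, a in ev if start - 1e-9 <= t <= end + 1e-9]
            assert len(members) >= 3
            gaps = np.diff([m[0] for m in members])
            assert np.all(gaps <= 0.05 + 1e-9)
            assert max(m[1] for m in members) > 100.0

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValueError):
            generate_current_trace(CurrentSimConfig(rise_ms=3.0, decay_ms=1.0))


class TestAPTrain:
    def test_constant_isi_peaks_are_arithmetic(self):
        cfg = APTrainConfig(isi_ms=tuple([20.0] * 9))
        _, _, truth = generate_ap_train(cfg)
        d = np.diff(truth.ap_peaks)
        assert d == pytest.approx(np.full(9, 0.020))

    def test_annotated_height(self):
        cfg = APTrainConfig()
        t, v, truth = generate_ap_train(cfg)
        assert v.max() == pytest.approx(cfg.peak, abs=0.5)
        assert cfg.peak - cfg.threshold == pytest.approx(70.0)

    def test_downstream_adaptation_ratio_matches_formula(self):
        isis = tuple(float(x) for x in range(10, 19))  # 10..18 ms
        cfg = APTrainConfig(isi_ms=isis)
        t, v, truth = generate_ap_train(cfg)
        feats = pc.ap_features(t, v)
        ar = pc.adaptation_ratio(feats["peak_times"])
        assert ar == pytest.approx(17.0 / 11.0, abs=0.01)

    def test_peak_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            generate_ap_train(APTrainConfig(peak=-50.0))


class TestFluorescence:
    def test_constant_without_anything(self):
        cfg = FluorescenceSimConfig(network_rate=0.0, noise_sd=0.0,
                                    bleach_tau=1e12, n_rois=2)
        _, F, _ = generate_fluorescence(cfg)
        assert F == pytest.approx(np.full_like(F, cfg.f0))

    def test_pure_bleach_closed_form(self):
        cfg = FluorescenceSimConfig(network_rate=0.0, noise_sd=0.0,
                                    bleach_tau=60.0, n_rois=1)
        t, F, _ = generate_fluorescence(cfg)
        assert F[0, -1] / F[0, 0] == pytest.approx(np.exp(-t[-1] / 60.0), rel=1e-6)

    def test_shared_events_round_trip_through_synchrony(self):
        cfg = FluorescenceSimConfig(seed=1, noise_sd=0.0, participation=1.0)
        _, F, truth = generate_fluorescence(cfg)
        res = ca.analyze_roi_set(ca.ROITraceSet(F, cfg.frame_rate))
        detected = res["synchrony"]["rate_per_min"] * (cfg.duration / 60.0)
        assert detected == len(truth.network_event_times)

    def test_invalid_bleach_rejected(self):
        with pytest.raises(ValueError):
            generate_fluorescence(FluorescenceSimConfig(bleach_tau=0.0))


class TestMorphologyGenerator:
    def test_single_unbranched_dendrite(self):
        cfg = MorphologySimConfig(n_primary=1, total_length=100.0,
                                  branch_prob=0.0, wiggle=0.0)
        tree = mo.parse_swc(generate_morphology(cfg))
        m = mo.morphometrics(tree)
        assert m["n_primary_dendrites"] == 1
        assert m["n_nodes"] == 0
        assert m["n_ends"] == 1
        # SWC coordinates are written at 1e-4 um precision
        assert m["total_length_um"] == pytest.approx(100.0, abs=1e-2)

    def test_byte_identical_on_same_seed(self):
        cfg = MorphologySimConfig(seed=6)
        assert generate_morphology(cfg) == generate_morphology(cfg)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_total_length_within_one_percent_of_target(self, seed):
        cfg = MorphologySimConfig(seed=seed, total_length=1000.0)
        tree = mo.parse_swc(generate_morphology(cfg))
        m = mo.morphometrics(tree)
        assert abs(m["total_length_um"] - 1000.0) / 1000.0 < 0.01

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            generate_morphology(MorphologySimConfig(total_length=0.0))
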