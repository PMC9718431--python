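"""Signal conditioning: filter behaviour, R-peak detection, NN cleaning,
iskNA integration and burst detection, scored against generator truth."""

import numpy as np
import pytest

from adreflex.processing import (BeatSeries, Burst, SknaDerived, clean_nn,
                                 detect_bursts, detect_r_peaks, filter_ecg,
                                 filter_signals, filter_skna, integrate_skna)
from adreflex.simulate import SimulationConfig, simulate_recording
from adreflex.simulate import _render_ecg  # template renderer reused as oracle input

FS = 10_000.0


def _tone(freq, fs=FS, dur=10.0):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestFilters:
    def test_skna_band_rejects_cardiac_frequencies(self):
        x = _tone(50.0)
        y = filter_skna(x, FS)
        assert np.sqrt(np.mean(y**2)) < 0.01 * np.sqrt(np.mean(x**2))

    def test_skna_band_passes_nerve_frequencies(self):
        x = _tone(700.0)
        y = filter_skna(x, FS)
        assert np.sqrt(np.mean(y**2)) >= 0.90 * np.sqrt(np.mean(x**2))

    def test_zero_input_zero_output(self):
        assert not filter_skna(np.zeros(int(FS)), FS).any()
        assert not filter_ecg(np.zeros(int(FS)), FS).any()

    def test_zero_phase_time_reversal_symmetry(self):
        rng = np.random.default_rng(0)
        # float64 input, long enough that the 0.5 Hz edge transient fits in the pad
        x = rng.standard_normal(300_000)
        for filt in (filter_ecg, filter_skna):
            y = filt(x, FS)
            y_rev = filt(x[::-1], FS)[::-1]
            assert np.allclose(y, y_rev, rtol=0, atol=1e-6 * np.abs(y).max())

    def test_missing_channel_and_low_rate_errors(self, crd_recording):
        import copy

        rec = copy.copy(crd_recording)
        rec.channels = {k: v for k, v in crd_recording.channels.items() if k != "skna"}
        with pytest.raises(KeyError, match="skna"):
            filter_signals(rec)
        with pytest.raises(ValueError, match="sampling rate"):
            filter_skna(np.zeros(4000), fs=1500.0)

    def test_lengths_preserved(self, crd_recording):
        ecg_f, skna_f = filter_signals(crd_recording)
        assert ecg_f.size == crd_recording.channels["ecg"].size
        assert skna_f.size == crd_recording.channels["skna"].size


class TestRPeaks:
    def test_recovery_against_simulator_truth(self):
        cfg = SimulationConfig(seed=4)  # 400 bpm baseline, default noise
        rec = simulate_recording(cfg, "rat01", 7, [], duration_s=60.0)
        ecg_f = filter_ecg(rec.channels["ecg"], FS)
        beats = detect_r_peaks(ecg_f, FS)
        truth = rec.truth["beat_times_s"]
        d = np.abs(truth[None, :] - beats.r_peak_times[:, None])
        assert np.mean(d.min(axis=0) < 0.005) >= 0.99

    def test_constant_zero_gives_empty_series_not_exception(self):
        beats = detect_r_peaks(np.zeros(int(3 * FS)), FS)
        assert beats.empty
        assert beats.r_peak_times.size == 0

    def test_exact_spacing_reproduced(self):
        cfg = SimulationConfig(seed=0, noise_sd_ecg=0.01)
        times = np.arange(0.5, 29.5, 0.150)
        rng = np.random.default_rng(0)
        ecg = _render_ecg(cfg, 30.0, times, rng)
        beats = detect_r_peaks(filter_ecg(ecg, FS), FS)
        assert np.all(np.abs(beats.rr_ms - 150.0) <= 0.2)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            detect_r_peaks(np.zeros(1000), FS)

    def test_sensitivity_nonincreasing_in_noise(self):
        sens = []
        for noise in (0.05, 0.4, 0.8):
            cfg = SimulationConfig(seed=8, noise_sd_ecg=noise)
            rec = simulate_recording(cfg, "rat01", 7, [], duration_s=30.0)
            beats = detect_r_peaks(filter_ecg(rec.channels["ecg"], FS), FS)
            truth = rec.truth["beat_times_s"]
            if beats.r_peak_times.size == 0:
                sens.append(0.0)
                continue
            d = np.abs(truth[None, :] - beats.r_peak_times[:, None])
            sens.append(np.mean(d.min(axis=0) < 0.005))
        assert sens[0] + 0.01 >= sens[1] - 0.01
        assert sens[1] + 0.01 >= sens[2] - 0.01
        assert sens[0] >= 0.99


class TestCleanNN:
    def _series(self, rr_ms):
        times = np.concatenate(([0.0], np.cumsum(rr_ms) / 1000.0))
        return BeatSeries(times, np.asarray(rr_ms, dtype=float))

    def test_constant_series_untouched(self):
        beats = clean_nn(self._series([150.0] * 5))
        assert np.array_equal(beats.nn_ms, [150.0] * 5)
        assert beats.rejected_idx.size == 0

    def test_ectopic_interval_rejected(self):
        beats = clean_nn(self._series([150.0, 150.0, 300.0, 150.0, 150.0]))
        assert 300.0 not in beats.nn_ms
        assert list(beats.rejected_idx) == [2]
        assert np.array_equal(beats.nn_ms, [150.0] * 4)

    def test_all_rejected_raises(self):
        # alternating series: every interval deviates 33% from the running median
        beats = self._series([100.0, 200.0, 100.0, 200.0])
        with pytest.raises(ValueError, match="signal quality"):
            clean_nn(beats)

    def test_false_rejection_rate_on_clean_beats(self, quiet_recording):
        ecg_f = filter_ecg(quiet_recording.channels["ecg"], FS)
        beats = clean_nn(detect_r_peaks(ecg_f, FS))
        assert beats.rr_ms.size >= 1000
        assert beats.rejected_idx.size / beats.rr_ms.size <= 0.01


class TestIntegrateSkna:
    def test_moving_average_identity_on_constant(self):
        skd = integrate_skna(np.full(20_000, 3.0), FS)
        assert np.allclose(skd.iskna, 3.0, atol=1e-6)

    def test_folded_normal_mean(self):
        rng = np.random.default_rng(1)
        sigma = 2.0
        skd = integrate_skna(rng.normal(0, sigma, 200_000), FS)
        assert abs(np.mean(skd.iskna) - sigma * np.sqrt(2 / np.pi)) < 0.05 * sigma * np.sqrt(2 / np.pi)

    def test_iskna_peak_inside_injected_packet(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.3, int(10 * FS))
        i0, i1 = int(4.0 * FS), int(4.2 * FS)
        x[i0:i1] += 5.0 * np.sin(2 * np.pi * 700 * np.arange(i1 - i0) / FS)
        skd = integrate_skna(x, FS)
        peak = np.argmax(skd.iskna)
        assert 3.9 * FS <= peak <= 4.3 * FS

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="integration window"):
            integrate_skna(np.zeros(100), FS)

    def test_iskna_nonnegative(self, crd_processed):
        _, skd = crd_processed
        assert np.all(skd.iskna >= 0)


class TestDetectBursts:
    def _skd(self, iskna, mu=0.0, sigma=1.0):
        return SknaDerived(filtered=iskna, rectified=np.abs(iskna), iskna=iskna,
                           sampling_rate=FS, baseline_mu=mu, baseline_sigma=sigma)

    def test_subthreshold_trace_has_no_bursts(self):
        skd = detect_bursts(self._skd(np.ones(int(FS)) * 0.5))
        assert skd.bursts == []

    def test_nearby_intervals_merge(self):
        x = np.zeros(int(FS))
        x[1000:2000] = 10.0   # 100 ms burst
        x[2500:3500] = 10.0   # 50 ms gap -> merged
        skd = detect_bursts(self._skd(x))
        assert len(skd.bursts) == 1
        assert skd.bursts[0].start_s == pytest.approx(0.1, abs=0.01)
        assert skd.bursts[0].end_s == pytest.approx(0.35, abs=0.01)

    def test_distant_intervals_stay_separate(self):
        x = np.zeros(int(FS))
        x[1000:2000] = 10.0
        x[3500:4500] = 10.0   # 150 ms gap -> two bursts
        skd = detect_bursts(self._skd(x))
        assert len(skd.bursts) == 2

    def test_short_blips_dropped(self):
        x = np.zeros(int(FS))
        x[1000:1300] = 10.0   # 30 ms < 50 ms minimum
        skd = detect_bursts(self._skd(x))
        assert skd.bursts == []

    def test_degenerate_baseline_falls_back_with_warning(self):
        x = np.zeros(int(FS))
        x[1000:2000] = 10.0
        with pytest.warns(UserWarning, match="degenerate"):
            skd = detect_bursts(self._skd(x, mu=0.0, sigma=0.0))
        assert len(skd.bursts) == 1

    def test_threshold_monotonicity(self, crd_recording):
        skna_f = filter_skna(crd_recording.channels["skna"], FS)
        counts = []
        for k in (2.0, 3.0, 5.0, 8.0):
            skd = integrate_skna(skna_f, FS, annotations=crd_recording.annotations)
            skd = detect_bursts(skd, threshold_k=k, peak_k=k)
            counts.append(len(skd.bursts))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_recovery_against_simulator_truth(self, crd_recording, crd_processed):
        _, skd = crd_processed
        truth = crd_recording.truth["bursts"]
        det = [(b.start_s, b.end_s) for b in skd.bursts]

        def overlaps(a, b):
            return a[0] < b[1] and b[0] < a[1]

        tp = sum(any(overlaps((t[0], t[1]), d) for d in det) for t in truth)
        fp = sum(not any(overlaps((t[0], t[1]), d) for t in truth) for d in det)
        assert tp / len(truth) >= 0.95
        assert fp <= max(1, 0.05 * len(det))


class TestEndToEndOracle:
    def test_noiseless_nn_matches_truth_within_1ms(self):
        cfg = SimulationConfig(seed=6, noise_sd_ecg=0.0)
        rec = simulate_recording(cfg, "rat01", 7, [], duration_s=60.0)
        beats = clean_nn(detect_r_peaks(filter_ecg(rec.channels["ecg"], FS), FS))
        truth_nn = rec.truth["nn_ms"]
        assert beats.rr_ms.size == truth_nn.size
        assert np.max(np.abs(beats.rr_ms - truth_nn)) < 1.0
        assert beats.rejected_idx.size == 0
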