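"""Photometry pipeline: trimming, despiking, isosbestic ΔF/F, PETHs."""

import logging

import numpy as np
import pytest

import spckit as sk
from spckit.errors import (
    DegenerateFitError,
    EmptyPETHError,
    InvalidBaselineError,
    OutOfRangeError,
    PairingError,
    TooShortError,
)
from spckit.photometry import read_photometry_csv, write_photometry_csv
from spckit.photometry import read_photometry_hdf5, write_photometry_hdf5


def make_recording(duration_s=300.0, fs=50.0, signal=None, control=None, ttl=()):
    t = np.arange(0.0, duration_s, 1.0 / fs)
    sig = np.ones_like(t) if signal is None else signal(t)
    ctl = np.ones_like(t) if control is None else control(t)
    return sk.PhotometryRecording(t, sig, ctl, np.asarray(ttl, float))


class TestTrim:
    def test_first_minute_removed(self):
        rec = make_recording(300.0)
        trimmed = sk.trim_initial(rec, 60.0)
        assert trimmed.t[0] == pytest.approx(60.0)
        assert trimmed.duration_s == pytest.approx(240.0, abs=0.1)

    def test_zero_trim_is_identity(self):
        rec = make_recording(100.0)
        assert sk.trim_initial(rec, 0.0) is rec

    def test_early_ttl_dropped_with_warning(self, caplog):
        rec = make_recording(300.0, ttl=[30.0, 120.0])
        with caplog.at_level(logging.WARNING, logger="spckit.photometry"):
            trimmed = sk.trim_initial(rec)
        assert trimmed.ttl_times_s.tolist() == [120.0]
        assert any("TTL" in r.message for r in caplog.records)

    def test_too_short_recording_rejected(self):
        with pytest.raises(TooShortError):
            sk.trim_initial(make_recording(30.0), 60.0)


class TestDespike:
    def test_constant_trace_unchanged(self):
        rec = make_recording(10.0)
        out = sk.remove_point_artifacts(rec)
        np.testing.assert_array_equal(out.f_signal, rec.f_signal)

    def test_single_large_spike_replaced_by_local_median(self):
        rng = np.random.default_rng(0)
        rec = make_recording(
            20.0, signal=lambda t: 1.0 + 0.01 * rng.standard_normal(len(t))
        )
        sig = rec.f_signal.copy()
        sig[500] = 100.0
        spiked = sk.PhotometryRecording(rec.t, sig, rec.f_control, rec.ttl_times_s)
        out = sk.remove_point_artifacts(spiked)
        assert abs(out.f_signal[500] - 1.0) < 0.1

    def test_injected_spikes_corrected_without_false_positives(self):
        sched = sk.build_probe_schedule()
        spikes = (70.0, 120.0, 200.0, 290.0, 330.0)
        truth = sk.PhotometryGroundTruth(
            artifact_times_s=spikes, artifact_amplitude=1.0, noise_sd=0.02
        )
        rec, _ = sk.simulate_photometry(sched, truth, fs=50, seed=4)
        clean_truth = sk.PhotometryGroundTruth(noise_sd=0.02)
        clean, _ = sk.simulate_photometry(sched, clean_truth, fs=50, seed=4)
        out = sk.remove_point_artifacts(rec)
        spike_idx = np.array([int(round(s * 50)) for s in spikes])
        corrected = np.abs(out.f_signal[spike_idx] - clean.f_signal[spike_idx]) < 0.1
        assert corrected.sum() >= len(spikes) - 1
        # away from the spikes only a small fraction of noise samples is
        # touched, and each replacement stays within the local noise scale
        mask = np.ones(len(rec.t), bool)
        for i in spike_idx:
            mask[i - 5 : i + 6] = False
        changed = out.f_signal[mask] != rec.f_signal[mask]
        assert changed.mean() < 0.01
        assert np.max(np.abs(out.f_signal[mask] - rec.f_signal[mask])) < 6 * 0.02


class TestIsosbesticFit:
    def test_identical_channels_give_identity_fit(self):
        rec = make_recording(10.0, signal=np.cos, control=np.cos)
        fitted, a, b = sk.fit_control_to_signal(rec)
        assert a == pytest.approx(1.0) and b == pytest.approx(0.0, abs=1e-12)

    def test_affine_relation_recovered_exactly(self):
        rec = make_recording(10.0, signal=lambda t: 2 * np.exp(-t) + 3,
                             control=lambda t: np.exp(-t))
        _, a, b = sk.fit_control_to_signal(rec)
        assert a == pytest.approx(2.0) and b == pytest.approx(3.0)

    def test_noisy_fit_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 60, 0.02)
        ctl = np.exp(-t / 100) + 0.01 * rng.standard_normal(len(t))
        sig = 1.7 * ctl + 0.4 + 0.02 * rng.standard_normal(len(t))
        rec = sk.PhotometryRecording(t, sig, ctl, np.array([]))
        _, a, b = sk.fit_control_to_signal(rec)
        X = np.column_stack([ctl, np.ones_like(ctl)])
        a0, b0 = np.linalg.solve(X.T @ X, X.T @ sig)
        assert a == pytest.approx(a0, rel=1e-8) and b == pytest.approx(b0, rel=1e-8)

    def test_constant_control_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            sk.fit_control_to_signal(make_recording(10.0))


class TestDff:
    def test_signal_equal_fitted_control_gives_zero(self):
        rec = make_recording(10.0, signal=lambda t: np.exp(-t / 50),
                             control=lambda t: np.exp(-t / 50))
        np.testing.assert_allclose(sk.compute_dff(rec).dff, 0.0, atol=1e-12)

    def test_ten_percent_elevation_over_given_baseline(self):
        # against a fixed fitted baseline, a 1.1x signal is exactly 0.1
        fitted = 2 * np.exp(-np.arange(0, 10, 0.02) / 50)
        rec = make_recording(
            10.0,
            signal=lambda t: 1.1 * (2 * np.exp(-t / 50)),
            control=lambda t: 2 * np.exp(-t / 50),
        )
        np.testing.assert_allclose(sk.compute_dff(rec, fitted=fitted).dff, 0.1, atol=1e-9)
        # refitting absorbs a global scale: a pure 1.1x rescale is no response
        np.testing.assert_allclose(sk.compute_dff(rec).dff, 0.0, atol=1e-9)

    def test_shared_bleach_removed(self):
        sched = sk.build_probe_schedule()
        truth = sk.PhotometryGroundTruth(noise_sd=0.01).with_amplitudes_in_noise_units(
            (3.0, 3.0), (200.0, 260.0), duration_s=360.0
        )
        rec, _ = sk.simulate_photometry(sched, truth, fs=50, seed=2)
        trimmed = sk.trim_initial(rec)
        raw_slope = np.polyfit(trimmed.t, trimmed.f_signal, 1)[0]
        dff = sk.process_recording(rec, zscore=None)
        dff_slope = np.polyfit(dff.t, dff.dff, 1)[0]
        assert abs(dff_slope) < 0.05 * abs(raw_slope)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 30, 0.02)
        ctl = np.exp(-t / 80) + 0.005 * rng.standard_normal(len(t))
        sig = 2 * np.exp(-t / 80) + 0.01 * rng.standard_normal(len(t))
        rec1 = sk.PhotometryRecording(t, sig, ctl, np.array([]))
        rec2 = sk.PhotometryRecording(t, 7.5 * sig, 7.5 * ctl, np.array([]))
        np.testing.assert_allclose(
            sk.compute_dff(rec1).dff, sk.compute_dff(rec2).dff, atol=1e-10
        )

    def test_nonpositive_fitted_baseline_reported(self):
        t = np.arange(0, 10, 0.02)
        ctl = np.linspace(1.0, -0.5, len(t))
        rec = sk.PhotometryRecording(t, ctl.copy(), ctl, np.array([]))
        with pytest.raises(InvalidBaselineError):
            sk.compute_dff(rec)

    def test_despike_is_noop_on_clean_trace(self):
        rec = make_recording(60.0, signal=lambda t: 2 * np.exp(-t / 100),
                             control=lambda t: np.exp(-t / 100))
        via_despike = sk.process_recording(rec, trim_s=10, zscore=None)
        direct = sk.compute_dff(sk.trim_initial(rec, 10))
        np.testing.assert_array_equal(via_despike.dff, direct.dff)


class TestZscore:
    def test_whole_trace_zscore_is_standardized(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 20, 0.02)
        dff = sk.DffTrace(t, rng.normal(3.0, 2.0, len(t)))
        z = sk.zscore_trace(dff)
        assert np.mean(z.dff) == pytest.approx(0.0, abs=1e-6)
        assert np.std(z.dff, ddof=1) == pytest.approx(1.0, abs=1e-6)
        assert z.is_zscored

    def test_constant_trace_is_degenerate(self):
        t = np.arange(0, 5, 0.1)
        with pytest.raises(DegenerateFitError):
            sk.zscore_trace(sk.DffTrace(t, np.full(len(t), 2.0)))

    def test_peak_z_approximates_amplitude_over_noise(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 120, 0.01)
        sigma, amp = 0.02, 0.2
        dt = t - 60
        kernel = np.zeros_like(t)
        post = dt >= 0
        kernel[post] = np.exp(-dt[post] / 0.6) - np.exp(-dt[post] / 0.05)
        kernel /= kernel.max()
        dff = sk.DffTrace(t, amp * kernel + rng.normal(0, sigma, len(t)))
        z = sk.zscore_trace(dff, baseline=(0.0, 50.0))
        # smooth before reading the maximum so the sample-level noise
        # maximum does not inflate the peak estimate
        zs = sk.photometry.smooth_trace(z, 0.1)
        peak = zs.dff[(t > 59.5) & (t < 61.5)].max()
        assert peak == pytest.approx(amp / sigma, rel=0.1)


class TestSynchronize:
    def test_single_ttl_offset(self):
        m = sk.synchronize(np.array([12.0]), np.array([250]), fps=25)
        assert m.offset_s == pytest.approx(2.0) and m.drift == 1.0
        assert m.video_to_photometry(10.0) == pytest.approx(12.0)

    def test_identical_clocks(self):
        ttl = np.array([10.0, 20.0, 30.0])
        m = sk.synchronize(ttl, ttl * 25, fps=25)
        assert m.offset_s == pytest.approx(0.0, abs=1e-9)
        assert m.drift == pytest.approx(1.0)

    def test_jittered_ttls_match_least_squares_oracle(self):
        rng = np.random.default_rng(6)
        tv = np.array([10.0, 50.0, 100.0, 200.0, 300.0])
        tp = 1.001 * tv + 3.0 + rng.normal(0, 0.01, 5)
        m = sk.synchronize(tp, tv * 25, fps=25)
        X = np.column_stack([tv, np.ones(5)])
        drift0, off0 = np.linalg.solve(X.T @ X, X.T @ tp)
        assert m.drift == pytest.approx(drift0, rel=1e-10)
        assert m.offset_s == pytest.approx(off0, rel=1e-10)

    def test_unequal_counts_rejected(self):
        with pytest.raises(PairingError):
            sk.synchronize(np.array([1.0, 2.0]), np.array([25]), fps=25)


class TestPeth:
    def _trace(self, duration=100.0, fs=50.0, fn=None):
        t = np.arange(0, duration, 1 / fs)
        vals = np.zeros_like(t) if fn is None else fn(t)
        return sk.DffTrace(t, vals)

    def test_single_onset_mean_equals_trial(self):
        trace = self._trace(fn=np.sin)
        peth = sk.build_peth(trace, np.array([50.0]), window_s=(-2, 2))
        assert peth.n_trials == 1
        np.testing.assert_array_equal(peth.mean, peth.trial_matrix[0])

    def test_identical_trials_zero_sem(self):
        trace = self._trace(fn=lambda t: np.sin(2 * np.pi * t))  # 1-s periodic
        peth = sk.build_peth(trace, np.array([40.0, 60.0]), window_s=(-1, 1))
        np.testing.assert_allclose(peth.sem, 0.0, atol=1e-9)

    def test_uncovered_onsets_dropped_with_warning(self, caplog):
        trace = self._trace()
        with caplog.at_level(logging.WARNING, logger="spckit.photometry"):
            peth = sk.build_peth(trace, np.array([1.0, 50.0]), window_s=(-5, 5))
        assert peth.n_trials == 1
        assert any("onset" in r.message for r in caplog.records)

    def test_no_usable_onsets_is_empty_error(self):
        with pytest.raises(EmptyPETHError):
            sk.build_peth(self._trace(), np.array([0.5]), window_s=(-5, 5))

    def test_mean_peak_recovers_injected_amplitude(self):
        sched = sk.build_preconditioning_schedule()
        onsets = sched.event_onsets()
        mats = []
        for seed in range(6):
            truth = sk.PhotometryGroundTruth().with_amplitudes_in_noise_units(
                (3.0,) * len(onsets), tuple(onsets), duration_s=sched.total_duration_s
            )
            rec, _ = sk.simulate_photometry(sched, truth, fs=100, seed=seed)
            z = sk.process_recording(rec)
            mats.append(sk.build_peth(z, onsets, smooth_s=0.1).trial_matrix)
        peth6 = sk.build_peth(z, onsets, smooth_s=0.1)
        pooled = sk.PETH(peth6.time_s, np.vstack(mats), onsets, peth6.window_s)
        peak = pooled.mean[(pooled.time_s >= 0) & (pooled.time_s < 1)].max()
        assert peak == pytest.approx(3.0, rel=0.1)


class TestTrialStats:
    def _peth_from_rows(self, rows, fs=50.0, window=(-2.0, 2.0)):
        time = np.arange(window[0], window[1], 1 / fs)
        return sk.PETH(time, np.asarray(rows, float), np.arange(len(rows)), window)

    def test_triangular_transient_peak(self):
        time = np.arange(-2, 2, 0.02)
        tri = np.clip(3 * (1 - np.abs(time - 0.4) / 0.3), 0, None)
        peth = self._peth_from_rows([tri])
        summary = sk.peak_response(peth)
        assert summary.peak_post[0] == pytest.approx(3.0, abs=0.1)

    def test_flat_trace_zero_peaks(self):
        peth = self._peth_from_rows([np.zeros(200)])
        summary = sk.peak_response(peth)
        assert summary.peak_post[0] == 0.0 and summary.peak_baseline[0] == 0.0

    def test_window_outside_peth_rejected(self):
        peth = self._peth_from_rows([np.zeros(200)])
        with pytest.raises(OutOfRangeError):
            sk.peak_response(peth, post_window_s=(0, 5))

    def test_suprathreshold_count_strict(self):
        time = np.arange(-2, 2, 0.02)
        rows = [np.where((time > 0) & (time < 0.5), peak, 0.0) for peak in (1.5, 2.5, 3.0)]
        peth = self._peth_from_rows(rows)
        assert sk.count_suprathreshold_trials(peth, threshold=2.0) == 2
        assert sk.count_suprathreshold_trials(peth, threshold=3.0) == 0  # strict

    def test_all_zero_trials_count_zero(self):
        peth = self._peth_from_rows([np.zeros(200)] * 4)
        assert sk.count_suprathreshold_trials(peth) == 0

    def test_injected_k_of_n_suprathreshold(self):
        sched = sk.build_preconditioning_schedule()
        onsets = tuple(sched.event_onsets())
        base = sk.PhotometryGroundTruth()
        sd = base.expected_dff_noise_sd(60.0, sched.total_duration_s)
        k = 3
        amps = tuple([4.0 * sd] * k + [0.0] * (len(onsets) - k))
        truth = sk.PhotometryGroundTruth(
            transient_times_s=onsets, transient_amplitudes_dff=amps
        )
        rec, _ = sk.simulate_photometry(sched, truth, fs=100, seed=11)
        z = sk.process_recording(rec)
        peth = sk.build_peth(z, np.asarray(onsets), smooth_s=0.1)
        assert sk.count_suprathreshold_trials(peth) == k

    def test_post_peaks_exceed_baseline_peaks(self):
        sched = sk.build_preconditioning_schedule()
        onsets = sched.event_onsets()
        truth = sk.PhotometryGroundTruth().with_amplitudes_in_noise_units(
            (4.0,) * len(onsets), tuple(onsets), duration_s=sched.total_duration_s
        )
        rec, _ = sk.simulate_photometry(sched, truth, fs=100, seed=12)
        z = sk.process_recording(rec)
        summary = sk.peak_response(sk.build_peth(z, onsets, smooth_s=0.1))
        assert np.sum(summary.peak_post > summary.peak_baseline) >= len(onsets) - 1


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        rec = make_recording(5.0, fs=20.0, ttl=[1.0, 2.0])
        write_photometry_csv(rec, tmp_path / "rec.csv", tmp_path / "ttl.csv")
        back = read_photometry_csv(tmp_path / "rec.csv", tmp_path / "ttl.csv")
        np.testing.assert_allclose(back.f_signal, rec.f_signal)
        np.testing.assert_allclose(back.ttl_times_s, rec.ttl_times_s)

    def test_hdf5_round_trip(self, tmp_path):
        rec = make_recording(5.0, fs=20.0, ttl=[1.0])
        write_photometry_hdf5(rec, tmp_path / "rec.h5")
        back = read_photometry_hdf5(tmp_path / "rec.h5")
        np.testing.assert_array_equal(back.f_signal, rec.f_signal)
        np.testing.assert_array_equal(back.t, rec.t)
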