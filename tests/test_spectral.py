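"""Power spectra, band powers, and stimulus-locked analyses."""

import numpy as np
import pytest

from soclas import (
    EEGRecording,
    Hypnogram,
    band_powers,
    baseline_normalize,
    extract_stim_locked,
    generate_session,
    grand_average,
    power_spectrum,
    spindle_rms_locked,
)
from soclas.simulate import EvokedTemplate, GeneratorConfig, add_evoked_responses
from soclas.spectral import StimLockedSet
from soclas.spindles import SpindlePeaks, spindle_rms_envelope

from conftest import scaled_generator


def _recording(x, fs=500.0, label="Fz"):
    return EEGRecording([label], fs, np.asarray(x)[np.newaxis, :])


def _n2_hypnogram(duration_s: float) -> Hypnogram:
    return Hypnogram(("N2",) * int(np.ceil(duration_s / 30)))


class TestPowerSpectrum:
    def test_bin_spacing_is_fs_over_fftn(self, cfg):
        rng = np.random.default_rng(0)
        rec = _recording(rng.normal(0, 10, int(60 * 500)))
        spec = power_spectrum(rec, _n2_hypnogram(60), cfg)["Fz"]
        df = np.diff(spec.freqs_hz)
        assert np.allclose(df, 500 / 4096)
        assert spec.freqs_hz[0] == 0.0

    def test_parseval_for_sinusoid(self, cfg):
        """∫PSD df of an amplitude-A sinusoid ≈ A²/2 (within 10 %)."""
        amp = 40.0
        t = np.arange(int(120 * 500)) / 500
        rec = _recording(amp * np.sin(2 * np.pi * 2.0 * t))
        spec = power_spectrum(rec, _n2_hypnogram(120), cfg)["Fz"]
        total = spec.psd.sum() * (spec.freqs_hz[1] - spec.freqs_hz[0])
        assert total == pytest.approx(amp**2 / 2, rel=0.10)

    def test_zero_signal_zero_psd(self, cfg):
        rec = _recording(np.zeros(int(60 * 500)))
        spec = power_spectrum(rec, _n2_hypnogram(60), cfg)["Fz"]
        assert np.allclose(spec.psd, 0.0)

    def test_too_short_data_error_names_requirement(self, cfg):
        rec = _recording(np.zeros(2000))
        with pytest.raises(ValueError, match="4096"):
            power_spectrum(rec, _n2_hypnogram(4), cfg)

    def test_nrem_restriction(self, cfg):
        """Only N2/N3 artefact-free stretches enter the estimate: a loud
        wake segment does not contaminate the NREM spectrum."""
        rng = np.random.default_rng(1)
        quiet = rng.normal(0, 5, int(60 * 500))
        loud = rng.normal(0, 500, int(60 * 500))
        rec = _recording(np.concatenate([quiet, loud]))
        hyp = Hypnogram(("N2",) * 2 + ("Wake",) * 2)
        spec = power_spectrum(rec, hyp, cfg)["Fz"]
        total = spec.psd.sum() * (spec.freqs_hz[1] - spec.freqs_hz[0])
        assert total < 100  # ≈ var of the quiet part only


class TestBandPowers:
    def test_swa_is_sum_of_so_and_delta(self, cfg):
        rng = np.random.default_rng(2)
        rec = _recording(rng.normal(0, 20, int(120 * 500)))
        spec = power_spectrum(rec, _n2_hypnogram(120), cfg)["Fz"]
        bp = band_powers(spec, cfg.bands_hz)
        swa_lin = 10 ** bp["SWA"]
        so_delta = 10 ** bp["SO"] + 10 ** bp["delta"]
        assert swa_lin == pytest.approx(so_delta, rel=1e-9)

    def test_13hz_tone_lands_in_fast_spindle_band(self, cfg):
        t = np.arange(int(120 * 500)) / 500
        rec = _recording(30 * np.sin(2 * np.pi * 13.0 * t))
        spec = power_spectrum(rec, _n2_hypnogram(120), cfg)["Fz"]
        bands = {"slow_spindle": (9.5, 12.5), "fast_spindle": (12.5, 15.5)}
        bp = band_powers(spec, bands)
        fast = 10 ** bp["fast_spindle"]
        slow = 10 ** bp["slow_spindle"]
        assert fast / (fast + slow) >= 0.95

    def test_amplitude_doubling_adds_log10_4(self, cfg):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 20, int(120 * 500))
        spec1 = power_spectrum(_recording(x), _n2_hypnogram(120), cfg)["Fz"]
        spec2 = power_spectrum(_recording(2 * x), _n2_hypnogram(120), cfg)["Fz"]
        bp1 = band_powers(spec1, cfg.bands_hz)
        bp2 = band_powers(spec2, cfg.bands_hz)
        for name in bp1:
            assert bp2[name] - bp1[name] == pytest.approx(np.log10(4), abs=1e-9)

    def test_zero_band_power_is_error(self, cfg):
        rec = _recording(np.zeros(int(60 * 500)))
        spec = power_spectrum(rec, _n2_hypnogram(60), cfg)["Fz"]
        with pytest.raises(ValueError, match="zero power"):
            band_powers(spec, {"SO": (0.5, 1.5)})

    def test_stage_conditional_swa_ordering(self, cfg):
        """Generated sessions satisfy SWA(N3) > SWA(N2) > SWA(REM)."""
        gen = scaled_generator(
            1.0, duration_s=1800, seed=31,
            stages=("N3",) * 20 + ("N2",) * 20 + ("REM",) * 20,
        )
        rec, hyp, _ = generate_session(gen)
        swa = {}
        for stage in ("N3", "N2", "REM"):
            # isolate one stage by relabelling the rest as Wake
            iso = Hypnogram(
                tuple("N2" if s == stage else "Wake" for s in hyp.stages)
            )
            spec = power_spectrum(rec, iso, cfg, channels=["Fz"])["Fz"]
            swa[stage] = band_powers(spec, cfg.bands_hz)["SWA"]
        assert swa["N3"] > swa["N2"] > swa["REM"]


class TestStimLocked:
    def test_grid_is_400_samples_half_open(self, cfg):
        rng = np.random.default_rng(4)
        rec = _recording(rng.normal(0, 10, int(120 * 500)))
        stim = extract_stim_locked(rec, [30.0, 60.0, 90.0], _n2_hypnogram(120), cfg)
        assert len(stim.time_s) == 400
        assert stim.time_s[0] == pytest.approx(-1.0)
        assert stim.time_s[-1] == pytest.approx(3.0 - 0.01)

    def test_constant_signal_constant_epochs(self, cfg):
        rec = _recording(np.full(int(120 * 500), 7.0))
        stim = extract_stim_locked(rec, [30.0, 60.0], _n2_hypnogram(120), cfg)
        assert np.allclose(stim.epoch_traces, 7.0, atol=0.01)
        assert np.allclose(stim.sem, 0.0, atol=1e-9)

    def test_triggers_near_edge_excluded_and_counted(self, cfg):
        rng = np.random.default_rng(5)
        rec = _recording(rng.normal(0, 10, int(120 * 500)))
        stim = extract_stim_locked(
            rec, [30.0, 119.5], _n2_hypnogram(120), cfg
        )
        assert stim.n_epochs == 1
        assert stim.n_excluded == 1

    def test_triggers_outside_nrem_excluded(self, cfg):
        rng = np.random.default_rng(6)
        rec = _recording(rng.normal(0, 10, int(120 * 500)))
        hyp = Hypnogram(("N2", "REM", "N2", "N2"))
        stim = extract_stim_locked(rec, [40.0, 100.0], hyp, cfg)
        assert stim.n_epochs == 1  # the 40-s trigger window touches REM
        assert stim.n_excluded == 1

    def test_evoked_peak_latency_recovered(self, cfg):
        """Template at a known latency: the grand-mean extremum lands within
        ±30 ms of the template's extremum over 100 epochs."""
        rng = np.random.default_rng(7)
        fs = 500.0
        rec = _recording(rng.normal(0, 12, int(1300 * fs)))
        tmpl = EvokedTemplate(amp_uv=60, latency_s=0.5)
        triggers = list(np.arange(10.0, 1290.0, 12.5))[:100]
        rec = add_evoked_responses(rec, triggers, tmpl)
        stim = extract_stim_locked(rec, triggers, _n2_hypnogram(1300), cfg)
        wave = tmpl.waveform(100.0)
        true_lat = tmpl.latency_s + np.argmin(wave) / 100.0
        post = stim.time_s >= 0
        got_lat = stim.time_s[post][np.argmin(stim.mean[post])]
        assert got_lat == pytest.approx(true_lat, abs=0.03)


class TestBaseline:
    @pytest.fixture()
    def stim_set(self, cfg):
        rng = np.random.default_rng(8)
        rec = _recording(rng.normal(0, 10, int(300 * 500)) + 15.0)
        triggers = list(np.arange(20.0, 280.0, 10.0))
        return rec, triggers, extract_stim_locked(
            rec, triggers, _n2_hypnogram(300), cfg
        )

    def test_per_epoch_baseline_mean_zero(self, cfg, stim_set):
        _, _, stim = stim_set
        normed = baseline_normalize(stim, cfg)
        b0, b1 = cfg.baseline_window_s
        mask = (normed.time_s >= b0) & (normed.time_s <= b1)
        assert np.allclose(normed.epoch_traces[:, mask].mean(axis=1), 0, atol=1e-9)
        assert normed.baseline_applied

    def test_idempotent(self, cfg, stim_set):
        _, _, stim = stim_set
        once = baseline_normalize(stim, cfg)
        twice = baseline_normalize(once, cfg)
        np.testing.assert_allclose(twice.epoch_traces, once.epoch_traces)

    def test_offset_invariance(self, cfg, stim_set):
        rec, triggers, stim = stim_set
        shifted = _recording(rec.data[0] + 10.0)
        stim2 = extract_stim_locked(shifted, triggers, _n2_hypnogram(300), cfg)
        a = baseline_normalize(stim, cfg)
        b = baseline_normalize(stim2, cfg)
        np.testing.assert_allclose(a.epoch_traces, b.epoch_traces, atol=1e-6)

    def test_window_outside_epoch_is_error(self, cfg, stim_set):
        _, _, stim = stim_set
        bad = cfg.replace(baseline_window_s=(-2.0, -1.5))
        with pytest.raises(ValueError):
            baseline_normalize(stim, bad)


class TestSpindleRmsLocked:
    def test_rms_of_pure_sinusoid_closed_form(self, cfg):
        """RMS envelope of an amplitude-A sinusoid ≈ A/√2 away from edges."""
        fs = 100.0
        t = np.arange(int(30 * fs)) / fs
        x = 35.0 * np.sin(2 * np.pi * 13.0 * t)
        env = spindle_rms_envelope(x, fs, cfg)
        core = env[int(2 * fs) : -int(2 * fs)]
        assert np.allclose(core, 35.0 / np.sqrt(2), rtol=0.05)

    def test_injected_spindle_after_trigger_peaks_in_window(self, cfg):
        """A 1.0-s spindle whose envelope peaks 1.1 s after each trigger: the
        baseline-normalized RMS trace peaks between 0.8 and 1.4 s."""
        from soclas.simulate import make_spindle_waveform

        rng = np.random.default_rng(9)
        fs = 500.0
        x = rng.normal(0, 10, int(600 * fs))
        triggers = list(np.arange(20.0, 580.0, 10.0))
        wave = make_spindle_waveform(13.0, 1.0, 30.0, fs)
        for trig in triggers:
            i0 = int((trig + 0.6) * fs)
            x[i0 : i0 + len(wave)] += wave
        rec = _recording(x)
        peaks = SpindlePeaks(11.0, 13.0)
        out = spindle_rms_locked(
            rec, triggers, _n2_hypnogram(600), peaks, cfg
        )["fast"]
        peak_t = out.time_s[np.argmax(out.mean)]
        assert 0.8 <= peak_t <= 1.4

    def test_no_spindles_traces_fluctuate_around_zero(self, cfg):
        rng = np.random.default_rng(10)
        rec = _recording(rng.normal(0, 10, int(300 * 500)))
        triggers = list(np.arange(20.0, 280.0, 10.0))
        out = spindle_rms_locked(
            rec, triggers, _n2_hypnogram(300), SpindlePeaks(11.0, 13.0), cfg
        )["fast"]
        assert abs(out.mean.mean()) < 0.5  # μV, centred on zero post-baseline


class TestGrandAverage:
    def test_grand_mean_is_mean_of_session_means(self, cfg):
        rng = np.random.default_rng(11)
        t = np.arange(400) / 100.0 - 1.0
        sets = [
            StimLockedSet.from_epochs(t, rng.normal(0, 1, (n, 400)), 0)
            for n in (5, 9, 14)
        ]
        grand = grand_average(sets)
        expected = np.mean([s.mean for s in sets], axis=0)
        np.testing.assert_allclose(grand.mean, expected)
        assert grand.n_epochs == 3

    def test_grid_mismatch_is_error(self):
        t1 = np.arange(400) / 100.0 - 1.0
        s1 = StimLockedSet.from_epochs(t1, np.zeros((3, 400)), 0)
        s2 = StimLockedSet.from_epochs(t1 + 0.5, np.zeros((3, 400)), 0)
        with pytest.raises(ValueError):
            grand_average([s1, s2])
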