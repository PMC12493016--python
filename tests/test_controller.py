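"""Online controller: streams, threshold adaptation, gating and timing."""

import numpy as np
import pytest
from scipy import signal as sps

from soclas import (
    EEGRecording,
    Hypnogram,
    SessionConfig,
    SOEvent,
    delta_theta_ratio,
    individual_delay,
    prepare_streams,
    run_controller,
    select_dt_threshold,
    stimulus_burst,
    update_threshold,
)
from soclas.core import ChannelNotFoundError
from soclas import generate_session

from conftest import scaled_generator


def _recording(x: np.ndarray, fs: float = 500.0, label: str = "Fpz") -> EEGRecording:
    return EEGRecording([label], fs, x[np.newaxis, :])


class TestPrepareStreams:
    def test_dc_offset_removed(self, cfg):
        rec = _recording(np.full(int(60 * 500), 40.0))
        so_stream, _ = prepare_streams(rec, cfg)
        assert abs(so_stream[-1000:].mean()) < 1.0

    def test_10hz_attenuated_at_least_20db(self, cfg):
        t = np.arange(int(60 * 500)) / 500
        rec = _recording(100 * np.sin(2 * np.pi * 10 * t))
        so_stream, _ = prepare_streams(rec, cfg)
        # steady-state amplitude of the tail
        assert np.abs(so_stream[-2000:]).max() < 100 * 10 ** (-20 / 20)

    def test_stream_length_ratio(self, cfg):
        rec = _recording(np.zeros(50000))  # 100 s at 500 Hz
        so_stream, broadband = prepare_streams(rec, cfg)
        assert abs(len(so_stream) - 50000 * 2 / 5) <= 1
        assert len(so_stream) == len(broadband)

    def test_missing_channel(self, cfg):
        rec = _recording(np.zeros(5000), label="Cz")
        with pytest.raises(ChannelNotFoundError, match="Fpz"):
            prepare_streams(rec, cfg)


class TestUpdateThreshold:
    def test_empty_history_returns_initial(self, cfg):
        assert update_threshold(np.array([]), cfg) == -80.0

    def test_never_laxer_than_initial(self, cfg):
        assert update_threshold(np.array([-60.0, -70.0]), cfg) == -80.0

    def test_tracks_deeper_troughs(self, cfg):
        assert update_threshold(np.array([-100.0, -120.0]), cfg) == -110.0


class TestDeltaThetaRatio:
    def test_pure_delta_tone(self, cfg):
        t = np.arange(int(5 * 200)) / 200
        assert delta_theta_ratio(50 * np.sin(2 * np.pi * 1 * t), cfg) > 100

    def test_pure_theta_tone(self, cfg):
        t = np.arange(int(5 * 200)) / 200
        assert delta_theta_ratio(50 * np.sin(2 * np.pi * 6 * t), cfg) < 0.01

    def test_equal_mixture_near_one(self, cfg):
        t = np.arange(int(5 * 200)) / 200
        x = 50 * np.sin(2 * np.pi * 1 * t) + 50 * np.sin(2 * np.pi * 6 * t)
        assert 0.5 <= delta_theta_ratio(x, cfg) <= 2.0

    def test_zero_window_neutral_with_warning(self, cfg):
        with pytest.warns(UserWarning, match="all-zero"):
            assert delta_theta_ratio(np.zeros(1000), cfg) == 1.0


class TestSelectDtThreshold:
    def test_well_separated_classes(self):
        ratios = np.array([30.0] * 50 + [5.0] * 50)
        stages = ["N3"] * 50 + ["Wake"] * 50
        assert select_dt_threshold(ratios, stages) == 6.0

    def test_identical_distributions_warn(self):
        ratios = np.array([10.0] * 40)
        stages = ["N3"] * 20 + ["REM"] * 20
        with pytest.warns(UserWarning, match="degenerate"):
            t = select_dt_threshold(ratios, stages)
        assert t == 10.0  # smallest bin edge

    def test_overlapping_gaussians(self):
        rng = np.random.default_rng(5)
        nrem = rng.normal(25, 3, 200)
        wake = rng.normal(8, 3, 200)
        ratios = np.concatenate([nrem, wake])
        stages = ["N2"] * 200 + ["Wake"] * 200
        assert 13 <= select_dt_threshold(ratios, stages) <= 20

    def test_empty_class_is_error(self):
        with pytest.raises(ValueError):
            select_dt_threshold(np.array([10.0, 20.0]), ["N2", "N3"])


def _so_event(trough_t: float, peak_t: float) -> SOEvent:
    return SOEvent("Fpz", trough_t - 0.5, peak_t + 0.5, trough_t, -100.0,
                   peak_t, 50.0, 1.0, 1.0)


class TestIndividualDelay:
    def test_constant_interval(self):
        events = [_so_event(10.0 + i, 10.45 + i) for i in range(5)]
        assert individual_delay(events) == pytest.approx(450.0)

    def test_mean_of_mixed_intervals(self):
        events = [_so_event(10.0, 10.4), _so_event(20.0, 20.5)]
        assert individual_delay(events) == pytest.approx(450.0)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            individual_delay([])

    def test_half_sine_construction_intervals(self):
        """Events built as half-sines (neg 1.0 s, pos 0.9 s): the trough→peak
        interval is neg/2 + pos/2 = 950 ms."""
        from soclas.simulate import make_so_waveform

        fs = 500.0
        wave = make_so_waveform(-100, 1.0, 60, 0.9, fs)
        trough_t = np.argmin(wave) / fs
        peak_t = np.argmax(wave) / fs
        events = [_so_event(10.0 + 3 * i + trough_t, 10.0 + 3 * i + peak_t) for i in range(100)]
        assert individual_delay(events) == pytest.approx(950.0, abs=20.0)


class TestRunController:
    def test_all_wake_no_triggers(self, cfg):
        rng = np.random.default_rng(0)
        rec = _recording(rng.normal(0, 30, int(300 * 500)))
        hyp = Hypnogram(("Wake",) * 10)
        assert run_controller(rec, hyp, cfg) == []

    def test_single_so_two_bursts_1075ms(self, cfg):
        """One deep SO in stable N3 yields exactly one burst pair, spaced
        1075 ms on the 200-Hz controller clock."""
        from soclas.simulate import make_pink_noise, make_so_waveform

        fs = 500.0
        x = make_pink_noise(600, fs, 2.0, 3)
        # strong delta context so that the NREM gate passes
        t = np.arange(len(x)) / fs
        x = x + 25 * np.sin(2 * np.pi * 1.1 * t)
        wave = make_so_waveform(-160, 0.7, 90, 0.7, fs)
        i0 = int(400 * fs)
        x[i0 : i0 + len(wave)] += wave
        rec = _recording(x)
        hyp = Hypnogram(("N3",) * 20)
        triggers = run_controller(rec, hyp, cfg)
        assert len(triggers) == 2
        assert [tr.burst_index for tr in triggers] == [1, 2]
        spacing_ms = (triggers[1].time_s - triggers[0].time_s) * 1000
        assert spacing_ms == pytest.approx(1075.0, abs=1e-6)
        assert triggers[0].time_s - triggers[0].detection_time_s == pytest.approx(
            cfg.delay_ms / 1000, abs=1e-6
        )

    def test_dense_sos_respect_refractory(self, cfg):
        """Deep troughs every second: consecutive detections are separated by
        at least delay + interburst + refractory."""
        from soclas.simulate import make_so_waveform

        fs = 500.0
        x = np.zeros(int(600 * fs))
        wave = make_so_waveform(-120, 0.5, 80, 0.45, fs)
        for k in range(300, 595):
            i0 = int(k * fs)
            x[i0 : i0 + len(wave)] += wave
        rec = _recording(x)
        hyp = Hypnogram(("N3",) * 20)
        triggers = run_controller(rec, hyp, cfg)
        pairs = [tr for tr in triggers if tr.burst_index == 2]
        dets = sorted(set(tr.detection_time_s for tr in triggers))
        assert len(dets) >= 2
        min_cycle = (cfg.delay_ms + cfg.interburst_ms) / 1000 + cfg.refractory_s
        for a, b in zip(dets, dets[1:]):
            assert b - a >= min_cycle - 1e-6
        for b2, nxt in zip(pairs, dets[1:]):
            assert nxt - b2.time_s >= cfg.refractory_s - 1e-6

    def test_no_triggers_outside_enabled_epochs(self, cfg):
        gen = scaled_generator(
            0.3, duration_s=900, seed=13,
            stages=("N3",) * 12 + ("Wake",) * 6 + ("N3",) * 12,
        )
        rec, hyp, _ = generate_session(gen)
        triggers = run_controller(rec, hyp, cfg)
        assert triggers, "expected some stimulation in stable N3"
        for tr in triggers:
            assert hyp.stage_at(tr.time_s) == "N3"
            ep = hyp.epoch_of(tr.time_s)
            # first bout: enabled after 4 min (8 epochs); later bout: 2 min
            assert ep >= 8

    def test_stimulation_limited_to_first_4h(self, cfg):
        fast = cfg.replace(stim_window_h=0.1)  # 6 min window for test speed
        gen = scaled_generator(0.3, duration_s=900, seed=13, stages=("N3",) * 30)
        rec, hyp, _ = generate_session(gen)
        triggers = run_controller(rec, hyp, fast)
        assert triggers
        assert all(tr.time_s < 0.1 * 3600 + hyp.epoch_length_s for tr in triggers)

    def test_threshold_never_laxer_than_initial(self, cfg):
        gen = scaled_generator(0.3, duration_s=600, seed=17, stages=("N3",) * 20)
        rec, hyp, _ = generate_session(gen)
        triggers = run_controller(rec, hyp, cfg)
        assert triggers
        assert all(tr.threshold_uv <= -80.0 for tr in triggers)
        assert all(tr.dt_ratio >= cfg.dt_ratio_threshold for tr in triggers)

    def test_burst_timing_tracks_true_troughs(self, cfg):
        """Steep (~1-Hz) SOs at high SNR: burst 1 lands within 50 ms of
        trough + delay (median over pairs)."""
        gen = scaled_generator(
            0.2, duration_s=600, seed=11, stages=("N3",) * 20,
            so_neg_dur_range_s=(0.5, 0.7), so_pos_dur_range_s=(0.6, 0.9),
        )
        rec, hyp, truth = generate_session(gen)
        triggers = run_controller(rec, hyp, cfg)
        b1 = [tr for tr in triggers if tr.burst_index == 1]
        assert len(b1) >= 10
        troughs = np.array([ev.trough_time_s for ev in truth.so_on("Fpz")])
        errs = [
            np.abs(troughs - (tr.time_s - cfg.delay_ms / 1000)).min() for tr in b1
        ]
        assert np.median(errs) <= 0.050

    def test_causality_under_truncation(self, cfg):
        """Triggers of a truncated run equal the full run's prefix."""
        gen = scaled_generator(0.3, duration_s=600, seed=19, stages=("N3",) * 20)
        rec, hyp, _ = generate_session(gen)
        full = run_controller(rec, hyp, cfg)
        assert full
        for t_cut in (300.0, 450.0):
            part = run_controller(rec.truncate(t_cut), hyp.truncate(t_cut), cfg)
            margin = (cfg.delay_ms + cfg.interburst_ms) / 1000
            expected = [tr for tr in full if tr.time_s <= t_cut - margin]
            got = [tr for tr in part if tr.time_s <= t_cut - margin]
            assert [(tr.time_s, tr.burst_index) for tr in got] == [
                (tr.time_s, tr.burst_index) for tr in expected
            ]


def test_stimulus_burst_envelope(cfg):
    burst = stimulus_burst(cfg, 44100.0, seed=0)
    assert len(burst) == int(round(0.050 * 44100))
    ramp_n = int(round(0.005 * 44100))
    assert np.abs(burst[:2]).max() < np.abs(burst).max() * 0.05
    assert abs(burst[-1]) < 1e-9
    assert np.abs(burst[ramp_n:-ramp_n]).max() > 0
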