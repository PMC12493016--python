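"""Sleep-spindle detection at individual peak frequencies via RMS thresholding.

Per channel, individual slow (9–12 Hz) and fast (12–16 Hz) spindle peak
frequencies are first read off the NREM power spectrum.  Detection then
runs on the 35-Hz low-passed, 100-Hz downsampled signal: a 3-Hz-wide FIR
band-pass centred on the peak frequency, a 0.2-s sliding-window RMS (step
one sample), 0.2-s moving-average smoothing, and thresholding at 1.5 SD of
the band-passed NREM signal for 0.5–3 s with at least one sample above
2.5 SD.  Neighbouring detections closer than 0.5 s are merged when their
total supra-threshold time stays below 3 s.  Because both thresholds are
standard deviations of the signal itself, the detected event set is
invariant to global amplitude scaling and to DC offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import EEGRecording, Hypnogram, SpindleEvent
from .config import SessionConfig
from .filters import design_spindle_bandpass, lowpass_downsample, zero_phase_fir


@dataclass
class SpindlePeaks:
    """Individual slow and fast spindle peak frequencies (Hz)."""

    slow_peak_hz: float
    fast_peak_hz: float

    def center(self, type: str) -> float:
        return self.slow_peak_hz if type == "slow" else self.fast_peak_hz


@dataclass
class SpindleSummary:
    channel: str
    type: str
    count: int
    density_per_epoch: float  # per 30 s of artefact-free NREM
    mean_p2p_uv: float
    mean_length_s: float
    mean_rms_uv: float


def estimate_spindle_peaks(
    recording: EEGRecording,
    hypnogram: Hypnogram,
    config: SessionConfig,
    channel: str | None = None,
) -> SpindlePeaks:
    """Peak frequency of maximal NREM power within each spindle range.

    A peak sitting on a range boundary or barely rising above the
    surrounding spectrum is reported with a warning rather than rejected —
    the individual peak always exists, it just may be poorly defined.
    """
    from .spectral import power_spectrum

    ch = channel or recording.channel_labels[0]
    spec = power_spectrum(recording, hypnogram, config, channels=[ch])[ch]
    freqs, psd = spec.freqs_hz, spec.psd
    peaks = {}
    for name, band in (
        ("slow", config.slow_spindle_range_hz),
        ("fast", config.fast_spindle_range_hz),
    ):
        mask = (freqs >= band[0]) & (freqs <= band[1])
        sub_f, sub_p = freqs[mask], psd[mask]
        k = int(np.argmax(sub_p))
        if k in (0, len(sub_p) - 1):
            warnings.warn(
                f"{name} spindle peak sits on the {band} Hz range boundary",
                stacklevel=2,
            )
        med = np.median(sub_p)
        if med > 0 and sub_p[k] < 2.0 * med:
            warnings.warn(
                f"low-prominence {name} spindle peak at {sub_f[k]:.2f} Hz",
                stacklevel=2,
            )
        peaks[name] = float(sub_f[k])
    return SpindlePeaks(slow_peak_hz=peaks["slow"], fast_peak_hz=peaks["fast"])


def _moving_mean(x: np.ndarray, win: int) -> np.ndarray:
    """Centred moving average, same length (edges use partial windows)."""
    kernel = np.ones(win)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def spindle_rms_envelope(
    band: np.ndarray, fs: float, config: SessionConfig
) -> np.ndarray:
    """Sliding-window RMS (step one sample) followed by moving-average smoothing."""
    win = max(1, int(round(config.rms_window_s * fs)))
    rms = np.sqrt(_moving_mean(band**2, win))
    smooth_win = max(1, int(round(config.smooth_window_s * fs)))
    return _moving_mean(rms, smooth_win)


def detect_spindles(
    recording: EEGRecording,
    hypnogram: Hypnogram,
    peaks: SpindlePeaks,
    config: SessionConfig,
    channel: str | None = None,
    types: tuple[str, ...] = ("slow", "fast"),
) -> list[SpindleEvent]:
    """Detect slow and fast spindles on one channel (default: first).

    Detection is independent per type; an interval crossing both bands may
    appear in both lists.  Events are restricted to artefact-free N2/N3.
    """
    ch = channel or recording.channel_labels[0]
    fs_in = recording.sampling_rate_hz
    fs = config.erp_fs_hz
    x = lowpass_downsample(recording.channel(ch), fs_in, fs, config.erp_lowpass_hz - 3.0)
    nrem = hypnogram.sample_mask(fs, len(x))
    if not nrem.any():
        return []

    dur_lo, dur_hi = config.spindle_dur_bounds_s
    events: list[SpindleEvent] = []
    for sp_type in types:
        taps = design_spindle_bandpass(fs, peaks.center(sp_type), config.spindle_bandwidth_hz)
        band = zero_phase_fir(x, taps)
        sd = band[nrem].std()
        if sd == 0:
            continue
        env = spindle_rms_envelope(band, fs, config)
        above = (env > config.spindle_thresh_sd * sd) & nrem

        # contiguous supra-threshold segments
        edges = np.diff(above.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(len(above))

        segs = []
        for s, e in zip(starts, ends):
            dur = (e - s) / fs
            if not dur_lo <= dur <= dur_hi:
                continue
            if not np.any(env[s:e] > config.spindle_peak_sd * sd):
                continue
            segs.append((s, e))

        # merge rule: gap < merge_gap_s and combined supra-threshold
        # time < merge_total_max_s, else keep separate
        merged: list[list[int]] = []  # [start, end, n_merged, supra_samples]
        for s, e in segs:
            if merged:
                ps, pe, pn, psupra = merged[-1]
                gap = (s - pe) / fs
                supra = (psupra + (e - s)) / fs
                if gap < config.merge_gap_s and supra < config.merge_total_max_s:
                    merged[-1] = [ps, e, pn + 1, psupra + (e - s)]
                    continue
            merged.append([s, e, 1, e - s])

        for s, e, n_merged, _ in merged:
            seg = band[s:e]
            events.append(
                SpindleEvent(
                    channel=ch,
                    type=sp_type,
                    start_s=s / fs,
                    end_s=e / fs,
                    p2p_amp_uv=float(seg.max() - seg.min()),
                    mean_rms_uv=float(env[s:e].mean()),
                    merged_from=n_merged,
                )
            )
    events.sort(key=lambda ev: (ev.type, ev.start_s))
    return events


def spindle_recall(events: list[SpindleEvent], truth_spindles) -> float:
    """Fraction of injected spindles whose midpoint falls inside a detection
    of the same type."""
    if not truth_spindles:
        return float("nan")
    hits = 0
    for tr in truth_spindles:
        mid = 0.5 * (tr.start_s + tr.end_s)
        hits += any(
            ev.type == tr.type and ev.start_s <= mid <= ev.end_s for ev in events
        )
    return hits / len(truth_spindles)


def summarize_spindles(
    events: list[SpindleEvent],
    hypnogram: Hypnogram,
    config: SessionConfig,
    channel: str | None = None,
) -> dict[str, SpindleSummary]:
    """Per-type count, density (per 30 s NREM), mean p2p, length and RMS."""
    n_nrem = int(hypnogram.epoch_mask().sum())
    out: dict[str, SpindleSummary] = {}
    for sp_type in ("slow", "fast"):
        evs = [ev for ev in events if ev.type == sp_type]
        ch = channel or (evs[0].channel if evs else "")
        density = len(evs) / n_nrem if n_nrem else float("nan")
        if not evs:
            nan = float("nan")
            out[sp_type] = SpindleSummary(ch, sp_type, 0, density, nan, nan, nan)
            continue
        out[sp_type] = SpindleSummary(
            channel=ch,
            type=sp_type,
            count=len(evs),
            density_per_epoch=density,
            mean_p2p_uv=float(np.mean([ev.p2p_amp_uv for ev in evs])),
            mean_length_s=float(np.mean([ev.length_s for ev in evs])),
            mean_rms_uv=float(np.mean([ev.mean_rms_uv for ev in evs])),
        )
    return out
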