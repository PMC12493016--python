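"""Power spectra, band powers and stimulus-locked time courses.

Spectra are Welch averages of Hanning-windowed 4096-point periodograms with
50 % overlap over artefact-free NREM stretches (frequency resolution
fs/4096, i.e. 0.12 Hz at 500 Hz).  Stimulus-locked analyses low-pass the
EEG at 35 Hz (FIR, −3 dB at 32.0 Hz), downsample to 100 Hz, and extract
[−1, 3) s windows around first-burst triggers from artefact-free N2/N3
epochs; per-epoch baseline normalization subtracts the mean over
[−0.99, −0.01] s.  Per-session averaging precedes grand averaging, so the
per-session layer is stored explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .core import EEGRecording, Hypnogram
from .config import SessionConfig
from .filters import design_spindle_bandpass, lowpass_downsample, zero_phase_fir
from .spindles import SpindlePeaks, spindle_rms_envelope


@dataclass
class PowerSpectrum:
    """One-sided PSD in μV²/Hz on a uniform grid starting at 0 Hz."""

    freqs_hz: np.ndarray
    psd: np.ndarray
    n_segments: int


@dataclass
class StimLockedSet:
    """Stimulus-locked epochs of one session plus their mean ± SEM."""

    time_s: np.ndarray
    epoch_traces: np.ndarray  # (n_epochs, n_times)
    mean: np.ndarray
    sem: np.ndarray
    n_epochs: int
    n_excluded: int
    baseline_applied: bool = False
    baseline_window_s: Optional[tuple[float, float]] = None

    @classmethod
    def from_epochs(
        cls, time_s: np.ndarray, traces: np.ndarray, n_excluded: int, **kw
    ) -> "StimLockedSet":
        traces = np.atleast_2d(np.asarray(traces, dtype=float))
        mean = traces.mean(axis=0)
        if traces.shape[0] > 1:
            sem = traces.std(axis=0, ddof=1) / np.sqrt(traces.shape[0])
        else:
            sem = np.zeros_like(mean)
        return cls(
            time_s=np.asarray(time_s),
            epoch_traces=traces,
            mean=mean,
            sem=sem,
            n_epochs=traces.shape[0],
            n_excluded=n_excluded,
            **kw,
        )


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def _nrem_runs(hypnogram: Hypnogram, fs: float, n_samples: int) -> list[tuple[int, int]]:
    """Contiguous artefact-free N2/N3 sample runs."""
    mask = hypnogram.sample_mask(fs, n_samples)
    edges = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask.any() and mask[-1]:
        ends.append(n_samples)
    return list(zip(starts, ends))


def power_spectrum(
    recording: EEGRecording,
    hypnogram: Hypnogram,
    config: SessionConfig,
    channels: Optional[Sequence[str]] = None,
) -> dict[str, PowerSpectrum]:
    """Welch PSD over artefact-free NREM sleep, per channel.

    Density-normalized: a unit-variance white signal integrates to ≈ 1.
    Raises if no NREM run reaches one full FFT window.
    """
    channels = list(channels or recording.channel_labels)
    fs = recording.sampling_rate_hz
    nperseg = config.fft_n
    noverlap = int(round(config.fft_overlap * nperseg))
    runs = [
        (s, e) for s, e in _nrem_runs(hypnogram, fs, recording.n_samples) if e - s >= nperseg
    ]
    if not runs:
        raise ValueError(
            f"no artefact-free NREM stretch of at least {nperseg} samples "
            f"({nperseg / fs:.1f} s) available"
        )
    out: dict[str, PowerSpectrum] = {}
    for ch in channels:
        x = recording.channel(ch)
        acc = None
        total_segments = 0
        for s, e in runs:
            k = 1 + (e - s - nperseg) // (nperseg - noverlap)
            freqs, psd = signal.welch(
                x[s:e],
                fs=fs,
                window="hann",
                nperseg=nperseg,
                noverlap=noverlap,
                detrend="constant",
            )
            acc = psd * k if acc is None else acc + psd * k
            total_segments += k
        out[ch] = PowerSpectrum(freqs_hz=freqs, psd=acc / total_segments, n_segments=total_segments)
    return out


def band_powers(
    spectrum: PowerSpectrum, bands_hz: dict[str, tuple[float, float]]
) -> dict[str, float]:
    """log10 of the integrated PSD over each half-open band [lo, hi)."""
    freqs, psd = spectrum.freqs_hz, spectrum.psd
    df = freqs[1] - freqs[0]
    out: dict[str, float] = {}
    for name, (lo, hi) in bands_hz.items():
        if lo < freqs[0] or hi > freqs[-1] + df:
            raise ValueError(f"band {name!r} {lo}-{hi} Hz outside spectrum range")
        power = float(psd[(freqs >= lo) & (freqs < hi)].sum() * df)
        if power <= 0:
            raise ValueError(f"band {name!r} has zero power: log10 undefined")
        out[name] = float(np.log10(power))
    return out


# ---------------------------------------------------------------------------
# stimulus-locked time courses
# ---------------------------------------------------------------------------

def _extract_epochs(
    trace: np.ndarray,
    fs: float,
    triggers: Sequence[float],
    hypnogram: Hypnogram,
    config: SessionConfig,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Half-open [t0, t1) windows on the ``fs`` grid around each trigger.

    Windows touching the recording edge, an artefact epoch, or a staging
    epoch outside N2/N3 are excluded and counted.
    """
    t0, t1 = config.erp_window_s
    n_win = int(round((t1 - t0) * fs))
    time_s = t0 + np.arange(n_win) / fs
    ok_epochs = hypnogram.epoch_mask()
    segs = []
    excluded = 0
    for trig in triggers:
        c = int(round(trig * fs))  # snapped to the grid
        lo = c + int(round(t0 * fs))
        hi = lo + n_win
        if lo < 0 or hi > len(trace):
            excluded += 1
            continue
        ep_lo = hypnogram.epoch_of(lo / fs)
        ep_hi = hypnogram.epoch_of((hi - 1) / fs)
        if not all(ok_epochs[e] for e in range(ep_lo, ep_hi + 1)):
            excluded += 1
            continue
        segs.append(trace[lo:hi])
    if not segs:
        raise ValueError("no usable stimulus-locked windows")
    return time_s, np.asarray(segs), excluded


def extract_stim_locked(
    recording: EEGRecording,
    triggers: Sequence[float],
    hypnogram: Hypnogram,
    config: SessionConfig,
    channel: Optional[str] = None,
) -> StimLockedSet:
    """Stimulus-locked EEG epochs: 35-Hz low-pass, 100 Hz, [−1, 3) s windows."""
    ch = channel or recording.channel_labels[0]
    fs = config.erp_fs_hz
    trace = lowpass_downsample(
        recording.channel(ch), recording.sampling_rate_hz, fs, config.erp_lowpass_hz - 3.0
    )
    time_s, segs, excluded = _extract_epochs(trace, fs, triggers, hypnogram, config)
    return StimLockedSet.from_epochs(time_s, segs, excluded)


def baseline_normalize(stim_set: StimLockedSet, config: SessionConfig) -> StimLockedSet:
    """Subtract each epoch's mean over the baseline window (idempotent)."""
    b0, b1 = config.baseline_window_s
    t = stim_set.time_s
    if b0 < t[0] or b1 > t[-1]:
        raise ValueError(f"baseline window {b0}-{b1} s outside the epoch window")
    mask = (t >= b0) & (t <= b1)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    traces = stim_set.epoch_traces - stim_set.epoch_traces[:, mask].mean(
        axis=1, keepdims=True
    )
    return StimLockedSet.from_epochs(
        t,
        traces,
        stim_set.n_excluded,
        baseline_applied=True,
        baseline_window_s=(b0, b1),
    )


def spindle_rms_locked(
    recording: EEGRecording,
    triggers: Sequence[float],
    hypnogram: Hypnogram,
    peaks: SpindlePeaks,
    config: SessionConfig,
    channel: Optional[str] = None,
) -> dict[str, StimLockedSet]:
    """Stimulus-locked slow/fast spindle RMS traces, baseline-normalized.

    Pipeline: 3-Hz-wide band-pass at the individual peak frequency →
    0.2-s sliding RMS → 0.2-s smoothing → [−1, 3) s epochs → per-epoch
    baseline subtraction.
    """
    ch = channel or recording.channel_labels[0]
    fs = config.erp_fs_hz
    x = lowpass_downsample(
        recording.channel(ch), recording.sampling_rate_hz, fs, config.erp_lowpass_hz - 3.0
    )
    out: dict[str, StimLockedSet] = {}
    for sp_type in ("slow", "fast"):
        taps = design_spindle_bandpass(fs, peaks.center(sp_type), config.spindle_bandwidth_hz)
        env = spindle_rms_envelope(zero_phase_fir(x, taps), fs, config)
        time_s, segs, excluded = _extract_epochs(env, fs, triggers, hypnogram, config)
        raw = StimLockedSet.from_epochs(time_s, segs, excluded)
        out[sp_type] = baseline_normalize(raw, config)
    return out


def grand_average(sets: Sequence[StimLockedSet]) -> StimLockedSet:
    """Grand mean ± SEM across sessions (mean of per-session means).

    Statistics are computed per subject/session first; the grand mean
    weighs every session equally regardless of its epoch count.
    """
    if not sets:
        raise ValueError("need at least one session")
    t = sets[0].time_s
    for s in sets[1:]:
        if len(s.time_s) != len(t) or not np.allclose(s.time_s, t):
            raise ValueError("sessions disagree on the time grid")
    session_means = np.array([s.mean for s in sets])
    return StimLockedSet.from_epochs(
        t,
        session_means,
        n_excluded=sum(s.n_excluded for s in sets),
        baseline_applied=all(s.baseline_applied for s in sets),
        baseline_window_s=sets[0].baseline_window_s,
    )
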