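"""Synthetic polysomnography with exact ground truth.

The generator emulates the features of NREM sleep EEG that the detectors in
this package rely on: a pink (1/f) broadband background whose amplitude is
stage-dependent, extra delta colouring in N3 (and less in N2), extra theta
in REM/Wake, slow oscillations injected as biphasic half-sine waveforms in
N2/N3, sleep spindles as amplitude-modulated sinusoids optionally coupled
to the SO up-state, and K-complex-like damped biphasic evoked responses to
acoustic triggers.  Every injected event is recorded with sample-exact
timing in a :class:`GroundTruth` object, and a seed fully determines the
output (random streams are split per event family, so e.g. adding spindles
does not perturb SO placement).

It is a test harness, not a biophysical model: real EEG has asymmetric
SO shapes, non-stationary background and arousal microstructure that are
deliberately absent here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import signal

from .core import EEGRecording, Hypnogram, NREM_STAGES


# ---------------------------------------------------------------------------
# primitive waveforms
# ---------------------------------------------------------------------------

def make_pink_noise(
    duration_s: float,
    fs_hz: float,
    scale_uv: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Zero-mean pink (1/f power) noise with standard deviation ``scale_uv``.

    Synthesized in the frequency domain: white Gaussian spectrum shaped by
    1/sqrt(f), giving a power spectral density falling ~1/f.
    """
    if fs_hz <= 0:
        raise ValueError("fs_hz must be > 0")
    if duration_s < 0:
        raise ValueError("duration_s must be >= 0")
    n = int(round(duration_s * fs_hz))
    if n == 0:
        return np.zeros(0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * shaping, n=n)
    x -= x.mean()
    sd = x.std()
    if sd > 0 and scale_uv > 0:
        x *= scale_uv / sd
    elif scale_uv == 0:
        x[:] = 0.0
    return x


def make_so_waveform(
    trough_amp_uv: float,
    neg_dur_s: float,
    pos_amp_uv: float,
    pos_dur_s: float,
    fs_hz: float,
) -> np.ndarray:
    """Biphasic SO template: negative half-sine then positive half-sine.

    Zero at both ends and continuous at the junction.  ``pos_amp_uv = 0``
    yields a monophasic negative half-wave.
    """
    for name, val in (
        ("trough_amp_uv", trough_amp_uv),
        ("neg_dur_s", neg_dur_s),
        ("pos_amp_uv", pos_amp_uv),
        ("pos_dur_s", pos_dur_s),
        ("fs_hz", fs_hz),
    ):
        if not np.isfinite(val):
            raise ValueError(f"{name} must be finite")
    if not trough_amp_uv < 0:
        raise ValueError("trough_amp_uv must be < 0")
    if pos_amp_uv < 0:
        raise ValueError("pos_amp_uv must be >= 0")
    if neg_dur_s <= 0 or pos_dur_s <= 0:
        raise ValueError("durations must be > 0")
    n_neg = int(round(neg_dur_s * fs_hz))
    n_pos = int(round(pos_dur_s * fs_hz))
    t_neg = np.arange(n_neg) / fs_hz
    t_pos = np.arange(n_pos) / fs_hz
    neg = trough_amp_uv * np.abs(np.sin(np.pi * t_neg / neg_dur_s))
    pos = pos_amp_uv * np.sin(np.pi * t_pos / pos_dur_s)
    if pos_amp_uv == 0:
        pos = np.zeros(0)
    return np.concatenate([neg, pos])


def make_spindle_waveform(
    freq_hz: float, dur_s: float, amp_uv: float, fs_hz: float
) -> np.ndarray:
    """Sinusoid under a raised-cosine (Hann) envelope; peak envelope ``amp_uv``."""
    if dur_s <= 0:
        raise ValueError("dur_s must be > 0")
    if freq_hz <= 0:
        raise ValueError("freq_hz must be > 0")
    n = int(round(dur_s * fs_hz))
    t = np.arange(n) / fs_hz
    envelope = 0.5 * (1 - np.cos(2 * np.pi * t / dur_s))
    return amp_uv * envelope * np.sin(2 * np.pi * freq_hz * t)


@dataclass
class EvokedTemplate:
    """K-complex-like damped biphasic response: A·exp(−t/τ)·sin(2πft)."""

    amp_uv: float = 60.0
    freq_hz: float = 1.0
    decay_s: float = 0.5
    latency_s: float = 0.5
    duration_s: float = 2.0

    def waveform(self, fs_hz: float) -> np.ndarray:
        n = int(round(self.duration_s * fs_hz))
        t = np.arange(n) / fs_hz
        # negative-first deflection, as for an evoked K-complex
        return -self.amp_uv * np.exp(-t / self.decay_s) * np.sin(
            2 * np.pi * self.freq_hz * t
        )


# ---------------------------------------------------------------------------
# session-level generation
# ---------------------------------------------------------------------------

class TrueSO(NamedTuple):
    channel: str
    trough_time_s: float
    trough_amp_uv: float
    neg_halfwave_s: float
    pos_halfwave_s: float
    pos_peak_amp_uv: float = 0.0


class TrueSpindle(NamedTuple):
    channel: str
    start_s: float
    end_s: float
    freq_hz: float
    amp_uv: float
    type: str  # "slow" | "fast"


@dataclass
class GroundTruth:
    """Exact record of every injected event of a generated session."""

    so_events: list[TrueSO] = field(default_factory=list)
    spindle_events: list[TrueSpindle] = field(default_factory=list)
    evoked_times: list[float] = field(default_factory=list)
    stage_plan: Optional[Hypnogram] = None

    def so_on(self, channel: str) -> list[TrueSO]:
        return [ev for ev in self.so_events if ev.channel == channel]

    def spindles_on(self, channel: str, type: Optional[str] = None) -> list[TrueSpindle]:
        return [
            ev
            for ev in self.spindle_events
            if ev.channel == channel and (type is None or ev.type == type)
        ]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic session generator.

    Defaults emulate a full 8-h night at the 500-Hz acquisition rate, with
    SO trough amplitudes in the −150 to −80 μV range, slow spindles around
    10.8 Hz and fast spindles around 13.5 Hz, and Poisson event counts per
    30-s N2/N3 epoch.
    """

    duration_s: float = 8 * 3600.0
    fs_hz: float = 500.0
    channels: tuple[str, ...] = ("Fpz", "Fz", "Cz")
    epoch_length_s: float = 30.0
    #: broadband pink-noise SD per stage (μV)
    background_scale_uv: dict = field(
        default_factory=lambda: {"Wake": 15.0, "N1": 15.0, "N2": 18.0, "N3": 20.0, "REM": 15.0}
    )
    #: extra delta-band (0.5–2 Hz) colouring per stage (μV SD); most N3
    #: delta power comes from the injected SOs themselves, as in real SWA
    delta_extra_uv: dict = field(
        default_factory=lambda: {"Wake": 0.0, "N1": 3.0, "N2": 8.0, "N3": 12.0, "REM": 0.0}
    )
    #: extra theta-band (4–8 Hz) colouring per stage (μV SD)
    theta_extra_uv: dict = field(
        default_factory=lambda: {"Wake": 8.0, "N1": 6.0, "N2": 0.0, "N3": 0.0, "REM": 10.0}
    )
    #: mean SO count per 30-s epoch, by stage
    so_rate_per_epoch: dict = field(default_factory=lambda: {"N2": 1.5, "N3": 5.0})
    so_amp_range_uv: tuple[float, float] = (-150.0, -80.0)
    so_neg_dur_range_s: tuple[float, float] = (1.0, 1.4)
    so_pos_dur_range_s: tuple[float, float] = (1.0, 1.4)
    #: positive peak amplitude as a fraction of |trough|
    so_pos_frac_range: tuple[float, float] = (0.4, 0.7)
    #: mean spindle count per 30-s N2/N3 epoch, per type
    spindle_rate_per_epoch: dict = field(default_factory=lambda: {"slow": 1.0, "fast": 2.0})
    spindle_freq_ranges: dict = field(
        default_factory=lambda: {"slow": (10.3, 11.3), "fast": (13.0, 14.0)}
    )
    spindle_amp_range_uv: tuple[float, float] = (15.0, 30.0)
    spindle_dur_range_s: tuple[float, float] = (0.6, 1.5)
    #: probability that a spindle is coupled to an SO up-state
    coupling_prob: float = 0.5
    #: spindle onset relative to the SO positive peak (s)
    coupling_offset_s: float = 0.0
    evoked_template: EvokedTemplate = field(default_factory=EvokedTemplate)
    #: explicit stage plan (one token per epoch); None draws plausible cycles
    stages: Optional[Sequence[str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz < 100:
            raise ValueError("fs_hz must be >= 100")
        for name in ("so_rate_per_epoch", "spindle_rate_per_epoch"):
            if any(v < 0 for v in getattr(self, name).values()):
                raise ValueError(f"{name} rates must be >= 0")
        if not 0 <= self.coupling_prob <= 1:
            raise ValueError("coupling_prob must lie in [0, 1]")


def _plan_stages(n_epochs: int, rng: np.random.Generator) -> tuple[str, ...]:
    """Plausible hypnogram: brief wake/N1 onset, then N2→N3→N2→REM cycles.

    Across cycles, N3 shrinks and REM grows, mimicking the usual overnight
    redistribution of deep and REM sleep.
    """
    plan: list[str] = ["Wake", "Wake", "N1", "N1"]
    cycle = 0
    while len(plan) < n_epochs:
        n3 = max(4, int(round(rng.normal(30 - 8 * cycle, 3))))
        rem = max(2, int(round(rng.normal(10 + 6 * cycle, 2))))
        n2a = max(4, int(round(rng.normal(20, 3))))
        n2b = max(2, int(round(rng.normal(10, 2))))
        plan += ["N2"] * n2a + ["N3"] * n3 + ["N2"] * n2b + ["REM"] * rem
        cycle += 1
    return tuple(plan[:n_epochs])


def _band_noise(
    n: int, fs_hz: float, band: tuple[float, float], scale_uv: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited Gaussian noise with SD ``scale_uv``."""
    if scale_uv <= 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs_hz, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x * (scale_uv / sd) if sd > 0 else x


def _place_without_overlap(
    count: int,
    lo_s: float,
    hi_s: float,
    length_s: float,
    rng: np.random.Generator,
    max_tries: int = 50,
) -> list[float]:
    """Uniform starts in [lo, hi - length) rejecting overlaps; drops on failure."""
    placed: list[float] = []
    span = hi_s - lo_s - length_s
    if span <= 0:
        return placed
    for _ in range(count):
        for _ in range(max_tries):
            start = lo_s + rng.uniform(0, span)
            if all(abs(start - p) >= length_s for p in placed):
                placed.append(start)
                break
    return sorted(placed)


def generate_session(
    cfg: GeneratorConfig,
) -> tuple[EEGRecording, Hypnogram, GroundTruth]:
    """Generate a seeded synthetic session with exact ground truth.

    SOs and spindles are injected only into N2/N3 epochs, with Poisson
    counts per epoch at the configured rates; a configurable fraction of
    spindles is coupled to the SO up-state.  The same event waveforms are
    injected on every channel (a frontal-montage idealization); the
    background noise is independent per channel.
    """
    if cfg.duration_s < cfg.epoch_length_s:
        raise ValueError("duration must cover at least one epoch")
    fs = cfg.fs_hz
    n_samples = int(round(cfg.duration_s * fs))
    n_epochs = int(np.ceil(cfg.duration_s / cfg.epoch_length_s))

    root = np.random.SeedSequence(cfg.seed)
    ss_stages, ss_so, ss_spindle, ss_background = root.spawn(4)
    rng_stages = np.random.default_rng(ss_stages)
    rng_so = np.random.default_rng(ss_so)
    rng_spindle = np.random.default_rng(ss_spindle)

    if cfg.stages is not None:
        stages = tuple(cfg.stages)
        if len(stages) != n_epochs:
            raise ValueError(
                f"explicit stage plan has {len(stages)} epochs, need {n_epochs}"
            )
    else:
        stages = _plan_stages(n_epochs, rng_stages)
    hypnogram = Hypnogram(stages=stages, epoch_length_s=cfg.epoch_length_s)

    # --- event placement (shared across channels) --------------------------
    so_list: list[tuple[float, np.ndarray, TrueSO]] = []
    spindle_list: list[tuple[float, np.ndarray, TrueSpindle]] = []
    for ep, stage in enumerate(stages):
        rate = cfg.so_rate_per_epoch.get(stage, 0.0)
        ep_lo = ep * cfg.epoch_length_s
        ep_hi = min((ep + 1) * cfg.epoch_length_s, cfg.duration_s)
        if rate > 0:
            count = rng_so.poisson(rate)
            max_len = cfg.so_neg_dur_range_s[1] + cfg.so_pos_dur_range_s[1]
            starts = _place_without_overlap(count, ep_lo, ep_hi, max_len, rng_so)
            for start in starts:
                trough = rng_so.uniform(*cfg.so_amp_range_uv)
                neg_dur = rng_so.uniform(*cfg.so_neg_dur_range_s)
                pos_dur = rng_so.uniform(*cfg.so_pos_dur_range_s)
                pos_amp = -trough * rng_so.uniform(*cfg.so_pos_frac_range)
                wave = make_so_waveform(trough, neg_dur, pos_amp, pos_dur, fs)
                so_list.append(
                    (
                        start,
                        wave,
                        TrueSO("*", start + neg_dur / 2, trough, neg_dur, pos_dur, pos_amp),
                    )
                )
        if stage in NREM_STAGES:
            for sp_type, sp_rate in cfg.spindle_rate_per_epoch.items():
                if sp_rate <= 0:
                    continue
                count = rng_spindle.poisson(sp_rate)
                for _ in range(count):
                    freq = rng_spindle.uniform(*cfg.spindle_freq_ranges[sp_type])
                    dur = rng_spindle.uniform(*cfg.spindle_dur_range_s)
                    amp = rng_spindle.uniform(*cfg.spindle_amp_range_uv)
                    coupled = (
                        rng_spindle.uniform() < cfg.coupling_prob
                        and any(ep_lo <= s < ep_hi for s, _, _ in so_list)
                    )
                    if coupled:
                        host = [
                            tso
                            for s, _, tso in so_list
                            if ep_lo <= s < ep_hi
                        ]
                        tso = host[rng_spindle.integers(len(host))]
                        # onset at SO positive peak + configured offset
                        start = (
                            tso.trough_time_s
                            + tso.neg_halfwave_s / 2
                            + tso.pos_halfwave_s / 2
                            + cfg.coupling_offset_s
                        )
                    else:
                        start = rng_spindle.uniform(ep_lo, ep_hi - dur)
                    if start < 0 or start + dur > cfg.duration_s:
                        continue
                    wave = make_spindle_waveform(freq, dur, amp, fs)
                    spindle_list.append(
                        (start, wave, TrueSpindle("*", start, start + dur, freq, amp, sp_type))
                    )

    # --- assemble channels ---------------------------------------------------
    data = np.zeros((len(cfg.channels), n_samples))
    bg_streams = ss_background.spawn(len(cfg.channels))
    spe = int(round(cfg.epoch_length_s * fs))
    for ci, ss in enumerate(bg_streams):
        rng_bg = np.random.default_rng(ss)
        x = make_pink_noise(cfg.duration_s, fs, 1.0, rng_bg)
        # stage-dependent broadband scaling
        scale = np.ones(n_samples)
        for ep, stage in enumerate(stages):
            lo, hi = ep * spe, min((ep + 1) * spe, n_samples)
            scale[lo:hi] = cfg.background_scale_uv.get(stage, 15.0)
        x = x * scale
        # stage-specific oscillatory colouring
        for extra, band in (
            (cfg.delta_extra_uv, (0.5, 2.0)),
            (cfg.theta_extra_uv, (4.0, 8.0)),
        ):
            if any(v > 0 for v in extra.values()):
                coloured = _band_noise(n_samples, fs, band, 1.0, rng_bg)
                amp = np.zeros(n_samples)
                for ep, stage in enumerate(stages):
                    lo, hi = ep * spe, min((ep + 1) * spe, n_samples)
                    amp[lo:hi] = extra.get(stage, 0.0)
                x = x + coloured * amp
        data[ci] = x

    truth = GroundTruth(stage_plan=hypnogram)
    for start, wave, tso in so_list:
        i0 = int(round(start * fs))
        i1 = min(i0 + len(wave), n_samples)
        data[:, i0:i1] += wave[: i1 - i0]
        for ch in cfg.channels:
            truth.so_events.append(tso._replace(channel=ch))
    for start, wave, tsp in spindle_list:
        i0 = int(round(start * fs))
        i1 = min(i0 + len(wave), n_samples)
        data[:, i0:i1] += wave[: i1 - i0]
        for ch in cfg.channels:
            truth.spindle_events.append(tsp._replace(channel=ch))

    recording = EEGRecording(
        channel_labels=list(cfg.channels), sampling_rate_hz=fs, data=data
    )
    return recording, hypnogram, truth


def add_evoked_responses(
    recording: EEGRecording,
    trigger_times: Sequence[float],
    template: EvokedTemplate,
) -> EEGRecording:
    """Superimpose the evoked template at each trigger + its fixed latency.

    Returns a new recording; a trigger outside the recording raises an
    error naming the offending index.
    """
    fs = recording.sampling_rate_hz
    wave = template.waveform(fs)
    data = recording.data.copy()
    for idx, t in enumerate(trigger_times):
        if t < 0 or t > recording.duration_s:
            raise ValueError(f"trigger {idx} at {t:.3f} s is outside the recording")
        i0 = int(round((t + template.latency_s) * fs))
        i1 = min(i0 + len(wave), recording.n_samples)
        if i0 < recording.n_samples:
            data[:, i0:i1] += wave[: i1 - i0]
    return EEGRecording(
        channel_labels=list(recording.channel_labels),
        sampling_rate_hz=fs,
        data=data,
        start_time=recording.start_time,
        reference=recording.reference,
    )
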