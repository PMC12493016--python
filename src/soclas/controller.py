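"""Deterministic replay of the online SO detector and stimulus scheduler.

The controller monitors one prefrontal channel (Fpz by default) through two
causally filtered 200-Hz streams: an SO stream (0.25–4 Hz) for negativity
detection and a broadband stream (0.25–45 Hz) for the delta/theta NREM
gate.  A stimulation pair is emitted when (1) the SO stream crosses an
adaptive negativity threshold — initially −80 μV, updated every 0.5 s from
the troughs of the preceding 5 s and never laxer than the initial value —
and (2) the delta/theta power ratio is above the individual gate.  Burst 1
follows the detection by the individualized delay, burst 2 a fixed
1075 ms later, and a pause of at least 2.5 s precedes re-detection.
Stimulation is only enabled after a stretch of stable N3 (4 min for the
first deep-sleep bout, 2 min for later bouts) and within the first 4 h.

Everything is causal: output up to time ``t`` depends only on input
samples at or before ``t`` (zero-phase filtering is deliberately not used
here — it belongs to the offline detectors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import EEGRecording, Hypnogram, TriggerEvent
from .config import SessionConfig
from .simulate import make_pink_noise


# ---------------------------------------------------------------------------
# stream preparation
# ---------------------------------------------------------------------------

def _causal_resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling with a causal anti-alias FIR (no delay removal)."""
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    if up == down == 1:
        return x.copy()
    m = max(up, down)
    numtaps = 2 * 10 * m + 1
    h = signal.firwin(numtaps, 1.0 / m) * up
    y = signal.upfirdn(h, x, up=up, down=down)
    n_out = int(len(x) * up / down)
    return y[:n_out]


def prepare_streams(
    recording: EEGRecording,
    config: SessionConfig,
    channel: str = "Fpz",
) -> tuple[np.ndarray, np.ndarray]:
    """Causally filtered 200-Hz SO (0.25–4 Hz) and broadband (0.25–45 Hz) streams.

    Raises :class:`~soclas.core.ChannelNotFoundError` if the monitoring
    channel is missing.
    """
    x = recording.channel(channel)
    fs = config.online_fs_hz
    y = _causal_resample(x, recording.sampling_rate_hz, fs)
    # composite design: a gentle order-1 high-pass (an order-3 causal
    # high-pass at 0.25 Hz rings for seconds and displaces SO troughs) and
    # a steeper order-4 low-pass for out-of-band rejection
    streams = []
    for lo, hi in (config.so_band_hz, config.broadband_hz):
        hp = signal.butter(1, lo, btype="highpass", fs=fs, output="sos")
        lp = signal.butter(4, hi, btype="lowpass", fs=fs, output="sos")
        streams.append(signal.sosfilt(lp, signal.sosfilt(hp, y)))
    return streams[0], streams[1]


# ---------------------------------------------------------------------------
# threshold adaptation and the delta/theta gate
# ---------------------------------------------------------------------------

def update_threshold(trough_history: np.ndarray, config: SessionConfig) -> float:
    """Adaptive negativity threshold from troughs of the trailing window.

    Empty history → the initial −80 μV; otherwise the mean trough amplitude,
    floored at the initial value so the criterion never becomes laxer than
    at start.
    """
    trough_history = np.asarray(trough_history, dtype=float)
    if trough_history.size == 0:
        return config.init_threshold_uv
    return min(config.init_threshold_uv, float(trough_history.mean()))


def delta_theta_ratio(broadband_window: np.ndarray, config: SessionConfig) -> float:
    """Delta (0.5–4 Hz) over theta (4–8 Hz) power of one trailing window.

    The NREM-depth proxy used to gate stimulation.  An all-zero window is
    defined as a neutral ratio of 1 (logged as a warning).
    """
    x = np.asarray(broadband_window, dtype=float)
    if not np.any(x):
        warnings.warn("all-zero window: delta/theta ratio defined as 1", stacklevel=2)
        return 1.0
    fs = config.online_fs_hz
    nperseg = min(len(x), int(2 * fs))
    freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg)
    df = freqs[1] - freqs[0]
    delta = psd[(freqs >= 0.5) & (freqs < 4.0)].sum() * df
    theta = psd[(freqs >= 4.0) & (freqs < 8.0)].sum() * df
    if theta <= 0:
        theta = np.finfo(float).tiny
    return float(delta / theta)


def select_dt_threshold(
    epoch_ratios: np.ndarray, stages: "list[str] | tuple[str, ...]"
) -> float:
    """Automated stand-in for the visual per-subject gate selection.

    Given the delta/theta ratio of every 30-s epoch of an adaptation night,
    two histograms (bin width 1) are formed for NREM (N1/N2/N3) versus
    Wake∪REM epochs, and the returned gate is the smallest bin edge ``t``
    maximizing ``J(t) = P(ratio ≥ t | NREM) − P(ratio ≥ t | Wake∪REM)`` —
    the edge where NREM epochs are still abundant but Wake/REM epochs have
    dropped off.
    """
    ratios = np.asarray(epoch_ratios, dtype=float)
    stages = list(stages)
    if len(ratios) != len(stages):
        raise ValueError("epoch_ratios and stages must have equal length")
    nrem = ratios[[s in ("N1", "N2", "N3") for s in stages]]
    wr = ratios[[s in ("Wake", "REM") for s in stages]]
    if nrem.size == 0 or wr.size == 0:
        raise ValueError("need at least one epoch of each class (NREM and Wake/REM)")
    edges = np.arange(np.floor(ratios.min()), np.ceil(ratios.max()) + 1.0)
    j = np.array([(nrem >= t).mean() - (wr >= t).mean() for t in edges])
    best = j.max()
    if best <= 0:
        warnings.warn(
            "degenerate delta/theta distributions: no separating threshold",
            stacklevel=2,
        )
    return float(edges[int(np.argmax(j))])


def individual_delay(so_events) -> float:
    """Mean negative-peak → positive-peak interval (ms) over adaptation SOs."""
    if not so_events:
        raise ValueError("need at least one SO event to compute the delay")
    intervals = [ev.pos_peak_time_s - ev.trough_time_s for ev in so_events]
    return float(np.mean(intervals) * 1000.0)


# ---------------------------------------------------------------------------
# stimulation gating from the hypnogram
# ---------------------------------------------------------------------------

def _stim_enabled_epochs(hypnogram: Hypnogram, config: SessionConfig) -> np.ndarray:
    """Per-epoch stimulation-enabled mask.

    Stability accrues over consecutive artefact-free N3 epochs; once the
    required stretch (4 min for the first bout, 2 min later) is complete,
    stimulation stays enabled through artefact-free N2/N3 epochs and is cut
    by any epoch lighter than N2 (or an artefact), after which stability
    must re-accrue.  Everything outside the first ``stim_window_h`` hours
    is disabled.
    """
    epl = hypnogram.epoch_length_s
    enabled = np.zeros(hypnogram.n_epochs, dtype=bool)
    first_bout_done = False
    streak = 0
    active = False
    limit_epochs = int(config.stim_window_h * 3600.0 / epl)
    for i, stage in enumerate(hypnogram.stages):
        clean_n3 = stage == "N3" and not hypnogram.artefact[i]
        clean_n2 = stage == "N2" and not hypnogram.artefact[i]
        if clean_n3:
            streak += 1
        else:
            streak = 0
        required_min = (
            config.n3_stable_first_min if not first_bout_done else config.n3_stable_later_min
        )
        required = int(np.ceil(required_min * 60.0 / epl))
        if not active and streak >= required:
            active = True
            first_bout_done = True
        if active and not (clean_n2 or clean_n3):
            active = False
        enabled[i] = active and i < limit_epochs
    return enabled


# ---------------------------------------------------------------------------
# the controller proper
# ---------------------------------------------------------------------------

@dataclass
class ControllerState:
    """Snapshot of the streaming detector (for introspection/debugging)."""

    phase: str = "idle"  # idle | armed | awaiting_delay | refractory
    current_threshold_uv: float = -80.0
    sample_clock_s: float = 0.0
    stim_enabled: bool = False


def run_controller(
    recording: EEGRecording,
    hypnogram: Hypnogram,
    config: SessionConfig,
    channel: str = "Fpz",
) -> list[TriggerEvent]:
    """Replay the closed-loop controller over a recording.

    Returns the list of emitted acoustic-burst triggers, two per detected
    SO (onset-to-onset spacing ``interburst_ms`` on the 200-Hz controller
    clock).  Deterministic given identical inputs.
    """
    so_stream, broadband = prepare_streams(recording, config, channel)
    fs = config.online_fs_hz
    n = len(so_stream)

    update_step = int(round(config.threshold_update_s * fs))
    history_len = int(round(config.threshold_history_s * fs))
    delay_n = int(round(config.delay_ms / 1000.0 * fs))
    interburst_n = int(round(config.interburst_ms / 1000.0 * fs))
    refractory_n = int(round(config.refractory_s * fs))

    # per-sample stimulation-enabled mask from epoch-level gating
    epoch_enabled = _stim_enabled_epochs(hypnogram, config)
    spe = int(round(hypnogram.epoch_length_s * fs))

    def enabled_at(sample: int) -> bool:
        ep = min(sample // spe, len(epoch_enabled) - 1)
        return bool(epoch_enabled[ep])

    # delta/theta ratio per update step over the trailing history window
    n_updates = n // update_step + 1
    ratio_at_update = np.ones(n_updates)
    for u in range(n_updates):
        hi = u * update_step
        lo = max(0, hi - history_len)
        if hi - lo >= int(fs):  # need at least 1 s of context
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ratio_at_update[u] = delta_theta_ratio(broadband[lo:hi], config)

    triggers: list[TriggerEvent] = []
    trough_history: list[tuple[int, float]] = []  # (sample, amplitude)
    threshold = config.init_threshold_uv
    armed = True
    refractory_until = -1
    in_excursion = False
    excursion_min = 0.0

    for i in range(n):
        if i % update_step == 0:
            recent = [a for (s, a) in trough_history if i - s <= history_len]
            threshold = update_threshold(np.array(recent), config)
            current_ratio = ratio_at_update[i // update_step]

        x = so_stream[i]

        # track sub-threshold excursions for the adaptation history,
        # irrespective of gating, mirroring amplitude tracking of ongoing EEG
        if in_excursion:
            excursion_min = min(excursion_min, x)
            if x > threshold:
                trough_history.append((i, excursion_min))
                in_excursion = False
        elif x <= threshold:
            in_excursion = True
            excursion_min = x

        # re-arm only once the signal has risen above threshold after the
        # refractory period (an expiring timer mid-crossing is ignored)
        if not armed and i >= refractory_until and x > threshold:
            armed = True

        if (
            armed
            and i >= refractory_until
            and x <= threshold
            and (i == 0 or so_stream[i - 1] > threshold)
            and enabled_at(i)
            and current_ratio >= config.dt_ratio_threshold
        ):
            b1 = i + delay_n
            b2 = b1 + interburst_n
            if b2 < n and enabled_at(b1) and enabled_at(b2):
                det_t = i / fs
                triggers.append(TriggerEvent(b1 / fs, 1, det_t, threshold, current_ratio))
                triggers.append(TriggerEvent(b2 / fs, 2, det_t, threshold, current_ratio))
                refractory_until = b2 + refractory_n
                armed = False
            else:
                # gating or the recording edge forbids the pair: stay armed
                # but skip this crossing entirely
                armed = False
                refractory_until = i + 1

    return triggers


def stimulus_burst(
    config: SessionConfig, fs_hz: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """One acoustic burst: 50 ms of pink 1/f noise with 5-ms linear ramps."""
    n = int(round(config.burst_ms / 1000.0 * fs_hz))
    burst = make_pink_noise(n / fs_hz, fs_hz, 1.0, seed)
    ramp_n = int(round(config.ramp_ms / 1000.0 * fs_hz))
    env = np.ones(n)
    if ramp_n > 0:
        env[:ramp_n] = np.linspace(0, 1, ramp_n, endpoint=False)
        env[-ramp_n:] = np.linspace(1, 0, ramp_n)
    return burst * env
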