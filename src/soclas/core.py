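"""Domain containers for polysomnographic recordings, hypnograms and detected events.

All signal amplitudes are in microvolts (μV), all times in seconds from the
start of the recording, sample indexing is 0-based and intervals are
half-open ``[start, end)`` unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Canonical AASM stage labels.
STAGES: tuple[str, ...] = ("Wake", "N1", "N2", "N3", "REM")

#: Stages counted as NREM sleep for detection purposes.
NREM_STAGES: frozenset[str] = frozenset({"N2", "N3"})

#: Stages counted as sleep (for TST and sleep-onset logic).
SLEEP_STAGES: frozenset[str] = frozenset({"N1", "N2", "N3", "REM"})


class ChannelNotFoundError(KeyError):
    """A requested channel label is absent from a recording or file."""


class HypnogramParseError(ValueError):
    """A hypnogram file contains an unknown stage token."""


class ConfigError(ValueError):
    """A configuration file is invalid (unknown key or out-of-range value)."""


@dataclass
class EEGRecording:
    """Multi-channel EEG time series in μV.

    Parameters
    ----------
    channel_labels
        10–20-system channel names, one per row of ``data``.
    sampling_rate_hz
        Sampling rate in Hz, > 0.
    data
        Array of shape ``(n_channels, n_samples)`` in μV.
    start_time
        Offset of the first sample in seconds (0 for synthetic data).
    reference
        Free-text reference description, e.g. ``"linked mastoids"``.
    """

    channel_labels: list[str]
    sampling_rate_hz: float
    data: np.ndarray
    start_time: float = 0.0
    reference: str = "linked mastoids"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[np.newaxis, :]
        if self.data.ndim != 2:
            raise ValueError("data must be a (n_channels, n_samples) array")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("all samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ChannelNotFoundError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D sample vector of one channel (a view)."""
        return self.data[self.channel_index(label)]

    def pick(self, labels: Sequence[str]) -> "EEGRecording":
        """Sub-recording containing ``labels`` in the requested order."""
        idx = [self.channel_index(lb) for lb in labels]
        return EEGRecording(
            channel_labels=list(labels),
            sampling_rate_hz=self.sampling_rate_hz,
            data=self.data[idx].copy(),
            start_time=self.start_time,
            reference=self.reference,
        )

    def truncate(self, duration_s: float) -> "EEGRecording":
        """First ``duration_s`` seconds of the recording."""
        n = int(round(duration_s * self.sampling_rate_hz))
        return EEGRecording(
            channel_labels=list(self.channel_labels),
            sampling_rate_hz=self.sampling_rate_hz,
            data=self.data[:, :n].copy(),
            start_time=self.start_time,
            reference=self.reference,
        )


@dataclass
class Hypnogram:
    """Sleep-stage sequence scored in fixed-length (default 30-s) epochs."""

    stages: tuple[str, ...]
    epoch_length_s: float = 30.0
    artefact: np.ndarray = None  # type: ignore[assignment]
    arousal: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage tokens: {sorted(set(bad))}")
        if not self.epoch_length_s > 0:
            raise ValueError("epoch_length_s must be > 0")
        n = len(self.stages)
        if self.artefact is None:
            self.artefact = np.zeros(n, dtype=bool)
        if self.arousal is None:
            self.arousal = np.zeros(n, dtype=bool)
        self.artefact = np.asarray(self.artefact, dtype=bool)
        self.arousal = np.asarray(self.arousal, dtype=bool)
        if len(self.artefact) != n or len(self.arousal) != n:
            raise ValueError("stages, artefact and arousal must have equal length")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length_s

    def epoch_of(self, time_s: float) -> int:
        """Epoch index containing ``time_s`` (clipped to the last epoch)."""
        if time_s < 0:
            raise ValueError("time before recording start")
        return min(int(time_s / self.epoch_length_s), self.n_epochs - 1)

    def stage_at(self, time_s: float) -> str:
        return self.stages[self.epoch_of(time_s)]

    def epoch_mask(
        self,
        stages: Iterable[str] = NREM_STAGES,
        artefact_free: bool = True,
    ) -> np.ndarray:
        """Boolean per-epoch mask selecting the given stages."""
        wanted = frozenset(stages)
        mask = np.array([s in wanted for s in self.stages], dtype=bool)
        if artefact_free:
            mask &= ~self.artefact
        return mask

    def sample_mask(
        self,
        fs_hz: float,
        n_samples: int,
        stages: Iterable[str] = NREM_STAGES,
        artefact_free: bool = True,
    ) -> np.ndarray:
        """Per-sample boolean mask for a recording of ``n_samples`` at ``fs_hz``."""
        em = self.epoch_mask(stages, artefact_free)
        mask = np.zeros(n_samples, dtype=bool)
        spe = self.epoch_length_s * fs_hz
        for i, ok in enumerate(em):
            if ok:
                lo = int(round(i * spe))
                hi = min(int(round((i + 1) * spe)), n_samples)
                mask[lo:hi] = True
        return mask

    def truncate(self, duration_s: float) -> "Hypnogram":
        n = max(1, int(np.ceil(duration_s / self.epoch_length_s)))
        n = min(n, self.n_epochs)
        return Hypnogram(
            stages=self.stages[:n],
            epoch_length_s=self.epoch_length_s,
            artefact=self.artefact[:n].copy(),
            arousal=self.arousal[:n].copy(),
        )


@dataclass
class SOEvent:
    """One detected slow oscillation: negative half-wave followed by the up-state.

    ``start_s``/``end_s`` are the zero-crossings bounding the negative and
    positive half-waves; the trough is the negative (down-state) peak.
    """

    channel: str
    start_s: float
    end_s: float
    trough_time_s: float
    trough_amp_uv: float
    pos_peak_time_s: float
    pos_peak_amp_uv: float
    neg_halfwave_s: float
    pos_halfwave_s: float

    @property
    def length_s(self) -> float:
        return self.neg_halfwave_s + self.pos_halfwave_s

    @property
    def p2p_amp_uv(self) -> float:
        return self.pos_peak_amp_uv - self.trough_amp_uv

    @property
    def slope_uv_per_s(self) -> float:
        """Down-to-up-state slope: peak-to-peak amplitude over trough→peak time."""
        return self.p2p_amp_uv / (self.pos_peak_time_s - self.trough_time_s)


@dataclass
class SpindleEvent:
    """One detected sleep spindle (slow ~9–12 Hz or fast ~12–16 Hz)."""

    channel: str
    type: str  # "slow" | "fast"
    start_s: float
    end_s: float
    p2p_amp_uv: float
    mean_rms_uv: float
    merged_from: int = 1

    def __post_init__(self) -> None:
        if self.type not in ("slow", "fast"):
            raise ValueError("spindle type must be 'slow' or 'fast'")
        if not self.start_s < self.end_s:
            raise ValueError("spindle start must precede end")

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class TriggerEvent:
    """One acoustic burst emitted by the closed-loop controller."""

    time_s: float
    burst_index: int  # 1 or 2 within a stimulation pair
    detection_time_s: float
    threshold_uv: float
    dt_ratio: float
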