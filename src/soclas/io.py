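"""Readers and writers for recordings, hypnograms and event tables.

Two on-disk recording formats are supported:

* **EDF** (16-bit integer, the clinical interchange format).  Reading goes
  through MNE; writing uses a minimal EDF writer (1-s data records, one
  scaling per channel), since no lossless float EDF exists by design —
  round trips are exact only to one quantization step of the channel range.
* **Native HDF5** (``.h5``): lossless float64 storage for tests and
  intermediate results that need bit-exactness.

Hypnograms are plain text, one AASM stage token per 30-s epoch, ``#``
comments allowed, with optional ``artefact`` / ``arousal`` flags after the
token.  Event tables are CSV with a fixed column order and a
schema-version comment header; times are seconds from recording start.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence, Type

import h5py
import numpy as np
import pandas as pd

from .core import (
    ChannelNotFoundError,
    EEGRecording,
    Hypnogram,
    HypnogramParseError,
    SOEvent,
    SpindleEvent,
    STAGES,
    TriggerEvent,
)

_SCHEMA = "soclas-events v1"


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def save_recording_h5(recording: EEGRecording, path: str | Path) -> None:
    """Write a recording to the native lossless HDF5 container."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("data_uv", data=recording.data)
        ds.attrs["channel_labels"] = [str(c) for c in recording.channel_labels]
        ds.attrs["sampling_rate_hz"] = recording.sampling_rate_hz
        ds.attrs["start_time"] = recording.start_time
        ds.attrs["reference"] = recording.reference


def _load_recording_h5(path: Path) -> EEGRecording:
    with h5py.File(path, "r") as fh:
        ds = fh["data_uv"]
        return EEGRecording(
            channel_labels=[str(c) for c in ds.attrs["channel_labels"]],
            sampling_rate_hz=float(ds.attrs["sampling_rate_hz"]),
            data=ds[...],
            start_time=float(ds.attrs["start_time"]),
            reference=str(ds.attrs["reference"]),
        )


def write_edf(recording: EEGRecording, path: str | Path) -> None:
    """Write a recording as plain EDF (16-bit, 1-s data records).

    The last partial second, if any, is zero-padded to a whole data record.
    Physical scaling is per channel from the data range, so the round-trip
    error is at most one quantization step of that range.
    """
    path = Path(path)
    fs = recording.sampling_rate_hz
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_ch = recording.n_channels
    n_rec = int(np.ceil(recording.n_samples / spr)) if recording.n_samples else 0

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii", "replace")[:width]
        return b + b" " * (width - len(b))

    phys_min, phys_max, scaled = [], [], []
    for row in recording.data:
        lo, hi = float(row.min()), float(row.max())
        if hi - lo < 1e-12:
            lo, hi = lo - 1.0, hi + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        dig = np.round(
            (row - lo) / (hi - lo) * (32767 - (-32768)) + (-32768)
        ).astype("<i2")
        full = np.zeros(n_rec * spr, dtype="<i2")
        full[: len(dig)] = dig
        scaled.append(full)

    with open(path, "wb") as fh:
        fh.write(pad("0", 8))  # version
        fh.write(pad("X X X X", 80))  # patient id (anonymous)
        fh.write(pad("Startdate X X X X", 80))  # recording id
        fh.write(pad("01.01.00", 8))
        fh.write(pad("00.00.00", 8))
        fh.write(pad(str(256 * (1 + n_ch)), 8))
        fh.write(pad("", 44))
        fh.write(pad(str(n_rec), 8))
        fh.write(pad("1", 8))  # record duration, s
        fh.write(pad(str(n_ch), 4))
        for lb in recording.channel_labels:
            fh.write(pad(f"EEG {lb}", 16))
        for _ in range(n_ch):
            fh.write(pad("AgAgCl electrode", 80))
        for _ in range(n_ch):
            fh.write(pad("uV", 8))
        for v in phys_min:
            fh.write(pad(f"{v:.8g}"[:8], 8))
        for v in phys_max:
            fh.write(pad(f"{v:.8g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(pad("-32768", 8))
        for _ in range(n_ch):
            fh.write(pad("32767", 8))
        for _ in range(n_ch):
            fh.write(pad("", 80))  # prefiltering
        for _ in range(n_ch):
            fh.write(pad(str(spr), 8))
        for _ in range(n_ch):
            fh.write(pad("", 32))  # reserved
        for rec in range(n_rec):
            for ch in range(n_ch):
                fh.write(scaled[ch][rec * spr : (rec + 1) * spr].tobytes())


def _load_recording_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    labels = [lb.removeprefix("EEG ").strip() for lb in raw.ch_names]
    return EEGRecording(
        channel_labels=labels,
        sampling_rate_hz=float(raw.info["sfreq"]),
        data=data_uv,
        start_time=0.0,
    )


def read_recording(
    path: str | Path, channels: Optional[Sequence[str]] = None
) -> EEGRecording:
    """Read an EDF/EDF+ or native ``.h5`` recording (units μV).

    ``channels`` selects a label subset in the requested order; a missing
    label raises :class:`ChannelNotFoundError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        rec = _load_recording_h5(path)
    elif path.suffix.lower() == ".edf":
        rec = _load_recording_edf(path)
    else:
        raise OSError(f"unrecognized recording format: {path.suffix!r}")
    if channels is not None:
        rec = rec.pick(channels)
    return rec


# ---------------------------------------------------------------------------
# hypnograms
# ---------------------------------------------------------------------------

def read_hypnogram(path: str | Path, epoch_length_s: float = 30.0) -> Hypnogram:
    """Parse a plain-text hypnogram: one stage token per epoch, ``#`` comments.

    Optional ``artefact`` / ``arousal`` flags may follow the stage token.
    An unknown stage token raises :class:`HypnogramParseError` naming the
    line number.
    """
    stages: list[str] = []
    artefact: list[bool] = []
    arousal: list[bool] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            token = parts[0]
            if token not in STAGES:
                raise HypnogramParseError(
                    f"{path}: line {lineno}: unknown stage token {token!r}"
                )
            flags = {p.lower() for p in parts[1:]}
            unknown = flags - {"artefact", "arousal"}
            if unknown:
                raise HypnogramParseError(
                    f"{path}: line {lineno}: unknown flags {sorted(unknown)}"
                )
            stages.append(token)
            artefact.append("artefact" in flags)
            arousal.append("arousal" in flags)
    return Hypnogram(
        stages=tuple(stages),
        epoch_length_s=epoch_length_s,
        artefact=np.array(artefact, dtype=bool),
        arousal=np.array(arousal, dtype=bool),
    )


def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> None:
    lines = [f"# hypnogram, {hypnogram.epoch_length_s:g}-s epochs"]
    for stage, art, aro in zip(hypnogram.stages, hypnogram.artefact, hypnogram.arousal):
        line = stage
        if art:
            line += " artefact"
        if aro:
            line += " arousal"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

_EVENT_KINDS: dict[str, Type] = {
    "SOEvent": SOEvent,
    "SpindleEvent": SpindleEvent,
    "TriggerEvent": TriggerEvent,
}


def write_events(events: Sequence, path: str | Path) -> None:
    """Write a homogeneous list of events to CSV (times in s, μs precision)."""
    if not events:
        raise ValueError("cannot infer event schema from an empty list")
    kind = type(events[0]).__name__
    if kind not in _EVENT_KINDS:
        raise TypeError(f"unsupported event type {kind}")
    if any(type(ev).__name__ != kind for ev in events):
        raise TypeError("all events must share one type")
    cols = [f.name for f in dataclasses.fields(events[0])]
    frame = pd.DataFrame([[getattr(ev, c) for c in cols] for ev in events], columns=cols)
    with open(path, "w") as fh:
        fh.write(f"# {_SCHEMA} {kind}\n")
        frame.to_csv(fh, index=False, float_format="%.6f")


def read_events(path: str | Path) -> list:
    """Read back a CSV event table written by :func:`write_events`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(f"# {_SCHEMA}"):
            raise OSError(f"{path}: missing event-table schema header")
        kind = header.split()[-1]
        if kind not in _EVENT_KINDS:
            raise OSError(f"{path}: unknown event kind {kind!r}")
        frame = pd.read_csv(fh)
    cls = _EVENT_KINDS[kind]
    out = []
    for row in frame.itertuples(index=False):
        kwargs = dict(zip(frame.columns, row))
        for key in ("channel", "type"):
            if key in kwargs:
                kwargs[key] = str(kwargs[key])
        for key in ("burst_index", "merged_from"):
            if key in kwargs:
                kwargs[key] = int(kwargs[key])
        out.append(cls(**kwargs))
    return out
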