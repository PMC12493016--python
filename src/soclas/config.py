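"""Pipeline configuration: every numeric parameter in one validated structure.

The defaults encode the full parameter set of the closed-loop acoustic
stimulation (CLAS) protocol and the offline analyses: the online detector
runs on a 200-Hz stream with an adaptive negativity threshold starting at
−80 μV updated every 0.5 s from the preceding 5 s, bursts are paired at a
fixed 1075-ms interval with a ≥ 2.5-s pause, and the offline detectors use
0.5–3.5-Hz band-passed signals with 1.25× relative amplitude thresholds
(SOs) and 1.5/2.5-SD RMS thresholds (spindles).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .core import ConfigError

#: Offline analysis frequency bands (Hz, half-open [lo, hi)).
DEFAULT_BANDS_HZ: dict[str, tuple[float, float]] = {
    "SO": (0.5, 1.5),
    "delta": (1.5, 4.0),
    "SWA": (0.5, 4.0),
    "theta": (4.0, 9.0),
    "slow_spindle": (9.5, 12.5),
    "fast_spindle": (12.5, 15.5),
}


@dataclass
class SessionConfig:
    """Every tunable parameter of the online controller and offline pipeline."""

    # --- online controller -------------------------------------------------
    online_fs_hz: float = 200.0
    so_band_hz: tuple[float, float] = (0.25, 4.0)
    broadband_hz: tuple[float, float] = (0.25, 45.0)
    init_threshold_uv: float = -80.0
    threshold_update_s: float = 0.5
    threshold_history_s: float = 5.0
    #: Individual delta/theta ratio gate for NREM; the population average of
    #: the visually chosen per-subject value is used as default.
    dt_ratio_threshold: float = 23.6
    #: Individual delay from SO negative-peak detection to the first burst,
    #: targeting shortly before the SO positive peak.
    delay_ms: float = 500.0
    interburst_ms: float = 1075.0
    burst_ms: float = 50.0
    ramp_ms: float = 5.0
    refractory_s: float = 2.5
    stim_window_h: float = 4.0
    n3_stable_first_min: float = 4.0
    n3_stable_later_min: float = 2.0

    # --- offline SO detection ----------------------------------------------
    offline_so_band_hz: tuple[float, float] = (0.5, 3.5)
    halfwave_bounds_s: tuple[float, float] = (0.75, 2.0)
    so_threshold_factor: float = 1.25

    # --- spindle detection --------------------------------------------------
    slow_spindle_range_hz: tuple[float, float] = (9.0, 12.0)
    fast_spindle_range_hz: tuple[float, float] = (12.0, 16.0)
    spindle_bandwidth_hz: float = 3.0
    rms_window_s: float = 0.2
    smooth_window_s: float = 0.2
    spindle_thresh_sd: float = 1.5
    spindle_peak_sd: float = 2.5
    spindle_dur_bounds_s: tuple[float, float] = (0.5, 3.0)
    merge_gap_s: float = 0.5
    merge_total_max_s: float = 3.0

    # --- stimulus-locked analyses -------------------------------------------
    erp_lowpass_hz: float = 35.0
    erp_fs_hz: float = 100.0
    erp_window_s: tuple[float, float] = (-1.0, 3.0)
    baseline_window_s: tuple[float, float] = (-0.99, -0.01)

    # --- spectra --------------------------------------------------------------
    fft_n: int = 4096
    fft_overlap: float = 0.5
    bands_hz: dict = field(default_factory=lambda: dict(DEFAULT_BANDS_HZ))
    density_epoch_s: float = 30.0

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ConfigError` on any out-of-range value."""
        for name in (
            "so_band_hz",
            "broadband_hz",
            "offline_so_band_hz",
            "halfwave_bounds_s",
            "slow_spindle_range_hz",
            "fast_spindle_range_hz",
            "spindle_dur_bounds_s",
            "erp_window_s",
            "baseline_window_s",
        ):
            val = getattr(self, name)
            if not (isinstance(val, (tuple, list)) and len(val) == 2):
                raise ConfigError(f"{name} must be a (low, high) pair, got {val!r}")
            lo, hi = float(val[0]), float(val[1])
            if not lo < hi:
                raise ConfigError(f"{name} must be ordered low < high, got {val!r}")
            setattr(self, name, (lo, hi))

        if not isinstance(self.bands_hz, dict) or not self.bands_hz:
            raise ConfigError("bands_hz must be a non-empty mapping")
        bands = {}
        for key, val in self.bands_hz.items():
            if not (isinstance(val, (tuple, list)) and len(val) == 2 and val[0] < val[1]):
                raise ConfigError(f"band {key!r} must be ordered (low, high), got {val!r}")
            bands[str(key)] = (float(val[0]), float(val[1]))
        self.bands_hz = bands

        positive = (
            "online_fs_hz",
            "threshold_update_s",
            "threshold_history_s",
            "dt_ratio_threshold",
            "delay_ms",
            "interburst_ms",
            "burst_ms",
            "stim_window_h",
            "n3_stable_first_min",
            "n3_stable_later_min",
            "so_threshold_factor",
            "spindle_bandwidth_hz",
            "rms_window_s",
            "smooth_window_s",
            "spindle_thresh_sd",
            "spindle_peak_sd",
            "merge_gap_s",
            "merge_total_max_s",
            "erp_lowpass_hz",
            "erp_fs_hz",
            "density_epoch_s",
        )
        for name in positive:
            if not float(getattr(self, name)) > 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in ("refractory_s", "ramp_ms"):
            if float(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not self.init_threshold_uv < 0:
            raise ConfigError("init_threshold_uv must be negative (μV)")
        if not (isinstance(self.fft_n, int) and self.fft_n > 0):
            raise ConfigError(f"fft_n must be a positive integer, got {self.fft_n!r}")
        if not 0 <= float(self.fft_overlap) < 1:
            raise ConfigError(f"fft_overlap must lie in [0, 1), got {self.fft_overlap!r}")

    # ------------------------------------------------------------------
    def replace(self, **kwargs) -> "SessionConfig":
        """A copy with the named fields overridden (validated)."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_NAMES = {f.name for f in dataclasses.fields(SessionConfig)}


def load_config(path: Optional[str | Path] = None) -> SessionConfig:
    """Load a :class:`SessionConfig` from a YAML/JSON key–value file.

    ``path=None`` (or a missing-by-design call without a file) returns all
    defaults.  A partial file overrides only the named fields.  Unknown keys
    are an error so that typos cannot silently fall back to defaults.
    """
    if path is None:
        return SessionConfig()
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return SessionConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    unknown = set(raw) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, val in raw.items():
        if isinstance(val, list) and key != "bands_hz":
            val = tuple(val)
        if key == "bands_hz" and isinstance(val, dict):
            merged = dict(DEFAULT_BANDS_HZ)
            merged.update({k: tuple(v) for k, v in val.items()})
            val = merged
        kwargs[key] = val
    try:
        return SessionConfig(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
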