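"""Shared offline filter designs.

The stimulus-locked and spindle pipelines both start from a 35-Hz low-pass
FIR whose −3-dB point is tuned to 32.0 Hz, followed by downsampling to
100 Hz.  Filters here are zero-phase (linear-phase FIR applied centred);
causal filtering lives in the online controller only.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal


@lru_cache(maxsize=8)
def design_erp_lowpass(fs_hz: float, db3_hz: float = 32.0) -> np.ndarray:
    """Linear-phase FIR low-pass with its −3-dB point at ``db3_hz``.

    ``firwin`` places −6 dB at the nominal cutoff; the cutoff is found by
    bisection so that the single-pass magnitude at ``db3_hz`` is 1/sqrt(2).
    """
    numtaps = int(0.4 * fs_hz) | 1  # ~0.4 s, odd for symmetric delay

    def mag_at(cutoff: float) -> float:
        taps = signal.firwin(numtaps, cutoff, fs=fs_hz)
        _, h = signal.freqz(taps, worN=[db3_hz], fs=fs_hz)
        return float(np.abs(h[0]))

    lo, hi = db3_hz, min(0.49 * fs_hz, db3_hz * 2.0)
    target = 1.0 / np.sqrt(2.0)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if mag_at(mid) < target:
            lo = mid
        else:
            hi = mid
    return signal.firwin(numtaps, 0.5 * (lo + hi), fs=fs_hz)


def zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR with its group delay removed (centred)."""
    return np.convolve(x, taps, mode="same")


def lowpass_downsample(
    x: np.ndarray, fs_in: float, fs_out: float, db3_hz: float = 32.0
) -> np.ndarray:
    """35-Hz-class low-pass (−3 dB at ``db3_hz``) then decimation to ``fs_out``."""
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"fs ratio {fs_in}/{fs_out} must be an integer")
    y = zero_phase_fir(x, design_erp_lowpass(fs_in, db3_hz))
    return y[:: int(round(factor))]


def design_spindle_bandpass(
    fs_hz: float, center_hz: float, width_hz: float
) -> np.ndarray:
    """Linear-phase FIR band-pass of ``width_hz`` centred on ``center_hz``."""
    numtaps = int(3.3 * fs_hz / 1.0) | 1  # ~1-Hz transition band
    lo = center_hz - width_hz / 2.0
    hi = center_hz + width_hz / 2.0
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs_hz)
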