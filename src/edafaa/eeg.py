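"""Frontal alpha asymmetry (FAA) from a frontal EEG channel pair.

Alpha-band (8-13 Hz) power is computed per observation window in the time
domain, ``P = (1/N) * sum_n x[n]^2`` [uV^2], on the zero-phase band-pass
filtered channel.  Channel convention: left = F7, right = F8.  Three FAA
variants are exposed:

* normalized ratio   (Rpower - Lpower) / (Rpower + Lpower), bounded in [-1, 1];
* logarithmic        ln(Rpower) - ln(Lpower)  (natural log; same sign as the
  ratio form);
* mutual-information the Miller-Madow-corrected MI between the left and right
  alpha envelopes inside the window.  The MI variant is sign-free: it measures
  how strongly the two hemispheres' alpha amplitude fluctuations are coupled,
  not which side dominates.  The exact construction (rectified smoothed
  envelopes, equal-frequency bins) is a package choice and is pluggable.

Positive ratio/log values (greater right-side alpha, i.e. greater *left*
cortical activation, alpha being inversely related to activity) index
approach-oriented / positive affect; negative values index withdrawal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .infotheory import mutual_information_mm

__all__ = [
    "AlphaPowerPair",
    "bandpass_alpha",
    "alpha_envelope",
    "window_alpha_power",
    "faa_ratio",
    "faa_log",
    "faa_mi",
]

ALPHA_BAND = (8.0, 13.0)


@dataclass(frozen=True)
class AlphaPowerPair:
    """Window alpha power of the left (F7) and right (F8) frontal channels."""

    l_power: float
    r_power: float
    window: tuple[int, int]
    n_samples: int

    def __post_init__(self) -> None:
        if self.l_power < 0 or self.r_power < 0:
            raise ValueError("powers must be non-negative")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


def bandpass_alpha(eeg, fs: float, band: tuple[float, float] = ALPHA_BAND,
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass of the alpha band."""
    if fs < 2 * band[1]:
        raise ValueError(f"fs={fs} Hz below Nyquist requirement for {band[1]} Hz")
    x = np.asarray(eeg, dtype=float).ravel()
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def alpha_envelope(alpha, fs: float, smooth_s: float = 0.25) -> np.ndarray:
    """Instantaneous alpha amplitude: |Hilbert| with moving-average smoothing."""
    x = np.asarray(alpha, dtype=float).ravel()
    env = np.abs(sps.hilbert(x))
    n = max(1, int(round(smooth_s * fs)))
    if n > 1:
        kernel = np.ones(n) / n
        env = np.convolve(env, kernel, mode="same")
    return env


def window_alpha_power(filtered, window: tuple[int, int]) -> float:
    """Mean squared amplitude over a half-open sample window, in uV^2."""
    x = np.asarray(filtered, dtype=float).ravel()
    start, stop = window
    if not (0 <= start < stop <= x.size):
        raise ValueError(f"window {window} outside sequence of length {x.size}")
    seg = x[start:stop]
    return float(np.mean(seg * seg))


def faa_ratio(pair: AlphaPowerPair) -> float:
    """Normalized-ratio FAA: (R - L) / (R + L), in [-1, 1]."""
    tot = pair.r_power + pair.l_power
    if tot == 0:
        raise ValueError("both powers are zero; ratio FAA undefined")
    return (pair.r_power - pair.l_power) / tot


def faa_log(pair: AlphaPowerPair) -> float:
    """Logarithmic FAA: ln(Rpower) - ln(Lpower)."""
    if pair.r_power <= 0 or pair.l_power <= 0:
        raise ValueError("log FAA requires strictly positive powers")
    return float(np.log(pair.r_power) - np.log(pair.l_power))


def faa_mi(left_alpha, right_alpha, n_bins: int = 12, *, fs: float = 200.0,
           envelope: bool = True, smooth_s: float = 0.25) -> float:
    """Mutual-information FAA: corrected MI between the hemispheric envelopes.

    ``left_alpha`` / ``right_alpha`` are the band-passed alpha signals inside
    one window.  When ``envelope`` is true (default) the rectified smoothed
    Hilbert envelope of each side is binned; passing precomputed envelopes
    with ``envelope=False`` is supported.  Constant sequences make the
    equal-frequency binning degenerate and are rejected.
    """
    lx = np.asarray(left_alpha, dtype=float).ravel()
    rx = np.asarray(right_alpha, dtype=float).ravel()
    if lx.size != rx.size:
        raise ValueError("left and right sequences must have equal length")
    if lx.size < 5 * n_bins:
        raise ValueError(f"need at least {5 * n_bins} samples for {n_bins} bins")
    if envelope:
        lx = alpha_envelope(lx, fs, smooth_s)
        rx = alpha_envelope(rx, fs, smooth_s)
    if np.ptp(lx) == 0 or np.ptp(rx) == 0:
        raise ValueError("constant envelope; MI-FAA undefined")
    return mutual_information_mm(lx, rx, n_bins)
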