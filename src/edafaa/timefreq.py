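"""Time-frequency EDA features: complex-Morlet CWT and VFCDM / TVSymp.

Complex Morlet wavelet
----------------------
The mother wavelet is a Gaussian-enveloped complex carrier

    psi(eta) = (pi*fb)^(-1/2) * exp(-eta^2 / fb) * exp(j*2*pi*fc*eta)

with non-dimensional bandwidth ``fb`` and center frequency ``fc``.  Daughter
wavelets are scaled by ``a`` and translated by ``b`` with an ``1/sqrt(a)``
amplitude factor so every daughter carries the mother's energy:

    CWT(a, b) = sum_t x[t] * (1/sqrt(a)) * psi((t - b)/a)

(discrete evaluation; ``a`` in samples).  The pseudo-frequency of scale ``a``
is ``fc * fs / a``, so a scale grid is derived from the physiological band of
interest (tonic < 0.05 Hz, phasic 0.05-0.15 Hz; full grid 0.005-0.5 Hz with 25
log-spaced scales).  Coefficients whose wavelet support (3 envelope SDs)
overhangs the signal edge are flagged as edge-affected and excluded from
window statistics when alternatives exist.

Note the mother wavelet above is *not* unit-energy: its energy is
``1/sqrt(2*pi*fb)`` (~0.326 for fb = 1.5).  The ``(pi*fb)^(-1/2)`` factor
stabilizes coefficient magnitudes across ``fb`` choices; only energy equality
across scales matters for comparing coefficients, and that is exact by the
``1/sqrt(a)`` normalization.

VFCDM and TVSymp
----------------
Variable-frequency complex demodulation decomposes a signal into band-limited
components on a grid of center frequencies ``f_oi = (i-1) * 2*F_w`` spanning
(0, f_max].  Each band is obtained by frequency-shifting the signal by
``exp(-j*2*pi*f_oi*t)``, low-pass filtering (linear-phase FIR, bandwidth
``F_w``, applied with centered convolution so the net phase is zero), and
re-modulating; the instantaneous amplitude/phase follow as ``A = 2*|z_LP|``,
``phi = arg(z_LP)``, refined through the Hilbert transform of each
reconstructed component.  TVSymp is the sum of instantaneous amplitudes of the
components whose centers fall in the sympathetic 0.08-0.24 Hz band, normalized
to unit variance over the recording.  EDA is decimated to 2 Hz (f_max = 1 Hz)
before VFCDM, the operating rate customary for this index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "Scaleogram",
    "VFCDMComponents",
    "cmorlet",
    "scales_for_band",
    "pseudo_frequencies",
    "cwt_scaleogram",
    "wavelet_window_features",
    "vfcdm_decompose",
    "tvsymp",
]

DEFAULT_FB = 1.5
DEFAULT_FC = 1.0
TVSYMP_BAND = (0.08, 0.24)
_SUPPORT_SIGMAS = 5.0   # truncation of the Gaussian envelope (kernel length)
_EDGE_SIGMAS = 3.0      # overhang that flags a coefficient as edge-affected


@dataclass(frozen=True)
class Scaleogram:
    """Complex CWT coefficients on a (scales x translations) grid."""

    coefficients: np.ndarray        # (n_scales, n_translations) complex
    scales: np.ndarray              # samples, strictly increasing
    translations_s: np.ndarray      # seconds
    fb: float
    fc: float
    fs: float
    edge_mask: np.ndarray           # True where edge-affected

    def __post_init__(self) -> None:
        if self.coefficients.shape[0] != self.scales.size:
            raise ValueError("one coefficient row per scale required")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        if not np.all(np.isfinite(np.abs(self.coefficients))):
            raise ValueError("non-finite coefficients")

    @property
    def pseudo_frequencies_hz(self) -> np.ndarray:
        return self.fc * self.fs / self.scales


@dataclass(frozen=True)
class VFCDMComponents:
    """Band-limited components with instantaneous amplitude/frequency/phase."""

    components: np.ndarray          # (n_components, n) band signals d_i
    center_frequencies: np.ndarray  # Hz, f_oi for i >= 2 (dc excluded)
    inst_amplitude: np.ndarray      # (n_components, n), >= 0
    inst_frequency: np.ndarray      # Hz
    inst_phase: np.ndarray          # rad
    dc: np.ndarray                  # baseband component
    filter_bandwidth: float         # F_w, Hz
    filter_length: int              # N_w, taps
    fs_internal: float              # Hz

    @property
    def reconstruction(self) -> np.ndarray:
        return self.dc + self.components.sum(axis=0)


def cmorlet(eta, fb: float = DEFAULT_FB, fc: float = DEFAULT_FC) -> np.ndarray:
    """Complex Morlet mother wavelet evaluated at non-dimensional time eta."""
    if fb <= 0:
        raise ValueError("fb must be positive")
    eta = np.asarray(eta, dtype=float)
    out = (np.exp(-eta ** 2 / fb) / np.sqrt(np.pi * fb)
           * np.exp(2j * np.pi * fc * eta))
    return out if out.ndim else complex(out)


def scales_for_band(f_min: float, f_max: float, n_scales: int = 25,
                    fc: float = DEFAULT_FC, fs: float = 200.0) -> np.ndarray:
    """Log-spaced scales whose pseudo-frequencies fc*fs/a span [f_min, f_max]."""
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    if f_max > fs / 2:
        raise ValueError(f"f_max={f_max} Hz above Nyquist ({fs / 2} Hz)")
    if n_scales < 2:
        raise ValueError("n_scales must be >= 2")
    return np.geomspace(fc * fs / f_max, fc * fs / f_min, n_scales)


def pseudo_frequencies(scales, fc: float = DEFAULT_FC,
                       fs: float = 200.0) -> np.ndarray:
    """Pseudo-frequency (Hz) of each scale under the map f = fc*fs/a."""
    return fc * fs / np.asarray(scales, dtype=float)


def cwt_scaleogram(signal, fs: float, scales, fb: float = DEFAULT_FB,
                   fc: float = DEFAULT_FC,
                   translation_step_s: float = 1.0) -> Scaleogram:
    """CWT of a real signal on a scale grid with a uniform translation grid.

    The kernel at each scale is the daughter wavelet truncated at 5 envelope
    SDs (or the signal length); the convolution is evaluated at every sample
    and subsampled onto the ``translation_step_s`` grid.  The edge mask flags
    translations closer than 3 envelope SDs to either signal edge.
    """
    x = np.asarray(signal, dtype=float).ravel()
    scales = np.sort(np.asarray(scales, dtype=float).ravel())
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    if x.size < 2:
        raise ValueError("signal too short")
    step = max(1, int(round(translation_step_s * fs)))
    b_idx = np.arange(0, x.size, step)
    sigma = np.sqrt(fb / 2.0)

    coeffs = np.empty((scales.size, b_idx.size), dtype=complex)
    edge = np.zeros((scales.size, b_idx.size), dtype=bool)
    for i, a in enumerate(scales):
        half = int(np.ceil(_SUPPORT_SIGMAS * sigma * a))
        m = np.arange(-half, half + 1)
        w = cmorlet(m / a, fb, fc) / np.sqrt(a)
        # C[b] = sum_t x[t] w[t-b]  ==  conv(x, w reversed), centered
        row = sps.fftconvolve(x, w[::-1], mode="same")
        coeffs[i] = row[b_idx]
        guard = _EDGE_SIGMAS * sigma * a
        edge[i] = (b_idx < guard) | (b_idx > x.size - 1 - guard)
    return Scaleogram(coefficients=coeffs, scales=scales,
                      translations_s=b_idx / fs, fb=fb, fc=fc, fs=fs,
                      edge_mask=edge)


def wavelet_window_features(scaleogram: Scaleogram,
                            window: tuple[float, float],
                            exclude_edges: bool = True) -> tuple[float, float]:
    """(mean, population SD) of |coefficients| pooled over scales in a window.

    ``window`` is a half-open time range in seconds over the translation grid.
    Edge-affected coefficients are excluded when any clean ones remain in the
    window; if every in-window point is edge-affected (short trials at large
    scales) the statistics fall back to all in-window points.
    """
    t0, t1 = window
    cols = (scaleogram.translations_s >= t0) & (scaleogram.translations_s < t1)
    if not np.any(cols):
        raise ValueError(f"window {window} contains no translation grid points")
    mags = np.abs(scaleogram.coefficients[:, cols])
    if exclude_edges:
        keep = ~scaleogram.edge_mask[:, cols]
        if np.any(keep):
            vals = mags[keep]
        else:
            vals = mags.ravel()
    else:
        vals = mags.ravel()
    return float(vals.mean()), float(vals.std())


def _centered_conv(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Zero-phase application of a symmetric FIR via centered convolution."""
    return sps.fftconvolve(x, h, mode="same")


def vfcdm_decompose(signal, fs: float, f_w: float = 0.03,
                    n_w: int = 64) -> VFCDMComponents:
    """Fixed-grid complex demodulation with Hilbert refinement.

    Center frequencies ``f_oi = (i-1)*2*F_w`` for ``i = 1..int(f_max/(2 F_w))``
    with ``f_max = fs/2``; the i = 1 (zero-frequency) band is the dc component.
    Each remaining band is demodulated, low-pass filtered (``F_w`` cutoff,
    ``N_w``-tap linear-phase FIR, centered application) and re-modulated into a
    real band-limited component; instantaneous amplitude/phase/frequency are
    then refined per component via the Hilbert transform.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if f_w <= 0:
        raise ValueError("F_w must be positive")
    f_max = fs / 2.0
    n_bands = int(f_max / (2 * f_w))
    if n_bands < 2:
        raise ValueError(
            f"F_w={f_w} Hz too large for f_max={f_max} Hz (needs >= 2 bands)")
    if x.size < 2 * (n_w + 1):
        raise ValueError("signal shorter than two filter lengths")

    h = sps.firwin(n_w + 1, f_w, fs=fs)  # odd length -> symmetric, type I
    centers = np.array([(i - 1) * 2 * f_w for i in range(2, n_bands + 1)])

    # Reflect-pad through the whole chain (demodulation, filtering, Hilbert)
    # so filter and analytic-signal edge transients fall in the padding.
    pad = min(x.size - 1, 2 * (n_w + 1))
    xp = np.pad(x, pad, mode="reflect")
    tp = np.arange(-pad, x.size + pad) / fs
    core = slice(pad, pad + x.size)

    dc = _centered_conv(xp, h)[core]
    comps = np.empty((centers.size, x.size))
    amp = np.empty_like(comps)
    phase = np.empty_like(comps)
    freq = np.empty_like(comps)
    for k, f0 in enumerate(centers):
        z = xp * np.exp(-2j * np.pi * f0 * tp)
        z_lp = _centered_conv(z, h)
        comp_p = 2.0 * np.real(z_lp * np.exp(2j * np.pi * f0 * tp))
        analytic = sps.hilbert(comp_p)
        comps[k] = comp_p[core]
        amp[k] = np.abs(analytic)[core]
        ph = np.unwrap(np.angle(analytic))
        phase[k] = ph[core]
        freq[k] = (np.gradient(ph) * fs / (2 * np.pi))[core]
    return VFCDMComponents(components=comps, center_frequencies=centers,
                           inst_amplitude=amp, inst_frequency=freq,
                           inst_phase=phase, dc=dc, filter_bandwidth=f_w,
                           filter_length=n_w, fs_internal=fs)


def tvsymp(signal, fs: float, band: tuple[float, float] = TVSYMP_BAND,
           f_w: float = 0.03, n_w: int = 64,
           return_raw: bool = False):
    """Time-varying sympathetic index from the VFCDM decomposition.

    Sums the instantaneous amplitudes of components whose center frequencies
    fall inside ``band`` (default 0.08-0.24 Hz) and normalizes the series to
    unit variance over the recording.  With ``return_raw`` the unnormalized
    amplitude sum is returned alongside.
    """
    dec = vfcdm_decompose(signal, fs, f_w=f_w, n_w=n_w)
    sel = ((dec.center_frequencies >= band[0])
           & (dec.center_frequencies <= band[1]))
    if not np.any(sel):
        raise ValueError(
            f"band {band} contains no component centers; available: "
            f"{dec.center_frequencies.tolist()}")
    raw = dec.inst_amplitude[sel].sum(axis=0)
    sd = raw.std()
    if sd == 0:
        raise ValueError("degenerate TVSymp: amplitude sum is constant")
    norm = raw / sd
    return (norm, raw) if return_raw else norm
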