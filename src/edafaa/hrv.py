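"""Time-domain heart-rate-variability metrics from R-R interval series.

Only RMSSD (root mean square of successive differences) is computed:

    RMSSD = sqrt( 1/(N-1) * sum_i (RR_{i+1} - RR_i)^2 )   [ms]

a short-window index of parasympathetic (vagal) activity.  The pipeline
consumes R-R interval series directly (synthetic, or pre-extracted from ECG);
R-peak detection from raw ECG is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RRSeries", "rmssd", "window_rmssd", "windowed_rmssd"]


@dataclass(frozen=True)
class RRSeries:
    """R-R intervals (ms) with cumulative beat times (s).

    ``beat_times_s[k]`` is the time of the beat *ending* interval k, i.e. the
    cumulative sum of the first k+1 intervals.
    """

    rr_ms: np.ndarray
    beat_times_s: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr_ms, dtype=float).ravel()
        if rr.size == 0:
            raise ValueError("empty R-R series")
        if np.any(rr <= 0):
            raise ValueError("R-R intervals must be positive")
        object.__setattr__(self, "rr_ms", rr)
        object.__setattr__(self, "beat_times_s", np.cumsum(rr) / 1000.0)


def rmssd(rr_ms) -> float:
    """RMSSD of an R-R interval sequence, in milliseconds."""
    rr = np.asarray(rr_ms, dtype=float).ravel()
    if rr.size < 2:
        raise ValueError("RMSSD needs at least 2 intervals")
    d = np.diff(rr)
    return float(np.sqrt(np.mean(d * d)))


def window_rmssd(series: RRSeries, window: tuple[float, float]) -> float:
    """RMSSD over intervals whose ending beat falls in ``[t0, t1)`` seconds.

    Returns ``nan`` when fewer than 2 intervals end inside the window; callers
    that evaluate a grid of windows should use :func:`windowed_rmssd`, which
    forward-fills those gaps.
    """
    t0, t1 = window
    sel = (series.beat_times_s >= t0) & (series.beat_times_s < t1)
    rr = series.rr_ms[sel]
    if rr.size < 2:
        return float("nan")
    return rmssd(rr)


def windowed_rmssd(series: RRSeries, windows) -> np.ndarray:
    """Per-window RMSSD over a sequence of ``(t0, t1)`` windows.

    Windows with fewer than 2 intervals are forward-filled from the previous
    window; a missing leading value is back-filled from the first valid one
    (documented convention so downstream binning never sees gaps).
    """
    out = np.array([window_rmssd(series, w) for w in windows], dtype=float)
    if np.all(np.isnan(out)):
        raise ValueError("no window contains two R-R intervals")
    # forward fill, then back fill the head
    for i in range(1, out.size):
        if np.isnan(out[i]):
            out[i] = out[i - 1]
    first = np.flatnonzero(~np.isnan(out))[0]
    out[:first] = out[first]
    return out
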