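"""Per-window feature table: 13 autonomic features + 3 FAA targets + labels.

All signals are aligned to a reference 200 Hz grid per trial and cut by a
moving window of 13,000 samples (65 s) advancing 325 samples (1.625 s) per
step — the hop needed by the slow time-frequency indices.  The feature roster:

====================  ====================================================
Mean_Tn / Std_Tn      mean / population SD of the tonic EDA component (uS)
Mean_Ph / Std_Ph      same for the phasic component
Mean_WL_Tn/Std_WL_Tn  mean / SD of C-Morlet scaleogram magnitude (tonic)
Mean_WL_Ph/Std_WL_Ph  same for the phasic scaleogram
SCR_Ampl              mean SCR amplitude of events peaking in the window
SCR_RiseT             mean SCR rise time (s)
SCR_Count             number of SCR events in the window
TVSymp                in-window mean of the normalized TVSymp index
HRV                   in-window RMSSD (ms), forward-filled when undefined
====================  ====================================================

Targets: P_Asym (normalized-ratio FAA), Log_Asym (log FAA), MI_Asym
(within-window mutual information between hemispheric alpha envelopes).
Labels: participant, task, trial.

Features are ranked by the Miller-Madow-corrected mutual information between
each feature's window series and an FAA target, estimated per group (default
one (participant, task, trial) series) and averaged across groups; the six
highest-MI features feed the downstream classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import eda as _eda
from . import eeg as _eeg
from . import hrv as _hrv
from . import timefreq as _tf
from .infotheory import mutual_information_mm
from .synthetic import SyntheticSession

__all__ = [
    "FEATURE_COLUMNS",
    "TARGET_COLUMNS",
    "LABEL_COLUMNS",
    "WindowGrid",
    "make_window_grid",
    "build_feature_table",
    "mi_feature_ranking",
    "select_top_features",
]

FEATURE_COLUMNS = [
    "Mean_Tn", "Std_Tn", "Mean_Ph", "Std_Ph",
    "Mean_WL_Tn", "Std_WL_Tn", "Mean_WL_Ph", "Std_WL_Ph",
    "SCR_Ampl", "SCR_RiseT", "SCR_Count", "TVSymp", "HRV",
]
TARGET_COLUMNS = ["P_Asym", "Log_Asym", "MI_Asym"]
LABEL_COLUMNS = ["participant", "task", "trial"]

DEFAULT_WINDOW_LEN = 13_000
DEFAULT_STEP = 325
FS_REF = 200.0
_FS_SLOW = 2.0  # Hz; operating rate of the CWT/VFCDM stage
_CWT_BAND = (0.005, 0.5)
_CWT_N_SCALES = 25


@dataclass(frozen=True)
class WindowGrid:
    """Half-open sample windows advancing by a fixed step."""

    window_len: int
    step: int
    n_samples: int
    fs_ref: float = FS_REF

    def __post_init__(self) -> None:
        if self.step > self.window_len:
            raise ValueError("step must not exceed window_len")
        if self.n_samples < self.window_len:
            raise ValueError("signal shorter than one window")

    @property
    def starts(self) -> np.ndarray:
        return np.arange(0, self.n_samples - self.window_len + 1, self.step)

    @property
    def windows(self) -> list[tuple[int, int]]:
        return [(int(s), int(s) + self.window_len) for s in self.starts]

    @property
    def n_windows(self) -> int:
        return (self.n_samples - self.window_len) // self.step + 1

    def time_windows(self) -> list[tuple[float, float]]:
        return [(a / self.fs_ref, b / self.fs_ref) for a, b in self.windows]


def make_window_grid(n_samples: int, window_len: int = DEFAULT_WINDOW_LEN,
                     step: int = DEFAULT_STEP,
                     fs_ref: float = FS_REF) -> WindowGrid:
    """Window grid over ``n_samples``; count = ⌊(n - len)/step⌋ + 1."""
    return WindowGrid(window_len=window_len, step=step, n_samples=n_samples,
                      fs_ref=fs_ref)


def build_feature_table(session: SyntheticSession, *,
                        window_len: int = DEFAULT_WINDOW_LEN,
                        step: int = DEFAULT_STEP,
                        fs_ref: float = FS_REF,
                        n_bins_mi: int = 12,
                        scr_threshold_us: float = _eda.DEFAULT_SCR_THRESHOLD_US,
                        include_hrv: bool = True) -> pd.DataFrame:
    """One row per window per trial; deterministic for a given session.

    EDA is resampled to ``fs_ref`` so the window arithmetic applies to every
    signal identically; the slow time-frequency stage (CWT, TVSymp) runs on a
    2 Hz decimated copy with windows mapped by time.
    """
    rows = []
    for tr in session.trials:
        rows.append(_trial_features(tr, window_len, step, fs_ref, n_bins_mi,
                                    scr_threshold_us, include_hrv))
    table = pd.concat(rows, ignore_index=True)
    return table[LABEL_COLUMNS + ["window_start_s"] + FEATURE_COLUMNS
                 + TARGET_COLUMNS]


def _trial_features(tr, window_len, step, fs_ref, n_bins_mi,
                    scr_threshold_us, include_hrv) -> pd.DataFrame:
    eda200 = _eda.resample_signal(tr.eda, tr.fs_eda, fs_ref)
    n = min(eda200.size, tr.eeg_left.size, tr.eeg_right.size)
    if abs(eda200.size - tr.eeg_left.size) > fs_ref:
        raise ValueError(
            f"misaligned signal lengths in trial "
            f"({tr.participant}, {tr.task}, {tr.trial}): "
            f"eda {eda200.size} vs eeg {tr.eeg_left.size} samples at fs_ref")
    grid = make_window_grid(n, window_len, step, fs_ref)
    windows = grid.windows
    t_windows = grid.time_windows()

    dec = _eda.decompose_eda(eda200[:n], fs_ref)
    events = _eda.detect_scr_events(dec.phasic, fs_ref, scr_threshold_us)

    tonic2 = _eda.resample_signal(dec.tonic, fs_ref, _FS_SLOW)
    phasic2 = _eda.resample_signal(dec.phasic, fs_ref, _FS_SLOW)
    eda2 = _eda.resample_signal(eda200[:n], fs_ref, _FS_SLOW)
    scales = _tf.scales_for_band(*_CWT_BAND, _CWT_N_SCALES, fs=_FS_SLOW)
    sg_tn = _tf.cwt_scaleogram(tonic2, _FS_SLOW, scales)
    sg_ph = _tf.cwt_scaleogram(phasic2, _FS_SLOW, scales)
    tvs = _tf.tvsymp(eda2, _FS_SLOW)
    t2 = np.arange(tvs.size) / _FS_SLOW

    alpha_l = _eeg.bandpass_alpha(tr.eeg_left[:n], fs_ref)
    alpha_r = _eeg.bandpass_alpha(tr.eeg_right[:n], fs_ref)
    env_l = _eeg.alpha_envelope(alpha_l, fs_ref)
    env_r = _eeg.alpha_envelope(alpha_r, fs_ref)

    if include_hrv:
        rr = _hrv.RRSeries(tr.rr_ms)
        hrv_vals = _hrv.windowed_rmssd(rr, t_windows)
    else:
        hrv_vals = np.zeros(len(windows))

    recs = []
    for w, tw, hrv_val in zip(windows, t_windows, hrv_vals):
        mean_tn, std_tn = _eda.component_window_stats(dec.tonic, w)
        mean_ph, std_ph = _eda.component_window_stats(dec.phasic, w)
        mwl_tn, swl_tn = _tf.wavelet_window_features(sg_tn, tw)
        mwl_ph, swl_ph = _tf.wavelet_window_features(sg_ph, tw)
        n_scr, scr_amp, scr_rise = _eda.scr_window_features(events, w, fs_ref)
        in_w = (t2 >= tw[0]) & (t2 < tw[1])
        tvs_val = float(tvs[in_w].mean()) if np.any(in_w) else 0.0

        l_pow = _eeg.window_alpha_power(alpha_l, w)
        r_pow = _eeg.window_alpha_power(alpha_r, w)
        pair = _eeg.AlphaPowerPair(l_power=l_pow, r_power=r_pow, window=w,
                                   n_samples=w[1] - w[0])
        p_asym = _eeg.faa_ratio(pair)
        log_asym = _eeg.faa_log(pair)
        mi_asym = _eeg.faa_mi(env_l[w[0]:w[1]], env_r[w[0]:w[1]],
                              n_bins_mi, fs=fs_ref, envelope=False)

        recs.append({
            "participant": tr.participant, "task": tr.task, "trial": tr.trial,
            "window_start_s": tw[0],
            "Mean_Tn": mean_tn, "Std_Tn": std_tn,
            "Mean_Ph": mean_ph, "Std_Ph": std_ph,
            "Mean_WL_Tn": mwl_tn, "Std_WL_Tn": swl_tn,
            "Mean_WL_Ph": mwl_ph, "Std_WL_Ph": swl_ph,
            "SCR_Ampl": scr_amp, "SCR_RiseT": scr_rise, "SCR_Count": n_scr,
            "TVSymp": tvs_val, "HRV": hrv_val,
            "P_Asym": p_asym, "Log_Asym": log_asym, "MI_Asym": mi_asym,
        })
    return pd.DataFrame.from_records(recs)


def mi_feature_ranking(table: pd.DataFrame, target: str = "P_Asym",
                       group_by=("participant", "task", "trial"),
                       n_bins: int = 12,
                       features=None) -> pd.DataFrame:
    """Features ranked by group-averaged corrected MI with an FAA target.

    MI is estimated within each group (default one trial of one participant
    and task) and averaged across groups; groups with fewer than ``5 *
    n_bins`` rows are skipped with a warning.  Ties break alphabetically.
    Returns a DataFrame with columns ``feature`` and ``mi_bits`` in
    descending MI order.
    """
    if target not in table.columns:
        raise ValueError(f"target {target!r} not in table")
    feats = list(features) if features is not None else list(FEATURE_COLUMNS)
    group_by = list(group_by)
    sums = {f: 0.0 for f in feats}
    n_groups = 0
    for key, grp in table.groupby(group_by, sort=True):
        if len(grp) < 5 * n_bins:
            warnings.warn(
                f"group {key} has {len(grp)} rows < {5 * n_bins}; skipped",
                stacklevel=2)
            continue
        y = grp[target].to_numpy()
        n_groups += 1
        for f in feats:
            x = grp[f].to_numpy()
            if np.ptp(x) == 0:  # constant feature in this group: no information
                continue
            sums[f] += mutual_information_mm(x, y, n_bins)
    if n_groups == 0:
        raise ValueError("no group large enough for MI estimation")
    out = pd.DataFrame({
        "feature": feats,
        "mi_bits": [sums[f] / n_groups for f in feats],
    })
    return (out.sort_values(["mi_bits", "feature"],
                            ascending=[False, True],
                            kind="stable")
               .reset_index(drop=True))


def select_top_features(ranking: pd.DataFrame, k: int = 6) -> list[str]:
    """Names of the top-k features by mean MI."""
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds the {len(ranking)} ranked features")
    return ranking["feature"].head(k).tolist()
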