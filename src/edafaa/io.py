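"""CSV import/export for sessions, decompositions and event tables.

Layout written by :func:`write_session` under an output directory::

    manifest.csv                              one row per (participant, task,
                                              trial, signal) with fs and path
    p<P>/<task>/t<T>_eda.csv                  time_s,value   (uS, fs_eda)
    p<P>/<task>/t<T>_eeg_left.csv             time_s,value   (uV, fs_eeg)
    p<P>/<task>/t<T>_eeg_right.csv            time_s,value
    p<P>/<task>/t<T>_rr.csv                   beat_time_s,rr_ms
    p<P>/<task>/t<T>_latent.csv               time_s,latent_faa (ground truth)

:func:`read_session` reconstructs the session from the manifest.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SessionConfig, SyntheticSession, TrialData

__all__ = ["write_session", "read_session", "write_decomposition",
           "write_scr_events"]


def _signal_frame(values: np.ndarray, fs: float) -> pd.DataFrame:
    return pd.DataFrame({"time_s": np.arange(values.size) / fs,
                         "value": values})


def write_session(session: SyntheticSession, outdir) -> Path:
    """Write one CSV per (participant, task, trial, signal) plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for tr in session.trials:
        d = outdir / f"p{tr.participant:02d}" / tr.task
        d.mkdir(parents=True, exist_ok=True)
        stem = f"t{tr.trial:02d}"
        files = {
            "eda": (_signal_frame(tr.eda, tr.fs_eda), tr.fs_eda),
            "eeg_left": (_signal_frame(tr.eeg_left, tr.fs_eeg), tr.fs_eeg),
            "eeg_right": (_signal_frame(tr.eeg_right, tr.fs_eeg), tr.fs_eeg),
            "rr": (pd.DataFrame({
                "beat_time_s": np.cumsum(tr.rr_ms) / 1000.0,
                "rr_ms": tr.rr_ms}), np.nan),
            "latent": (pd.DataFrame({
                "time_s": np.arange(tr.latent_faa.size, dtype=float),
                "latent_faa": tr.latent_faa}), 1.0),
        }
        for name, (frame, fs) in files.items():
            path = d / f"{stem}_{name}.csv"
            frame.to_csv(path, index=False)
            manifest.append({
                "participant": tr.participant, "task": tr.task,
                "trial": tr.trial, "signal": name, "fs_hz": fs,
                "path": str(path.relative_to(outdir)),
            })
    mpath = outdir / "manifest.csv"
    pd.DataFrame(manifest).to_csv(mpath, index=False)
    return mpath


def read_session(manifest_path, config: SessionConfig | None = None
                 ) -> SyntheticSession:
    """Rebuild a session from a manifest written by :func:`write_session`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    man = pd.read_csv(manifest_path)
    trials = []
    keys = man[["participant", "task", "trial"]].drop_duplicates()
    fs_eda = fs_eeg = None
    for _, key in keys.iterrows():
        sel = man[(man["participant"] == key["participant"])
                  & (man["task"] == key["task"])
                  & (man["trial"] == key["trial"])]
        data = {}
        for _, row in sel.iterrows():
            frame = pd.read_csv(root / row["path"])
            data[row["signal"]] = (frame, row["fs_hz"])
        fs_eda = float(data["eda"][1])
        fs_eeg = float(data["eeg_left"][1])
        trials.append(TrialData(
            participant=int(key["participant"]), task=str(key["task"]),
            trial=int(key["trial"]),
            eda=data["eda"][0]["value"].to_numpy(),
            eeg_left=data["eeg_left"][0]["value"].to_numpy(),
            eeg_right=data["eeg_right"][0]["value"].to_numpy(),
            rr_ms=data["rr"][0]["rr_ms"].to_numpy(),
            latent_faa=data["latent"][0]["latent_faa"].to_numpy(),
            fs_eda=fs_eda, fs_eeg=fs_eeg))
    if config is None:
        tasks = tuple(dict.fromkeys(t.task for t in trials))
        config = SessionConfig(
            n_participants=int(man["participant"].max()), tasks=tasks,
            n_trials=int(man["trial"].max()), fs_eeg=fs_eeg, fs_eda=fs_eda,
            trial_duration_s=float(trials[0].latent_faa.size))
    return SyntheticSession(config=config, trials=tuple(trials))


def write_decomposition(decomposition, path) -> None:
    """time_s,tonic,phasic CSV for one decomposed EDA trace."""
    n = decomposition.tonic.size
    pd.DataFrame({
        "time_s": np.arange(n) / decomposition.fs,
        "tonic": decomposition.tonic,
        "phasic": decomposition.phasic,
    }).to_csv(path, index=False)


def write_scr_events(events, fs: float, path) -> None:
    """onset_s,peak_s,amplitude_uS,rise_time_s CSV for detected SCRs."""
    pd.DataFrame([{
        "onset_s": e.onset_index / fs,
        "peak_s": e.peak_index / fs,
        "amplitude_uS": e.amplitude,
        "rise_time_s": e.rise_time_s,
    } for e in events]).to_csv(path, index=False)
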