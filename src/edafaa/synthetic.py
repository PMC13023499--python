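"""Synthetic physiological sessions with the structure the analysis assumes.

No public recording accompanies the protocol this pipeline targets, so this
module generates sessions — participants × cognitive tasks (EAT, Ship Search,
N-Back, PVT) × trials — whose statistical structure exercises every downstream
stage:

* a latent frontal-alpha-asymmetry (FAA) trajectory per trial, smooth within
  trials, with a fatigue dip across trials centered on ``fatigue_peak_trial``
  (default trial 7, the late-night low point of a sleep-deprivation protocol);
  early and late trials sit at positive FAA, fatigued mid-session trials at
  negative FAA, so the pooled distribution straddles zero;
* a tonic skin-conductance level monotonically coupled to the latent FAA
  through a tanh map with tunable strength and sign ``coupling_kappa`` (the
  cross-participant couplings seen in practice carry mixed signs);
* Poisson-timed SCR events with a rise/decay difference-of-exponentials
  kernel superimposed on the tonic level;
* left/right frontal alpha-band EEG whose window powers realize the latent
  FAA exactly in the noiseless limit (amplitudes scale with sqrt(1 -+ faa));
* an R-R interval series calibrated to a target RMSSD.

Within-trial latent fluctuations are demeaned, so each trial's mean latent FAA
equals its deterministic fatigue profile value exactly — the trial-level
ground truth used by recovery tests.  All randomness derives from a single
seed via spawned generators, so identical configs give bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "TASK_DURATIONS_S",
    "SessionConfig",
    "TrialData",
    "SyntheticSession",
    "fatigue_profile",
    "generate_latent_trial",
    "generate_eda_trial",
    "generate_eeg_alpha_pair",
    "generate_rr_trial",
    "generate_session",
]

TASK_DURATIONS_S = {"EAT": 300.0, "SHIP": 1200.0, "NBACK": 600.0, "PVT": 600.0}


@dataclass(frozen=True)
class SessionConfig:
    """Study-design parameters of one synthetic cohort."""

    n_participants: int = 10
    tasks: tuple[str, ...] = ("EAT", "SHIP", "NBACK", "PVT")
    n_trials: int = 12
    trial_duration_s: float | None = None   # None -> per-task defaults
    fs_eeg: float = 200.0
    fs_eda: float = 400.0
    coupling_kappa: float = 0.9
    fatigue_peak_trial: int = 7
    scr_rate_hz: float = 0.08
    scr_amp_mean_us: float = 0.3
    rmssd_target_ms: float = 40.0
    mean_rr_ms: float = 800.0
    noise_sd: dict = field(default_factory=lambda: {
        "eeg": 3.0,     # uV broadband added to each channel
        "eda": 0.01,    # uS white measurement noise
        "tonic": 0.08,  # uS slow tonic fluctuation (smoothed; arousal-modulated)
    })
    alpha_amp_uv: float = 10.0
    alpha_freq_hz: float = 10.0
    window_len_samples: int = 13_000  # at fs_eeg; minimum trial length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        if self.fs_eeg <= 0 or self.fs_eda <= 0:
            raise ValueError("sampling rates must be positive")
        if abs(self.coupling_kappa) > 1:
            raise ValueError("|coupling_kappa| must be <= 1")
        if self.scr_rate_hz < 0:
            raise ValueError("scr_rate_hz must be non-negative")
        min_dur = self.window_len_samples / self.fs_eeg
        for task in self.tasks:
            if self.duration_for(task) < min_dur:
                raise ValueError(
                    f"trial duration for {task} shorter than one analysis "
                    f"window ({min_dur:.0f} s)")

    def duration_for(self, task: str) -> float:
        if self.trial_duration_s is not None:
            return self.trial_duration_s
        try:
            return TASK_DURATIONS_S[task]
        except KeyError:
            raise ValueError(f"no duration configured for task {task!r}") from None


@dataclass(frozen=True)
class TrialData:
    """Raw signals of one (participant, task, trial)."""

    participant: int
    task: str
    trial: int                 # 1-based
    eda: np.ndarray            # uS at fs_eda
    eeg_left: np.ndarray       # uV at fs_eeg (F7 surrogate)
    eeg_right: np.ndarray      # uV at fs_eeg (F8 surrogate)
    rr_ms: np.ndarray          # R-R intervals
    latent_faa: np.ndarray     # per-second ground truth, in (-1, 1)
    fs_eda: float
    fs_eeg: float

    def latent_at_samples(self, fs: float) -> np.ndarray:
        """Latent FAA linearly interpolated onto a sample grid at ``fs``."""
        n = int(round(self.latent_faa.size * fs))
        t = np.arange(n) / fs
        return np.interp(t, np.arange(self.latent_faa.size, dtype=float),
                         self.latent_faa)

    def latent_window_means(self, windows, fs: float) -> np.ndarray:
        """Ground-truth latent FAA mean per half-open sample window at ``fs``."""
        lat = self.latent_at_samples(fs)
        return np.array([lat[a:b].mean() for a, b in windows])


@dataclass(frozen=True)
class SyntheticSession:
    """All trials of a synthetic cohort plus the generating config."""

    config: SessionConfig
    trials: tuple[TrialData, ...]

    def get(self, participant: int, task: str, trial: int) -> TrialData:
        for tr in self.trials:
            if (tr.participant, tr.task, tr.trial) == (participant, task, trial):
                return tr
        raise KeyError((participant, task, trial))


def fatigue_profile(trial: int, peak_trial: int, base: float = 0.32,
                    depth: float = 0.72, width: float = 2.5,
                    power: int = 6) -> float:
    """Deterministic per-trial latent FAA mean: a fatigue dip at the peak trial.

    Early/late trials sit near ``base`` (positive affect); the dip bottoms out
    at ``base - depth`` at ``peak_trial`` — the unique minimum across trials.
    The super-Gaussian shape (``power`` > 2: flat bottom, steep edges) holds
    the fatigued trials in a sustained low-FAA state and keeps the alert
    trials near baseline, giving the session the two-regime (high/low FAA)
    structure that the downstream two-cluster analysis assumes, with only the
    shoulder trials in between.
    """
    z = abs(trial - peak_trial) / width
    return base - depth * np.exp(-(z ** power))


def _smooth_noise(rng: np.random.Generator, n: int, sd: float,
                  corr_len: float) -> np.ndarray:
    """Zero-mean smooth Gaussian noise with unit-SD scaling before demeaning."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    w = gaussian_filter1d(rng.standard_normal(n + 1), corr_len, mode="wrap")[:n]
    s = w.std()
    return w / s * sd if s > 0 else np.zeros(n)


def generate_latent_trial(rng: np.random.Generator, n_seconds: int, trial: int,
                          peak_trial: int, participant_offset: float = 0.0,
                          wiggle_sd: float = 0.12,
                          wiggle_max: float = 0.3) -> np.ndarray:
    """Per-second latent FAA for one trial.

    Smooth within-trial fluctuations are demeaned (and amplitude-capped at
    ``wiggle_max``) so the trial mean equals ``fatigue_profile(trial) +
    participant_offset`` exactly, and the total stays inside (-1, 1).
    """
    level = fatigue_profile(trial, peak_trial) + participant_offset
    wiggle = _smooth_noise(rng, n_seconds, wiggle_sd, corr_len=20.0)
    wiggle -= wiggle.mean()
    peak = np.abs(wiggle).max()
    if peak > wiggle_max:
        wiggle *= wiggle_max / peak
        wiggle -= wiggle.mean()
    return level + wiggle


def generate_eda_trial(tonic_trajectory, scr_rate_hz: float, fs: float,
                       seed, noise_sd: float = 0.0,
                       scr_amp_mean_us: float = 0.3,
                       tau_rise: float = 0.75,
                       tau_decay: float = 2.0,
                       rate_modulation=None,
                       amp_modulation=None) -> np.ndarray:
    """Tonic trajectory plus Poisson-timed SCR kernels plus white noise.

    The SCR kernel is the same rise/decay difference of exponentials the
    detector assumes (rise 0.75 s, decay 2 s), unit peak, scaled by a
    log-normal amplitude with mean ``scr_amp_mean_us``.

    ``rate_modulation`` / ``amp_modulation`` are optional per-sample relative
    multipliers (non-negative): the event process becomes an inhomogeneous
    Poisson process with rate ``scr_rate_hz * rate_modulation(t)`` (sampled by
    thinning) and event amplitudes scale with ``amp_modulation`` at the event
    time.  Sympathetic arousal raises both SCR frequency and amplitude, which
    is how session generation couples phasic activity to the latent state.
    """
    from .eda import scr_kernel

    tonic = np.asarray(tonic_trajectory, dtype=float).ravel()
    if np.any(tonic <= 0):
        raise ValueError("tonic trajectory must be positive")
    if scr_rate_hz < 0:
        raise ValueError("scr_rate_hz must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = tonic.size
    out = tonic.copy()
    if scr_rate_hz > 0:
        duration = n / fs
        if rate_modulation is None:
            rate_mod = np.ones(n)
        else:
            rate_mod = np.asarray(rate_modulation, dtype=float).ravel()
            if rate_mod.size != n or np.any(rate_mod < 0):
                raise ValueError("rate_modulation must be non-negative, per-sample")
        peak_rate = scr_rate_hz * rate_mod.max()
        n_cand = rng.poisson(peak_rate * duration)
        starts = np.sort(rng.uniform(0, duration, size=n_cand))
        idx = np.minimum((starts * fs).round().astype(int), n - 1)
        keep = rng.uniform(size=n_cand) * rate_mod.max() <= rate_mod[idx]
        idx = idx[keep]
        kernel = scr_kernel(fs, tau_rise, tau_decay)
        # mean of lognormal(-0.08, 0.4) is 1, so amplitudes average scr_amp_mean_us
        amps = scr_amp_mean_us * rng.lognormal(-0.08, 0.4, size=idx.size)
        if amp_modulation is not None:
            amp_mod = np.asarray(amp_modulation, dtype=float).ravel()
            if amp_mod.size != n or np.any(amp_mod < 0):
                raise ValueError("amp_modulation must be non-negative, per-sample")
            amps = amps * amp_mod[idx]
        for i0, a in zip(idx, amps):
            m = min(kernel.size, n - i0)
            if m > 0:
                out[i0:i0 + m] += a * kernel[:m]
    if noise_sd > 0:
        out = out + noise_sd * rng.standard_normal(n)
    return out


def generate_eeg_alpha_pair(latent_faa, fs: float, seed,
                            duration_s: float | None = None,
                            alpha_amp_uv: float = 10.0,
                            alpha_freq_hz: float = 10.0,
                            noise_sd: float = 3.0,
                            latent_rate_hz: float = 1.0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Left/right alpha-band channels realizing a latent FAA trajectory.

    The noiseless alpha parts are amplitude-modulated carriers with
    instantaneous powers ``A0² (1 - f(t))`` (left) and ``A0² (1 + f(t))``
    (right), so the window power ratio (R-L)/(R+L) equals the window-mean
    latent FAA exactly before noise.  Broadband Gaussian noise is added on
    top of each channel independently.
    """
    lat = np.asarray(latent_faa, dtype=float).ravel()
    if np.any(np.abs(lat) >= 1):
        raise ValueError("latent FAA must lie strictly inside (-1, 1)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if duration_s is None:
        duration_s = lat.size / latent_rate_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    f = np.interp(t, np.arange(lat.size) / latent_rate_hz, lat)
    phase_l, phase_r = rng.uniform(0, 2 * np.pi, size=2)
    carrier_l = np.sqrt(2.0) * np.sin(2 * np.pi * alpha_freq_hz * t + phase_l)
    carrier_r = np.sqrt(2.0) * np.sin(2 * np.pi * alpha_freq_hz * t + phase_r)
    left = alpha_amp_uv * np.sqrt(1.0 - f) * carrier_l
    right = alpha_amp_uv * np.sqrt(1.0 + f) * carrier_r
    if noise_sd > 0:
        left = left + noise_sd * rng.standard_normal(n)
        right = right + noise_sd * rng.standard_normal(n)
    return left, right


def generate_rr_trial(duration_s: float, mean_rr_ms: float,
                      rmssd_target_ms: float, seed) -> np.ndarray:
    """R-R intervals (ms) spanning ``duration_s`` with a target RMSSD.

    Beat-to-beat white jitter with SD target/sqrt(2) yields the requested
    RMSSD; a small slow oscillation (amplitude 0.25 × target, 60 s period)
    adds realistic low-frequency structure without moving the RMSSD.
    Intervals accumulate until the trial duration is covered.
    """
    if mean_rr_ms <= 0:
        raise ValueError("mean_rr_ms must be positive")
    if rmssd_target_ms < 0:
        raise ValueError("rmssd_target_ms must be non-negative")
    if rmssd_target_ms > mean_rr_ms:
        raise ValueError("rmssd target exceeding the mean R-R is unphysiological")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n_max = int(np.ceil(duration_s * 1000.0 / mean_rr_ms)) + 64
    jitter = (rmssd_target_ms / np.sqrt(2.0)) * rng.standard_normal(n_max)
    beat_idx = np.arange(n_max)
    slow = 0.25 * rmssd_target_ms * np.sin(
        2 * np.pi * beat_idx * mean_rr_ms / 1000.0 / 60.0)
    rr = np.maximum(mean_rr_ms + jitter + slow, 0.25 * mean_rr_ms)
    total = np.cumsum(rr)
    n_keep = int(np.searchsorted(total, duration_s * 1000.0)) + 1
    return rr[:min(n_keep, n_max)]


def generate_session(config: SessionConfig) -> SyntheticSession:
    """Generate the full cohort described by ``config``.

    Deterministic given the config (seed included): participant-level offsets
    and each trial's draws come from generators spawned from a single seed
    sequence in a fixed order.
    """
    root = np.random.SeedSequence(config.seed)
    part_seq = root.spawn(config.n_participants)
    trials: list[TrialData] = []
    for p, pseq in enumerate(part_seq, start=1):
        prng = np.random.default_rng(pseq)
        faa_offset = prng.uniform(-0.02, 0.02)
        scl_base = prng.uniform(1.95, 2.05)
        task_seqs = pseq.spawn(len(config.tasks))
        for task, tseq in zip(config.tasks, task_seqs):
            duration = config.duration_for(task)
            n_sec = int(round(duration))
            trial_seqs = tseq.spawn(config.n_trials)
            for k, trseq in enumerate(trial_seqs, start=1):
                rng = np.random.default_rng(trseq)
                latent = generate_latent_trial(
                    rng, n_sec, k, config.fatigue_peak_trial, faa_offset)
                trials.append(_generate_trial(
                    config, rng, p, task, k, latent, scl_base))
    return SyntheticSession(config=config, trials=tuple(trials))


def _generate_trial(config: SessionConfig, rng: np.random.Generator,
                    participant: int, task: str, trial: int,
                    latent: np.ndarray, scl_base: float) -> TrialData:
    duration = latent.size  # seconds (per-second latent grid)
    n_eda = int(round(duration * config.fs_eda))
    t_eda = np.arange(n_eda) / config.fs_eda
    lat_eda = np.interp(t_eda, np.arange(latent.size, dtype=float), latent)
    # Slow tonic fluctuations whose amplitude rises with sympathetic arousal
    # (inverse latent FAA): spectral EDA intensity is elevated throughout the
    # fatigued trials, which is what makes tonic variability and its wavelet
    # magnitude informative about the latent state.
    slow = _smooth_noise(rng, latent.size,
                         config.noise_sd.get("tonic", 0.0), corr_len=15.0)
    slow_mod = 1.0 - 0.5 * config.coupling_kappa * latent
    tonic = (scl_base
             + config.coupling_kappa * np.tanh(1.5 * lat_eda)
             + np.interp(t_eda, np.arange(latent.size, dtype=float),
                         slow * slow_mod))
    # Sympathetic arousal (inverse latent FAA) raises SCR rate and amplitude;
    # scaled by the same kappa so kappa=0 leaves phasic activity uncoupled.
    rate_mod = 1.0 - config.coupling_kappa * lat_eda
    amp_mod = 1.0 - 0.6 * config.coupling_kappa * lat_eda
    eda = generate_eda_trial(tonic, config.scr_rate_hz, config.fs_eda, rng,
                             noise_sd=config.noise_sd.get("eda", 0.0),
                             scr_amp_mean_us=config.scr_amp_mean_us,
                             rate_modulation=rate_mod,
                             amp_modulation=amp_mod)
    left, right = generate_eeg_alpha_pair(
        latent, config.fs_eeg, rng, duration_s=duration,
        alpha_amp_uv=config.alpha_amp_uv,
        alpha_freq_hz=config.alpha_freq_hz,
        noise_sd=config.noise_sd.get("eeg", 0.0))
    rr = generate_rr_trial(duration, config.mean_rr_ms,
                           config.rmssd_target_ms, rng)
    return TrialData(participant=participant, task=task, trial=trial,
                     eda=eda, eeg_left=left, eeg_right=right, rr_ms=rr,
                     latent_faa=latent, fs_eda=config.fs_eda,
                     fs_eeg=config.fs_eeg)
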