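# Methods

`edafaa` implements an information-theoretic analysis linking electrodermal
activity (EDA) features to frontal alpha asymmetry (FAA), and an EDA-only
classifier of approach/withdrawal emotional states validated against the FAA
sign. This note records the models, the estimator conventions, the synthetic
data the package is tested on, and the numerical choices a maintainer would
want to know about.

## Signals and features

All per-trial signals are aligned to a 200 Hz reference grid and cut by a
moving window of 13,000 samples (65 s) advancing 325 samples (1.625 s) per
step. The window length is defined by *sample count*; at 200 Hz that is 65 s
(the slow sympathetic indices need windows of roughly a minute). Thirteen
candidate features are computed per window:

* **Tonic / phasic statistics** (`Mean_Tn`, `Std_Tn`, `Mean_Ph`, `Std_Ph`).
  EDA (μS, recorded at 400 Hz, resampled to 200 Hz) is split into a tonic
  level (skin conductance level, < 0.05 Hz) and a phasic residual. The
  default decomposer is a zero-phase low-pass split at 0.05 Hz computed on a
  4 Hz decimated copy; reconstruction (tonic + phasic = input) is exact by
  construction. A sparse-deconvolution option models phasic activity
  explicitly as a non-negative driver convolved with the canonical SCR
  kernel, alternating baseline and driver fits; it recovers transient peaks
  more faithfully than the band split (a lone SCR has genuine sub-0.05 Hz
  content, so the band split absorbs roughly a third of its peak into the
  baseline — a property, not a bug, of any fixed-band decomposition).
  Window statistics use the population (divisor *N*) standard deviation.
* **SCR event features** (`SCR_Ampl`, `SCR_RiseT`, `SCR_Count`). Skin
  conductance responses are detected on the phasic channel after zero-phase
  2 Hz smoothing (SCRs live well below 1 Hz; unsmoothed noise fragments the
  onset search). A peak's onset is the last local minimum before it,
  amplitude is peak minus onset value, rise time is onset-to-peak. The
  amplitude threshold defaults to 0.05 μS — typical SCRs are well under
  1 μS, and the occasionally quoted 5 μS figure is only reachable as an
  explicit configuration. Windows aggregate events whose peak falls inside
  the half-open sample range; empty windows report zeros so downstream
  binning never sees gaps.
* **Wavelet features** (`Mean_WL_Tn`, `Std_WL_Tn`, `Mean_WL_Ph`,
  `Std_WL_Ph`). A complex-Morlet continuous wavelet transform
  ψ(η) = (πf_b)^(−1/2) exp(−η²/f_b) exp(j2πf_c η), with f_b = 1.5 and
  f_c = 1, is evaluated on 25 log-spaced scales spanning pseudo-frequencies
  0.005–0.5 Hz (a = f_c·f_s/f) with a 1 s translation grid. Daughter
  wavelets are scaled by 1/√a so their energies agree to better than 1%.
  Note the mother wavelet is not unit-energy: ∫|ψ|²dη = 1/√(2πf_b) ≈ 0.326
  for f_b = 1.5; only cross-scale energy *equality* matters for comparing
  coefficients. The transform runs on a 2 Hz decimated copy of the tonic
  and phasic components — the band of interest lies three decades below the
  acquisition rate, and the scale grid is derived from the band at the
  operating rate, so pseudo-frequencies are unchanged. Coefficients whose
  wavelet support (3 envelope SDs) overhangs a trial edge are flagged and
  excluded from window statistics whenever clean points remain.
* **TVSymp** — the time-varying sympathetic index. Variable-frequency
  complex demodulation (VFCDM) decomposes the 2 Hz EDA into band-limited
  components on a grid of center frequencies f_oi = (i−1)·2F_ω: each band is
  frequency-shifted, low-pass filtered (linear-phase FIR, cutoff F_ω = 0.03
  Hz, N_ω = 64 taps, applied by centered convolution so the net phase is
  zero), re-modulated, and refined through the Hilbert transform for
  instantaneous amplitude/phase/frequency. TVSymp sums the instantaneous
  amplitudes of components centered in 0.08–0.24 Hz and normalizes to unit
  variance over the recording. The whole chain runs on a reflect-padded
  copy so filter and analytic-signal transients fall outside the trial.
  The 65-tap default keeps the filter usable on short (two-minute) trials;
  band *reconstruction* fidelity, in contrast, requires the FIR transition
  band to fit inside the 2F_ω spacing (roughly N_ω ≳ 3.3·f_s/(2F_ω) ≈ 110
  taps at 2 Hz), which is why the reconstruction and dc-leakage tests use
  longer filters on longer fixtures.
* **HRV** — RMSSD, √(1/(N−1)·Σ(RR_{i+1}−RR_i)²) in ms, over the R-R
  intervals whose ending beat falls inside the window; windows with fewer
  than two intervals are forward-filled. R-peak detection from raw ECG is
  out of scope; the pipeline consumes interval series.

## FAA targets

Alpha power is computed in the time domain, P = (1/N)Σx[n]², on the
zero-phase 8–13 Hz band-passed frontal channels (left = F7, right = F8).
Three variants are reported per window: the normalized ratio
(R−L)/(R+L) (`P_Asym`), the logarithmic form ln R − ln L (`Log_Asym`;
natural log, same sign as the ratio), and a mutual-information form
(`MI_Asym`): the corrected MI between the rectified, smoothed Hilbert
envelopes of the two hemispheres inside the window. The MI variant is
sign-free — it quantifies how strongly the hemispheric amplitude
fluctuations are coupled, not which side dominates — and its exact
construction is a package choice (the variables entering an MI-as-FAA
statistic are not standardized in the literature); alternative definitions
can be plugged in by passing precomputed envelopes.

## Mutual information estimation

Window series are discretized by equal-frequency (uniform-count) binning
into B = 12 bins holding ⌈N/B⌉ or ⌊N/B⌋ samples each (ties broken by stable
sample order), which maximizes marginal entropy and makes all MI estimates
invariant to monotone transforms. MI is the plug-in estimate
I = ΣΣ p(x,y) log₂[p(x,y)/(p(x)p(y))] minus a Miller–Madow first-order bias
term (B_xy − B_x − B_y + 1)/(2N ln 2), floored at zero.

The support-size convention matters in the sparse regime N < B². Under
equal-frequency binning every marginal bin is occupied by construction, and
under the independence null every joint cell has non-zero probability, so
the default uses the full table (B_xy = B² = 144). The classical plug-in
support estimate (count of occupied cells) is available as an option but
under-corrects badly when N is small: at N = 127 it leaves ≈ 0.45 bits of
residual bias on independent data, versus ≈ 0.14 bits (about 1.5
permutation-null SDs) for the full-table form. Even the full-table form
retains some sparse-regime bias beyond the first-order Miller term, which
is why calibration checks at N = 127 are stated about the estimator's
average rather than a single draw.

Significance uses a permutation test: the corrected MI is recomputed for
uniformly shuffled copies of one variable, and p = (1 + #{MI_perm ≥
MI_obs})/(n_perm + 1), so p is never zero and bottoms out at 1/(n_perm+1) —
9.999×10⁻⁵ for the canonical 10,000 surrogates. Because bin assignments are
rank-based, shuffling the assignment vector is equivalent and fast.
Overlapping windows make the series heavily autocorrelated; plain shuffling
is the default (matching the surrogate convention of the analysis this
package operationalizes), and a block-shuffle option preserves
autocorrelation when a calibrated null is needed — the test suite uses
trial-level blocks for exactly that purpose. A Pearson screen (r with its
two-sided p) is reported alongside MI; the motivating contrast is a
symmetric non-linear dependence (y = x²) with r ≈ 0 but large MI.
Multiple-comparison control uses the Bonferroni threshold α/m (0.05/6 =
0.0083 for the six selected features).

## Feature selection and classification

Features are ranked by the group-averaged corrected MI between each feature
and an FAA target — by default one group per (participant, task, trial),
each group needing at least 5·B rows; the scaled-down pipeline pools each
participant's trials instead (120 s trials yield 34 windows, too few for 12
bins). The six highest-MI features are retained.

Class labels come from the data, not from FAA: training windows are
standardized (z-scores from training-fold statistics only) and grouped into
two clusters by bottom-up agglomerative clustering on squared-Euclidean
dissimilarities (average linkage by default; single and complete are
available). FAA is used only to *name* the clusters — higher mean ratio-FAA
becomes Class 1 (approach), the other Class 2 (withdrawal) — and a schema
firewall rejects any FAA or label column offered as a clustering/SVM
feature. An RBF-kernel SVM (C = 1, γ = scale) trained on those labels is
evaluated by leave-one-trial-out cross-validation per task: per fold, the
standardizer, cluster labels and SVM are fit on the remaining trials
(pooled over participants) and the held-out trial's windows are scored by
coincidence with the FAA sign — the share of predicted Class-1 windows with
positive ratio-FAA, and of Class-2 windows with non-positive ratio-FAA
(zero counts as non-positive; an empty class reports missing, and averages
skip missing entries). Per-fold labeling is the default to preserve CV
hygiene (a mutation test asserts that perturbing held-out rows leaves the
fitted fold model bit-identical); a global-labeling mode exists for
comparison.

## The synthetic cohort

No public recording accompanies the acquisition protocol this analysis
targets, so the package ships a generator whose sessions have the
statistical structure the analysis assumes, and the whole pipeline is
validated on it:

* a latent FAA trajectory per trial, bounded in (−1, 1), with a
  super-Gaussian fatigue dip across trials centered on trial 7 (the
  late-night low of a sleep-deprivation protocol): alert trials sit near
  +0.32, fatigued trials near −0.40, with a sharp transition at the
  shoulders. Within-trial fluctuations are smooth, demeaned, and
  amplitude-capped, so each trial's mean latent FAA equals its profile
  value exactly — the ground truth for recovery tests;
* a tonic skin-conductance level coupled to the latent state through
  base + κ·tanh(1.5·faa) plus slow fluctuations whose amplitude rises with
  sympathetic arousal (inverse FAA) — spectral EDA intensity is elevated
  throughout fatigued trials, which is what makes tonic variability and its
  wavelet magnitude informative;
* Poisson-timed SCR events (rise 0.75 s / decay 2 s
  difference-of-exponentials kernel, log-normal amplitudes averaging
  0.3 μS, base rate 0.08 Hz) whose rate and amplitude also scale with
  arousal via the same κ, so κ = 0 switches every coupling off at once;
* left/right alpha (10 Hz carriers, amplitudes √(1∓faa)·10 μV) whose
  window-power ratio equals the window-mean latent FAA exactly before
  noise, plus 3 μV broadband noise per channel;
* R-R intervals with beat-to-beat jitter calibrated so the sample RMSSD
  matches a 40 ms target.

All randomness derives from one seed through spawned generators, so equal
configurations produce bit-identical sessions.

What the generator does **not** emulate: task-specific psychophysics (tasks
differ only by duration and the shared coupling parameters), inter-trial
rest-period continuity, motion/contact artifacts, eye-blink or EMG
contamination of EEG, and — important for interpreting the scaled-down
evaluation — *within-trial* emotional-state alternation. At the scaled
trial length (120 s) a 65 s window overlaps any plausible state switch, so
each synthetic trial effectively carries one state and held-out trials are
one-sided in FAA sign. Passing tests therefore demonstrate that the
estimators, the selection chain and the cross-validated classifier recover
a planted coupling under realistic noise; they do not demonstrate
performance on real multi-state recordings.

## Evaluation at desk scale

The end-to-end evaluation runs 5 participants × 4 tasks × 12 trials of
120 s with κ = 0.9 (8,160 windows; about half a minute on one CPU). The
tonic mean ranks first by MI, as it should under this coupling. The
fold-averaged per-class coincidence lands in the high 60s (the acceptance
script computes the exact value), short of the ≈ 80–90 % averages reported
for real multi-hour cohorts, for a quantified reason: with oracle sign
labels replacing the clustering step the same condition yields 82.8 % (and
95.5 % per-window sign agreement), so the gap is label impurity — the
two-cluster cut on pooled windowed features sometimes peels a sub-mode or
an outlier clump instead of cutting at the between-state neck, and the
per-class precision metric scores a fold's minority class at 0 % when a
single stray window lands in an otherwise one-sided fold. Both effects are
properties of the scaled condition (one-sided 120 s trials, noisy
short-trial window features), not of the estimator implementations, and the
ledgered per-window agreement stays above 95 %.

## Known limitations

* The low-pass tonic/phasic split attenuates SCR peaks by design; use the
  sparse-deconvolution decomposer when event amplitudes matter.
* The default 65-tap VFCDM filter trades band resolution for usability on
  short trials; reconstruction-grade analyses should raise `n_w`.
* MI between heavily overlapping windows is inflated by autocorrelation;
  rankings inherit this, and significance statements should use the block
  permutation option.
* The MI-based FAA variant is exploratory: it is sign-free and its
  construction is a package convention.
* The agglomerative two-cluster cut is sensitive to outliers and
  heteroscedastic state clouds; inspect the merge tree (exported with each
  clustering result) before trusting pooled-cohort labels.
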