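# edafaa

Mutual-information analysis linking electrodermal activity (EDA) to frontal
alpha asymmetry (FAA), with an EDA-only classifier of approach/withdrawal
emotional states.

FAA — the difference in alpha-band (8–13 Hz) power between the right and
left frontal EEG channels, here the normalized ratio
FAA = (R_power − L_power)/(R_power + L_power) with
P = (1/N)·Σ x[n]² per 65 s window — indexes approach (positive) versus
withdrawal (negative) affect, but needs an EEG montage. EDA (skin
conductance, μS) needs two finger electrodes. This package asks, and
operationalizes, the question: *how much information do windowed EDA
features carry about FAA, and can EDA alone track the FAA sign?* It is
aimed at psychophysiologists and biosignal/ML researchers working on
affective state monitoring under cognitive load and sleep deprivation.

The pipeline:

1. **Feature extraction** — tonic/phasic decomposition of EDA, SCR event
   detection (count, amplitude, rise time), complex-Morlet CWT magnitude
   statistics of both components (f_b = 1.5, f_c = 1, 25 scales over
   0.005–0.5 Hz), the TVSymp sympathetic index from variable-frequency
   complex demodulation (0.08–0.24 Hz band), and RMSSD from R-R intervals —
   13 features per moving window (13,000 samples, 325-sample step, 200 Hz).
2. **Dependence estimation** — equal-frequency binning into B = 12
   uniform-count bins, then
   I(X;Y) = ΣΣ p(x,y) log₂[p(x,y)/(p(x)p(y))] with the Miller–Madow
   first-order bias correction, permutation significance
   (p = (1+k)/(n_perm+1)), a Pearson screen, and Bonferroni control.
3. **Classification** — top-6 features by MI, two-cluster agglomerative
   labeling (clusters named by mean FAA, never clustered on FAA), an RBF
   SVM, and leave-one-trial-out cross-validation scored by *coincidence*
   of predicted classes with the FAA sign.

Because the underlying human recordings are not public, the package
includes a first-class synthetic-session generator (`edafaa.synthetic`)
with a latent FAA trajectory (fatigue dip at trial 7), tunable FAA↔EDA
coupling κ, Poisson SCR events, alpha-band EEG realizing the latent FAA,
and RMSSD-calibrated R-R series; every stage is tested against it.

## Worked example

```python
from edafaa.pipeline import run_cohort_pipeline
from edafaa.infotheory import (bonferroni_threshold, pearson_screen,
                               permutation_test_mi)

res = run_cohort_pipeline(seed=7, n_participants=2, tasks=("EAT",))
print(res.ranking.head(6).to_string(index=False))

grp = res.table[res.table.participant == 1]
mi, p = permutation_test_mi(grp["Mean_Tn"], grp["P_Asym"],
                            n_perm=10_000, seed=7)
r, _ = pearson_screen(grp["Mean_Tn"], grp["P_Asym"])
print(f"Mean_Tn vs P_Asym: MI={mi:.3f} bits (perm p={p:.2e}), "
      f"Pearson r={r:.3f}")
print(f"Bonferroni threshold (6 tests): {bonferroni_threshold(0.05, 6):.4f}")
print(f"grand average coincidence: {res.report.grand_average:.1f}%")
```

prints

```
   feature  mi_bits
   Mean_Tn 1.573511
 Std_WL_Ph 1.293997
 Std_WL_Tn 1.293181
    Std_Ph 1.264687
Mean_WL_Tn 1.238041
Mean_WL_Ph 1.236251
Mean_Tn vs P_Asym: MI=1.816 bits (perm p=1.00e-04), Pearson r=0.967
Bonferroni threshold (6 tests): 0.0083
grand average coincidence: 80.0%
```

Reading it: on this strongly coupled cohort (κ = 0.9) the tonic mean is the
most informative feature about FAA (1.57 bits averaged over groups, out of
log₂12 ≈ 3.58 attainable); for one participant the Mean_Tn–FAA dependence
is overwhelming (1.82 bits, permutation p at the 1/10,001 floor of 10,000
surrogates) and strongly linear here (r = 0.97); and the EDA-only SVM
agrees with the FAA sign on 80% of the per-class fold rates.

A command-line interface wraps the same stages:

```bash
edafaa simulate --participants 2 --tasks EAT --trial-duration 120 \
       --seed 7 --out session/
edafaa extract --manifest session/manifest.csv --out features.csv
edafaa mi --features features.csv --group-by participant,task \
       --out ranking.csv
edafaa classify --features features.csv --group-by participant,task \
       --top-k 6 --out report.csv
```

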