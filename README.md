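# bsdetect

Automated burst-suppression detection for frontal anesthesia EEG, threshold
calibration against expert annotations, and the cohort statistics that link
burst suppression and anesthetic agent to postoperative delirium.

## The problem

Under deep general anesthesia the EEG can enter **burst suppression (BS)**:
alternating high-amplitude polyphasic bursts and near-isoelectric suppressed
stretches. BS in elderly surgical patients is a marker of postoperative
delirium (POD) risk, and the prognostic weight of a BS episode depends on the
anesthetic agent producing it. Quantifying BS from the 4-channel frontal
montage (Fp1, Fp2, F7, F8) of intraoperative monitors — and relating it,
per agent, to POD — requires three things this package provides:

1. **A detector.** Per channel, the amplitude envelope is a centered moving
   average of the rectified signal over a window `w_env` (default 0.5 s).
   Suppression = maximal runs with envelope < θ (default 5 μV) lasting
   ≥ 0.5 s; a burst is the waveform between consecutive suppressions when it
   lasts ≥ 0.5 s and has ≥ 4 phases (half-waves). BS is accepted only where
   **all** channels are simultaneously suppressed (sample-wise consensus);
   consensus suppressions separated by ≤ 30 s gaps are chained into BS
   epochs. Summary: total suppressed time `bs_duration`, epoch span, and the
   burst-suppression ratio `BSR = 100 · bs_duration / analyzed time`.

2. **Calibration.** θ and `w_env` are chosen on annotated recordings by
   exhaustive grid search minimizing the mean squared BS-duration error, and
   validated by k-fold cross-validation stratified on the anesthetic group
   (propofol vs sevoflurane): per fold, fit on the other folds, measure
   held-out absolute duration and BSR errors, report medians and IQRs.

3. **Cohort statistics.** Agent × POD contingency analysis (uncorrected
   Pearson χ², relative risk with log-scale Wald CI, Cohen's
   h = |2 asin√p₁ − 2 asin√p₂|, two-proportion z-test power), multivariable
   logistic POD models with several BS representations (binary any-BS, raw
   duration, continuous BSR; subgroup and BS-only dose-response variants),
   and the interaction model with a sevoflurane × any-BS product term whose
   fit is decomposed into the four conditional odds ratios relative to
   propofol without BS.

Synthetic generators — agent-specific background EEG (propofol: alpha +
slow-delta; sevoflurane: theta) with ground-truth-labeled injected episodes,
and cohorts with a specified conditional POD-odds structure — make every
stage testable end to end with exact truth.

## Worked example

```python
import bsdetect as bd

spec = bd.EEGSimSpec(
    agent="propofol", duration=300.0,
    episode_plan=[
        bd.Episode(onset=60.0, supp_duration=6.0, burst_duration=1.0, n_alternations=3),
        bd.Episode(onset=200.0, supp_duration=20.0, burst_duration=1.0, n_alternations=0),
    ],
    seed=7,
)
recording, truth = bd.generate_eeg(spec)
summary = bd.summarize(recording, bd.DetectionParams())
```

prints (via `python examples/detect_burst_suppression.py`):

```
true suppression      :   44.00 s
detected bs_duration  :   42.52 s
epoch span            :   46.56 s
BSR                   :  14.172 %
episodes              : [(60.1, 86.9), (200.1, 219.9)]
```

44 s of suppression were injected; the detector recovers 42.5 s (the ~1.5 s
shortfall is envelope boundary smear, bounded by `w_env` per episode
boundary), delimits both epochs at their true locations, and the epoch span
additionally counts the 1-s bursts inside the first episode. The BSR is the
suppressed fraction of the 300 s analyzed: 42.52/300 ≈ 14.2 %.

Other capabilities, one script each, under `examples/`:
`calibrate_thresholds_cv.py` (cross-validated calibration),
`cohort_interaction_analysis.py` (contingency + interaction decomposition),
`model_comparison.py` (the BS modelling strategies side by side).

A thin CLI mirrors the library: `bsdetect detect`, `bsdetect cv`,
`bsdetect simulate-eeg`, `bsdetect simulate-cohort`,
`bsdetect analyze-cohort` (see `bsdetect --help`).

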