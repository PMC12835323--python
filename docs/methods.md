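# Methods

## Detector

**Envelope.** For each channel the amplitude envelope is the centered moving
average of the rectified signal over `w_env` seconds (default 0.5 s,
window = `round(w_env · fs)` samples). Edges are truncated — the average is
taken over the samples actually available — rather than padded, so no
fabricated samples enter the estimate and the envelope has no phase lag.

**Suppression.** Maximal runs where the envelope stays below `theta_supp`
(default 5 μV) are kept when they last at least `d_supp_min` seconds
(default 0.5 s). The 5 μV / 0.5 s defaults follow the convention of
amplitude-based BS-probability algorithms in commercial depth-of-anesthesia
monitors; the stricter visual gold standard (0.5 μV for > 1 s) is available
by overriding both parameters. Intervals are half-open `[onset, onset+dur)`
in float seconds, so abutting intervals never overlap and duration sums are
unambiguous.

**Bursts.** Candidate bursts are exactly the gaps between consecutive
suppressions of a channel — activity outside the neighborhood of any
suppression is ordinary background. A candidate qualifies when it lasts
≥ `d_burst_min` (0.5 s) and contains ≥ `n_phases_min` (4) phases. A phase is
one half-wave: the count is interior baseline crossings + 1. The baseline is
the zero line (EEG acquisition is AC-coupled, so a burst waveform rests on
zero); a `baseline="mean"` option re-references segments with DC drift, with
the caveat that mean-subtracting an asymmetric waveform can manufacture edge
crossings. Samples exactly on the baseline are ignored for crossing purposes.

**Consensus.** BS is accepted only where every channel is suppressed: the
per-channel suppression masks are ANDed sample-wise, surviving runs
re-extracted and re-filtered by `d_supp_min`. Consensus is taken on
suppression masks, then epochs are delimited on the consensus — the
mask-level AND is the stricter and fully deterministic ordering of the two
operations, and guarantees the consensus set is contained in every channel's
own suppression set.

**Epochs.** Consecutive consensus suppressions with gaps ≤ `g_max` (default
30 s) chain into one BS epoch running from its first suppression's onset to
its last suppression's end. No numeric gap bound is canonical in the
clinical definitions; 30 s matches the flat-EEG horizon beyond which
thalamocortical reactivation is described as a distinct event, and it is a
parameter. Gaps are chained regardless of whether they pass the burst test;
delimitation by suppressions alone keeps the epoch rule independent of the
phase-counting rule.

**Summary.** `bs_duration` is cumulative consensus-suppressed time (the
primary quantity; `epoch_span`, which additionally includes intra-epoch
bursts, is reported alongside because an expert's "BS duration" could mean
either). `BSR = 100 · bs_duration / analyzed time`; `any_bs` is always
derived as `bs_duration > 0`, never stored.

**Known bias.** The envelope mixes samples across a suppression boundary, so
each detected boundary can shift by up to `w_env/2`, and the crossing point
depends on the amplitude contrast; total-duration error is bounded by
`w_env` per episode boundary. A true inter-suppression gap of `g` seconds is
detected as roughly `g + w_env`, so gaps just under `d_burst_min` can
qualify as bursts after smearing. No band-pass prefilter is applied by
default (an optional 0.5–47 Hz zero-phase Butterworth flag exists); no
artifact rejection is performed.

## Calibration and cross-validation

The objective is the mean squared error of total BS duration in seconds
(squared-BSR objective by flag — both error metrics are standard and the
optimizer accepts either). The search is exhaustive over the grid
θ ∈ {1,…,10} μV × `w_env` ∈ {0.25, 0.5, 1.0} s (other parameters fixed),
which brackets the 5 μV literature value; ties break toward smaller θ, then
smaller `w_env` (the least aggressive detector among equals). Envelopes are
cached per (recording, `w_env`), so the grid sweep costs one envelope pass
per window value plus cheap threshold scans.

Cross-validation uses scikit-learn's `StratifiedKFold` (shuffled, seeded)
with the anesthetic group as the stratum, so every test fold preserves the
corpus's group mix; `--per-group` runs two fully independent CVs instead.
When a group has fewer members than k the split falls back to a plain
shuffled k-fold with a warning. Held-out errors are per-recording absolute
errors — |detected − true| total duration, and the same difference as a
percentage of recording length for BSR. Medians and IQRs use
linear-interpolation (type-7) quartiles, the numpy default, stated so IQRs
are reproducible. No leakage: a fold's parameters are a deterministic
function of the other folds' error table only (asserted by refitting in the
tests).

## Synthetic EEG

The background is a minimal surrogate, not a physiological forward model:
broadband Gaussian noise plus agent-specific coherent oscillations —
propofol: 10 Hz alpha (RMS 0.55 × background) and 1.5 Hz slow-delta
(0.40 ×); sevoflurane: 6 Hz theta (0.60 ×) — with component variances
summing to `background_rms`² (default 15 μV RMS). This is sufficient to
give each agent a distinct spectral peak for per-group calibration tests;
it does not emulate spindles, arousal dynamics, artifacts, or the
concentration-dependence of real anesthesia EEG, so passing tests speak to
the detector's segmentation logic, not to robustness against clinical
artifact.

Episodes replace the background: `n_alternations + 1` suppression segments
(Gaussian noise at `suppression_rms`, default 1.5 μV) interleaved with
`n_alternations` bursts (10 Hz sine at `burst_amp`, default 40 μV — a 0.5 s
segment has 10 half-waves, comfortably polyphasic), identical timing across
channels. Truth tracks carry every suppression (channel "all"), every
burst, and each episode as a `bs_epoch` delimited by its first and last
suppression — by construction consistent with the detector's definitions.

Corpus intensity "low" draws each recording's total true suppression from a
zero-inflated log-normal: zero mass 45 % (propofol) / 65 % (sevoflurane),
non-zero draws log-normal with medians 45 s / 6 s (σ = 1.1 / 1.0), capped at
half the recording. The asymmetry (propofol longer, sevoflurane more zeros)
mirrors the observed skew of intraoperative BS in elderly two-agent cohorts,
whose duration distributions are approximately logarithmic; exact cohort
quantiles are not targets. The budget is split into 1–12 s segments grouped
into episodes of 1–3 alternations placed at random non-overlapping onsets.
Default recording length for calibration experiments is 600 s at 178 Hz —
long enough for multi-episode structure at a few seconds' compute per CV.

All randomness descends from one `SeedSequence` per generator call; there is
no global RNG state, and equal seeds give bit-identical output.

## Synthetic cohorts

Per patient: agent ~ Bernoulli(`p_sevo`, default 126/265); BS presence ~
Bernoulli(0.55 | propofol, 0.35 | sevoflurane — the complements of the
zero-BS fractions above); POD from the logistic model in the README with
conditional odds ratios (1.50, 1.63, interaction 3.80, hence
1.50·1.63·3.80 = 9.30 for sevoflurane with BS). `baseline_pod = 0.25` was
chosen so the mixture reproduces arm-level POD incidences near 30 % / 45 %
given those ORs. BS duration given presence is log-normal (longer under
propofol), clipped to half the surgery; covariates (age ~ N(77, 5²), ASA
categorical, surgery hours ~ N(2.7, 1²) clipped at 0.5) are independent of
POD unless `or_surgery_per_h` is set (e.g. 1.27/h) for regression-recovery
tests.

## Statistics

χ² is Pearson's without continuity correction (df = 1); the uncorrected
test reproduces the two-sided p ≈ 0.017 on the reference 2×2 counts, the
Yates-corrected one (available via flag) does not. The relative risk is
recomputed from the counts with a log-scale Wald CI. The two-proportion
power uses the documented normal-approximation closed form (pooled variance
under H0, unpooled under H1); at p₁ = p₂ it returns α by symmetry. Note
that G*Power's sub-procedures can give materially different numbers for the
same inputs; this implementation is the textbook formula and is validated
against its own closed form, not against any one software's output.

Logistic models are maximum-likelihood (`statsmodels.Logit`), 95 % Wald CIs,
ORs as exponentiated coefficients. Covariate sets: "full" (agent, age, ASA
as a numeric ordinal, surgery hours, care location) or "reduced" (agent +
BS term only). Missing covariates are dropped listwise with the count
reported. Perfect or quasi-separation (non-convergence, or a non-intercept
coefficient beyond ±15 on the logit scale) sets a `separation` flag rather
than returning silent estimates. The BS-only dose-response model uses
log(1 + duration) by default — the duration distribution is heavily
right-skewed with a point mass at the subset boundary — with raw seconds by
flag. In the interaction model the four conditional ORs are algebraic
functions of the fitted coefficients, so the identity
OR(sevo+BS) = OR(sevo)·OR(BS)·OR(interaction) holds to float precision by
construction, and all four cells must be non-empty before fitting.

`group_compare` wraps the two-sided Mann–Whitney U (asymptotic with tie
correction); a pooled-constant input returns p = 1 since the statistic
carries no information. `log_transform_for_plot` is log(1+x) — zeros map to
zero, order preserved — used for display of skewed durations only, never
inside models.

## Problem sizes used by the reproduction script

The acceptance script evaluates the detector on 60 recordings of 600 s
(30 per agent, "low" intensity) under 10-fold stratified CV with the
default grid — enough recordings for stable medians and balanced folds
while keeping the whole run under a minute — and recovers the interaction
structure in tests at n = 2×10⁵ patients, where sampling error in the cell
odds ratios is a few percent. Calibration-coverage tests use 100 seeded
replicates of n = 2000 cohorts and 1000 Mann–Whitney replicates at
n = 30 + 30.

## Limitations

* The detector has no artifact handling; on real intraoperative EEG,
  electrocautery and movement artifact would contaminate both the envelope
  and the consensus rule.
* The synthetic EEG's suppression/burst transitions are instantaneous;
  real transitions are gradual, so the boundary-smear bound measured here
  is optimistic.
* Cohort-dependent regression estimates from any particular clinical
  dataset are not reproducible from synthetic data; the package recovers
  generative parameters, which validates the estimator, not any specific
  cohort's numbers.
* The Mann–Whitney wrapper and the power formula are generic utilities;
  no claim is made that they match any proprietary software's variants.
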