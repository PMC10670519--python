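# Methods

This package implements, as a tested pipeline over synthetic data, the
analysis chain of an EEG study of cybersickness, immersion and emotion in
five virtual-reality scenes (zombie survival TWD, optical illusions PNI,
calm mountain viewing TL, ski racing PVR, roller coaster RC), each mapped
to a quadrant of the valence–arousal plane (HVHA/LVHA/LVLA/HVLA).  The
original recordings are not publicly released, so every stage is validated
by *parameter recovery*: structure planted by the generator must be
recovered by the downstream analysis, and a matched null control must not
produce spurious structure.

## Synthetic EEG model

Each of 32 channels (10–20 montage, differentially mounted against a CMS
reference) is a sum of

* five **band-limited Gaussian noise** processes (delta 1–4, theta 4–8,
  alpha 8–13, beta 13–30, gamma 30–45 Hz), synthesised spectrally
  (complex-Gaussian coefficients on the in-band FFT bins) with baseline RMS
  amplitudes 6/4/8/3/1.5 µV — the alpha-dominant profile of resting adult
  EEG;
* a **1/f pink background** (default RMS 5 µV);
* **blink artifacts**: a shared ocular source of 400-ms biphasic pulses
  (unit-peak template, amplitude 10× the background RMS, default 10
  events/min) projected onto the frontal channels with decaying weights
  (Fp1/Fp2 1.0, AF3/AF4 0.6, F7/F8 0.3);
* a per-channel DC offset (SD 2 µV), later removed by baseline correction.

A recording is a 10-s pre-experiment baseline followed by five 90-s trials
(one scene each, order randomised per subject) at a raw rate of 1024 Hz.
Scene/region class membership is planted as multiplicative band-power
offsets: trial power in band *b* is scaled by `1 + offset(scene, b) +
offset(region, b)`.  The stock contrast configuration steps the alpha
offset by +50% of baseline power per scene (0, 0.5, 1.0, 1.5, 2.0).

Inter-subject variability of band power is not characterised by any source
we reproduce, so it is an explicit knob chosen once: a log-normal global
gain per band (SD 0.05) plus independent per-channel log-normal gains
(SD 0.10).  These defaults deliberately understate the several-fold alpha
differences seen across real subjects, so that the planted class contrasts
remain the dominant source of between-trial variance; passing recovery
tests therefore demonstrates pipeline correctness, *not* that comparable
accuracy is attainable on real recordings.  The model has no cortical
sources, volume conduction or nonstationarity beyond the planted
modulation; features that depend only on second-order spectral structure
are exactly the ones the analysis uses, which is why this generator is
sufficient for validating it.

All randomness flows from `(seed, subject)` through NumPy's seed-sequence
mechanism; identical configuration reproduces recordings bit for bit.

## Questionnaires

**SSQ** — 16 symptom items rated 0–3.  Item *i* of subject *s* in scene *c*
is Binomial(3, p) with `p = severity(c) · g_s / 3`, where `g_s ~
Gamma(4, 1/4)` is a subject susceptibility factor (mean 1, CV 0.5).  The
per-scene mean severities (TWD 0.38, PNI 0.43, TL 0.12, PVR 0.40, RC 0.65)
are derived from the observed per-scene total-score ordering by dividing
raw score totals over the 21 item–subscale slots; the roller coaster is
most severe and the calm viewing scene least.

**SAM** — valence/arousal/dominance as rounded, clipped Gaussians (SD 1.5)
around per-scene centers on the 1–9 scale, consistent with each scene's
intended valence–arousal quadrant.

**VRI** — 42 seven-point Likert items in the hierarchical immersion
structure (engagement: interest 6, time investment 6, usability 6;
engrossment: emotional engagement 5, focus of attention 7; total
immersion: presence 8, flow 4).  Responses follow an orthogonal
common-factor model: primary loading 0.75 on the item's own factor plus a
general immersion factor loading 0.30, unit total variance, linearly
discretised onto 1–7.  The general factor keeps between-factor item
correlations positive, as in real immersion data, and lifts each level's
internal consistency above the α ≥ 0.7 "quite reliable" band.

## Preprocessing

Chain (fixed order): differential re-reference (provided for completeness;
generated data are already differentially mounted, mirroring the
acquisition hardware) → polyphase resampling to 128 Hz → zero-phase
Kaiser-windowed-sinc FIR low-pass at 45 Hz (≥ 60 dB single-pass stopband
design beyond 1.2× cutoff; `filtfilt` application doubles that; < 1 dB
passband ripple below 0.8× cutoff) → cutting one 90-s epoch per trial
marker → FastICA artifact rejection → baseline correction (per-channel
mean of the pre-experiment segment).

ICA runs on the concatenated epochs (the epoch-domain placement follows
the operation contract; the continuous segments between trials carry no
task signal here, so nothing is lost).  Components whose absolute Pearson
correlation with the mean frontal signal (Fp1/Fp2/AF3/AF4) exceeds 0.7 are
zeroed before back-projection.  The threshold is a design constant: the
original workflow used interactive component selection with no published
criterion, and 0.7 cleanly separates the planted ocular source from
neural components in this generator.

## Features

Per channel, the **time-domain** block has ten measures: power, mean,
population standard deviation σ, mean absolute first/second differences
(raw and σ-normalised), Hjorth activity (= population variance, exactly),
mobility and complexity — 10 × 32 = 320 columns.  Variance appears as the
activity column rather than twice.  Constant channels yield σ = 0; the
normalised differences and mobility/complexity are then reported as 0 with
a warning instead of NaN so feature tables stay complete.

The **frequency-domain** block (1416 columns) combines

* an FFT-derived set of 360: per-channel relative band power (5 × 32),
  per-channel band spectral entropy (5 × 32), and left–right band-power
  asymmetry over eight homologous pairs (5 × 8).  Only the total 360 is
  fixed by the reference configuration; this composition is a documented
  reconstruction from standard EEG feature families, and the extractor
  records it in its manifest;
* the raw Welch spectrum: 64-sample Hamming windows with hop 32 (50%
  overlap) give 33 bins × 32 channels = 1056 columns.  The 64/32 geometry
  is forced by the 1056 = 32 × 33 identity; a fixed eight-segment reading
  of the estimator would contradict that count and is not used.

Band powers are fractions of 1–45 Hz power with half-open band bins
(the top band keeps its upper edge), so the five fractions partition to 1.
For per-band classification runs the signal is zero-phase band-passed
(4th-order Butterworth) before extraction.

## Multi-instance classification

Each 90-s trial is a bag of 15-s sub-epoch instances (6 per trial; 15 s
tiles the window exactly, sits between the two conflicting epoch-length
readings of the source configuration, and gives each Welch estimate ~59
windows).  Default bag summary is **mean+max embedding** (one
meta-instance of doubled width per bag), which composes with all four
classifiers unchanged; **instance voting** (majority over per-instance
predictions, positive-witness rule for binary tasks) is the alternative.
Multi-class bag labels are the trial labels directly — all instances of a
trial share them — while the witness rule applies to derived binary tasks.

Classifiers (fixed study settings): Gaussian naive Bayes; RBF-SVM with
C = 1, γ = 0.01; 3-NN with brute-force search; random forest with 100
trees, unlimited depth, `int(log2 p) + 1` features per split, seed 1,
100% bootstrap.  Features are min–max scaled to [0, 1] inside each
training fold — the normalisation convention of the toolchain these
hyperparameters come from, without which a fixed RBF γ has no meaning.
The SVM's ROC areas come from decision-value ranking; its probability
errors use a softmax over the one-vs-rest margins.  Error metrics (MAE,
RMSE, RAE %, RRSE %) are computed on class-probability vectors against
one-hot truth, normalised by the class-prior predictor.

**Cross-validation.**  `cross_validate` defaults to plain stratified
10-fold over bags, with LOOCV as the second scheme.  The end-to-end
recovery experiment uses *subject-grouped* stratified 10-fold CV.  The
reason is a genuine pitfall of this design: every subject contributes
exactly one bag per class, so under a null (no class signal) a classifier
that keys on subject identity finds same-subject training bags that all
carry the *other* labels, and bag-level CV pushes accuracy far **below**
chance — an anti-learning artifact, not conservatism.  Grouping folds by
subject removes the artifact (null accuracy returns to the chance band)
and is also the leakage-safe choice for the planted-effect runs.

## Cybersickness statistics

SSQ scoring uses the standard overlapping item→subscale map with
conversion weights N × 9.54, O × 7.58, D × 13.92 and total score
TS = 3.74 × (rawN + rawO + rawD).  (The published per-scene medians are
integer multiples of these constants, which confirms the convention.)

Scene effects per scale: Friedman omnibus on the subjects × scenes matrix
(within-subject mid-ranks, tie-corrected statistic, chi-square reference
with k − 1 df), then Conover pairwise post-hoc comparisons on the Friedman
ranks — the rank-ANOVA LSD statistic
`t = (R_i − R_j) / sqrt(2 (n·A − B) / ((n−1)(k−1)))` with A the sum of
squared ranks and B the sum of squared column rank sums, referred to the t
distribution with (n−1)(k−1) df, two-sided.  p-values are reported
unadjusted by default (matching the reference report, whose matrix shows
no multiplicity correction), with Holm adjustment behind a flag.
Degenerate inputs: identical scores in every row give a zero statistic;
zero residual rank variance sets all off-diagonal post-hoc p to 1 with a
warning.

## Immersion reliability and EFA

Cronbach's α follows the k/(k−1) · (1 − Σσᵢ²/σₜ²) form with sample (n−1)
variances.  KMO uses anti-image partial correlations from the inverted
correlation matrix; Bartlett's sphericity is
χ² = −(n − 1 − (2p+5)/6) ln|R| with df = p(p−1)/2.  EFA extracts principal
components of the item correlation matrix (the configuration consistent
with reporting percent of *total* variance), retains eigenvalues > 1
(Kaiser) unless overridden, varimax-rotates, and reports items with
|loading| ≥ 0.5 per factor.  The item→level map is an input; no item
counts are hard-coded, because the published description of the
engagement level is internally inconsistent (12 items / 5 factors in the
text vs 18 items / 3 factors in the instrument table).

## ERP latency topography

Per condition, epochs are averaged per channel, low-pass filtered with the
same zero-phase sinc at 45 Hz, and each channel's latency of the maximum
*absolute* deflection in the 0–90 s window is taken (ties to the earliest
sample; flat channels flagged with latency 0).  "Maximum voltage" is read
as maximum absolute deviation since only the latency, not the polarity, is
analysed; the signed peak is retained for QC.  Latencies are interpolated
over the unit scalp disk (nominal azimuthal-equidistant 10–20 coordinates)
by cubic inverse-distance weighting; squared-distance weighting was
rejected because remote electrodes wash out local latency structure.  Raw
latency (not its rank) is interpolated.

## Problem sizes and numerical choices

The recovery experiments use the full study geometry — 32 subjects × 5
scenes = 160 trials (960 instances) — for both the planted-contrast cohort
and the zero-effect null; questionnaire statistics use n = 32 subjects
with 20 seeded replicates; EFA simulations use up to 1000 respondents.
Welch uses Hamming windows; FFT features use the unwindowed periodogram of
the full (sub-)epoch.  Spectral entropy is in bits (log₂) and defined on
the normalised PSD restricted to the relevant bins; an all-zero PSD is an
error, a single-bin PSD has entropy 0.  FastICA runs with tol 1e-4 and at
most 500 iterations; non-convergence warnings are suppressed because the
frontal-correlation criterion operates on whatever rotation was reached
and the unattainable-threshold identity is preserved regardless.

## Known limitations

* The generator's stationary Gaussian bands cannot probe artifacts of
  nonstationarity, line noise, electrode pops, or genuine neural dynamics;
  results transfer to real data only as far as second-order spectral
  structure drives the analyses.
* The 360-column FFT feature composition is a reconstruction; any other
  composition with the same total would also be consistent with the
  reference counts.
* Accuracies obtained here quantify recoverability of planted structure,
  not expected performance on human EEG, where inter-subject variability
  alone is larger than the planted contrasts.
* The Conover matrix reproduces the unadjusted, symmetric textbook form;
  asymmetries present in the reference report (e.g. mirror cells differing
  in the third decimal) cannot be modelled from the available description.
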