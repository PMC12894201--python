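# Methods

This note documents the models, defaults, numerical choices, and known
limitations of `sdbscreen`: what each stage assumes, what the synthetic data
generator does and does not emulate, and which design decisions were
genuinely open.

## Signal model and preprocessing

**R-peak detection.** The detector is a band-limited energy detector: the
ECG is band-passed to 5–25 Hz (3rd-order Butterworth, zero-phase), squared,
and smoothed over 150 ms; candidate beats are envelope maxima above an
adaptive threshold (30% of the rolling per-10 s 95th percentile, floored at
1% of the global 99th percentile so quiet noise cannot fire) separated by a
0.25 s refractory period, with each peak refined to the local extremum of
the band-passed signal within ±50 ms. Two artifact flags mark a detection
*suspect*: band-passed amplitude above 3× the running median beat amplitude
(±10 beats), or envelope occupancy above 50% of a 0.6 s neighborhood
(a QRS complex is ~0.1 s; sustained supra-threshold energy is motion
artifact). Flat or all-artifact input yields an empty beat series with a
logged warning rather than an exception. Externally detected beats (or a
two-column `beat_time_s rr_s` file) are accepted everywhere a trace is,
because the scientific content of the pipeline is downstream of peak times.

**R-R cleaning.** Intervals are anchored at the later beat of each pair.
An interval is excluded when outside 0.3–2.0 s (30–200 bpm) or when it jumps
more than 50% relative to the last *kept* interval (comparing against the
last kept value makes the rule idempotent and lets sinus rhythm resume after
an ectopic couplet). Excluded intervals leave temporal gaps; nothing is
interpolated, since interpolation fabricates autocorrelation and the
Lomb-Scargle estimator is defined for uneven sampling — the reason it is
used at all.

**Spectrogram.** Windows of 180 s advance by 5 s (175 s overlap), anchored
at the recording start; the last window must lie fully inside the record.
The frequency grid is uniform at the native resolution 1/180 Hz
(≈ 0.006 Hz as conventionally rounded) from one step up to 0.35 Hz; an
oversampling factor is exposed but defaults to 1 because band *averages* are
insensitive to modest oversampling. Each window's kept intervals are
mean-centered (no further detrending) and transformed with the classical
Lomb-Scargle periodogram; on uniformly sampled input this equals the FFT
periodogram `|X_k|²/N` at the Fourier frequencies, which the tests verify to
1e-6 relative error. A window is valid only with ≥ 60 kept intervals
(mean RR ≤ 3 s — a Nyquist-like floor for sparse uneven sampling) and
nonzero variance; invalid windows are flagged, never zero-filled. Valid
spectra are normalized to sum to 1 over the grid so band features are
relative-power fractions, comparable across subjects with very different
total HRV power.

## Features and labels

The 13 bands are half-open `[lo, hi)` intervals: 0.02 Hz wide from 0 to
0.20 Hz, then 0.05 Hz wide to 0.35 Hz. Band features are arithmetic means of
the normalized magnitudes of the grid bins inside each band; a grid too
coarse to give every band at least one bin is a configuration error raised
at construction, not a silently empty feature. SpO₂ features (range, mean,
sample SD with n−1 denominator) use only valid samples — readings outside
50–100% are oximeter dropout and treated as missing, never clamped — and
need at least two valid samples per window.

A window is labeled SDB-positive when the **union** of respiratory-event
intervals (hypopneas and obstructive apneas by default; the vocabulary is
configurable because scoring-software strings vary) covers at least 36 s =
20% of the window. The union, not the sum, so overlapping scored events are
not double-counted; the rule is monotone — adding an event can never flip a
positive window to negative.

Training data follow the two-cohort design: positives are all SDB-labeled
valid windows of severe-OSA subjects; negatives are a seeded uniform sample
(without replacement) of valid windows from no-OSA subjects, sized to
balance the positives. Windows with invalid spectra or SpO₂ are dropped from
training and excluded from both numerator and denominator of the stage-2
ratio. SpO₂ features are included by default, with an ECG-only 13-feature
variant behind a flag, because the historical record of this design leaves
ambiguous whether the oximetry features made the final model — both variants
are first-class here.

## Classifier

Stage 1 is a soft-margin RBF-kernel SVM (box constraint 1.0 — regularization
was an open choice; 1.0 is the common default) with per-feature
standardization fitted on the training set and stored inside the model. The
kernel bandwidth default is the data-driven `1/(d·var)` heuristic on
standardized inputs; the contract is cross-validation-metric equivalence on
synthetic data, not bit-level equality with any particular implementation's
"auto scale". Cross-validation is seeded stratified 10-fold with the fold
assignment deterministic given the seed; the pooled out-of-fold confusion
matrix is reported. Window-level folds are the default (mirroring the
original design), but **subject-grouped** folds are provided and matter: at
175 s overlap adjacent windows share ~97% of their data, so window-level
folds place near-duplicates of every test window in training and inflate
accuracy — the suite demonstrates the direction (grouped ≤ ungrouped) and
uses grouped folds wherever a leak-free measurement is the point.

Stage 2 is a linear SVM on the single ratio feature (the stage-1-positive
fraction of a subject's valid windows). On one feature the fitted decision
is exactly a threshold `-b/w`, which the model exposes, since a threshold is
the honest interpretable form of a one-feature SVM. Subjects with zero valid
windows are *unclassifiable* — explicitly distinct from negative, and never
silently reported as 0. Ground-truth dichotomization is AHI > 20 positive,
AHI < 20 negative; exact equality (undefined in the clinical rule) is
assigned positive with a logged note.

## Evaluation

Sensitivity, specificity, PPV, NPV, and accuracy carry 95% Wilson score
intervals; zero-denominator metrics are reported as undefined with a reason.
F1 carries no interval (Wilson does not apply to a harmonic mean). An exact
Clopper-Pearson interval is computed alongside Wilson and both are printed
in every report: at n ≈ 92 the exact interval is visibly wider, and the
reconstructed validation matrix shows the published interval endpoints
matching the exact form — the package reports both rather than adjudicate.
Percentages are printed to one decimal.

`reconstruct_confusion` enumerates all nonnegative-integer 2×2 matrices of a
given total whose four proportions round to a printed metric set; at n = 92
with the published validation percentages the solution is unique,
(TP, FP, FN, TN) = (34, 12, 13, 33), from which accuracy and F1 follow.

## Synthetic data generator

The generator emulates exactly the structure the classifier exploits:

* **Events.** The event count realizes the target AHI (rounded to the
  recording's whole-hour equivalent). At AHI ≥ 10, events form trains
  ("bouts") of 4–8 events at a 50 s period — an event-cycle frequency of
  0.02 Hz, inside the two lowest analysis bands, matching the known
  cyclical-variation physiology. Below AHI 10 events are isolated singles:
  a subclinical event rate cannot sustain trains, and a lone hypopnea
  produces one transient heart-rate response, not a sustained oscillation
  epoch. Durations are normal (mean 25 s, SD 6) clipped to 10–47 s.
* **Beats.** Instantaneous RR = 1.0 s + 0.03 s RSA at 0.25 Hz + 0.02 s
  low-frequency term at 0.10 Hz + 0.08 s event-locked oscillation at the
  bout frequency (active only inside bouts), plus 20 ms of broadband
  beat-to-beat jitter — real R-R series carry substantial fractal background
  power, and without it every window of a subject is a near-identical
  feature point, which lets a classifier memorize subject clusters instead
  of physiology. Beat times come from integrate-and-fire over the
  instantaneous rate, floored at 0.35 s.
* **SpO₂.** 96% baseline; each event contributes a ramp to −4% starting
  10 s after onset (circulation delay) with 15 s-constant exponential
  resaturation; the sum is clipped to 50–100% and quantized to integer
  percent at 1 Hz (oximeter realism).
* **ECG (optional).** A Gaussian QRS template (σ = 20 ms) per beat at
  256 Hz plus white noise; `noise_sd=0.1` of the QRS amplitude corresponds
  to 20 dB peak SNR.
* **Ectopy (optional).** Each beat is, with the configured probability,
  replaced by a premature beat at 0.40–0.75 of the preceding interval; the
  following sinus beat stands, producing the compensatory pause. Cleaning
  removes many but not all of the resulting interval pairs, and 10% ectopy
  measurably degrades window-classification accuracy, mirroring the known
  arrhythmia limitation of HRV-based screening.

Cohorts draw severe subjects' AHI uniformly from 30–60 and normal subjects'
from 0–5, with per-subject seeds derived deterministically from the cohort
seed.

What the generator does **not** emulate — and therefore what passing tests
do *not* establish about clinical data: sleep staging and stage-dependent
autonomic tone, central/mixed apnea physiology, arousal transients,
inter-individual variability in the autonomic response (amplitude and
frequency are fixed across subjects), oximeter motion artifact, realistic
ECG morphology beyond a QRS template, and the mild-OSA middle ground around
the AHI 20 cutoff. Synthetic cohorts are nearly separable by construction;
the ~100% held-out accuracy on them is a correctness check of the pipeline's
plumbing and feature physics, not a clinical performance claim — clinical
validation reported far lower subject-level accuracy, and nothing here
contradicts that.

## Study-analog problem sizes

The packaged study analogs (used by the test suite and the acceptance
script) run at desk scale, chosen as the package's own reproducibility
conditions: training cohort 14 severe + 15 normal subjects, held-out cohort
30 + 30, one hour per subject (≈ 685 windows each); the negative control —
event-locked oscillation and desaturations disabled — uses 10 + 10 subjects
with a balanced panel of equal window counts per subject (3,000 windows
total) and subject-grouped folds. The balanced panel makes any constant
predictor pool to exactly 50%, and grouped folds remove overlap leakage, so
the control measures discrimination and nothing else; with both in place the
null sits within a few points of 50% across seeds.

## Degenerate inputs and tie-breaks

Flatline ECG → empty beat series (warning, not an exception); fewer than two
beats → empty R-R series; records shorter than one window → empty
spectrogram with a warning; all-zero spectra → invalid window; identical
stage-2 ratios across classes → degenerate chance-level model with a
warning; missing AHI → subject excluded from evaluation; band-boundary
frequencies belong to the upper band (half-open intervals); an AHI exactly
at the cutoff is positive (logged). Model archives are versioned and refuse
to load across incompatible schema versions.

## Known limitations

The R-peak detector satisfies the pipeline's contract on template-based
synthetic ECG; it is not a clinically validated detector, and no arrhythmia
*classification* is attempted. The EDF codec covers 16-bit EDF/EDF+ signal
records with per-channel rates — sufficient for polysomnography fixtures —
not the full annotations-channel dialect. Window-level cross-validation
figures inherit overlap leakage by construction; subject-grouped figures are
the defensible ones for generalization claims.
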