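# sdbscreen

Screening for sleep-disordered breathing (SDB) from just two routinely
monitored signals — a single ECG channel and pulse-oximeter SpO₂ — aimed at
settings like hospital wards and ICUs where full polysomnography is
impractical but these channels are already on the monitor.

Repetitive obstructive apneas/hypopneas drive a bradycardia–tachycardia cycle
(the *cyclical variation of heart rate*) that concentrates R-R interval
spectral power near the event-cycle frequency (~0.01–0.04 Hz), while normal
sleep shows respiratory sinus arrhythmia at ~0.2–0.35 Hz; events are also
followed, after a circulation delay, by SpO₂ desaturations. `sdbscreen`
turns those physiological signatures into a two-stage classifier:

1. **Signal processing.** R-wave peaks are detected with a band-limited
   QRS-energy detector (5–25 Hz emphasis, adaptive threshold, 0.25 s
   refractory period, artifact flagging); the R-R series is cleaned
   (intervals outside 0.3–2.0 s or jumping > 50% against the last kept
   interval are excluded, leaving gaps). Because the series is unevenly
   sampled, per-window spectra use the classical **Lomb-Scargle
   periodogram** — no resampling — over sliding **180 s windows with 175 s
   overlap** (native resolution 1/180 ≈ 0.006 Hz), each spectrum normalized
   to unit total.
2. **Stage 1 — window SVM.** Each window yields 16 features: the mean
   normalized magnitude in 13 contiguous bands covering 0–0.35 Hz, plus the
   SpO₂ range, mean, and standard deviation. A window is labeled SDB when
   the union of scored respiratory events covers ≥ 36 s (20% of the window).
   An RBF-kernel SVM with standardized inputs is trained on SDB windows from
   severe-OSA subjects vs randomly sampled windows from no-OSA subjects and
   scored by seeded stratified 10-fold cross-validation.
3. **Stage 2 — subject SVM.** The fraction of a subject's valid windows that
   stage 1 flags (analogous to % time in apnea/hypopnea) feeds a 1-D SVM
   whose decision reduces to an interpretable ratio threshold; subjects are
   dichotomized against the AHI > 20 clinical rule.

Because clinical polysomnography cohorts are access-controlled, the package
includes a first-class **synthetic polysomnogram generator** (event bouts,
integrate-and-fire beat times, delayed desaturations, optional ECG waveform
rendering and ectopic beats) with exact ground truth, so every stage — and
the end-to-end pipeline — is testable and reproducible from nothing.

## Worked example

```python
import sdbscreen as sdb

train = sdb.run_training_analog(seed=3, n_sdb=6, n_normal=6)
record, truth = sdb.simulate_subject(
    sdb.SubjectParams(duration=3600.0, target_ahi=45.0, seed=101),
    subject_id="screen-ahi45",
)
pred = sdb.classify_subject(record, train.window_model, train.subject_model)
```

prints (via `python examples/03_train_and_classify.py`):

```
stage-1 CV       : sensitivity 99.1%  specificity 99.3%  (5542 windows)
stage-2 fit      : accuracy 100% at ratio threshold 0.412
screen-ahi45     : ratio 0.801 -> predicted 1 (truth 1)
screen-ahi2      : ratio 0.000 -> predicted 0 (truth 0)
```

The stage-1 numbers are the pooled out-of-fold confusion of the window
classifier; `ratio 0.801` says stage 1 flagged 80% of the severe subject's
windows, far above the fitted 0.412 threshold, so the subject screens
positive. The `examples/` directory has one short script per capability
(simulation, spectrogram/band features, training + screening, metric
reconstruction with confidence intervals).

A thin CLI mirrors the library for shell use:

```sh
sdbscreen simulate --n-sdb 2 --n-normal 2 --duration 900 --seed 5 cohort/
sdbscreen extract cohort/ windows.tsv
sdbscreen train windows.tsv cohort/ models/
sdbscreen classify models/models.joblib cohort/ reports/
```

## Evaluation conventions

Reports carry sensitivity, specificity, PPV, NPV, accuracy (each with a 95%
Wilson score interval *and* an exact Clopper-Pearson interval — their widths
differ visibly at screening-study sample sizes) and F1 (no interval), with
percentages to one decimal.

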