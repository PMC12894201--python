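"""Train the two-stage classifier on a small synthetic cohort and screen two
fresh subjects.

Stage 1 (window SVM, RBF kernel) is scored by 10-fold cross-validation; its
per-subject positive-window ratio feeds stage 2, a threshold on the fraction
of the night spent in SDB-like windows.
"""

import sdbscreen as sdb

train = sdb.run_training_analog(seed=3, n_sdb=6, n_normal=6)
print(f"stage-1 CV       : sensitivity {100 * train.cv_sensitivity:.1f}%  "
      f"specificity {100 * train.cv_specificity:.1f}%  "
      f"({train.n_windows} windows)")
print(f"stage-2 fit      : accuracy {100 * train.svm2_training_accuracy:.0f}% "
      f"at ratio threshold {train.svm2_threshold:.3f}")

for ahi, seed in ((45.0, 101), (2.0, 102)):
    record, truth = sdb.simulate_subject(
        sdb.SubjectParams(duration=3600.0, target_ahi=ahi, seed=seed),
        subject_id=f"screen-ahi{ahi:.0f}",
    )
    sp = sdb.classify_subject(record, train.window_model, train.subject_model)
    print(f"{record.subject_id:<16} : ratio {sp.ratio:.3f} -> predicted "
          f"{sp.label_pred} (truth {truth.subject_label})")

# The ratio is the fraction of the subject's valid 180 s windows that stage 1
# flags as containing respiratory events — analogous to percent time in
# apnea/hypopnea; the stage-2 threshold separates severe-SDB nights from
# normal ones.
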