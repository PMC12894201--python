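"""Reproducible study analogs on synthetic cohorts.

These routines run the full pipeline over seeded synthetic cohorts at desk
scale and return the same summary numbers a clinical study would report:
window-level cross-validated sensitivity/specificity for stage 1, stage-2
training accuracy, held-out subject-level accuracy, and a negative control
with the injected physiology disabled.

Cohort sizes mirror the screening-study design: 14 SDB + 15 no-SDB training
subjects and a held-out validation cohort dichotomized at AHI 20.  One hour
per subject keeps a full run in minutes on one CPU while leaving ~680 analysis
windows per subject.

The negative control uses subject-grouped CV folds: with 175 s of window
overlap, window-level folds place near-duplicates of every test window in the
training set, which inflates null accuracy by memorization alone and would
mask the point of the control (that the classifier learns the injected
physiology, nothing else).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import (
    SubjectModel,
    WindowModelConfig,
    crossvalidate,
    subject_ratio,
    train_subject_model,
    train_window_model,
)
from .config import PipelineConfig
from .evalmetrics import ConfusionMatrix, confusion, metrics
from .features import FEATURE_COLUMNS, assemble_window_dataset
from .pipeline import classify_subject, extract_windows, predict_windows
from .synth import SubjectParams, simulate_cohort

logger = logging.getLogger(__name__)

TRAIN_N_SDB = 14
TRAIN_N_NORMAL = 15
VALIDATION_N_SDB = 30
VALIDATION_N_NORMAL = 30
CONTROL_N_PER_GROUP = 10
SUBJECT_HOURS = 1.0
CONTROL_MAX_WINDOWS = 3000


def _cohort_tables(cohort, config: PipelineConfig):
    tables, labels = [], {}
    for record, truth in cohort:
        tables.append(extract_windows(record, config))
        labels[record.subject_id] = truth.subject_label
    return tables, labels


@dataclass
class TrainingAnalog:
    """Everything the training stage produces on a synthetic cohort."""

    cv_pooled: ConfusionMatrix
    cv_sensitivity: float
    cv_specificity: float
    svm2_training_accuracy: float
    svm2_threshold: float
    window_model: object
    subject_model: SubjectModel
    n_windows: int
    n_subjects: int


def run_training_analog(
    seed: int,
    n_sdb: int = TRAIN_N_SDB,
    n_normal: int = TRAIN_N_NORMAL,
    duration_s: float = SUBJECT_HOURS * 3600.0,
    config: PipelineConfig | None = None,
) -> TrainingAnalog:
    """Train both stages on a seeded synthetic cohort.

    Stage 1 is scored by stratified window-level 10-fold CV (pooled
    out-of-fold confusion matrix); stage 2 by its training fit, as in the
    original two-stage design.
    """
    config = (config or PipelineConfig()).with_overrides(seed=seed)
    cohort = simulate_cohort(n_sdb, n_normal, seed=seed, duration=duration_s)
    tables, labels = _cohort_tables(cohort, config)
    frame, y, groups = assemble_window_dataset(tables, labels, seed=seed)
    X = frame[FEATURE_COLUMNS].to_numpy(dtype=float)
    mcfg = WindowModelConfig(box_constraint=config.svm_box_constraint, seed=seed)
    cv = crossvalidate(X, y, subject_ids=groups, k=config.cv_folds,
                       grouping=config.cv_grouping, config=mcfg)
    cvm = cv.pooled_metrics()

    window_model = train_window_model(X, y, mcfg)
    ratios, subj_labels = [], []
    for (record, truth), table in zip(cohort, tables):
        pred = predict_windows(table, window_model, config)
        valid = table["valid"].to_numpy(dtype=bool)
        sp = subject_ratio(record.subject_id, np.where(valid, pred, 0), valid)
        if sp.unclassifiable:
            logger.warning("%s unclassifiable in training analog", record.subject_id)
            continue
        ratios.append(sp.ratio)
        subj_labels.append(truth.subject_label)
    subject_model = train_subject_model(ratios, subj_labels, config.svm_box_constraint)
    fit_acc = float(np.mean(subject_model.predict(ratios) == np.asarray(subj_labels)))
    return TrainingAnalog(
        cv_pooled=cv.pooled,
        cv_sensitivity=cvm["sensitivity"].estimate,
        cv_specificity=cvm["specificity"].estimate,
        svm2_training_accuracy=fit_acc,
        svm2_threshold=subject_model.threshold,
        window_model=window_model,
        subject_model=subject_model,
        n_windows=int(len(y)),
        n_subjects=len(subj_labels),
    )


@dataclass
class ValidationAnalog:
    """Held-out subject-level evaluation on a fresh synthetic cohort."""

    cm: ConfusionMatrix
    accuracy: float
    n_subjects: int
    n_unclassifiable: int


def run_validation_analog(
    window_model,
    subject_model: SubjectModel,
    seed: int,
    n_sdb: int = VALIDATION_N_SDB,
    n_normal: int = VALIDATION_N_NORMAL,
    duration_s: float = SUBJECT_HOURS * 3600.0,
    config: PipelineConfig | None = None,
) -> ValidationAnalog:
    """Classify a held-out seeded cohort end-to-end and score it against the
    by-construction AHI labels."""
    config = config or PipelineConfig()
    cohort = simulate_cohort(n_sdb, n_normal, seed=seed, duration=duration_s)
    y_true, y_pred, skipped = [], [], 0
    for record, truth in cohort:
        sp = classify_subject(record, window_model, subject_model, config)
        if sp.unclassifiable:
            skipped += 1
            continue
        y_true.append(truth.subject_label)
        y_pred.append(sp.label_pred)
    cm = confusion(y_true, y_pred)
    return ValidationAnalog(
        cm=cm,
        accuracy=metrics(cm)["accuracy"].estimate,
        n_subjects=len(y_true),
        n_unclassifiable=skipped,
    )


@dataclass
class NegativeControl:
    """Null-physiology control: CV accuracy should be chance."""

    cv_accuracy: float
    n_windows: int
    n_subjects: int


def run_negative_control(
    seed: int,
    n_per_group: int = CONTROL_N_PER_GROUP,
    duration_s: float = SUBJECT_HOURS * 3600.0,
    max_windows: int = CONTROL_MAX_WINDOWS,
    config: PipelineConfig | None = None,
) -> NegativeControl:
    """Disable the event-locked R-R oscillation and the desaturations, rerun
    the stage-1 CV, and report its accuracy.

    Events are still scored (so window labels exist) but leave no trace in
    either signal; a classifier that learns only the injected physiology must
    fall to chance.  Folds are grouped by subject — see the module docstring.
    """
    config = (config or PipelineConfig()).with_overrides(seed=seed)
    base = SubjectParams(event_rr_amp=0.0, desat_depth=0.0)
    cohort = simulate_cohort(
        n_per_group, n_per_group, seed=seed, duration=duration_s, base_params=base
    )
    tables, labels = _cohort_tables(cohort, config)
    # Balanced panel: the same number of windows from every subject (positives
    # from SDB subjects, negatives from normal subjects).  With equal per-fold
    # class counts any constant predictor pools to exactly 50%, so the control
    # measures discrimination, not fold-imbalance artifacts.
    rng = np.random.default_rng(seed)
    per_subject = max_windows // (2 * n_per_group)
    pools = []
    for table in tables:
        sid = table["subject_id"].iloc[0]
        rows = table[table["valid"]]
        if labels[sid] == 1:
            rows = rows[rows["label"] == 1]
        pools.append(rows)
    per_subject = min(per_subject, min(len(p) for p in pools))
    parts, ys = [], []
    for table, pool in zip(tables, pools):
        sid = table["subject_id"].iloc[0]
        take = pool.iloc[rng.choice(len(pool), size=per_subject, replace=False)]
        parts.append(take)
        ys.append(np.full(per_subject, labels[sid], dtype=int))
    panel = pd.concat(parts, ignore_index=True)
    X = panel[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = np.concatenate(ys)
    groups = panel["subject_id"].to_numpy()
    cv = crossvalidate(
        X, y, subject_ids=groups, k=config.cv_folds, grouping="subject",
        config=WindowModelConfig(seed=seed),
    )
    return NegativeControl(
        cv_accuracy=cv.pooled_metrics()["accuracy"].estimate,
        n_windows=int(len(y)),
        n_subjects=2 * n_per_group,
    )
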