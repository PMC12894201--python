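"""The two-stage SVM classifier.

Stage 1 (window level): an RBF-kernel soft-margin SVM on the 16 window
features, with per-feature standardization fitted on the training data and a
data-driven kernel bandwidth (``gamma='scale'``, i.e. 1 / (d * var) of the
standardized inputs).  Validated by seeded stratified 10-fold
cross-validation, either at the window level or grouped by subject (windows
overlap by 175/180, so window-level folds share nearly identical data across
train/test — both modes are provided).

Stage 2 (subject level): the fraction of a subject's valid windows that
stage 1 calls SDB-positive — analogous to percent time in apnea/hypopnea — is
the single input to a linear SVM whose decision on one feature reduces to a
threshold on the ratio; the fitted threshold is exposed for interpretability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .evalmetrics import ConfusionMatrix, confusion, metrics

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class WindowModelConfig:
    """Stage-1 SVM settings: RBF kernel, standardization, auto bandwidth."""

    kernel: str = "rbf"
    standardize: bool = True
    kernel_scale: str | float = "auto"  # 'auto' -> data-driven bandwidth
    box_constraint: float = 1.0
    seed: int = 0
    experimental_kernels: bool = False

    def __post_init__(self) -> None:
        if self.kernel != "rbf" and not self.experimental_kernels:
            raise ValueError(
                "kernel is fixed to 'rbf'; set experimental_kernels=True to override"
            )
        if self.box_constraint <= 0:
            raise ValueError("box_constraint must be > 0")


@dataclass
class SubjectPrediction:
    """Stage-2 output for one subject."""

    subject_id: str
    n_windows_total: int
    n_windows_sdb: int
    ratio: float | None
    label_pred: int | None = None
    unclassifiable: bool = False

    def __post_init__(self) -> None:
        if not self.unclassifiable:
            if not 0 <= self.n_windows_sdb <= self.n_windows_total:
                raise ValueError("window counts inconsistent")
            expect = self.n_windows_sdb / self.n_windows_total
            if self.ratio is None or abs(self.ratio - expect) > 1e-9:
                raise ValueError("ratio inconsistent with counts")


def _make_pipeline(config: WindowModelConfig) -> Pipeline:
    gamma = "scale" if config.kernel_scale == "auto" else config.kernel_scale
    steps = []
    if config.standardize:
        steps.append(("standardize", StandardScaler()))
    steps.append((
        "svm",
        SVC(
            kernel=config.kernel,
            C=config.box_constraint,
            gamma=gamma,
            random_state=config.seed,
            cache_size=500,
        ),
    ))
    return Pipeline(steps)


def _check_features(X: np.ndarray, y: np.ndarray) -> None:
    X = np.asarray(X, dtype=float)
    bad = np.flatnonzero(~np.isfinite(X).all(axis=1))
    if bad.size:
        raise ValueError(f"non-finite features in rows {bad[:20].tolist()}"
                         + (" ..." if bad.size > 20 else ""))
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")


def train_window_model(
    X: np.ndarray, y: np.ndarray, config: WindowModelConfig | None = None
) -> Pipeline:
    """Fit the stage-1 window classifier; standardization parameters are part
    of the returned model and applied automatically at inference."""
    config = config or WindowModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_features(X, y)
    model = _make_pipeline(config)
    model.fit(X, y)
    return model


@dataclass
class CVResult:
    """Pooled out-of-fold predictions from seeded stratified k-fold CV."""

    pooled: ConfusionMatrix
    fold_matrices: list[ConfusionMatrix]
    grouping: str
    k: int
    oof_pred: np.ndarray

    def pooled_metrics(self) -> dict:
        return metrics(self.pooled)


def crossvalidate(
    X: np.ndarray,
    y: np.ndarray,
    subject_ids: Sequence[str] | None = None,
    k: int = 10,
    grouping: str = "window",
    config: WindowModelConfig | None = None,
) -> CVResult:
    """Seeded stratified k-fold cross-validation of the stage-1 classifier.

    ``grouping='window'`` stratifies on the window labels directly;
    ``grouping='subject'`` keeps all of a subject's windows in one fold
    (StratifiedGroupKFold), which prevents the leakage caused by 175 s window
    overlap.  Returns the pooled out-of-fold confusion matrix plus per-fold
    matrices; fold assignment is deterministic given the config seed.
    """
    config = config or WindowModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_features(X, y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if min(np.bincount(y)) < k:
        raise ValueError(f"k={k} exceeds the smaller class count {min(np.bincount(y))}")
    if grouping == "window":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
        splits = splitter.split(X, y)
    elif grouping == "subject":
        if subject_ids is None:
            raise ValueError("subject grouping requires subject_ids")
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=config.seed)
        splits = splitter.split(X, y, groups=np.asarray(subject_ids))
    else:
        raise ValueError("grouping must be 'window' or 'subject'")

    oof = np.full(len(y), -1, dtype=int)
    fold_cms = []
    for train_idx, test_idx in splits:
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("a CV fold lost one class; reduce k")
        model = _make_pipeline(config)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        oof[test_idx] = pred
        fold_cms.append(confusion(y[test_idx], pred))
    seen = oof >= 0
    pooled = confusion(y[seen], oof[seen])
    return CVResult(pooled=pooled, fold_matrices=fold_cms, grouping=grouping, k=k, oof_pred=oof)


def subject_ratio(
    subject_id: str, window_predictions: Sequence[int], window_valid: Sequence[bool] | None = None
) -> SubjectPrediction:
    """Positive-window ratio over *valid* windows for one subject.

    Zero valid windows yields an unclassifiable prediction — explicitly
    distinct from a negative call.
    """
    pred = np.asarray(window_predictions, dtype=int)
    valid = np.ones(len(pred), dtype=bool) if window_valid is None else np.asarray(window_valid, dtype=bool)
    pred = pred[valid]
    if pred.size == 0:
        logger.warning("%s: no valid windows; subject unclassifiable", subject_id)
        return SubjectPrediction(subject_id, 0, 0, None, None, unclassifiable=True)
    n_sdb = int(pred.sum())
    return SubjectPrediction(subject_id, int(pred.size), n_sdb, n_sdb / pred.size)


@dataclass
class SubjectModel:
    """Stage-2 model: a linear SVM on the 1-D ratio, exposed as a threshold.

    ``threshold`` is the ratio at which the decision flips; predictions are
    1 iff ratio > threshold (monotone by construction).
    """

    threshold: float
    degenerate: bool = False

    def predict(self, ratios: Sequence[float]) -> np.ndarray:
        return (np.asarray(ratios, dtype=float) > self.threshold).astype(int)

    def predict_one(self, ratio: float) -> int:
        return int(ratio > self.threshold)


def train_subject_model(
    ratios: Sequence[float],
    subject_labels: Sequence[int],
    box_constraint: float = 1.0,
) -> SubjectModel:
    """Fit the stage-2 classifier on (ratio, subject label) pairs.

    A linear SVM on one feature has decision function w*r + b; the exposed
    threshold is -b/w.  Identical class-conditional ratios (inseparable in
    every direction) produce a degenerate chance-level model with a warning.
    """
    r = np.asarray(ratios, dtype=float).reshape(-1, 1)
    y = np.asarray(subject_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both subject classes to train the stage-2 model")
    if np.allclose(r[y == 1].mean(), r[y == 0].mean()) and np.allclose(r.std(), 0):
        warnings.warn("degenerate stage-2 training data: identical ratios across classes")
        return SubjectModel(threshold=float(r.mean()), degenerate=True)
    svc = SVC(kernel="linear", C=box_constraint)
    svc.fit(r, y)
    w = float(svc.coef_[0, 0])
    b = float(svc.intercept_[0])
    if abs(w) < 1e-12:
        warnings.warn("stage-2 SVM collapsed (zero weight); falling back to midpoint threshold")
        return SubjectModel(threshold=float((r[y == 1].mean() + r[y == 0].mean()) / 2), degenerate=True)
    thr = -b / w
    if w < 0:
        # a negative weight would invert the decision; with ratio-coded classes
        # this only happens in degenerate data
        warnings.warn("stage-2 SVM learned an inverted decision; data are degenerate")
        return SubjectModel(threshold=thr, degenerate=True)
    return SubjectModel(threshold=thr)


def validation_ground_truth(ahi: float | None, cutoff: float = 20.0) -> int | None:
    """Dichotomize a clinical AHI: 1 if AHI > cutoff, 0 if below.

    An AHI exactly at the cutoff is assigned positive with a logged note; a
    missing AHI returns None (subject excluded from evaluation).
    """
    if ahi is None:
        return None
    if ahi < 0:
        raise ValueError(f"AHI must be >= 0, got {ahi}")
    if ahi == cutoff:
        logger.info("AHI exactly at cutoff %.1f: assigned positive", cutoff)
        return 1
    return int(ahi > cutoff)


def save_models(path: str | Path, window_model: Pipeline, subject_model: SubjectModel) -> None:
    """Serialize both models with a schema version tag."""
    joblib.dump(
        {
            "schema_version": MODEL_SCHEMA_VERSION,
            "window_model": window_model,
            "subject_model": subject_model,
        },
        Path(path),
    )


def load_models(path: str | Path) -> tuple[Pipeline, SubjectModel]:
    """Load a model archive, refusing incompatible schema versions."""
    payload = joblib.load(Path(path))
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"model archive schema {version!r} incompatible with supported "
            f"version {MODEL_SCHEMA_VERSION}"
        )
    return payload["window_model"], payload["subject_model"]
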