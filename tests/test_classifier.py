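"""classify: both SVM stages, cross-validation, ratios, model persistence."""

from __future__ import annotations

import numpy as np
import pytest

from sdbscreen.classify import (
    SubjectModel,
    WindowModelConfig,
    crossvalidate,
    load_models,
    save_models,
    subject_ratio,
    train_subject_model,
    train_window_model,
    validation_ground_truth,
)


def _blobs(n=200, sep=10.0, seed=0, d=5):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, d)), rng.normal(sep, 1, (n, d))])
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    return X, y


class TestWindowModel:
    def test_separable_blobs_fit_perfectly(self):
        X, y = _blobs()
        model = train_window_model(X, y)
        assert (model.predict(X) == y).all()

    def test_duplication_invariance(self):
        """Duplicating every row leaves the decision function unchanged.

        Holds exactly when no margin violations are active (separable data);
        with violations the per-sample penalty would rescale with the
        duplicate count."""
        X, y = _blobs(n=100, sep=10.0)
        m1 = train_window_model(X, y)
        m2 = train_window_model(np.vstack([X, X]), np.concatenate([y, y]))
        grid = np.random.default_rng(1).normal(1.5, 2.0, (200, X.shape[1]))
        np.testing.assert_allclose(
            m1.decision_function(grid), m2.decision_function(grid), atol=1e-6
        )

    def test_single_class_rejected(self):
        X, _ = _blobs(n=50)
        with pytest.raises(ValueError, match="both classes"):
            train_window_model(X, np.zeros(len(X), dtype=int))

    def test_nan_features_rejected_listing_rows(self):
        X, y = _blobs(n=20)
        X[3, 0] = np.nan
        with pytest.raises(ValueError, match="rows \\[3\\]"):
            train_window_model(X, y)

    def test_non_rbf_kernel_needs_experimental_flag(self):
        with pytest.raises(ValueError, match="experimental"):
            WindowModelConfig(kernel="linear")
        WindowModelConfig(kernel="linear", experimental_kernels=True)


class TestCrossValidate:
    def test_separable_data_scores_perfectly(self):
        X, y = _blobs()
        cv = crossvalidate(X, y, k=10)
        assert cv.pooled_metrics()["accuracy"].estimate == 1.0
        assert len(cv.fold_matrices) == 10

    def test_permuted_labels_score_at_chance(self):
        """Label permutation destroys the signal: pooled accuracy 50% +/- 5."""
        X, y = _blobs(n=500, sep=10.0, seed=2)
        rng = np.random.default_rng(3)
        y_perm = rng.permutation(y)
        cv = crossvalidate(X, y_perm, k=10)
        assert abs(cv.pooled_metrics()["accuracy"].estimate - 0.5) <= 0.05

    def test_subject_grouping_never_beats_window_grouping(self, training_analog):
        """With 175 s overlap, window-level folds leak; grouped folds cannot
        score better on the same data."""
        # reuse the training cohort's dataset via a fresh small cohort
        import sdbscreen as sdb
        from sdbscreen.features import FEATURE_COLUMNS
        from sdbscreen.pipeline import extract_windows

        cohort = sdb.simulate_cohort(6, 6, seed=99, duration=3600.0)
        tables, labels = [], {}
        for rec, truth in cohort:
            tables.append(extract_windows(rec))
            labels[rec.subject_id] = truth.subject_label
        frame, y, groups = sdb.assemble_window_dataset(tables, labels, seed=99)
        X = frame[FEATURE_COLUMNS].to_numpy(dtype=float)
        acc = {}
        for grouping in ("window", "subject"):
            cv = crossvalidate(X, y, subject_ids=groups, k=6, grouping=grouping)
            acc[grouping] = cv.pooled_metrics()["accuracy"].estimate
        assert acc["subject"] <= acc["window"] + 1e-9

    def test_excessive_k_rejected(self):
        X, y = _blobs(n=5)
        with pytest.raises(ValueError, match="k="):
            crossvalidate(X, y, k=10)

    def test_fold_assignment_deterministic(self):
        X, y = _blobs(n=100, sep=2.0)
        cv1 = crossvalidate(X, y, k=5, config=WindowModelConfig(seed=4))
        cv2 = crossvalidate(X, y, k=5, config=WindowModelConfig(seed=4))
        np.testing.assert_array_equal(cv1.oof_pred, cv2.oof_pred)


class TestSubjectRatio:
    def test_basic_ratio(self):
        sp = subject_ratio("s", [1] * 30 + [0] * 70)
        assert sp.ratio == pytest.approx(0.30)
        assert (sp.n_windows_sdb, sp.n_windows_total) == (30, 100)

    def test_zero_positive_windows(self):
        assert subject_ratio("s", [0] * 50).ratio == 0.0

    def test_all_invalid_is_unclassifiable(self):
        sp = subject_ratio("s", [1, 0, 1], window_valid=[False, False, False])
        assert sp.unclassifiable and sp.ratio is None

    def test_invalid_windows_excluded_from_both_sides(self):
        sp = subject_ratio("s", [1, 1, 0, 0], window_valid=[True, False, True, False])
        assert sp.n_windows_total == 2 and sp.ratio == pytest.approx(0.5)


class TestSubjectModel:
    def test_separable_ratios_yield_interior_threshold(self):
        ratios = [0.05, 0.08, 0.10, 0.60, 0.70, 0.80]
        labels = [0, 0, 0, 1, 1, 1]
        model = train_subject_model(ratios, labels)
        assert 0.10 < model.threshold < 0.60
        assert (model.predict(ratios) == labels).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            train_subject_model([0.1, 0.2], [0, 0])

    def test_degenerate_identical_ratios_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            model = train_subject_model([0.3, 0.3, 0.3, 0.3], [0, 0, 1, 1])
        assert model.degenerate

    def test_threshold_monotonicity(self):
        """Flipping any window 0->1 can only move a subject toward positive."""
        model = SubjectModel(threshold=0.35)
        base = [0] * 60 + [1] * 40
        assert model.predict_one(np.mean(base)) == 1
        for i in range(60):
            flipped = list(base)
            flipped[i] = 1
            assert model.predict_one(np.mean(flipped)) >= 1


class TestGroundTruth:
    @pytest.mark.parametrize("ahi,label", [(35.2, 1), (7.0, 0), (20.0, 1), (0.0, 0)])
    def test_ahi_cutoff_rule(self, ahi, label):
        assert validation_ground_truth(ahi) == label

    def test_missing_ahi_excluded(self):
        assert validation_ground_truth(None) is None

    def test_negative_ahi_rejected(self):
        with pytest.raises(ValueError):
            validation_ground_truth(-1.0)


class TestPersistence:
    def test_round_trip(self, tmp_path):
        X, y = _blobs(n=50, sep=4.0)
        wm = train_window_model(X, y)
        sm = SubjectModel(threshold=0.31)
        path = tmp_path / "models.joblib"
        save_models(path, wm, sm)
        wm2, sm2 = load_models(path)
        np.testing.assert_array_equal(wm.predict(X), wm2.predict(X))
        assert sm2.threshold == 0.31

    def test_incompatible_schema_refused(self, tmp_path):
        import joblib

        path = tmp_path / "models.joblib"
        joblib.dump({"schema_version": 999}, path)
        with pytest.raises(ValueError, match="schema"):
            load_models(path)
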