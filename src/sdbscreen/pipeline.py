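"""End-to-end orchestration: record -> windows -> features -> subject call.

The per-record path is: R-peak detection (or supplied beat times) -> R-R
series construction and artifact cleaning -> sliding-window Lomb spectrogram
-> 13 band means + 3 SpO2 statistics per window -> stage-1 window predictions
-> positive-window ratio -> stage-2 subject label.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classify import SubjectModel, SubjectPrediction, subject_ratio
from .config import PipelineConfig
from .features import (
    BAND_COLUMNS,
    FEATURE_COLUMNS,
    SPO2_COLUMNS,
    BandScheme,
    band_features,
    label_window,
    spo2_features,
)
from .record_io import PolysomRecord, filter_respiratory_events
from .rpeak import BeatSeries, RRSeries, build_rr, clean_rr, detect_rpeaks
from .spectral import FrequencyGrid, build_spectrogram

logger = logging.getLogger(__name__)


def record_rr(record: PolysomRecord, config: PipelineConfig | None = None) -> RRSeries:
    """Cleaned R-R series for a record: detect R-peaks from the ECG waveform
    when present, otherwise use supplied beat times."""
    if record.ecg is not None:
        beats = detect_rpeaks(record.ecg)
    elif record.beat_times is not None and len(record.beat_times) >= 2:
        beats = BeatSeries(record.beat_times, np.zeros(len(record.beat_times), dtype=bool))
    else:
        logger.warning("%s: no ECG and no beat times", record.subject_id)
        return RRSeries(np.empty(0), np.empty(0))
    return clean_rr(build_rr(beats))


def extract_windows(
    record: PolysomRecord,
    config: PipelineConfig | None = None,
    rr: RRSeries | None = None,
) -> pd.DataFrame:
    """Per-window feature/label table for one record.

    Columns: subject_id, window_start_s, b01..b13, spo2_range/mean/sd, label,
    valid.  A window is valid when its spectrum is valid and (if SpO2 features
    are enabled) at least two valid SpO2 samples fall inside it; invalid
    windows keep NaN features and are excluded from training and from both
    sides of the stage-2 ratio.
    """
    config = config or PipelineConfig()
    if rr is None:
        rr = record_rr(record, config)
    duration = record.duration
    grid = FrequencyGrid.for_window(config.window_length_s, config.f_max_hz)
    scheme = BandScheme(config.band_edges)
    scheme.bin_assignments(grid)  # fail fast if the grid cannot resolve a band
    spect = build_spectrogram(
        rr,
        window_length_s=config.window_length_s,
        overlap_s=config.overlap_s,
        grid=grid,
        record_duration=duration,
        min_beats=config.min_beats_per_window,
    )
    resp_events = filter_respiratory_events(record.events, config.respiratory_event_names)

    spo2_t = record.spo2.times() if record.spo2 is not None else None
    rows = []
    for k, start in enumerate(spect.window_starts):
        valid = bool(spect.valid[k])
        bands = (
            band_features(spect.spectra[k], grid, scheme)
            if valid
            else np.full(len(BAND_COLUMNS), np.nan)
        )
        spo2_vals = (np.nan, np.nan, np.nan)
        if config.include_spo2_features:
            if record.spo2 is None:
                valid = False
            else:
                mask = (spo2_t >= start) & (spo2_t < start + config.window_length_s)
                feats = spo2_features(record.spo2.samples[mask])
                if feats is None:
                    valid = False
                else:
                    spo2_vals = feats
        row = {
            "subject_id": record.subject_id,
            "window_start_s": float(start),
            **dict(zip(BAND_COLUMNS, bands)),
            **dict(zip(SPO2_COLUMNS, spo2_vals)),
            "label": label_window(
                start, resp_events, config.window_length_s, config.min_event_seconds
            ),
            "valid": valid,
        }
        rows.append(row)
    cols = ["subject_id", "window_start_s", *FEATURE_COLUMNS, "label", "valid"]
    return pd.DataFrame(rows, columns=cols)


def predict_windows(table: pd.DataFrame, window_model, config: PipelineConfig | None = None) -> np.ndarray:
    """Stage-1 predictions for the valid rows of a window table; invalid rows
    get -1."""
    config = config or PipelineConfig()
    cols = FEATURE_COLUMNS if config.include_spo2_features else BAND_COLUMNS
    pred = np.full(len(table), -1, dtype=int)
    valid = table["valid"].to_numpy(dtype=bool)
    if valid.any():
        pred[valid] = window_model.predict(table.loc[valid, cols].to_numpy(dtype=float))
    return pred


def classify_subject(
    record: PolysomRecord,
    window_model,
    subject_model: SubjectModel,
    config: PipelineConfig | None = None,
) -> SubjectPrediction:
    """Full pipeline for one subject: signals -> windows -> SVM-1 -> ratio ->
    SVM-2 label.  A record that yields no valid windows (flatline ECG, too
    short, all-artifact) is returned as unclassifiable, never silently 0."""
    config = config or PipelineConfig()
    table = extract_windows(record, config)
    if not len(table):
        return SubjectPrediction(record.subject_id, 0, 0, None, None, unclassifiable=True)
    pred = predict_windows(table, window_model, config)
    valid = table["valid"].to_numpy(dtype=bool)
    sp = subject_ratio(record.subject_id, np.where(valid, pred, 0), valid)
    if not sp.unclassifiable:
        sp.label_pred = subject_model.predict_one(sp.ratio)
    return sp
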