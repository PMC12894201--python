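"""Window features and labels for the window-level (stage 1) classifier.

Each 180 s analysis window yields a 16-dimensional feature vector:

* 13 frequency-band means — the average normalized Lomb magnitude of the grid
  bins inside 13 contiguous half-open bands spanning 0-0.35 Hz (0.02 Hz wide
  up to 0.20 Hz, then 0.05 Hz wide).  The two lowest bands (0-0.04 Hz) capture
  the cyclical variation of heart rate locked to repetitive respiratory
  events; the top bands capture respiratory sinus arrhythmia.
* 3 SpO2 statistics over the window's valid oximeter samples — range
  (max - min), mean, and sample standard deviation (n-1 denominator).

A window is labeled SDB-positive (1) when the union of scored respiratory
event intervals covers at least 36 s of it — 20% of the 180 s window length.
The union (not the sum) is used so overlapping scored events are not
double-counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .record_io import ScoredEvent
from .spectral import FrequencyGrid

logger = logging.getLogger(__name__)

#: Band edges in Hz; bands are half-open [lo, hi).
DEFAULT_BAND_EDGES: tuple[float, ...] = (
    0.0, 0.02, 0.04, 0.06, 0.08, 0.10, 0.12, 0.14, 0.16, 0.18, 0.20, 0.25, 0.30, 0.35,
)

#: Minimum seconds of a window covered by respiratory events for label 1
#: (20% of the 180 s window).
DEFAULT_MIN_EVENT_SECONDS = 36.0

BAND_COLUMNS = [f"b{i:02d}" for i in range(1, 14)]
SPO2_COLUMNS = ["spo2_range", "spo2_mean", "spo2_sd"]
FEATURE_COLUMNS = BAND_COLUMNS + SPO2_COLUMNS


class BandConfigurationError(ValueError):
    """Raised when the frequency grid cannot resolve every band."""


@dataclass(frozen=True)
class BandScheme:
    """The 13 contiguous half-open frequency bands [lo, hi) covering (0, 0.35) Hz."""

    edges: tuple[float, ...] = DEFAULT_BAND_EDGES

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) != 14:
            raise ValueError(f"need 14 edges for 13 bands, got {len(e)}")
        if not np.all(np.diff(e) > 0):
            raise ValueError("band edges must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return len(self.edges) - 1

    def intervals(self) -> list[tuple[float, float]]:
        return list(zip(self.edges[:-1], self.edges[1:]))

    def bin_assignments(self, grid: FrequencyGrid) -> list[np.ndarray]:
        """Indices of grid bins per band; raises if any band has no bins."""
        out = []
        for lo, hi in self.intervals():
            idx = np.flatnonzero((grid.frequencies >= lo - 1e-12) & (grid.frequencies < hi - 1e-12))
            if idx.size == 0:
                raise BandConfigurationError(
                    f"frequency grid (resolution {grid.resolution:.5f} Hz) has no "
                    f"bins in band [{lo}, {hi}) Hz"
                )
            out.append(idx)
        return out


def band_features(
    spectrum: np.ndarray,
    grid: FrequencyGrid,
    scheme: BandScheme | None = None,
) -> np.ndarray:
    """Mean normalized magnitude per band for one valid spectrum."""
    scheme = scheme or BandScheme()
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != grid.frequencies.shape:
        raise ValueError("spectrum does not match the frequency grid")
    return np.array([spectrum[idx].mean() for idx in scheme.bin_assignments(grid)])


def spo2_features(samples: np.ndarray) -> tuple[float, float, float] | None:
    """(range, mean, sample SD) over valid (finite) SpO2 samples in a window.

    Returns None when fewer than 2 valid samples remain — the window is then
    invalid for SpO2 features.  Only values matter; sample positions do not.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return None
    return float(x.max() - x.min()), float(x.mean()), float(x.std(ddof=1))


def _union_overlap_seconds(
    window: tuple[float, float], events: Sequence[ScoredEvent]
) -> float:
    """Total measure of the union of event intervals clipped to the window."""
    w0, w1 = window
    clipped = sorted(
        (max(ev.start, w0), min(ev.end, w1))
        for ev in events
        if ev.end > w0 and ev.start < w1
    )
    total, cur0, cur1 = 0.0, None, None
    for a, b in clipped:
        if cur1 is None or a > cur1:
            if cur1 is not None:
                total += cur1 - cur0
            cur0, cur1 = a, b
        else:
            cur1 = max(cur1, b)
    if cur1 is not None:
        total += cur1 - cur0
    return total


def label_window(
    window_start: float,
    events: Sequence[ScoredEvent],
    window_length: float = 180.0,
    min_event_seconds: float = DEFAULT_MIN_EVENT_SECONDS,
) -> int:
    """1 iff the union of respiratory-event intervals covers at least
    ``min_event_seconds`` of [window_start, window_start + window_length).

    Events must already be filtered to respiratory types.  Monotone: adding an
    event can only raise the covered time, never flip 1 -> 0.
    """
    covered = _union_overlap_seconds(
        (window_start, window_start + window_length), events
    )
    return int(covered >= min_event_seconds)


def assemble_window_dataset(
    tables: Sequence[pd.DataFrame],
    subject_labels: dict[str, int],
    *,
    n_negative: int | None = None,
    seed: int = 0,
    feature_columns: Sequence[str] = FEATURE_COLUMNS,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Build the stage-1 training set from per-subject window tables.

    Positives are every SDB-labeled valid window of subjects whose subject
    label is 1.  Negatives are a seeded uniform sample without replacement of
    valid windows from subjects labeled 0 (regardless of their own window
    labels — these subjects are clinically event-free by design), sized to
    ``n_negative`` or, by default, to balance the positives.

    Returns ``(frame, y, groups)`` where ``frame`` holds subject_id,
    window_start_s and the feature columns, ``y`` the window labels, and
    ``groups`` the subject id per row for grouped cross-validation.
    """
    frames = [t for t in tables if len(t)]
    if not frames:
        raise ValueError("no window tables supplied")
    allw = pd.concat(frames, ignore_index=True)
    missing = set(allw["subject_id"]) - set(subject_labels)
    if missing:
        raise ValueError(f"no subject label for: {sorted(missing)}")
    allw = allw[allw["valid"]].copy()

    subj = allw["subject_id"].map(subject_labels)
    pos = allw[(subj == 1) & (allw["label"] == 1)]
    neg_pool = allw[subj == 0]
    n_neg = len(pos) if n_negative is None else int(n_negative)
    if n_neg > len(neg_pool):
        raise ValueError(
            f"requested {n_neg} negative windows but only {len(neg_pool)} "
            f"valid windows are available from non-SDB subjects"
        )
    rng = np.random.default_rng(seed)
    neg = neg_pool.iloc[rng.choice(len(neg_pool), size=n_neg, replace=False)]

    frame = pd.concat([pos, neg], ignore_index=True)
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(n_neg, dtype=int)])
    groups = frame["subject_id"].to_numpy()
    keep = ["subject_id", "window_start_s", *feature_columns]
    return frame[keep].reset_index(drop=True), y, groups


def write_window_table(table: pd.DataFrame, path) -> None:
    """Export a per-window feature table as TSV with the documented header."""
    cols = ["subject_id", "window_start_s", *FEATURE_COLUMNS, "label", "valid"]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_window_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
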