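"""features: band means, SpO2 statistics, window labeling, dataset assembly."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdbscreen.features import (
    BandConfigurationError,
    BandScheme,
    FEATURE_COLUMNS,
    assemble_window_dataset,
    band_features,
    label_window,
    spo2_features,
)
from sdbscreen.record_io import ScoredEvent
from sdbscreen.spectral import FrequencyGrid, lomb_periodogram, normalize_spectrum


GRID = FrequencyGrid.for_window(180.0)


class TestBandScheme:
    def test_thirteen_contiguous_bands(self):
        scheme = BandScheme()
        assert scheme.n_bands == 13
        intervals = scheme.intervals()
        assert intervals[0][0] == 0.0 and intervals[-1][1] == 0.35
        for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
            assert hi1 == lo2

    def test_grid_too_coarse_raises_at_construction(self):
        coarse = FrequencyGrid(frequencies=np.array([0.1, 0.2, 0.3]), resolution=0.1)
        with pytest.raises(BandConfigurationError, match="no\\s+bins"):
            BandScheme().bin_assignments(coarse)

    def test_every_default_band_has_bins(self):
        idx = BandScheme().bin_assignments(GRID)
        assert all(len(i) > 0 for i in idx)
        # bins partition: no bin in two bands
        allidx = np.concatenate(idx)
        assert len(allidx) == len(np.unique(allidx))


class TestBandFeatures:
    def test_uniform_spectrum_gives_equal_means(self):
        spectrum = np.full(len(GRID), 1.0 / len(GRID))
        means = band_features(spectrum, GRID)
        np.testing.assert_allclose(means, means[0])

    def test_power_at_quarter_hz_lands_in_its_band(self):
        spectrum = np.zeros(len(GRID))
        spectrum[np.argmin(np.abs(GRID.frequencies - 0.25))] = 1.0
        means = band_features(spectrum, GRID)
        assert np.argmax(means) == 11  # [0.25, 0.30)
        assert np.allclose(means[:10], 0.0)

    def test_modulation_frequency_separates_bands(self):
        """Event-cycle (0.02 Hz) vs RSA (0.25 Hz) modulation of the same
        amplitude concentrates mass in the low vs high bands respectively;
        oracle is the direct periodogram of the generated series."""
        t = np.arange(1.0, 181.0)
        low = 1.0 + 0.05 * np.sin(2 * np.pi * 0.02 * t)
        high = 1.0 + 0.05 * np.sin(2 * np.pi * 0.25 * t)
        m_low = band_features(normalize_spectrum(lomb_periodogram(t, low, GRID))[0], GRID)
        m_high = band_features(normalize_spectrum(lomb_periodogram(t, high, GRID))[0], GRID)
        assert m_low[:2].sum() > 0.8 * m_low.sum()
        assert np.argmax(m_high) == 11

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            band_features(np.zeros(10), GRID)


class TestSpO2Features:
    def test_worked_example(self):
        rng_, mean, sd = spo2_features(np.array([96.0, 95.0, 90.0, 95.0, 96.0]))
        assert rng_ == 6.0
        assert mean == pytest.approx(94.4)
        assert sd == pytest.approx(2.5100, abs=1e-4)

    def test_constant_window(self):
        rng_, mean, sd = spo2_features(np.full(180, 96.0))
        assert (rng_, mean, sd) == (0.0, 96.0, 0.0)

    def test_all_missing_invalid(self):
        assert spo2_features(np.full(180, np.nan)) is None
        assert spo2_features(np.array([96.0])) is None

    def test_missing_positions_irrelevant(self):
        a = np.array([96.0, np.nan, 94.0, np.nan, 92.0])
        b = np.array([np.nan, 96.0, np.nan, 94.0, 92.0])
        assert spo2_features(a) == spo2_features(b)


class TestLabelWindow:
    def test_single_event_meeting_threshold(self):
        events = [ScoredEvent("Obstructive apnea", 100.0, 40.0)]
        assert label_window(0.0, events) == 1

    def test_disjoint_events_below_threshold(self):
        events = [ScoredEvent("Hypopnea", 10.0, 20.0), ScoredEvent("Obstructive apnea", 50.0, 15.0)]
        assert label_window(0.0, events) == 0

    def test_overlapping_events_counted_once(self):
        """Two fully overlapping 40 s events cover 40 s (union), not 80 s."""
        events = [ScoredEvent("Hypopnea", 100.0, 40.0), ScoredEvent("Obstructive apnea", 100.0, 40.0)]
        assert label_window(0.0, events) == 1
        # union just below threshold stays 0 even doubled
        short = [ScoredEvent("Hypopnea", 100.0, 35.0), ScoredEvent("Obstructive apnea", 100.0, 35.0)]
        assert label_window(0.0, short) == 0

    def test_event_clipped_to_window(self):
        # 60 s event but only 30 s inside the window
        events = [ScoredEvent("Hypopnea", 150.0, 60.0)]
        assert label_window(0.0, events) == 0
        assert label_window(30.0, events) == 1

    @settings(max_examples=50, deadline=None)
    @given(
        starts=st.lists(st.floats(0, 170), min_size=0, max_size=6),
        extra=st.floats(0, 170),
    )
    def test_monotone_in_events(self, starts, extra):
        """Adding an event never flips a positive window to negative."""
        events = [ScoredEvent("Hypopnea", s, 15.0) for s in starts]
        before = label_window(0.0, events)
        after = label_window(0.0, events + [ScoredEvent("Hypopnea", extra, 15.0)])
        assert after >= before

    def test_event_order_irrelevant(self):
        events = [ScoredEvent("Hypopnea", 20.0, 20.0), ScoredEvent("Hypopnea", 60.0, 20.0)]
        assert label_window(0.0, events) == label_window(0.0, events[::-1])


def _table(subject_id, n, label):
    rng = np.random.default_rng(hash(subject_id) % 2**31)
    frame = pd.DataFrame(rng.random((n, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS)
    frame.insert(0, "window_start_s", 5.0 * np.arange(n))
    frame.insert(0, "subject_id", subject_id)
    frame["label"] = label
    frame["valid"] = True
    return frame


class TestAssemble:
    def _tables(self):
        tables = [
            _table("sdb-0", 50, 1), _table("sdb-1", 50, 1),
            _table("norm-0", 200, 0), _table("norm-1", 200, 0),
        ]
        labels = {"sdb-0": 1, "sdb-1": 1, "norm-0": 0, "norm-1": 0}
        return tables, labels

    def test_balanced_sampling(self):
        tables, labels = self._tables()
        frame, y, groups = assemble_window_dataset(tables, labels, seed=1)
        assert (y == 1).sum() == 100 and (y == 0).sum() == 100
        assert set(groups[y == 0]) <= {"norm-0", "norm-1"}

    def test_seed_determinism(self):
        tables, labels = self._tables()
        f1, _, _ = assemble_window_dataset(tables, labels, seed=7)
        f2, _, _ = assemble_window_dataset(tables, labels, seed=7)
        pd.testing.assert_frame_equal(f1, f2)
        f3, _, _ = assemble_window_dataset(tables, labels, seed=8)
        assert not f1.equals(f3)

    def test_oversized_request_reports_available(self):
        tables, labels = self._tables()
        with pytest.raises(ValueError, match="400"):
            assemble_window_dataset(tables, labels, n_negative=1000)

    def test_missing_subject_label_rejected(self):
        tables, labels = self._tables()
        del labels["norm-1"]
        with pytest.raises(ValueError, match="norm-1"):
            assemble_window_dataset(tables, labels)


class TestSignatureSeparation:
    def test_low_band_mass_higher_in_event_windows(self, sdb_record):
        """SDB subjects' labeled windows carry more 0-0.04 Hz mass than their
        quiet windows — the cyclic heart-rate signature stage 1 exploits."""
        from sdbscreen.pipeline import extract_windows

        record, _ = sdb_record
        table = extract_windows(record)
        valid = table[table["valid"]]
        low = valid["b01"] + valid["b02"]
        assert low[valid["label"] == 1].mean() > low[valid["label"] == 0].mean()
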