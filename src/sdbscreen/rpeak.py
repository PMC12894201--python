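"""R-wave peak detection and construction of the cleaned R-R interval series.

The detector is a band-limited QRS-energy detector: the ECG is band-passed to
the QRS band (5-25 Hz), squared, smoothed over ~150 ms, and candidate beats are
local maxima of that envelope above an adaptive (rolling-percentile) threshold
with a 0.25 s physiological refractory period.  Candidates whose amplitude or
envelope occupancy is atypical (motion artifact, electrode pops) are flagged
``suspect`` rather than silently kept.

Downstream spectral analysis works on the R-R (interbeat interval) series,
which is inherently unevenly sampled; artifact intervals are excluded, leaving
temporal gaps, because the Lomb-Scargle estimator tolerates uneven sampling and
interpolation would fabricate autocorrelation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .record_io import SignalTrace

logger = logging.getLogger(__name__)

#: Minimum time between consecutive beats (seconds): ventricular refractoriness.
REFRACTORY_S = 0.25

#: Physiological bounds on a sinus R-R interval (seconds): 30-200 bpm.
RR_BOUNDS_S: tuple[float, float] = (0.3, 2.0)


@dataclass
class BeatSeries:
    """Detected beat times (seconds) with per-beat quality flags."""

    times: np.ndarray
    suspect: np.ndarray  # True where the detection is artifact-flagged

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.suspect = np.asarray(self.suspect, dtype=bool)
        if self.times.shape != self.suspect.shape:
            raise ValueError("times and suspect flags must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def ok_times(self) -> np.ndarray:
        """Beat times not flagged as suspect."""
        return self.times[~self.suspect]


@dataclass
class RRSeries:
    """Unevenly sampled interbeat-interval series.

    ``times[i]`` is the time of the *later* beat of pair i, ``intervals[i]``
    the interval length, and ``kept_mask`` marks intervals that survived
    artifact cleaning.
    """

    times: np.ndarray
    intervals: np.ndarray
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.kept_mask is None:
            self.kept_mask = np.ones(len(self.times), dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if not (len(self.times) == len(self.intervals) == len(self.kept_mask)):
            raise ValueError("times, intervals and kept_mask must align")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("RR times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def kept_times(self) -> np.ndarray:
        return self.times[self.kept_mask]

    @property
    def kept_intervals(self) -> np.ndarray:
        return self.intervals[self.kept_mask]


def detect_rpeaks(
    ecg: SignalTrace,
    *,
    band_hz: tuple[float, float] = (5.0, 25.0),
    refractory_s: float = REFRACTORY_S,
    threshold_frac: float = 0.3,
    amplitude_flag_ratio: float = 3.0,
    occupancy_flag: float = 0.5,
) -> BeatSeries:
    """Detect candidate R-peaks in an ECG trace.

    Candidates are envelope local maxima above ``threshold_frac`` times a
    rolling 95th-percentile envelope level (10 s blocks), at least
    ``refractory_s`` apart, with the peak time refined to the local extremum of
    the band-passed signal.  Beats are flagged suspect when their band-passed
    amplitude exceeds ``amplitude_flag_ratio`` times the running median beat
    amplitude or when the envelope around them stays above threshold for more
    than ``occupancy_flag`` of a 0.6 s neighborhood (sustained energy is
    artifact; a QRS complex is ~0.1 s).

    A flatline or all-artifact trace yields an empty series with a logged
    warning, not an exception.
    """
    fs = ecg.sampling_rate
    if fs < 100:
        raise ValueError(f"ECG sampling rate {fs} Hz too low for QRS detection (need >= 100)")
    if ecg.duration < 10:
        raise ValueError(f"need >= 10 s of ECG, got {ecg.duration:.1f} s")

    x = np.nan_to_num(np.asarray(ecg.samples, dtype=float))
    x = x - np.median(x)
    nyq = fs / 2.0
    sos = sps.butter(3, [band_hz[0] / nyq, band_hz[1] / nyq], btype="band", output="sos")
    bp = sps.sosfiltfilt(sos, x)
    env = np.convolve(bp * bp, np.ones(max(1, int(0.15 * fs))) / max(1, int(0.15 * fs)), mode="same")

    scale = float(np.percentile(env, 99))
    if scale <= 0 or float(np.max(np.abs(bp))) < 1e-12:
        logger.warning("flatline or empty ECG: no beats detected")
        return BeatSeries(np.empty(0), np.empty(0, dtype=bool))

    # rolling threshold: per-10 s block 95th percentile, held constant in-block
    block = max(1, int(10 * fs))
    nblocks = int(np.ceil(len(env) / block))
    thr = np.empty_like(env)
    for b in range(nblocks):
        seg = env[b * block : (b + 1) * block]
        thr[b * block : b * block + len(seg)] = threshold_frac * np.percentile(seg, 95)
    thr = np.maximum(thr, 0.01 * scale)  # floor against quiet blocks of pure noise

    peaks, _ = sps.find_peaks(env, height=thr, distance=max(1, int(refractory_s * fs)))
    if peaks.size == 0:
        logger.warning("no supra-threshold envelope peaks: no beats detected")
        return BeatSeries(np.empty(0), np.empty(0, dtype=bool))

    # refine each peak to the local |band-passed| extremum within +/- 50 ms
    half = max(1, int(0.05 * fs))
    refined = np.empty(peaks.size, dtype=np.int64)
    for i, p in enumerate(peaks):
        lo, hi = max(0, p - half), min(len(bp), p + half + 1)
        refined[i] = lo + int(np.argmax(np.abs(bp[lo:hi])))
    refined, order = np.unique(refined, return_index=True)
    peaks = peaks[np.sort(order)]

    amps = np.abs(bp[refined])
    med_amp = np.empty_like(amps)
    k = 10  # running-median window, +/- 10 beats
    for i in range(len(amps)):
        lo, hi = max(0, i - k), min(len(amps), i + k + 1)
        med_amp[i] = np.median(amps[lo:hi])
    global_med = np.median(amps)
    med_amp = np.maximum(med_amp, 0.25 * global_med)

    nb = max(1, int(0.3 * fs))
    above = env > thr
    occupancy = np.array([
        above[max(0, p - nb) : p + nb + 1].mean() for p in refined
    ])
    suspect = (amps > amplitude_flag_ratio * med_amp) | (occupancy > occupancy_flag)

    times = refined / fs + ecg.start_offset
    keep = np.concatenate(([True], np.diff(times) > 1e-9))
    return BeatSeries(times[keep], suspect[keep])


def build_rr(beats: BeatSeries, *, use_suspect: bool = False) -> RRSeries:
    """Pair consecutive beats into an R-R series.

    ``intervals[i] = t[i+1] - t[i]`` anchored at the later beat.  Suspect
    beats are excluded by default before pairing.  Fewer than two usable beats
    yields an empty series.
    """
    t = beats.times if use_suspect else beats.ok_times()
    if len(t) < 2:
        return RRSeries(np.empty(0), np.empty(0))
    return RRSeries(times=t[1:], intervals=np.diff(t))


def clean_rr(
    rr: RRSeries,
    bounds: tuple[float, float] = RR_BOUNDS_S,
    max_rel_jump: float = 0.5,
) -> RRSeries:
    """Flag artifact intervals: out of physiological bounds, or jumping more
    than ``max_rel_jump`` relative to the previous *kept* interval.

    Flagged intervals are excluded from spectral analysis, leaving gaps (the
    Lomb periodogram handles uneven sampling); nothing is interpolated.
    Idempotent: cleaning an already-cleaned series changes nothing.
    """
    lo, hi = bounds
    n = len(rr)
    kept = np.zeros(n, dtype=bool)
    prev: float | None = None
    for i in range(n):
        if not rr.kept_mask[i]:
            continue
        v = rr.intervals[i]
        if not (lo <= v <= hi):
            continue
        if prev is not None and abs(v - prev) / prev > max_rel_jump:
            continue
        kept[i] = True
        prev = v
    return RRSeries(times=rr.times.copy(), intervals=rr.intervals.copy(), kept_mask=kept)


def read_rr_text(path: str | Path) -> RRSeries:
    """Read a bring-your-own-beats file: two whitespace/comma-delimited columns
    (beat_time_s, rr_s), '#' comments allowed."""
    data = np.loadtxt(Path(path), delimiter=None, comments="#", ndmin=2)
    if data.shape[1] < 2:
        data = np.loadtxt(Path(path), delimiter=",", comments="#", ndmin=2)
    return RRSeries(times=data[:, 0], intervals=data[:, 1])


def write_rr_text(path: str | Path, rr: RRSeries) -> None:
    """Write (beat_time_s, rr_s) columns; kept intervals only."""
    np.savetxt(
        Path(path),
        np.column_stack([rr.kept_times, rr.kept_intervals]),
        fmt="%.6f",
        header="beat_time_s rr_s",
    )
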