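"""Synthetic polysomnogram generator with known ground truth.

Emulates the physiological structure the screening pipeline exploits, so every
stage is testable without any cohort download:

* **Event process** — apneas/hypopneas recur quasi-periodically inside "bout"
  epochs (period ~50 s, i.e. an event-cycle frequency of ~0.02 Hz), as in
  repetitive obstructive sleep apnea; the number of events realizes the
  requested apnea-hypopnea index (AHI).
* **Heart rate** — instantaneous R-R interval = mean RR + respiratory sinus
  arrhythmia (0.25 Hz) + a low-frequency Mayer-wave term (0.10 Hz) + an
  event-locked bradycardia-tachycardia oscillation at the bout frequency,
  active only during bouts (the cyclical variation of heart rate).  Beat times
  come from integrate-and-fire (integral pulse frequency modulation) over the
  instantaneous rate — standard HRV simulation practice.
* **SpO2** — baseline with a per-event desaturation of configurable depth
  starting a circulation delay after event onset, exponential resaturation,
  quantized to integer percent at 1 Hz (oximeter realism).
* **ECG (optional)** — a Gaussian-template QRS train rendered at 256 Hz with
  additive Gaussian noise, for exercising the R-peak detector.
* **Ectopy (optional)** — premature beats with a shortened coupling interval
  and compensatory pause, mimicking PACs/PVCs that distort HRV spectra.

What this generator does **not** emulate: sleep staging, central/mixed apnea
morphology, airflow/effort channels, realistic multi-lead ECG morphology,
arousal-related transients, or oximeter motion artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .record_io import (
    PolysomRecord,
    ScoredEvent,
    SignalTrace,
    write_annotation_xml,
    write_edf,
)
from .rpeak import RRSeries, write_rr_text

logger = logging.getLogger(__name__)

ECG_FS = 256.0
SPO2_FS = 1.0


@dataclass(frozen=True)
class SubjectParams:
    """Generator settings for one synthetic subject.

    Amplitudes are in seconds of R-R modulation; the event-locked term is
    active only inside event bouts and sits at the bout frequency
    (1/bout_period ~ 0.02 Hz), inside the two lowest analysis bands.
    """

    duration: float = 6 * 3600.0  # s
    target_ahi: float = 0.0  # events per hour
    event_duration_mean: float = 25.0  # s
    event_duration_min: float = 10.0
    event_duration_max: float = 60.0
    bout_period: float = 50.0  # s between event onsets inside a bout
    mean_rr: float = 1.0  # s
    rsa_amp: float = 0.03  # s at 0.25 Hz
    lf_amp: float = 0.02  # s at 0.10 Hz
    event_rr_amp: float = 0.08  # s at the bout frequency, during bouts only
    rr_noise_sd: float = 0.02  # s, broadband beat-to-beat jitter
    desat_depth: float = 4.0  # percent
    desat_delay: float = 10.0  # s from event onset to desaturation onset
    spo2_baseline: float = 96.0  # percent
    ectopic_rate: float = 0.0  # fraction of beats
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.target_ahi < 0:
            raise ValueError("target_ahi must be >= 0")
        if not 0.4 <= self.mean_rr <= 1.5:
            raise ValueError("mean_rr must lie in [0.4, 1.5] s")
        for name in ("rsa_amp", "lf_amp", "event_rr_amp", "rr_noise_sd",
                     "desat_depth", "ectopic_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What the generator knows: exact beat times, events, and the AHI label."""

    true_beat_times: np.ndarray
    true_events: list[ScoredEvent]
    realized_ahi: float
    subject_label: int  # 1 iff realized_ahi > 20

    def __post_init__(self) -> None:
        self.true_beat_times = np.asarray(self.true_beat_times, dtype=float)


@dataclass(frozen=True)
class _Bout:
    start: float
    end: float


def _sample_events(params: SubjectParams, rng: np.random.Generator) -> tuple[list[ScoredEvent], list[_Bout]]:
    hours = params.duration / 3600.0
    n_events = int(round(params.target_ahi * hours))
    if n_events == 0:
        return [], []
    # Repetitive OSA presents as trains ("bouts") of events at the cyclic
    # period; an event rate too low to sustain trains (subclinical AHI)
    # presents as scattered isolated events with a single transient
    # heart-rate response each, not a sustained oscillation epoch.
    counts: list[int] = []
    remaining = n_events
    while remaining > 0:
        c = min(remaining, int(rng.integers(4, 9))) if params.target_ahi >= 10 else 1
        counts.append(c)
        remaining -= c
    bout_len = [c * params.bout_period for c in counts]
    slack = params.duration - sum(bout_len)
    if slack < 0.05 * params.duration:
        raise ValueError(
            f"target_ahi={params.target_ahi} infeasible for duration "
            f"{params.duration:.0f}s with bout_period {params.bout_period}s"
        )
    # distribute the slack as random gaps before each bout and at the end
    cuts = np.sort(rng.uniform(0, slack, size=len(counts)))
    events: list[ScoredEvent] = []
    bouts: list[_Bout] = []
    pos = 0.0
    prev_cut = 0.0
    for c, blen, cut in zip(counts, bout_len, cuts):
        pos += cut - prev_cut
        prev_cut = cut
        bstart = pos
        for j in range(c):
            onset = bstart + j * params.bout_period + float(rng.uniform(0, 2))
            dur = float(np.clip(
                rng.normal(params.event_duration_mean, 6.0),
                params.event_duration_min,
                min(params.event_duration_max, params.bout_period - 3.0),
            ))
            dur = min(dur, params.duration - onset - 1.0)
            if dur >= params.event_duration_min / 2:
                name = "Obstructive apnea" if rng.random() < 0.4 else "Hypopnea"
                events.append(ScoredEvent(name=name, start=round(onset, 2), duration=round(dur, 2)))
        bouts.append(_Bout(start=bstart, end=bstart + blen))
        pos += blen
    return sorted(events, key=lambda e: e.start), bouts


def _beat_times(params: SubjectParams, bouts: list[_Bout], rng: np.random.Generator) -> np.ndarray:
    phi_rsa = rng.uniform(0, 2 * np.pi)
    phi_lf = rng.uniform(0, 2 * np.pi)
    f_bout = 1.0 / params.bout_period
    starts = np.array([b.start for b in bouts])
    ends = np.array([b.end for b in bouts])

    def rr_inst(t: float) -> float:
        rr = (
            params.mean_rr
            + params.rsa_amp * np.sin(2 * np.pi * 0.25 * t + phi_rsa)
            + params.lf_amp * np.sin(2 * np.pi * 0.10 * t + phi_lf)
        )
        if starts.size:
            i = np.searchsorted(starts, t, side="right") - 1
            if i >= 0 and t < ends[i]:
                rr += params.event_rr_amp * np.sin(2 * np.pi * f_bout * (t - starts[i]))
        return max(0.35, rr)

    beats = []
    t = float(rng.uniform(0, params.mean_rr))  # random phase of the first beat
    while t < params.duration:
        beats.append(t)
        # broadband beat-to-beat jitter: real R-R series carry substantial
        # fractal background power on top of the oscillatory components
        step = rr_inst(t) + float(rng.normal(0.0, params.rr_noise_sd))
        t += max(0.35, step)
    beats = np.asarray(beats)

    if params.ectopic_rate > 0 and len(beats) > 2:
        beats = beats.copy()
        hit = rng.random(len(beats)) < params.ectopic_rate
        for k in np.flatnonzero(hit):
            if k < 1 or k >= len(beats) - 1:
                continue
            coupling = float(rng.uniform(0.4, 0.75))
            premature = beats[k - 1] + coupling * (beats[k] - beats[k - 1])
            # premature beat replaces the sinus beat; next sinus beat stands,
            # producing the compensatory pause
            beats[k] = premature
        beats = np.unique(beats)
    return beats


def render_ecg(
    beat_times: np.ndarray,
    duration: float,
    *,
    fs: float = ECG_FS,
    qrs_amplitude: float = 1.0,
    qrs_width: float = 0.02,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> SignalTrace:
    """Render a QRS train: one Gaussian template per beat plus white noise.

    ``noise_sd`` is in units of the QRS amplitude; 0.1 corresponds to a 20 dB
    peak signal-to-noise ratio.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    x = rng.normal(0.0, noise_sd * qrs_amplitude, size=n)
    half = int(round(4 * qrs_width * fs))
    tt = np.arange(-half, half + 1) / fs
    template = qrs_amplitude * np.exp(-0.5 * (tt / qrs_width) ** 2)
    for bt in beat_times:
        c = int(round(bt * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        x[lo:hi] += template[lo - (c - half) : len(template) - ((c + half + 1) - hi)]
    return SignalTrace(label="ECG", sampling_rate=fs, samples=x)


def _render_spo2(
    params: SubjectParams, events: list[ScoredEvent], rng: np.random.Generator
) -> SignalTrace:
    n = int(round(params.duration * SPO2_FS))
    t = np.arange(n) / SPO2_FS
    x = np.full(n, params.spo2_baseline, dtype=float)
    tau_resat = 15.0
    for ev in events:
        onset = ev.start + params.desat_delay
        u = t - onset
        shape = np.zeros_like(t)
        ramp = (u >= 0) & (u < ev.duration)
        shape[ramp] = u[ramp] / ev.duration
        tail = u >= ev.duration
        shape[tail] = np.exp(-(u[tail] - ev.duration) / tau_resat)
        x -= params.desat_depth * shape
    x = np.clip(x, 50.0, 100.0)
    return SignalTrace(label="SpO2", sampling_rate=SPO2_FS, samples=np.round(x))


def simulate_subject(
    params: SubjectParams,
    *,
    subject_id: str = "synth",
    render_ecg_waveform: bool = False,
    ecg_noise_sd: float = 0.05,
) -> tuple[PolysomRecord, GroundTruth]:
    """Generate one synthetic subject.

    Returns the record (beat times always included; ECG waveform only when
    ``render_ecg_waveform``) and the ground truth.  The realized AHI equals
    ``3600 * n_events / duration`` and lands within the generator's rounding
    of the target.
    """
    rng = np.random.default_rng(params.seed)
    events, bouts = _sample_events(params, rng)
    beats = _beat_times(params, bouts, rng)
    spo2 = _render_spo2(params, events, rng)
    ecg = None
    if render_ecg_waveform:
        ecg = render_ecg(
            beats, params.duration, noise_sd=ecg_noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    realized_ahi = 3600.0 * len(events) / params.duration
    truth = GroundTruth(
        true_beat_times=beats,
        true_events=list(events),
        realized_ahi=realized_ahi,
        subject_label=int(realized_ahi > 20.0),
    )
    record = PolysomRecord(
        subject_id=subject_id,
        ecg=ecg,
        spo2=spo2,
        events=list(events),
        ahi=realized_ahi,
        diagnosis_label=truth.subject_label,
        beat_times=beats,
    )
    return record, truth


def simulate_cohort(
    n_sdb: int,
    n_normal: int,
    *,
    seed: int = 0,
    duration: float = 6 * 3600.0,
    sdb_ahi_range: tuple[float, float] = (30.0, 60.0),
    normal_ahi_range: tuple[float, float] = (0.0, 5.0),
    base_params: SubjectParams | None = None,
    render_ecg_waveform: bool = False,
) -> list[tuple[PolysomRecord, GroundTruth]]:
    """Generate a cohort: SDB subjects draw their target AHI from a severe
    range, normal subjects from a low range; per-subject seeds derive
    deterministically from the cohort seed."""
    if n_sdb < 0 or n_normal < 0:
        raise ValueError("cohort sizes must be >= 0")
    base = base_params or SubjectParams()
    master = np.random.default_rng(seed)
    out = []
    specs = [("sdb", i, sdb_ahi_range) for i in range(n_sdb)]
    specs += [("normal", i, normal_ahi_range) for i in range(n_normal)]
    for kind, i, (lo, hi) in specs:
        subj_seed = int(master.integers(0, 2**31 - 1))
        ahi = float(master.uniform(lo, hi))
        params = replace(base, duration=duration, target_ahi=ahi, seed=subj_seed)
        sid = f"{kind}-{i:03d}"
        out.append(simulate_subject(params, subject_id=sid,
                                    render_ecg_waveform=render_ecg_waveform))
    return out


def write_fixture(
    record: PolysomRecord,
    truth: GroundTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write a round-trippable fixture: EDF (or RR text when no ECG waveform),
    annotation XML, and a plain-text truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = record.subject_id
    paths: dict[str, Path] = {}
    if record.ecg is not None:
        paths["edf"] = directory / f"{sid}.edf"
        write_edf(paths["edf"], [record.ecg, record.spo2], patient_id=sid)
    else:
        paths["rr"] = directory / f"{sid}.rr.txt"
        intervals = np.diff(truth.true_beat_times)
        write_rr_text(paths["rr"], RRSeries(times=truth.true_beat_times[1:], intervals=intervals))
        paths["spo2"] = directory / f"{sid}.spo2.txt"
        np.savetxt(paths["spo2"], record.spo2.samples, fmt="%.0f", header="spo2_pct (1 Hz)")
    paths["xml"] = directory / f"{sid}.xml"
    write_annotation_xml(paths["xml"], truth.true_events)
    paths["truth"] = directory / f"{sid}.truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("subject_id\trealized_ahi\tsubject_label\tn_events\n")
        fh.write(f"{sid}\t{truth.realized_ahi:.6f}\t{truth.subject_label}\t{len(truth.true_events)}\n")
    return paths


def read_truth_sidecar(path: str | Path) -> dict:
    """Read one truth sidecar row back as a dict."""
    lines = Path(path).read_text().strip().splitlines()
    keys, vals = lines[0].split("\t"), lines[1].split("\t")
    row = dict(zip(keys, vals))
    row["realized_ahi"] = float(row["realized_ahi"])
    row["subject_label"] = int(row["subject_label"])
    row["n_events"] = int(row["n_events"])
    return row
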