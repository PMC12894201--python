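"""Polysomnogram I/O: EDF signals, scored-event XML, and the in-memory record model.

Overnight sleep recordings arrive as an EDF (European Data Format) file holding
the physiological channels, each at its own sampling rate (ECG typically 256 Hz,
pulse-oximeter SpO2 at 1 Hz), plus an auxiliary Profusion-style XML file holding
the scored respiratory events (name, start in seconds, duration in seconds).
This module reads and writes both and defines :class:`PolysomRecord`, the
container every downstream stage consumes.

The EDF codec here is deliberately minimal: 16-bit EDF/EDF+ signal records with
per-channel physical scaling, which is all polysomnography fixtures need.  All
times are seconds from recording start; event intervals are half-open
``[start, start + duration)``.
"""

from __future__ import annotations

import logging
import re
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Default channel-label aliases (case-insensitive substring match).
DEFAULT_ECG_ALIASES: tuple[str, ...] = ("EKG", "ECG")
DEFAULT_SPO2_ALIASES: tuple[str, ...] = ("SPO2", "SAO2", "OSAT")

#: Default respiratory-event vocabulary used for window labeling: hypopneas and
#: obstructive apneas.  Central and mixed apneas are excluded unless configured.
DEFAULT_RESPIRATORY_EVENT_NAMES: tuple[str, ...] = ("hypopnea", "obstructive apnea")

#: SpO2 readings outside this physiological range (percent) are oximeter
#: dropout/artifact and are treated as missing (NaN), never clamped.
SPO2_VALID_RANGE: tuple[float, float] = (50.0, 100.0)

_EDF_HEADER_LEN = 256
_EDF_SIGNAL_HEADER_LEN = 256


class ChannelResolutionError(ValueError):
    """Raised when the channel map does not resolve exactly one channel."""


class EDFParseError(ValueError):
    """Raised for structurally invalid or truncated EDF files."""


class AnnotationError(ValueError):
    """Raised for malformed or invalid scored-event annotation files."""


@dataclass
class SignalTrace:
    """A single uniformly sampled channel.

    Parameters
    ----------
    label : str
        Channel name as recorded in the EDF header.
    sampling_rate : float
        Samples per second, > 0.
    samples : ndarray
        Physical-unit values; NaN marks missing samples (e.g. SpO2 dropout).
    start_offset : float
        Seconds from record start to the first sample (>= 0).
    """

    label: str
    sampling_rate: float
    samples: np.ndarray
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.start_offset < 0:
            raise ValueError("start_offset must be >= 0")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration(self) -> float:
        """Length of the trace in seconds."""
        return len(self.samples) / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds from record start."""
        return self.start_offset + np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class ScoredEvent:
    """One scored respiratory event: half-open interval [start, start+duration)."""

    name: str
    start: float
    duration: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise AnnotationError(f"event {self.name!r}: start {self.start} < 0")
        if self.duration <= 0:
            raise AnnotationError(
                f"event {self.name!r} at {self.start}s: duration {self.duration} <= 0"
            )

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class PolysomRecord:
    """One subject's recording: signals, scored events, and clinical metadata.

    Either an ECG trace or externally supplied beat times may drive the
    pipeline; ``beat_times`` supports bring-your-own-detector workflows and the
    waveform-free synthetic mode.
    """

    subject_id: str
    ecg: SignalTrace | None = None
    spo2: SignalTrace | None = None
    events: list[ScoredEvent] = field(default_factory=list)
    ahi: float | None = None
    diagnosis_label: int | None = None
    beat_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ecg is not None and self.spo2 is not None:
            if abs(self.ecg.duration - self.spo2.duration) > 1.0:
                raise ValueError(
                    f"{self.subject_id}: ECG ({self.ecg.duration:.1f}s) and SpO2 "
                    f"({self.spo2.duration:.1f}s) cover different intervals"
                )
        dur = self.duration
        if dur is not None:
            for ev in self.events:
                if ev.end > dur + 1.0:
                    raise ValueError(
                        f"{self.subject_id}: event {ev.name!r} [{ev.start}, {ev.end}) "
                        f"extends past the {dur:.1f}s recording"
                    )

    @property
    def duration(self) -> float | None:
        """Recording length in seconds (longest available channel)."""
        candidates = [t.duration for t in (self.ecg, self.spo2) if t is not None]
        if self.beat_times is not None and len(self.beat_times):
            candidates.append(float(self.beat_times[-1]))
        return max(candidates) if candidates else None


# ---------------------------------------------------------------------------
# EDF read / write
# ---------------------------------------------------------------------------

def _ascii_field(value: object, width: int) -> bytes:
    text = f"{value}"
    if len(text) > width:
        text = text[:width]
    return text.ljust(width).encode("ascii")


def _fmt_float(value: float, width: int) -> bytes:
    for fmt in (f"{value:.{width - 2}g}", f"{value:g}", f"{value:.0f}"):
        if len(fmt) <= width:
            return _ascii_field(fmt, width)
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(
    path: str | Path,
    traces: Sequence[SignalTrace],
    *,
    patient_id: str = "X",
    recording_id: str = "X",
) -> None:
    """Write signal traces to a 16-bit EDF file with 1-second data records.

    Each trace's sampling rate must be a positive integer (samples per 1 s
    record).  The recording is truncated to whole seconds common to all traces;
    NaN samples are encoded as the digital minimum (read back as missing for
    SpO2-range channels).
    """
    path = Path(path)
    if not traces:
        raise ValueError("no traces to write")
    for t in traces:
        if abs(t.sampling_rate - round(t.sampling_rate)) > 1e-9:
            raise ValueError(f"{t.label}: non-integer sampling rate {t.sampling_rate}")
    n_records = min(int(t.duration) for t in traces)
    if n_records < 1:
        raise ValueError("recording shorter than one 1-second EDF record")

    dig_min, dig_max = -32768, 32767
    scaled: list[np.ndarray] = []
    phys_ranges: list[tuple[float, float]] = []
    for t in traces:
        fs = int(round(t.sampling_rate))
        x = np.asarray(t.samples[: n_records * fs], dtype=float)
        finite = x[np.isfinite(x)]
        if finite.size:
            pmin, pmax = float(np.min(finite)), float(np.max(finite))
        else:
            pmin, pmax = 0.0, 1.0
        if pmax <= pmin:
            pmax = pmin + 1.0
        # widen slightly so round-trip error stays within one quantization step
        span = pmax - pmin
        pmin, pmax = pmin - 1e-3 * span, pmax + 1e-3 * span
        gain = (dig_max - dig_min) / (pmax - pmin)
        dig = np.round((x - pmin) * gain + dig_min)
        dig[~np.isfinite(x)] = dig_min
        scaled.append(dig.astype("<i2"))
        phys_ranges.append((pmin, pmax))

    ns = len(traces)
    header_bytes = _EDF_HEADER_LEN + ns * _EDF_SIGNAL_HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(_ascii_field("0", 8))
        fh.write(_ascii_field(patient_id, 80))
        fh.write(_ascii_field(recording_id, 80))
        fh.write(_ascii_field("01.01.00", 8))
        fh.write(_ascii_field("00.00.00", 8))
        fh.write(_ascii_field(header_bytes, 8))
        fh.write(_ascii_field("", 44))
        fh.write(_ascii_field(n_records, 8))
        fh.write(_ascii_field(1, 8))  # record duration: 1 s
        fh.write(_ascii_field(ns, 4))

        def per_signal(fn) -> None:
            for i, t in enumerate(traces):
                fh.write(fn(i, t))

        per_signal(lambda i, t: _ascii_field(t.label, 16))
        per_signal(lambda i, t: _ascii_field("", 80))
        per_signal(lambda i, t: _ascii_field("", 8))
        per_signal(lambda i, t: _fmt_float(phys_ranges[i][0], 8))
        per_signal(lambda i, t: _fmt_float(phys_ranges[i][1], 8))
        per_signal(lambda i, t: _ascii_field(dig_min, 8))
        per_signal(lambda i, t: _ascii_field(dig_max, 8))
        per_signal(lambda i, t: _ascii_field("", 80))
        per_signal(lambda i, t: _ascii_field(int(round(t.sampling_rate)), 8))
        per_signal(lambda i, t: _ascii_field("", 32))

        for rec in range(n_records):
            for i, t in enumerate(traces):
                fs = int(round(t.sampling_rate))
                fh.write(scaled[i][rec * fs : (rec + 1) * fs].tobytes())


def _read_exact(fh, n: int, what: str) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise EDFParseError(
            f"truncated EDF: expected {n} bytes for {what} at byte offset "
            f"{fh.tell() - len(data)}"
        )
    return data


def read_edf_signals(path: str | Path) -> list[SignalTrace]:
    """Read every signal from an EDF file, preserving per-channel rates."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = _read_exact(fh, _EDF_HEADER_LEN, "fixed header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_dur = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise EDFParseError(f"unparseable EDF header fields: {exc}") from exc
        if ns < 1 or n_records < 0 or record_dur <= 0:
            raise EDFParseError(
                f"invalid EDF header: n_signals={ns} n_records={n_records} "
                f"record_duration={record_dur}"
            )
        sig_head = _read_exact(fh, ns * _EDF_SIGNAL_HEADER_LEN, "signal headers")

        def fields(offset: int, width: int) -> list[str]:
            base = offset * ns
            return [
                sig_head[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]

        labels = fields(0, 16)
        pmins = [float(v) for v in fields(104, 8)]
        pmaxs = [float(v) for v in fields(104 + 8, 8)]
        dmins = [int(v) for v in fields(104 + 16, 8)]
        dmaxs = [int(v) for v in fields(104 + 24, 8)]
        spr = [int(v) for v in fields(104 + 32 + 80, 8)]

        traces: list[list[np.ndarray]] = [[] for _ in range(ns)]
        for rec in range(n_records):
            for i in range(ns):
                raw = _read_exact(fh, 2 * spr[i], f"record {rec} signal {i}")
                traces[i].append(np.frombuffer(raw, dtype="<i2"))

    out = []
    for i in range(ns):
        dig = np.concatenate(traces[i]).astype(float) if traces[i] else np.array([])
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        phys = (dig - dmins[i]) * gain + pmins[i]
        out.append(SignalTrace(label=labels[i], sampling_rate=spr[i] / record_dur, samples=phys))
    return out


def _resolve_channel(traces: Sequence[SignalTrace], aliases: Iterable[str], role: str) -> SignalTrace:
    aliases = [a.upper() for a in aliases]
    hits = [t for t in traces if any(a in t.label.upper() for a in aliases)]
    if len(hits) != 1:
        labels = [t.label for t in traces]
        raise ChannelResolutionError(
            f"channel resolution for {role!r} matched {len(hits)} of {labels} "
            f"using aliases {aliases}; need exactly one"
        )
    return hits[0]


def read_edf(
    path: str | Path,
    channel_map: Mapping[str, Sequence[str]] | None = None,
    *,
    subject_id: str | None = None,
) -> PolysomRecord:
    """Read an EDF recording into a :class:`PolysomRecord` (without events).

    ``channel_map`` maps roles to label aliases, default
    ``{"ecg": ("EKG", "ECG"), "spo2": ("SPO2", "SAO2", "OSAT")}``; matching is
    case-insensitive substring.  SpO2 values outside the physiological range
    are replaced with NaN (missing), not clamped.
    """
    channel_map = dict(channel_map or {})
    ecg_aliases = channel_map.get("ecg", DEFAULT_ECG_ALIASES)
    spo2_aliases = channel_map.get("spo2", DEFAULT_SPO2_ALIASES)
    traces = read_edf_signals(path)
    ecg = _resolve_channel(traces, ecg_aliases, "ecg")
    spo2 = _resolve_channel(traces, spo2_aliases, "spo2")
    lo, hi = SPO2_VALID_RANGE
    bad = (spo2.samples < lo) | (spo2.samples > hi)
    if bad.any():
        logger.info("%s: %d SpO2 samples outside [%g, %g]%% marked missing",
                    path, int(bad.sum()), lo, hi)
        spo2 = replace(spo2, samples=np.where(bad, np.nan, spo2.samples))
    return PolysomRecord(
        subject_id=subject_id or Path(path).stem,
        ecg=ecg,
        spo2=spo2,
    )


# ---------------------------------------------------------------------------
# Scored-event XML (Profusion / NSRR style)
# ---------------------------------------------------------------------------

def read_annotation_xml(path: str | Path) -> list[ScoredEvent]:
    """Read ScoredEvent elements (Name/Start/Duration) sorted by start time."""
    try:
        root = ET.parse(Path(path)).getroot()
    except ET.ParseError as exc:
        raise AnnotationError(f"malformed annotation XML {path}: {exc}") from exc
    events = []
    for el in root.iter("ScoredEvent"):
        name_el = el.find("Name")
        start_el = el.find("Start")
        dur_el = el.find("Duration")
        if name_el is None or start_el is None or dur_el is None:
            raise AnnotationError(f"{path}: ScoredEvent missing Name/Start/Duration")
        events.append(
            ScoredEvent(
                name=(name_el.text or "").strip(),
                start=float(start_el.text),
                duration=float(dur_el.text),
            )
        )
    return sorted(events, key=lambda e: e.start)


def write_annotation_xml(path: str | Path, events: Sequence[ScoredEvent]) -> None:
    """Write events as Profusion-style XML (fixture/round-trip support)."""
    root = ET.Element("CMPStudyConfig")
    container = ET.SubElement(root, "ScoredEvents")
    for ev in events:
        el = ET.SubElement(container, "ScoredEvent")
        ET.SubElement(el, "Name").text = ev.name
        ET.SubElement(el, "Start").text = f"{ev.start:g}"
        ET.SubElement(el, "Duration").text = f"{ev.duration:g}"
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(Path(path), encoding="unicode", xml_declaration=True)


def filter_respiratory_events(
    events: Sequence[ScoredEvent],
    include_names: Iterable[str] = DEFAULT_RESPIRATORY_EVENT_NAMES,
) -> list[ScoredEvent]:
    """Keep events whose name matches the respiratory vocabulary.

    Matching is case-insensitive substring (scoring software varies in exact
    strings, e.g. "Hypopnea" vs "Hypopnea|Hypopnea").  Default vocabulary is
    hypopnea + obstructive apnea; central/mixed apneas are excluded unless the
    vocabulary is extended.  Order-preserving and idempotent.
    """
    vocab = [v.lower() for v in include_names]
    kept, dropped = [], []
    for ev in events:
        if any(v in ev.name.lower() for v in vocab):
            kept.append(ev)
        else:
            dropped.append(ev.name)
    if dropped:
        logger.debug("dropped %d non-respiratory events: %s", len(dropped), sorted(set(dropped)))
    return kept
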