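"""EEG recordings, seizure annotations, and segment extraction.

Data model
----------
A subject is a set of :class:`EEGRecord` objects on one absolute timeline
(each record carries its start time ``t0`` in seconds since the subject
origin; gaps between records are allowed and never interpolated) plus a list
of :class:`SeizureAnnotation` onsets/offsets on the same timeline.

Two labelled classes are extracted for training:

* interictal — data at least ``guard_s`` (default 4 h) away from every seizure
  onset *and* offset;
* preictal — for each seizure, the interval ``[onset − (SOP+SPH),
  onset − SPH)`` (default 35 to 5 minutes before onset), clipped to available
  data and to the end of the previous seizure.

All times are 0-based seconds; intervals are half-open ``[start, end)``.
Everything else inside the guard (ictal/postictal) is discarded.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import numpy as np

INTERICTAL = "interictal"
PREICTAL = "preictal"

#: Default interictal guard: 4 hours away from any seizure.
DEFAULT_GUARD_S = 14400.0
#: Default seizure occurrence period (SOP) and prediction horizon (SPH).
DEFAULT_SOP_S = 1800.0
DEFAULT_SPH_S = 300.0


@dataclasses.dataclass
class EEGRecord:
    """Continuous multichannel EEG: (channels × samples) in µV."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[1] < 1:
            raise ValueError("record must contain at least one sample")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel label count must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration_s

    def slice_abs(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples covering absolute time [start_s, end_s)."""
        i0 = int(round((start_s - self.t0) * self.fs))
        i1 = int(round((end_s - self.t0) * self.fs))
        if i0 < 0 or i1 > self.data.shape[1] or i0 >= i1:
            raise ValueError(f"interval [{start_s}, {end_s}) outside record "
                             f"[{self.t0}, {self.t_end})")
        return self.data[:, i0:i1]


@dataclasses.dataclass(frozen=True)
class SeizureAnnotation:
    """One seizure event, in seconds on the subject timeline."""

    onset_s: float
    offset_s: float

    def __post_init__(self):
        if not (0 <= self.onset_s < self.offset_s):
            raise ValueError(f"need 0 <= onset < offset, got ({self.onset_s}, {self.offset_s})")


@dataclasses.dataclass
class LabeledSegment:
    """A half-open interval of one record carrying a class label."""

    record: EEGRecord
    start_s: float
    end_s: float
    label: str
    seizure_index: int | None = None

    def __post_init__(self):
        if self.label not in (INTERICTAL, PREICTAL):
            raise ValueError(f"label must be {INTERICTAL!r} or {PREICTAL!r}")
        if self.label == PREICTAL and self.seizure_index is None:
            raise ValueError("preictal segments must carry a seizure index")
        if self.start_s < self.record.t0 - 1e-9 or self.end_s > self.record.t_end + 1e-9:
            raise ValueError("segment lies outside its record")
        if self.start_s >= self.end_s:
            raise ValueError("empty segment")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def samples(self) -> np.ndarray:
        return self.record.slice_abs(self.start_s, self.end_s)


# ---------------------------------------------------------------------------
# EDF reading (writing lives in preictal.edf)
# ---------------------------------------------------------------------------

def read_edf(path, t0: float = 0.0) -> EEGRecord:
    """Read a 16-bit EDF file into an :class:`EEGRecord` (µV).

    Requires a uniform sampling rate across signals; mixed rates raise.
    ``t0`` places the record on the subject timeline.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"missing or empty EDF file: {path}")
    _check_uniform_rate(path)
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = (raw.get_data() * 1e6).astype(np.float32)  # V -> µV
    return EEGRecord(data=data, fs=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names), t0=t0)


def _check_uniform_rate(path: Path) -> None:
    with open(path, "rb") as f:
        header = f.read(256)
        if len(header) < 256:
            raise ValueError(f"malformed EDF header in {path}: too short")
        try:
            n_signals = int(header[252:256].decode("ascii").strip())
            record_dur = float(header[244:252].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise ValueError(f"malformed EDF header in {path}: {exc}") from exc
        if n_signals < 1 or record_dur <= 0:
            raise ValueError(f"malformed EDF header in {path}")
        sig = f.read(n_signals * 256)
        off = n_signals * 216
        nsamp = {int(sig[off + i * 8: off + (i + 1) * 8].decode("ascii").strip())
                 for i in range(n_signals)}
        if len(nsamp) != 1:
            raise ValueError(f"mixed per-signal sampling rates in {path}: {sorted(nsamp)}")


# ---------------------------------------------------------------------------
# CHB-MIT summary annotation dialect
# ---------------------------------------------------------------------------

_FILE_RE = re.compile(r"^File Name:\s*(\S+)")
_NSEIZ_RE = re.compile(r"^Number of Seizures in File:\s*(\d+)")
_START_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+Start Time:\s*(.+)$")
_END_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+End Time:\s*(.+)$")


def _parse_seconds(text: str, lineno: int) -> float:
    m = re.match(r"^\s*(\d+(?:\.\d+)?)\s*(?:seconds)?\s*$", text)
    if not m:
        raise ValueError(f"malformed seizure time on line {lineno}: {text!r}")
    return float(m.group(1))


def parse_chbmit_summary(text: str) -> dict[str, list[SeizureAnnotation]]:
    """Parse a CHB-MIT ``-summary.txt`` into per-file seizure annotations.

    Times are seconds relative to the start of each file. Files declaring
    ``Number of Seizures in File: 0`` map to an empty list.
    """
    out: dict[str, list[SeizureAnnotation]] = {}
    current: str | None = None
    pending_start: float | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        m = _FILE_RE.match(line)
        if m:
            if pending_start is not None:
                raise ValueError(f"seizure start without end before line {lineno}")
            current = m.group(1)
            out[current] = []
            continue
        if _NSEIZ_RE.match(line):
            continue
        m = _START_RE.match(line)
        if m:
            if current is None:
                raise ValueError(f"seizure time outside a file block at line {lineno}")
            pending_start = _parse_seconds(m.group(1), lineno)
            continue
        m = _END_RE.match(line)
        if m:
            if current is None or pending_start is None:
                raise ValueError(f"seizure end without start at line {lineno}")
            end = _parse_seconds(m.group(1), lineno)
            if pending_start >= end:
                raise ValueError(
                    f"seizure start {pending_start} >= end {end} at line {lineno}")
            out[current].append(SeizureAnnotation(pending_start, end))
            pending_start = None
    if pending_start is not None:
        raise ValueError("unterminated seizure block at end of summary")
    return out


# ---------------------------------------------------------------------------
# Segment extraction
# ---------------------------------------------------------------------------

def _subtract_intervals(span: tuple[float, float],
                        holes: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Remove half-open holes from a half-open span; returns remaining pieces."""
    pieces = [span]
    for h0, h1 in holes:
        nxt = []
        for s0, s1 in pieces:
            if h1 <= s0 or h0 >= s1:
                nxt.append((s0, s1))
                continue
            if s0 < h0:
                nxt.append((s0, h0))
            if h1 < s1:
                nxt.append((h1, s1))
        pieces = nxt
    return [(a, b) for a, b in pieces if b - a > 1e-9]


def extract_interictal(records: list[EEGRecord],
                       annotations: list[SeizureAnnotation],
                       guard_s: float = DEFAULT_GUARD_S) -> list[LabeledSegment]:
    """Maximal sub-intervals at distance ≥ guard_s from every seizure boundary."""
    holes = [(a.onset_s - guard_s, a.offset_s + guard_s) for a in annotations]
    segments: list[LabeledSegment] = []
    for rec in records:
        for s0, s1 in _subtract_intervals((rec.t0, rec.t_end), holes):
            segments.append(LabeledSegment(rec, s0, s1, INTERICTAL))
    return segments


def extract_preictal(records: list[EEGRecord],
                     annotations: list[SeizureAnnotation],
                     sop_s: float = DEFAULT_SOP_S,
                     sph_s: float = DEFAULT_SPH_S) -> list[LabeledSegment]:
    """Per seizure, the window [onset − (SOP+SPH), onset − SPH), clipped.

    The window is clipped to the end of the previous seizure (no preictal data
    from inside an earlier ictal span) and truncated at record edges; a
    seizure whose window is entirely swallowed is skipped.
    """
    if sop_s <= 0 or sph_s < 0:
        raise ValueError("need sop_s > 0 and sph_s >= 0")
    ordered = sorted(annotations, key=lambda a: a.onset_s)
    segments: list[LabeledSegment] = []
    for idx, ann in enumerate(ordered):
        w0 = ann.onset_s - (sop_s + sph_s)
        w1 = ann.onset_s - sph_s
        if idx > 0:
            w0 = max(w0, ordered[idx - 1].offset_s)
        w0 = max(w0, 0.0)
        if w1 - w0 <= 1e-9:
            continue
        for rec in records:
            s0, s1 = max(w0, rec.t0), min(w1, rec.t_end)
            if s1 - s0 > 1e-9:
                segments.append(LabeledSegment(rec, s0, s1, PREICTAL, seizure_index=idx))
    return segments


def filter_subjects_by_seizure_count(subjects: dict[str, list[SeizureAnnotation]],
                                     max_seizures: int = 10) -> dict[str, list[SeizureAnnotation]]:
    """Optionally drop subjects with more than `max_seizures` seizures.

    Subjects whose seizures cluster too densely leave little usable data
    between events; this filter mirrors that exclusion rule. Off by default in
    the synthetic pipeline.
    """
    return {k: v for k, v in subjects.items() if len(v) <= max_seizures}
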