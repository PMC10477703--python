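"""Minimal 16-bit EDF writer.

Writes standard EDF (not EDF+) with a 1-second data-record, one int16 signal
per EEG channel and physical units of µV. Reading goes through mne (see
:func:`preictal.eeg_io.read_edf`), so write/read round-trips exercise two
independent codecs. Amplitude resolution is the 16-bit quantisation step of
each channel's physical range.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .eeg_io import EEGRecord

DIG_MIN, DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        b = b[:width]
    return b.ljust(width)


def write_edf(record: EEGRecord, path) -> None:
    """Write `record` to `path`; trailing partial seconds are truncated."""
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = record.n_channels
    n_records = record.data.shape[1] // fs
    if n_records < 1:
        raise ValueError("record shorter than one EDF data record (1 s)")
    data = np.asarray(record.data[:, : n_records * fs], dtype=np.float64)

    phys_min = np.floor(np.minimum(data.min(axis=1), -1.0))
    phys_max = np.ceil(np.maximum(data.max(axis=1), 1.0))
    scale = (DIG_MAX - DIG_MIN) / (phys_max - phys_min)
    digital = np.clip(np.rint((data - phys_min[:, None]) * scale[:, None] + DIG_MIN),
                      DIG_MIN, DIG_MAX).astype("<i2")

    header_bytes = 256 + 256 * n_ch
    with open(Path(path), "wb") as f:
        f.write(_field("0", 8))
        f.write(_field("X X X X", 80))                      # patient id
        f.write(_field("Startdate X X X X", 80))            # recording id
        f.write(_field("01.01.00", 8))
        f.write(_field("00.00.00", 8))
        f.write(_field(str(header_bytes), 8))
        f.write(_field("", 44))
        f.write(_field(str(n_records), 8))
        f.write(_field("1", 8))                             # record duration, s
        f.write(_field(str(n_ch), 4))
        for lab in record.channel_labels:
            f.write(_field(lab, 16))
        for _ in range(n_ch):
            f.write(_field("", 80))                         # transducer
        for _ in range(n_ch):
            f.write(_field("uV", 8))
        for v in phys_min:
            f.write(_field(f"{v:.0f}", 8))
        for v in phys_max:
            f.write(_field(f"{v:.0f}", 8))
        for _ in range(n_ch):
            f.write(_field(str(DIG_MIN), 8))
        for _ in range(n_ch):
            f.write(_field(str(DIG_MAX), 8))
        for _ in range(n_ch):
            f.write(_field("", 80))                         # prefiltering
        for _ in range(n_ch):
            f.write(_field(str(fs), 8))
        for _ in range(n_ch):
            f.write(_field("", 32))
        # data records: per record, each signal's fs samples contiguously
        view = digital.reshape(n_ch, n_records, fs)
        for r in range(n_records):
            f.write(view[:, r, :].tobytes())


def quantization_step(record: EEGRecord) -> np.ndarray:
    """Per-channel physical µV per digital unit for the ranges write_edf picks."""
    data = np.asarray(record.data, dtype=np.float64)
    phys_min = np.floor(np.minimum(data.min(axis=1), -1.0))
    phys_max = np.ceil(np.maximum(data.max(axis=1), 1.0))
    return (phys_max - phys_min) / (DIG_MAX - DIG_MIN)
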