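"""Annotated synthetic scalp EEG with a controllable preictal signature.

The generator emulates the statistical structure the classifier relies on,
with no real data:

* stationary interictal background per channel: 1/f^α Gaussian noise plus a
  10 Hz alpha oscillator, in µV;
* 60 Hz power-line contamination on every channel (removed later by the
  preprocessing band filter);
* a preictal period before each seizure onset in which band-limited noise is
  added to a subset of channels, scaling band power by (1 + signature_gain) —
  only some channels are informative, which is what channel attention is for;
* a high-amplitude 3 Hz spike-wave ictal segment at each onset (used only to
  test exclusion logic; the classifier never trains on it).

Each channel is driven by its own child of the global seed, so adding
channels never perturbs earlier channels, and the preictal/ictal components
draw from further dedicated substreams, so changing ``signature_gain`` never
perturbs the background.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .eeg_io import EEGRecord, SeizureAnnotation

#: CHB-MIT-style bipolar montage labels for the default 22-channel layout.
CHB_LABELS_22 = [
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1", "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2", "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ", "P7-T7", "T7-FT9", "FT9-FT10", "FT10-T8",
]


@dataclasses.dataclass
class SyntheticSubjectSpec:
    """Generation parameters for one synthetic subject.

    Defaults mirror the reference recording setup (22 channels at 256 Hz) and
    the timing conventions of the pipeline (35-minute preictal horizon); the
    signature defaults (20–40 Hz band, gain 3 on four focal channels) give a
    clearly learnable but channel-sparse class difference.
    """

    duration_s: float
    seizure_onsets_s: Sequence[float]
    n_channels: int = 22
    fs: float = 256.0
    preictal_horizon_s: float = 2100.0
    affected_channels: Sequence[int] = (0, 1, 2, 3)
    signature_band_hz: tuple[float, float] = (20.0, 40.0)
    signature_gain: float = 3.0
    line_noise_amp: float = 5.0      # µV
    background_alpha: float = 1.0    # 1/f^α exponent
    noise_sd: float = 10.0           # µV
    ictal_duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self):
        self.seizure_onsets_s = sorted(float(t) for t in self.seizure_onsets_s)
        lo, hi = self.signature_band_hz
        if not 0 <= lo < hi:
            raise ValueError("signature band must satisfy 0 <= low < high")
        if self.fs <= 2 * hi:
            raise ValueError("sampling rate must exceed twice the signature band edge")
        if self.signature_gain < 0:
            raise ValueError("signature_gain must be >= 0")
        if any(c < 0 or c >= self.n_channels for c in self.affected_channels):
            raise ValueError("affected_channels must lie in [0, n_channels)")
        for t in self.seizure_onsets_s:
            if not (0 < t < self.duration_s):
                raise ValueError(f"onset {t} outside (0, {self.duration_s})")
        if self.seizure_onsets_s and self.duration_s < self.preictal_horizon_s:
            raise ValueError("record too short to hold a preictal horizon")
        for prev, nxt in zip(self.seizure_onsets_s, self.seizure_onsets_s[1:]):
            if nxt - self.preictal_horizon_s < prev + self.ictal_duration_s:
                raise ValueError(
                    f"preictal horizon of onset {nxt} overlaps the seizure at {prev}")

    def channel_labels(self) -> list[str]:
        if self.n_channels == 22:
            return list(CHB_LABELS_22)
        return [f"CH{i + 1:02d}" for i in range(self.n_channels)]


def _colored_noise(rng: np.random.Generator, n: int, alpha: float, sd: float) -> np.ndarray:
    """1/f^alpha Gaussian noise with standard deviation `sd`."""
    white = rng.standard_normal(n)
    if alpha == 0:
        return sd * white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-alpha / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return sd * x / x.std()


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    nper = min(len(x), 1024)
    f, pxx = sps.welch(x, fs=fs, nperseg=nper)
    mask = (f >= band[0]) & (f <= band[1])
    return float(pxx[mask].mean())


def generate_subject(spec: SyntheticSubjectSpec) -> tuple[EEGRecord, list[SeizureAnnotation]]:
    """Generate one continuous annotated record; bit-deterministic per seed."""
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    root = np.random.SeedSequence(spec.seed)
    chan_seeds = root.spawn(spec.n_channels)
    line = spec.line_noise_amp * np.sin(2 * np.pi * 60.0 * t)

    annotations = []
    for onset in spec.seizure_onsets_s:
        annotations.append(SeizureAnnotation(onset, min(onset + spec.ictal_duration_s,
                                                        spec.duration_s)))

    ictal_wave = None
    if annotations:
        # 3 Hz spike-wave: fundamental plus decaying harmonics
        ictal_wave = (np.sin(2 * np.pi * 3.0 * t) + 0.6 * np.sin(2 * np.pi * 6.0 * t)
                      + 0.3 * np.sin(2 * np.pi * 9.0 * t)) * 6.0 * spec.noise_sd

    sos = None
    if spec.affected_channels and spec.seizure_onsets_s:
        sos = sps.butter(4, spec.signature_band_hz, btype="bandpass",
                         fs=spec.fs, output="sos")

    data = np.empty((spec.n_channels, n), dtype=np.float32)
    for ch in range(spec.n_channels):
        ss_bg, ss_sig = chan_seeds[ch].spawn(2)
        rng = np.random.default_rng(ss_bg)
        bg = _colored_noise(rng, n, spec.background_alpha, spec.noise_sd)
        bg += spec.noise_sd * np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
        x = bg + line
        if ch in spec.affected_channels and spec.signature_gain > 0 and sos is not None:
            p_bg = _band_power(bg, spec.fs, spec.signature_band_hz)
            rng_sig = np.random.default_rng(ss_sig)
            for onset in spec.seizure_onsets_s:
                i1 = int(round(onset * spec.fs))
                i0 = max(0, int(round((onset - spec.preictal_horizon_s) * spec.fs)))
                raw = rng_sig.standard_normal(i1 - i0)
                sig = sps.sosfiltfilt(sos, raw)
                p_sig = _band_power(sig, spec.fs, spec.signature_band_hz)
                sig *= np.sqrt(spec.signature_gain * p_bg / p_sig)
                x[i0:i1] += sig
        if ictal_wave is not None:
            for ann in annotations:
                j0 = int(round(ann.onset_s * spec.fs))
                j1 = int(round(ann.offset_s * spec.fs))
                x[j0:j1] += ictal_wave[j0:j1]
        data[ch] = x.astype(np.float32)

    record = EEGRecord(data=data, fs=spec.fs, channel_labels=spec.channel_labels(), t0=0.0)
    return record, annotations


def spectral_power(record: EEGRecord, channel: int, band: tuple[float, float],
                   interval: tuple[float, float]) -> float:
    """Mean Welch periodogram power of one channel in `band` over `interval` (s)."""
    lo, hi = band
    if lo >= hi:
        raise ValueError("empty frequency band")
    x = record.slice_abs(*interval)[channel].astype(np.float64)
    return _band_power(x, record.fs, band)


def preictal_seconds(spec: SyntheticSubjectSpec) -> float:
    """Total preictal seconds implied by the spec (horizon per seizure, minus
    truncation at record start and clipping at the previous ictal end)."""
    total = 0.0
    prev_offset = 0.0
    for onset in spec.seizure_onsets_s:
        start = max(onset - spec.preictal_horizon_s, prev_offset, 0.0)
        total += max(onset - start, 0.0)
        prev_offset = onset + spec.ictal_duration_s
    return total


def split_record(record: EEGRecord, chunk_s: float) -> list[EEGRecord]:
    """Split one record into consecutive chunks (for multi-file EDF layouts)."""
    n_chunk = int(round(chunk_s * record.fs))
    out = []
    for i0 in range(0, record.data.shape[1], n_chunk):
        piece = record.data[:, i0:i0 + n_chunk]
        if piece.shape[1] == 0:
            break
        out.append(EEGRecord(data=piece, fs=record.fs,
                             channel_labels=list(record.channel_labels),
                             t0=record.t0 + i0 / record.fs))
    return out
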