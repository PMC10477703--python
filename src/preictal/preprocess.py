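"""30-s STFT spectrogram windows with line-noise bands removed.

Each labelled segment is cut into 30-second windows (non-overlapping for
interictal; a finer stride for preictal oversampling, see
:func:`balance_preictal`). Every window is transformed per channel with a
short-time Fourier transform (1-s Hann segments, 50% overlap → 59 time frames
at 1 Hz frequency resolution), and the magnitude is kept. Power-line bins
(57–63 Hz and 117–123 Hz, bin centres in the closed interval) and the DC bin
are deleted, leaving 114 of the 129 one-sided bins at 256 Hz. The output
orientation is (channel, time, frequency): 59 × 114 spatial maps. No log
transform is applied — the network's input batch-norm absorbs overall scale.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import signal as sps

from .eeg_io import INTERICTAL, PREICTAL, LabeledSegment

DEFAULT_WIN_S = 30.0


@dataclasses.dataclass
class StftConfig:
    window_len_s: float = DEFAULT_WIN_S
    nperseg: int = 256
    noverlap: int = 128
    removed_bands: tuple[tuple[float, float], ...] = ((57.0, 63.0), (117.0, 123.0))
    drop_dc: bool = True

    def __post_init__(self):
        if self.noverlap >= self.nperseg:
            raise ValueError("noverlap must be smaller than nperseg")

    def retained_bins(self, fs: float) -> np.ndarray:
        """Boolean mask over the one-sided bins that survive band removal."""
        freqs = np.fft.rfftfreq(self.nperseg, d=1.0 / fs)
        keep = np.ones(len(freqs), dtype=bool)
        if self.drop_dc:
            keep[0] = False
        for lo, hi in self.removed_bands:
            if not (0 <= lo <= hi <= fs / 2):
                raise ValueError(f"removed band ({lo}, {hi}) outside [0, fs/2]")
            keep &= ~((freqs >= lo) & (freqs <= hi))
        return keep

    def n_frames(self, fs: float) -> int:
        n = int(round(self.window_len_s * fs))
        return (n - self.nperseg) // (self.nperseg - self.noverlap) + 1


@dataclasses.dataclass
class SpectrogramWindow:
    """One model-ready window: (channels, time frames, frequency bins)."""

    x: np.ndarray
    label: int                      # 0 interictal, 1 preictal
    t_start: float
    seizure_index: int | None = None


@dataclasses.dataclass
class RawWindow:
    """A 30-s slab of samples awaiting the STFT."""

    samples: np.ndarray             # (channels, win_s * fs)
    label: int
    t_start: float
    seizure_index: int | None = None


def segment_windows(segment: LabeledSegment, win_s: float = DEFAULT_WIN_S,
                    stride_s: float = DEFAULT_WIN_S) -> list[RawWindow]:
    """Cut a segment into windows of exactly win_s·fs samples at the stride.

    Windows never straddle the segment boundary. A too-short segment yields an
    empty list (with a warning), not an error.
    """
    if stride_s <= 0:
        raise ValueError("stride must be positive")
    fs = segment.record.fs
    n_win = int(round(win_s * fs))
    dur = segment.duration_s
    if dur < win_s:
        warnings.warn(f"segment of {dur:.1f}s shorter than the {win_s:.0f}s window; skipped",
                      stacklevel=2)
        return []
    count = int(np.floor((dur - win_s) / stride_s)) + 1
    label = 1 if segment.label == PREICTAL else 0
    data = segment.samples()
    out = []
    stride_samp = stride_s * fs
    for i in range(count):
        i0 = int(round(i * stride_samp))
        if i0 + n_win > data.shape[1]:
            break
        out.append(RawWindow(samples=data[:, i0:i0 + n_win], label=label,
                             t_start=segment.start_s + i0 / fs,
                             seizure_index=segment.seizure_index))
    return out


def stft_spectrogram(samples: np.ndarray, fs: float,
                     cfg: StftConfig | None = None) -> np.ndarray:
    """Per-channel magnitude STFT of one window → (channels, frames, kept bins)."""
    cfg = cfg or StftConfig()
    samples = np.asarray(samples)
    if np.isnan(samples).any():
        raise ValueError("NaN in window samples")
    _, _, Z = sps.stft(samples, fs=fs, nperseg=cfg.nperseg, noverlap=cfg.noverlap,
                       boundary=None, padded=False)
    mag = np.abs(Z)                                  # (channels, bins, frames)
    keep = cfg.retained_bins(fs)
    mag = mag[:, keep, :]
    return np.ascontiguousarray(mag.transpose(0, 2, 1).astype(np.float32))


def spectrogram_windows(raw: list[RawWindow], fs: float,
                        cfg: StftConfig | None = None) -> list[SpectrogramWindow]:
    return [SpectrogramWindow(x=stft_spectrogram(w.samples, fs, cfg), label=w.label,
                              t_start=w.t_start, seizure_index=w.seizure_index)
            for w in raw]


def oversample_stride(total_duration_s: float, n_segments: int, target_count: int,
                      fs: float, win_s: float = DEFAULT_WIN_S) -> float:
    """Stride (s) so that ~target_count windows tile the preictal data.

    For one contiguous segment of duration D this is (D − win) / (target − 1),
    snapped down to a whole number of samples; for several segments the
    aggregate analogue (D_total − m·win) / (target − m) is used.
    """
    if target_count <= n_segments:
        return win_s
    s = (total_duration_s - n_segments * win_s) / (target_count - n_segments)
    s = max(np.floor(s * fs) / fs, 1.0 / fs)
    return min(s, win_s)


def balance_preictal(preictal_segments: list[LabeledSegment], target_count: int,
                     win_s: float = DEFAULT_WIN_S) -> list[RawWindow]:
    """Oversample preictal segments with a finer sliding stride.

    Chooses one common stride so the output count lands within about ±1 of
    `target_count` (snapping the stride to whole samples can add a window per
    segment when several segments are involved). target_count must be at least
    the non-overlapped count.
    """
    usable = [s for s in preictal_segments if s.duration_s >= win_s]
    if not usable:
        raise ValueError("no preictal segment reaches one window length")
    total = sum(s.duration_s for s in usable)
    fs = usable[0].record.fs
    base = sum(int(np.floor((s.duration_s - win_s) / win_s)) + 1 for s in usable)
    if target_count < base:
        raise ValueError(f"target_count {target_count} below non-overlapped count {base}")
    stride = oversample_stride(total, len(usable), target_count, fs, win_s)
    out: list[RawWindow] = []
    for seg in usable:
        out.extend(segment_windows(seg, win_s=win_s, stride_s=stride))
    return out
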