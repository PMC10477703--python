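"""Leave-one-seizure-out training of the spectrogram classifier.

For a subject with N seizures, each fold holds out one seizure's preictal
segments together with one temporal block of interictal data (the interictal
pool is partitioned into N contiguous blocks, so test interictal never
overlaps training interictal). Within a fold the training data is split
75/25 in time order — the last quarter of each class is the validation set —
and only then is the training-side preictal oversampled to match the
interictal window count, so near-duplicate overlapping windows can never
leak across the train/validation boundary.

Training runs mini-batch cross-entropy with the Lion optimizer (or Adam for
the ablation), monitors validation loss, stops early after
`early_stop_patience` epochs without improvement, and restores the
best-validation checkpoint.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .eeg_io import LabeledSegment
from .lion import Adam, Lion, LionHyper
from .model import CbamGruNet
from .preprocess import (RawWindow, SpectrogramWindow, StftConfig,
                         balance_preictal, segment_windows, spectrogram_windows)


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 64
    epochs: int = 50
    val_fraction: float = 0.25
    early_stop_patience: int = 10
    optimizer: str = "lion"          # "lion" | "adam"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.early_stop_patience > self.epochs:
            raise ValueError("patience must not exceed the epoch budget")
        if self.optimizer not in ("lion", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


class EarlyStopper:
    """Stop after `patience` consecutive epochs without validation improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self.stall = 0

    def update(self, val_loss: float, epoch: int) -> bool:
        """Record one epoch; returns True when training should stop (improvement
        is strict; the first epoch always improves on the +inf sentinel)."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self.stall = 0
            return False
        self.stall += 1
        return self.stall >= self.patience

    @property
    def improved(self) -> bool:
        return self.stall == 0


@dataclasses.dataclass
class FoldPlan:
    """One leave-one-seizure-out fold."""

    seizure_index: int
    train_preictal: list[LabeledSegment]
    train_interictal: list[LabeledSegment]
    test_preictal: list[LabeledSegment]
    test_interictal: list[LabeledSegment]


def _sorted(segments: list[LabeledSegment]) -> list[LabeledSegment]:
    return sorted(segments, key=lambda s: s.start_s)


def _split_at_fraction(segments: list[LabeledSegment],
                       fraction: float) -> tuple[list[LabeledSegment], list[LabeledSegment]]:
    """Cut a time-ordered segment list at a cumulative-duration fraction."""
    segments = _sorted(segments)
    total = sum(s.duration_s for s in segments)
    cut = total * fraction
    head: list[LabeledSegment] = []
    tail: list[LabeledSegment] = []
    acc = 0.0
    for seg in segments:
        if acc + seg.duration_s <= cut + 1e-9:
            head.append(seg)
        elif acc >= cut - 1e-9:
            tail.append(seg)
        else:
            t_cut = seg.start_s + (cut - acc)
            head.append(dataclasses.replace(seg, end_s=t_cut))
            tail.append(dataclasses.replace(seg, start_s=t_cut))
        acc += seg.duration_s
    return head, tail


def partition_interictal(segments: list[LabeledSegment], k: int) -> list[list[LabeledSegment]]:
    """Partition interictal segments into k contiguous temporal blocks of equal duration."""
    blocks: list[list[LabeledSegment]] = []
    rest = _sorted(segments)
    for i in range(k, 1, -1):
        head, rest = _split_at_fraction(rest, 1.0 / i)
        blocks.append(head)
    blocks.append(rest)
    return blocks


def make_folds(preictal_segments: list[LabeledSegment],
               interictal_segments: list[LabeledSegment]) -> list[FoldPlan]:
    """One fold per seizure; interictal partitioned into disjoint temporal blocks."""
    by_seizure: dict[int, list[LabeledSegment]] = {}
    for seg in preictal_segments:
        by_seizure.setdefault(seg.seizure_index, []).append(seg)
    indices = sorted(by_seizure)
    if len(indices) < 2:
        raise ValueError(f"leave-one-seizure-out needs >= 2 seizures with preictal data, "
                         f"got {len(indices)}")
    blocks = partition_interictal(interictal_segments, len(indices))
    folds = []
    for pos, idx in enumerate(indices):
        folds.append(FoldPlan(
            seizure_index=idx,
            train_preictal=[s for j in indices if j != idx for s in by_seizure[j]],
            train_interictal=[s for p, b in enumerate(blocks) if p != pos for s in b],
            test_preictal=by_seizure[idx],
            test_interictal=blocks[pos],
        ))
    return folds


def _windows_to_arrays(windows: list[SpectrogramWindow]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([w.x for w in windows]).astype(np.float32)
    y = np.array([w.label for w in windows], dtype=np.int64)
    return X, y


def _nonoverlap_windows(segments: list[LabeledSegment], fs: float,
                        stft_cfg: StftConfig) -> list[SpectrogramWindow]:
    raw: list[RawWindow] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seg in _sorted(segments):
            raw.extend(segment_windows(seg, win_s=stft_cfg.window_len_s))
    return spectrogram_windows(raw, fs, stft_cfg)


def _xentropy(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, 1.0)
    return float(-np.log(p).mean())


def train_fold(fold: FoldPlan, net_kwargs: dict, cfg: TrainConfig,
               stft_cfg: StftConfig | None = None,
               lion_hyper: LionHyper | None = None) -> tuple[CbamGruNet, dict]:
    """Train one fold; returns the best-validation network and the history."""
    stft_cfg = stft_cfg or StftConfig()
    fs = fold.train_interictal[0].record.fs if fold.train_interictal else \
        fold.train_preictal[0].record.fs

    pre_train_segs, pre_val_segs = _split_at_fraction(fold.train_preictal,
                                                      1.0 - cfg.val_fraction)
    int_train_segs, int_val_segs = _split_at_fraction(fold.train_interictal,
                                                      1.0 - cfg.val_fraction)

    int_train = _nonoverlap_windows(int_train_segs, fs, stft_cfg)
    target = max(len(int_train), 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = sum(int(np.floor((s.duration_s - stft_cfg.window_len_s)
                                / stft_cfg.window_len_s)) + 1
                   for s in pre_train_segs if s.duration_s >= stft_cfg.window_len_s)
        pre_raw = balance_preictal(pre_train_segs, max(target, base),
                                   win_s=stft_cfg.window_len_s)
    pre_train = spectrogram_windows(pre_raw, fs, stft_cfg)

    train_windows = int_train + pre_train
    val_windows = _nonoverlap_windows(int_val_segs, fs, stft_cfg) + \
        _nonoverlap_windows(pre_val_segs, fs, stft_cfg)
    if not train_windows or not val_windows:
        raise ValueError("empty training or validation set")
    X, y = _windows_to_arrays(train_windows)
    Xv, yv = _windows_to_arrays(val_windows)
    del train_windows, val_windows, int_train, pre_train, pre_raw
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")

    rng = np.random.default_rng(cfg.seed)
    kw = dict(net_kwargs)
    kw.setdefault("seed", int(rng.integers(2**31)))
    net = CbamGruNet(**kw)
    if cfg.optimizer == "lion":
        opt = Lion(net.parameters, lion_hyper or LionHyper(), net.decay_mask())
    else:
        opt = Adam(net.parameters)

    history = {"train_loss": [], "val_loss": [], "val_acc": []}
    stopper = EarlyStopper(cfg.early_stop_patience)
    best_state = net.state_dict()
    n = len(X)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo: lo + cfg.batch_size]
            net.zero_grad()
            loss = net.loss(X[idx], y[idx], rng=rng)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        pv = net.predict_proba(Xv)
        val_loss = _xentropy(pv, yv)
        val_acc = float((pv.argmax(axis=1) == yv).mean())
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        stop = stopper.update(val_loss, epoch)
        if stopper.improved:
            best_state = net.state_dict()
        if stop:
            break
    net.load_state_dict(best_state)
    history["best_epoch"] = stopper.best_epoch
    history["epochs_run"] = len(history["val_loss"])
    return net, history


@dataclasses.dataclass
class PredictionSeries:
    """Window predictions at the 30-s cadence for one contiguous segment."""

    t_start: float
    times: np.ndarray                # window start times, s
    probs: np.ndarray                # (N, 2): (p_interictal, p_preictal)
    truth: np.ndarray                # window labels
    label: str                       # segment label
    seizure_index: int | None


def predict_series(net: CbamGruNet, segments: list[LabeledSegment],
                   stft_cfg: StftConfig | None = None) -> list[PredictionSeries]:
    """Non-overlapping 30-s predictions per contiguous segment, time-ordered."""
    stft_cfg = stft_cfg or StftConfig()
    out = []
    for seg in _sorted(segments):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = segment_windows(seg, win_s=stft_cfg.window_len_s)
        if not raw:
            continue
        wins = spectrogram_windows(raw, seg.record.fs, stft_cfg)
        X, truth = _windows_to_arrays(wins)
        probs = net.predict_proba(X)
        out.append(PredictionSeries(
            t_start=seg.start_s,
            times=np.array([w.t_start for w in wins]),
            probs=probs, truth=truth, label=seg.label,
            seizure_index=seg.seizure_index))
    return out
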