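"""Alarm post-processing and SPH/SOP evaluation.

Window probabilities (one pair every 30 s) become binary labels, the k-of-n
rule turns labels into alarms (raise when ≥ k of the trailing n windows are
preictal; k=8, n=10 by default), and each alarm is adjudicated against the
seizure onsets: it is a true prediction iff no onset falls inside the
prediction horizon (SPH, 5 min) after the alarm and at least one onset falls
inside the occurrence period (SOP, 30 min) that follows the horizon;
otherwise it is a false alarm. After any alarm a refractory span of SPH+SOP
suppresses further alarms, so one anticipation window yields one alarm.

Window-level scoring uses the standard confusion-matrix metrics
(sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
accuracy = (TP+TN)/total), ROC AUC on the preictal probabilities, and the
false-alarm rate per interictal hour.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclasses.dataclass
class AlarmConfig:
    sph_s: float = 300.0
    sop_s: float = 1800.0
    k: int = 8
    n: int = 10
    cadence_s: float = 30.0
    refractory_s: float | None = None   # defaults to sop_s + sph_s

    def __post_init__(self):
        if not (0 < self.k <= self.n):
            raise ValueError("need 0 < k <= n")
        if self.sph_s <= 0 or self.sop_s <= 0:
            raise ValueError("SPH and SOP must be positive")
        if self.refractory_s is None:
            self.refractory_s = self.sop_s + self.sph_s


@dataclasses.dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)


@dataclasses.dataclass
class AlarmEvent:
    time_s: float
    verdict: str                     # "true_prediction" | "false_alarm"
    matched_seizure: int | None = None

    def __post_init__(self):
        if self.verdict not in ("true_prediction", "false_alarm"):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.verdict == "true_prediction" and self.matched_seizure is None:
            raise ValueError("true predictions must reference a seizure")


@dataclasses.dataclass
class EvalReport:
    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    auc: float | None
    event_sensitivity: float | None  # predicted seizures / evaluable seizures
    fpr_per_h: float | None
    n_seizures: int = 0
    n_predicted: int = 0
    interictal_hours: float = 0.0

    def to_dict(self) -> dict:
        return {
            "counts": dataclasses.asdict(self.counts),
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "auc": self.auc,
            "event_sensitivity": self.event_sensitivity, "fpr_per_h": self.fpr_per_h,
            "n_seizures": self.n_seizures, "n_predicted": self.n_predicted,
            "interictal_hours": self.interictal_hours,
        }


def classify_windows(probs: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Binary labels from (N, 2) probability pairs.

    Default rule: preictal iff p_pre > p_inter; ties go to interictal
    (conservative toward fewer false alarms). A scalar threshold on p_pre is
    available for ROC sweeps (label 1 iff p_pre > threshold).
    """
    probs = np.asarray(probs)
    if probs.ndim != 2 or probs.shape[1] != 2:
        raise ValueError("expected (N, 2) probability pairs")
    if threshold is None:
        return (probs[:, 1] > probs[:, 0]).astype(np.int64)
    return (probs[:, 1] > threshold).astype(np.int64)


def kofn_alarms(labels: np.ndarray, cfg: AlarmConfig, t0: float = 0.0) -> list[float]:
    """Alarm times from a time-ordered binary label series at cfg.cadence_s.

    At the end of each window, positives among the trailing (up to) n windows
    are counted; reaching k outside a refractory span raises an alarm at that
    timestamp and opens a refractory span of cfg.refractory_s.
    """
    labels = np.asarray(labels, dtype=np.int64)
    alarms: list[float] = []
    refractory_until = -np.inf
    for i in range(len(labels)):
        t = t0 + (i + 1) * cfg.cadence_s
        if t < refractory_until:
            continue
        window = labels[max(0, i + 1 - cfg.n): i + 1]
        if int(window.sum()) >= cfg.k:
            alarms.append(t)
            refractory_until = t + cfg.refractory_s
    return alarms


def adjudicate(alarm_times: list[float], onsets: list[float],
               cfg: AlarmConfig) -> tuple[list[AlarmEvent], list[bool]]:
    """Label each alarm true/false and flag which seizures were predicted.

    Alarm at t is a true prediction iff no onset lies in (t, t+SPH] and at
    least one onset lies in (t+SPH, t+SPH+SOP].
    """
    onsets = sorted(onsets)
    predicted = [False] * len(onsets)
    events: list[AlarmEvent] = []
    for t in alarm_times:
        in_sph = any(t < o <= t + cfg.sph_s for o in onsets)
        matched = None
        for j, o in enumerate(onsets):
            if t + cfg.sph_s < o <= t + cfg.sph_s + cfg.sop_s:
                matched = j
                break
        if not in_sph and matched is not None:
            events.append(AlarmEvent(t, "true_prediction", matched))
            predicted[matched] = True
        else:
            events.append(AlarmEvent(t, "false_alarm"))
    return events, predicted


def window_metrics(c: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(sensitivity, specificity, accuracy); None where the denominator is 0."""
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else None
    total = c.TP + c.TN + c.FP + c.FN
    acc = (c.TP + c.TN) / total if total > 0 else None
    return sens, spec, acc


def confusion_from_predictions(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    return ConfusionCounts(
        TP=int(((pred == 1) & (truth == 1)).sum()),
        FP=int(((pred == 1) & (truth == 0)).sum()),
        TN=int(((pred == 0) & (truth == 0)).sum()),
        FN=int(((pred == 0) & (truth == 1)).sum()),
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC of preictal scores; equals the Mann-Whitney pair statistic."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores)))


def fpr_per_hour(n_false_alarms: int, interictal_duration_s: float) -> float:
    if interictal_duration_s <= 0:
        raise ValueError("interictal duration must be positive")
    return n_false_alarms / (interictal_duration_s / 3600.0)
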