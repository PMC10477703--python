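"""k-of-n alarms, SPH/SOP adjudication, and window metrics vs oracles."""

import numpy as np
import pytest

from preictal.alarms import (AlarmConfig, ConfusionCounts, adjudicate,
                             classify_windows, confusion_from_predictions,
                             fpr_per_hour, kofn_alarms, roc_auc, window_metrics)

CFG = AlarmConfig()   # SPH 300, SOP 1800, k=8, n=10, 30-s cadence


def kofn_oracle(labels, cfg, t0=0.0):
    """Independent re-statement of the alarm rule: at each window end count
    positives among the trailing up-to-n windows; >= k and out of refractory
    raises an alarm and suppresses others for refractory_s."""
    alarms = []
    for i in range(len(labels)):
        t = t0 + (i + 1) * cfg.cadence_s
        recent = [labels[j] for j in range(max(0, i - cfg.n + 1), i + 1)]
        if sum(recent) >= cfg.k and all(t - a >= cfg.refractory_s for a in alarms):
            alarms.append(t)
    return alarms


class TestClassify:
    def test_majority_probability_wins(self):
        assert classify_windows(np.array([[0.3, 0.7]]))[0] == 1

    def test_tie_goes_to_interictal(self):
        assert classify_windows(np.array([[0.5, 0.5]]))[0] == 0

    def test_threshold_sweep_is_monotone(self, rng):
        probs = rng.random((200, 1))
        probs = np.hstack([1 - probs, probs])
        counts = [classify_windows(probs, threshold=th).sum()
                  for th in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestKofN:
    def test_eight_consecutive_positives_raise_one_alarm(self):
        labels = [1] * 8 + [0, 0]
        alarms = kofn_alarms(labels, CFG)
        # trailing count first reaches 8 at the 8th window's end
        assert alarms == [8 * 30.0]

    def test_all_zero_labels_raise_nothing(self):
        assert kofn_alarms([0] * 500, CFG) == []

    def test_constant_positives_space_alarms_by_refractory(self):
        labels = [1] * 240                       # 2 h at 30 s
        alarms = kofn_alarms(labels, CFG)
        assert len(alarms) >= 2
        diffs = np.diff(alarms)
        assert np.allclose(diffs, CFG.refractory_s)

    def test_matches_bruteforce_enumeration_on_random_sequences(self, rng):
        for trial in range(1000):
            n_lab = int(rng.integers(1, 40))
            labels = rng.integers(0, 2, n_lab).tolist()
            k = int(rng.integers(1, 11))
            n = int(rng.integers(k, 12))
            cfg = AlarmConfig(k=k, n=n, refractory_s=float(rng.choice([60, 300, 2100])))
            assert kofn_alarms(labels, cfg) == kofn_oracle(labels, cfg), \
                f"trial {trial}: labels={labels} k={k} n={n}"

    def test_alarm_count_non_increasing_in_k(self, rng):
        labels = rng.integers(0, 2, 300).tolist()
        counts = [len(kofn_alarms(labels, AlarmConfig(k=k, n=10))) for k in range(1, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_k_n_rejected(self):
        with pytest.raises(ValueError):
            AlarmConfig(k=11, n=10)
        with pytest.raises(ValueError):
            AlarmConfig(k=0, n=10)


class TestAdjudicate:
    def test_onset_inside_sop_is_true_prediction(self):
        events, predicted = adjudicate([1000.0], [1600.0], CFG)   # onset at t+600
        assert events[0].verdict == "true_prediction"
        assert predicted == [True]

    def test_onset_inside_sph_is_false_alarm(self):
        events, predicted = adjudicate([1000.0], [1120.0], CFG)   # onset at t+120
        assert events[0].verdict == "false_alarm"
        assert predicted == [False]

    def test_no_onset_before_sop_end_is_false_alarm(self):
        events, predicted = adjudicate([1000.0], [1000.0 + 2101.0], CFG)
        assert events[0].verdict == "false_alarm"
        assert predicted == [False]

    def test_verdicts_partition_all_alarms(self, rng):
        alarms = sorted(rng.uniform(0, 20000, 50))
        onsets = sorted(rng.uniform(0, 20000, 5))
        events, _ = adjudicate(alarms, onsets, CFG)
        assert len(events) == len(alarms)
        assert all(e.verdict in ("true_prediction", "false_alarm") for e in events)
        for e in events:
            if e.verdict == "true_prediction":
                assert e.matched_seizure is not None


class TestWindowMetrics:
    def test_closed_form_example(self):
        sens, spec, acc = window_metrics(ConfusionCounts(TP=8, FN=2, TN=90, FP=10))
        assert sens == pytest.approx(0.8)
        assert spec == pytest.approx(0.9)
        assert acc == pytest.approx(98 / 110)

    def test_perfect_classifier_scores_one(self):
        sens, spec, acc = window_metrics(ConfusionCounts(TP=5, FN=0, TN=7, FP=0))
        assert (sens, spec, acc) == (1.0, 1.0, 1.0)

    def test_all_zero_counts_report_missing_not_error(self):
        assert window_metrics(ConfusionCounts()) == (None, None, None)

    def test_random_counts_match_arithmetic_oracle(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 50, 4))
            sens, spec, acc = window_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert sens == tp / (tp + fn)
            assert spec == tn / (tn + fp)
            assert acc == (tp + tn) / (tp + fp + tn + fn)

    def test_confusion_tally_matches_bruteforce(self, rng):
        pred = rng.integers(0, 2, 500)
        truth = rng.integers(0, 2, 500)
        c = confusion_from_predictions(pred, truth)
        assert c.TP == sum(1 for p, t in zip(pred, truth) if p == 1 and t == 1)
        assert c.FP == sum(1 for p, t in zip(pred, truth) if p == 1 and t == 0)
        assert c.TN == sum(1 for p, t in zip(pred, truth) if p == 0 and t == 0)
        assert c.FN == sum(1 for p, t in zip(pred, truth) if p == 0 and t == 1)
        assert c.TP + c.FP + c.TN + c.FN == 500


class TestAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_independent_labels_near_half(self, rng):
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            scores = np.round(rng.random(30), 2)     # force some ties
            labels = rng.integers(0, 2, 30)
            if len(np.unique(labels)) < 2:
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            pairs = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert roc_auc(scores, labels) == pytest.approx(
                pairs / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestFpr:
    def test_simple_rate(self):
        assert fpr_per_hour(2, 10 * 3600) == pytest.approx(0.2)

    def test_zero_alarms(self):
        assert fpr_per_hour(0, 3600) == 0.0

    def test_additivity_over_record_splits(self, rng):
        n1, n2 = int(rng.integers(0, 5)), int(rng.integers(0, 5))
        d1, d2 = float(rng.uniform(1, 10)) * 3600, float(rng.uniform(1, 10)) * 3600
        joint = fpr_per_hour(n1 + n2, d1 + d2)
        assert joint == pytest.approx((n1 + n2) / ((d1 + d2) / 3600))

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            fpr_per_hour(1, 0.0)
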