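"""Voting fusion, clip aggregation and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feedstream.dataio import LABELS
from feedstream.fusion import (
    FusionError,
    aggregate_clip,
    fuse,
    fuse_scores,
    run_ablation,
)
from feedstream.metrics import MetricsError, compute_metrics, confusion_matrix
from feedstream.nn.train import StreamPrediction


def pred(scores) -> StreamPrediction:
    return StreamPrediction(scores=np.asarray(scores, dtype=float))


def peaked(label_idx: int, strength: float = 0.8) -> np.ndarray:
    scores = np.full(3, (1 - strength) / 2)
    scores[label_idx] = strength
    return scores


class TestFuse:
    def test_majority_wins(self):
        result = fuse([pred(peaked(2)), pred(peaked(2)), pred(peaked(1))])
        assert result.label == "strong"
        assert result.tie_broken is False

    def test_unanimity(self):
        result = fuse([pred(peaked(0))] * 3)
        assert result.label == "none"

    def test_three_way_tie_resolved_by_score_sum(self):
        # score triples summing to (0.9, 1.2, 0.9) -> weak wins by sum
        preds = [
            pred([0.5, 0.3, 0.2]),
            pred([0.1, 0.6, 0.3]),
            pred([0.3, 0.3, 0.4]),
        ]
        result = fuse(preds)
        np.testing.assert_allclose(result.score_sums, [0.9, 1.2, 0.9])
        assert result.label == "weak"
        assert result.tie_broken is True

    def test_requires_exactly_three(self):
        with pytest.raises(FusionError, match="exactly 3"):
            fuse([pred(peaked(0)), pred(peaked(1))])

    def test_score_sum_method(self):
        preds = [pred([0.4, 0.35, 0.25])] * 2 + [pred([0.0, 0.9, 0.1])]
        assert fuse(preds, method="score_sum").label == "weak"
        assert fuse(preds, method="vote").label == "none"

    def test_matches_brute_force_rule_on_all_27_vote_patterns(self):
        # Independent oracle: explicit majority/tie logic evaluated over
        # every argmax triple.
        def oracle(votes, sums):
            counts = [votes.count(i) for i in range(3)]
            if max(counts) >= 2:
                return LABELS[counts.index(max(counts))]
            return LABELS[int(np.argmax(sums))]

        for a in range(3):
            for b in range(3):
                for c in range(3):
                    preds = [pred(peaked(a, 0.7)), pred(peaked(b, 0.6)), pred(peaked(c, 0.5))]
                    sums = np.sum([p.scores for p in preds], axis=0)
                    assert fuse(preds).label == oracle([a, b, c], sums)


class TestAggregateClip:
    def test_unanimous(self):
        assert aggregate_clip(["strong"] * 10) == "strong"

    def test_tie_breaks_toward_stronger_class(self):
        assert aggregate_clip(["weak"] * 5 + ["strong"] * 5) == "strong"
        assert aggregate_clip(["none", "weak"]) == "weak"

    def test_plurality(self):
        assert aggregate_clip(["none"] * 6 + ["weak"] * 4) == "none"

    def test_empty_rejected(self):
        with pytest.raises(FusionError, match="empty"):
            aggregate_clip([])


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        labels = ["none", "weak", "strong", "weak"]
        conf = confusion_matrix(labels, labels)
        assert (conf == np.diag([1, 2, 1])).all()

    def test_single_error_off_diagonal(self):
        conf = confusion_matrix(["none"], ["weak"])
        assert conf[0, 1] == 1
        assert conf.sum() == 1

    def test_total_conserved(self, rng):
        true = [LABELS[i] for i in rng.integers(0, 3, size=50)]
        predicted = [LABELS[i] for i in rng.integers(0, 3, size=50)]
        assert confusion_matrix(true, predicted).sum() == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(MetricsError, match="length"):
            confusion_matrix(["none"], ["none", "weak"])


class TestComputeMetrics:
    def test_hand_computed_binary_example(self):
        # TP=8, FP=2, FN=1, TN=9 for the positive class:
        # accuracy 85.0%, precision 80.0%, recall 88.9%, F1 0.842.
        conf = np.array([[9, 2], [1, 8]])  # rows: (neg, pos) truth
        report = compute_metrics(conf, labels=("neg", "pos"))
        assert report.accuracy == pytest.approx(85.0)
        pos = report.per_class["pos"]
        assert pos["tp"] == 8 and pos["fp"] == 2 and pos["fn"] == 1 and pos["tn"] == 9
        assert pos["precision"] == pytest.approx(80.0)
        assert pos["recall"] == pytest.approx(88.9, abs=0.05)
        assert pos["f1"] == pytest.approx(0.842, abs=0.0005)

    def test_identity_confusion_is_perfect(self):
        report = compute_metrics(np.diag([5, 7, 9]))
        assert report.accuracy == 100.0
        assert all(report.per_class[l]["f1"] == 1.0 for l in LABELS)

    def test_zero_support_class_excluded_with_warning(self):
        conf = np.array([[4, 0, 0], [0, 5, 0], [0, 0, 0]])
        with pytest.warns(UserWarning, match="zero support"):
            report = compute_metrics(conf)
        assert report.avg_f1 == pytest.approx(1.0)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(MetricsError, match="all zero"):
            compute_metrics(np.zeros((3, 3), dtype=int))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=1, max_size=60))
    def test_micro_precision_equals_accuracy(self, pairs):
        true = [LABELS[t] for t, _ in pairs]
        predicted = [LABELS[p] for _, p in pairs]
        conf = confusion_matrix(true, predicted)
        report = compute_metrics(conf, averaging="micro")
        assert report.avg_precision == pytest.approx(report.accuracy)
        assert report.avg_recall == pytest.approx(report.accuracy)

    def test_per_class_counts_partition_total(self, rng):
        true = [LABELS[i] for i in rng.integers(0, 3, size=80)]
        predicted = [LABELS[i] for i in rng.integers(0, 3, size=80)]
        report = compute_metrics(confusion_matrix(true, predicted))
        for lab in LABELS:
            c = report.per_class[lab]
            assert c["tp"] + c["fp"] + c["fn"] + c["tn"] == 80

    def test_agrees_with_per_item_counting_oracle(self, rng):
        # Independent oracle: count TP/FP/FN per class by item-by-item loops.
        for _ in range(100):
            n = int(rng.integers(3, 40))
            true = [LABELS[i] for i in rng.integers(0, 3, size=n)]
            predicted = [LABELS[i] for i in rng.integers(0, 3, size=n)]
            report = compute_metrics(confusion_matrix(true, predicted))
            assert report.accuracy == pytest.approx(
                100.0 * sum(t == p for t, p in zip(true, predicted)) / n
            )
            for c, lab in enumerate(LABELS):
                tp = sum(1 for t, p in zip(true, predicted) if t == lab and p == lab)
                fp = sum(1 for t, p in zip(true, predicted) if t != lab and p == lab)
                fn = sum(1 for t, p in zip(true, predicted) if t == lab and p != lab)
                got = report.per_class[lab]
                assert (got["tp"], got["fp"], got["fn"]) == (tp, fp, fn)


class TestRunAblation:
    @staticmethod
    def _scores(rng, n=30):
        true = [LABELS[i] for i in rng.integers(0, 3, size=n)]
        scores = {}
        for name in ("temporal", "spatial", "glcm"):
            raw = rng.uniform(0.05, 1.0, size=(n, 3))
            scores[name] = raw / raw.sum(axis=1, keepdims=True)
        return scores, true

    def test_seven_subsets_reported(self, rng):
        scores, true = self._scores(rng)
        reports = run_ablation(scores, true)
        assert len(reports) == 7

    def test_singleton_equals_standalone_metrics(self, rng):
        scores, true = self._scores(rng)
        reports = run_ablation(scores, true)
        predicted = [LABELS[i] for i in scores["glcm"].argmax(axis=1)]
        standalone = compute_metrics(confusion_matrix(true, predicted))
        assert reports[("glcm",)].accuracy == standalone.accuracy

    def test_missing_stream_rejected(self, rng):
        scores, true = self._scores(rng)
        del scores["spatial"]
        with pytest.raises(FusionError, match="spatial"):
            run_ablation(scores, true)

    def test_pair_uses_summed_scores(self, rng):
        scores, true = self._scores(rng, n=10)
        reports = run_ablation(scores, true, streams=("temporal", "spatial"))
        summed = scores["temporal"] + scores["spatial"]
        predicted = [LABELS[i] for i in summed.argmax(axis=1)]
        expected = compute_metrics(confusion_matrix(true, predicted))
        assert reports[("temporal", "spatial")].accuracy == expected.accuracy
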