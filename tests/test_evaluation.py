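import numpy as np
import pytest

from jawdio.audio_io import AudioSegment
from jawdio.evaluation import (
    ConfusionMatrix,
    confusion_matrix,
    precision_recall_f1,
    processing_speed,
    segment_descriptors,
)
from jawdio.synthetic import generate_segment


def brute_force_report(counts):
    """One-vs-rest TP/FP/FN enumeration, independent of the implementation."""
    counts = np.asarray(counts)
    k = counts.shape[0]
    out = []
    for c in range(k):
        tp = fp = fn = 0
        for i in range(k):
            for j in range(k):
                n = counts[i, j]
                if i == c and j == c:
                    tp += n
                elif j == c:
                    fp += n
                elif i == c:
                    fn += n
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        out.append((p, r, f))
    return out


class TestConfusionMatrix:
    def test_perfect_predictions(self):
        labels = ["bite"] * 10 + ["chew"] * 10 + ["chew_bite"] * 10
        cm = confusion_matrix(labels, labels)
        np.testing.assert_array_equal(cm.counts, np.diag([10, 10, 10]))

    def test_degenerate_single_column(self):
        true = ["bite", "chew", "chew_bite", "chew"]
        cm = confusion_matrix(true, ["chew"] * 4)
        assert cm.counts[:, 1].sum() == 4
        assert cm.counts[:, [0, 2]].sum() == 0

    def test_row_normalized_diagonal_is_recall(self):
        cm = ConfusionMatrix(np.array([[8, 1, 1], [2, 6, 2], [0, 2, 8]]))
        report = precision_recall_f1(cm)
        rates = cm.row_normalized()
        for i, label in enumerate(cm.labels):
            assert rates[i, i] == pytest.approx(report.per_class[label]["recall"])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_matrix(["bite"], ["bite", "chew"])


class TestPrecisionRecallF1:
    def test_hand_worked_example(self):
        cm = ConfusionMatrix(np.array([[8, 1, 1], [2, 6, 2], [0, 2, 8]]))
        report = precision_recall_f1(cm)
        assert report.per_class["bite"]["precision"] == pytest.approx(0.8)
        assert report.per_class["bite"]["recall"] == pytest.approx(0.8)
        assert report.per_class["bite"]["f1"] == pytest.approx(0.8)
        for label, (p, r, f) in zip(cm.labels, brute_force_report(cm.counts)):
            assert report.per_class[label]["precision"] == pytest.approx(p)
            assert report.per_class[label]["recall"] == pytest.approx(r)
            assert report.per_class[label]["f1"] == pytest.approx(f)

    def test_perfect_diagonal(self):
        report = precision_recall_f1(ConfusionMatrix(np.diag([5, 6, 7])))
        for label in ("bite", "chew", "chew_bite"):
            assert report.per_class[label] == {
                "precision": 1.0, "recall": 1.0, "f1": 1.0,
            }
        assert report.overall["f1"] == 1.0

    def test_agrees_with_oracles_on_random_matrices(self):
        """100 random 3x3 matrices vs brute force and scikit-learn."""
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(12)
        for _ in range(100):
            counts = rng.integers(0, 30, size=(3, 3))
            counts[rng.integers(0, 3), rng.integers(0, 3)] += 1  # nonempty
            cm = ConfusionMatrix(counts)
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    report = precision_recall_f1(cm)
                    weighted = precision_recall_f1(cm, averaging="weighted")
            for label, (p, r, f) in zip(cm.labels, brute_force_report(counts)):
                assert report.per_class[label]["precision"] == pytest.approx(p)
                assert report.per_class[label]["recall"] == pytest.approx(r)
                assert report.per_class[label]["f1"] == pytest.approx(f)
            # cross-check against sklearn on the equivalent label sequences
            true, pred = [], []
            for i in range(3):
                for j in range(3):
                    true += [i] * counts[i, j]
                    pred += [j] * counts[i, j]
            if counts.sum(axis=1).all():  # sklearn weighted needs full support
                skl = precision_recall_fscore_support(
                    true, pred, labels=[0, 1, 2], average="weighted",
                    zero_division=0,
                )
                assert weighted.overall["precision"] == pytest.approx(skl[0])
                assert weighted.overall["recall"] == pytest.approx(skl[1])
                assert weighted.overall["f1"] == pytest.approx(skl[2])

    def test_micro_recall_equals_accuracy(self):
        rng = np.random.default_rng(5)
        for _ in range(20)        :
            counts = rng.integers(1, 20, size=(3, 3))
            cm = ConfusionMatrix(counts)
            report = precision_recall_f1(cm, averaging="weighted")
            accuracy = np.trace(counts) / counts.sum()
            assert report.overall["recall"] == pytest.approx(accuracy)

    def test_zero_prediction_warns(self):
        cm = ConfusionMatrix(np.array([[0, 5, 0], [0, 5, 0], [0, 5, 0]]))
        with pytest.warns(UserWarning, match="precision set to 0"):
            report = precision_recall_f1(cm)
        assert report.per_class["bite"]["precision"] == 0.0

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError, match="empty"):
            precision_recall_f1(ConfusionMatrix(np.zeros((3, 3), dtype=int)))


class TestProcessingSpeed:
    def test_normalization_arithmetic(self):
        assert processing_speed(5.0, 60.0) == pytest.approx(83.3333, abs=1e-3)
        assert processing_speed(60.0, 60.0) == 1000.0

    def test_zero_duration_raises(self):
        with pytest.raises(ValueError, match="duration"):
            processing_speed(1.0, 0.0)


class TestSegmentDescriptors:
    def test_full_scale_square_wave(self):
        x = np.tile(np.array([32767, -32768], dtype=np.int16), 100)
        d = segment_descriptors(AudioSegment(x))
        assert d.amplitude == pytest.approx(1.0, abs=2e-5)

    def test_duration(self):
        d = segment_descriptors(AudioSegment(np.ones(22050, dtype=np.int16)))
        assert d.duration == pytest.approx(1.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            segment_descriptors(AudioSegment(np.array([], dtype=np.int16)))

    def test_descriptor_recovers_generator_amplitude(self, spec_by_condition):
        """Module-crossing loop: generated loud-bite segments measure back to
        the condition's published mean amplitude."""
        spec = spec_by_condition[("bite", "tall_fescue", "short")]
        amps = [
            segment_descriptors(generate_segment(spec, 60_000 + i)).amplitude
            for i in range(200)
        ]
        se = spec.amplitude_sd / np.sqrt(200)
        assert abs(np.mean(amps) - 0.488) <= 2 * se
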