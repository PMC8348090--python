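"""Confusion matrices, precision/recall/F1, processing speed, descriptors.

Per class c (one-vs-rest):

    precision_c = TP_c / (TP_c + FP_c)
    recall_c    = TP_c / (TP_c + FN_c)
    F1_c        = 2 * precision_c * recall_c / (precision_c + recall_c)

Overall metrics are support-weighted averages by default (macro available).
A class with zero predicted (or true) positives gets metric 0 with a
warning.  Processing speed is normalized as milliseconds of computation
per second of audio, reported but never asserted — it is hardware-bound.

Segment descriptors are the two time-domain features on which behavior and
forage condition separate: amplitude = peak-to-peak sample range / 2**16
(unitless, in [0, 1]) and duration in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .audio_io import BEHAVIORS, AudioSegment


@dataclass
class ConfusionMatrix:
    """3x3 counts; rows = true behavior, columns = predicted.

    Class order is (bite, chew, chew_bite).
    """

    counts: np.ndarray
    labels: tuple[str, ...] = BEHAVIORS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be >= 0")

    @property
    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def row_normalized(self) -> np.ndarray:
        """Per-class rates; rows with zero support become zero rows."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(sums > 0, self.counts / sums, 0.0)
        return rates


@dataclass
class MetricsReport:
    per_class: dict[str, dict[str, float]]
    overall: dict[str, float]
    averaging: str = "weighted"


@dataclass
class SegmentDescriptors:
    amplitude: float
    duration: float


def confusion_matrix(true_labels, predicted_labels) -> ConfusionMatrix:
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label length mismatch: {len(true_labels)} true vs "
            f"{len(predicted_labels)} predicted"
        )
    index = {b: i for i, b in enumerate(BEHAVIORS)}
    counts = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"labels must be in {BEHAVIORS}: got ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts)


def precision_recall_f1(cm: ConfusionMatrix, averaging: str = "weighted") -> MetricsReport:
    """Per-class one-vs-rest metrics plus the averaged overall row."""
    if averaging not in ("weighted", "macro"):
        raise ValueError("averaging must be 'weighted' or 'macro'")
    counts = cm.counts
    if counts.sum() == 0:
        raise ValueError("cannot compute metrics from an empty confusion matrix")
    per_class: dict[str, dict[str, float]] = {}
    for i, label in enumerate(cm.labels):
        tp = float(counts[i, i])
        fp = float(counts[:, i].sum() - counts[i, i])
        fn = float(counts[i, :].sum() - counts[i, i])
        if tp + fp == 0:
            warnings.warn(
                f"no predicted positives for {label!r}; precision set to 0",
                stacklevel=2,
            )
            precision = 0.0
        else:
            precision = tp / (tp + fp)
        if tp + fn == 0:
            warnings.warn(
                f"no true instances of {label!r}; recall set to 0", stacklevel=2
            )
            recall = 0.0
        else:
            recall = tp / (tp + fn)
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        per_class[label] = {"precision": precision, "recall": recall, "f1": f1}
    support = cm.support.astype(float)
    if averaging == "weighted":
        weights = support / support.sum()
    else:
        weights = np.full(len(cm.labels), 1.0 / len(cm.labels))
    overall = {
        metric: float(
            sum(w * per_class[label][metric] for w, label in zip(weights, cm.labels))
        )
        for metric in ("precision", "recall", "f1")
    }
    return MetricsReport(per_class=per_class, overall=overall, averaging=averaging)


def processing_speed(
    total_processing_time_s: float, total_audio_duration_s: float
) -> float:
    """Milliseconds of processing per second of audio."""
    if total_audio_duration_s <= 0:
        raise ValueError("total audio duration must be positive")
    return 1000.0 * total_processing_time_s / total_audio_duration_s


def segment_descriptors(segment: AudioSegment) -> SegmentDescriptors:
    """Peak-to-peak amplitude (over 2**16) and duration of a segment."""
    if len(segment.samples) == 0:
        raise ValueError("descriptors undefined for an empty segment")
    samples = segment.samples.astype(np.int64)
    amplitude = float(samples.max() - samples.min()) / 65536.0
    return SegmentDescriptors(amplitude=amplitude, duration=segment.duration_s)
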