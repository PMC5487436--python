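"""Performance metrics for the spiking classifier.

* **Classifier Loss** — SNN test accuracy minus frame-based (ANN) classifier
  accuracy, in percentage points; negative means the conversion to spikes
  degraded performance, positive an improvement.
* **Latency** — time from the first input spike of a sample to the first
  classifier output spike.
* **Activity** — mean events per sample at the input and over the whole
  network, the quantities that drive energy cost on neuromorphic hardware.
* **Accuracy vs input fraction** — how accuracy evolves as only the first
  f% of each sample's events are presented.
* Wilson score **confidence intervals** on accuracies, and leave-one-out
  cross-validation for small sample sets.

All metrics are pure functions of recorded event logs and labels; they
never re-simulate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .aer import EventStream

__all__ = [
    "classifier_loss",
    "snn_predict",
    "latency_metric",
    "accuracy_vs_fraction",
    "confidence_interval",
    "loocv",
    "RunMetrics",
]

NO_DECISION = -1


def classifier_loss(ann_acc: float, snn_acc: float) -> float:
    """SNN accuracy minus ANN accuracy, both in percent."""
    for v in (ann_acc, snn_acc):
        if not 0.0 <= v <= 100.0:
            raise ValueError("accuracies must lie in [0, 100]")
    return snn_acc - ann_acc


def snn_predict(fc_events, n_classes: int,
                window: Optional[tuple[int, int]] = None) -> int:
    """Spiking-classifier readout: the class whose output neuron spiked most.

    Ties are broken by the earliest first spike among the tied classes; a
    sample with no output spikes at all returns ``NO_DECISION`` (-1), which
    scoring counts as incorrect.
    """
    data = fc_events.data if isinstance(fc_events, EventStream) \
        else np.asarray(fc_events)
    if data.size == 0:
        return NO_DECISION
    t, cls = data[:, 0], data[:, 1]
    if window is not None:
        mask = (t >= window[0]) & (t < window[1])
        t, cls = t[mask], cls[mask]
    if len(cls) == 0:
        return NO_DECISION
    counts = np.bincount(cls, minlength=n_classes)
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if len(tied) == 1:
        return int(tied[0])
    first_spike = [t[cls == c].min() for c in tied]
    return int(tied[int(np.argmin(first_spike))])


def latency_metric(input_stream: EventStream,
                   output_stream: EventStream) -> Optional[int]:
    """Time from the first input spike to the first output spike, in us.

    Returns ``None`` (flagged undefined) when no output spike exists; such
    samples are excluded from latency means.
    """
    if len(input_stream) == 0:
        raise ValueError("latency undefined for an empty input stream")
    if len(output_stream) == 0:
        return None
    return int(output_stream.t[0]) - int(input_stream.t[0])


def accuracy_vs_fraction(samples: Sequence[tuple[EventStream, int]],
                         classify: Callable[[EventStream], int],
                         fractions: Sequence[float]) -> pd.DataFrame:
    """Accuracy after truncating each sample to its first f% of events.

    Truncation is by event count (the first ``floor(n * f / 100)`` events);
    ``classify`` runs the network plus readout on the truncated stream.
    """
    rows = []
    for f in fractions:
        if not 0.0 < f <= 100.0:
            raise ValueError("fractions must lie in (0, 100]")
        correct = 0
        for stream, label in samples:
            n_keep = int(np.floor(len(stream) * f / 100.0))
            truncated = EventStream(stream.data[:n_keep].copy(), stream.width,
                                    stream.height, stream.duration,
                                    list(stream.samples))
            correct += int(classify(truncated) == label)
        rows.append((f, 100.0 * correct / len(samples)))
    return pd.DataFrame(rows, columns=["fraction", "accuracy"])


def confidence_interval(successes: int, n: int,
                        level: float = 0.99) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion at the given level."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level,
                                method="wilson")
    return float(lo), float(hi)


def loocv(samples: Sequence[tuple[EventStream, int]],
          slice_len_us: int,
          train_fold: Callable[[Sequence[tuple[EventStream, int]], int], object],
          classify: Callable[[object, EventStream], int],
          ) -> tuple[float, list[int]]:
    """Leave-one-out cross-validation over whole samples.

    For every held-out sample a classifier is trained on all *other*
    samples' fixed-length slices (``train_fold(train_items, slice_len_us)``)
    and the whole held-out sample is classified.  Returns the accuracy in
    percent over all folds together with the per-fold predictions.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("LOOCV needs at least two samples")
    preds: list[int] = []
    for i, (held_out, label) in enumerate(samples):
        train_items = samples[:i] + samples[i + 1:]
        train_labels = {lab for _, lab in train_items}
        if label not in train_labels:
            warnings.warn(f"fold {i}: class {label} has no remaining "
                          "training sample; this fold is untrainable for "
                          "its own class", stacklevel=2)
        model = train_fold(train_items, slice_len_us)
        preds.append(classify(model, held_out))
    correct = sum(int(p == lab) for p, (_, lab) in zip(preds, samples))
    return 100.0 * correct / len(samples), preds


@dataclass
class RunMetrics:
    """One row of the summary table for an experiment run."""

    ann_accuracy: float
    snn_accuracy: float
    mean_input_activity: float
    mean_total_activity: float
    latency_mean_us: float
    latency_std_us: float
    n_no_decision: int = 0

    @property
    def classifier_loss(self) -> float:
        return classifier_loss(self.ann_accuracy, self.snn_accuracy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "ANN (frames)": self.ann_accuracy,
            "SNN": self.snn_accuracy,
            "Classifier Loss": self.classifier_loss,
            "Average input sample activity": self.mean_input_activity,
            "Average total sample activity": self.mean_total_activity,
            "Latency (us)": self.latency_mean_us,
            "Latency std (us)": self.latency_std_us,
            "No decision": self.n_no_decision,
        }])
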