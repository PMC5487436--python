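"""Histogram readout and supervised training of the spiking classifier.

The classifier is trained in the frame domain and mapped back to spiking
weights in three steps:

1. run each sample through the feature-extraction network and build a
   **normalized spike-count histogram** over the Flatten outputs — counts
   divided by the maximum count, an analog vector in [0, 1];
2. fit a bias-free **softmax regression** on these frames with mini-batch
   stochastic gradient descent (MSGD) minimizing the negative log-likelihood,
   at a fixed learning rate for a fixed number of epochs;
3. **scale** the learned real weights by a constant positive integer K and
   round, using K as the firing threshold TH_FC of the spiking classifier
   neurons (default K = 10,000,000).

The fit is exposed statsmodels-style: :class:`SoftmaxClassifier` is the
model, ``fit()`` returns a :class:`SoftmaxClassifierResults` carrying the
weight matrix, the loss trajectory, ``predict``/``summary`` and the
``scale_weights`` mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aer import EventStream

__all__ = [
    "TrainConfig",
    "build_histogram",
    "histograms_for_windows",
    "softmax_forward",
    "nll_loss",
    "softmax_gradient",
    "train_msgd",
    "predict",
    "scale_weights",
    "SoftmaxClassifier",
    "SoftmaxClassifierResults",
]


# ---------------------------------------------------------------------------
# From events to frames
# ---------------------------------------------------------------------------

def build_histogram(flatten_events, h: int,
                    window: Optional[tuple[int, int]] = None) -> np.ndarray:
    """Normalized spike-count histogram of flatten-layer events.

    Parameters
    ----------
    flatten_events : EventStream or ndarray
        Events whose x field carries the flatten index (signs are counted
        in absolute value: every spike is one count).
    h : int
        Flatten size (histogram length).
    window : (t_start, t_end), optional
        Restrict to events with ``t_start <= t < t_end`` (One-Pass sample
        boundary); by default the whole record is used.

    Returns
    -------
    ndarray of shape (h,), values in [0, 1]; all-zero for an empty record.
    """
    data = flatten_events.data if isinstance(flatten_events, EventStream) \
        else np.asarray(flatten_events)
    if data.size:
        t, idx = data[:, 0], data[:, 1]
        if window is not None:
            mask = (t >= window[0]) & (t < window[1])
            idx = idx[mask]
    else:
        idx = np.empty(0, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= h):
        raise ValueError(f"flatten index outside [0, {h})")
    counts = np.bincount(idx, minlength=h).astype(np.float64)
    peak = counts.max()
    return counts / peak if peak > 0 else counts


def histograms_for_windows(flatten_stream: EventStream, h: int) -> np.ndarray:
    """One histogram per annotated sample window of a One-Pass record."""
    if not flatten_stream.samples:
        raise ValueError("stream carries no sample annotations")
    return np.stack([
        build_histogram(flatten_stream, h, window=(w.t_start, w.t_end))
        for w in flatten_stream.samples
    ])


# ---------------------------------------------------------------------------
# Softmax regression (no biases)
# ---------------------------------------------------------------------------

def softmax_forward(W: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Class probabilities ``Y_k = exp(W_k . x) / sum_j exp(W_j . x)``.

    ``x`` may be a single frame (h,) or a batch (n, h); stabilized by
    max-subtraction.
    """
    logits = np.atleast_2d(x) @ W.T
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    return probs[0] if np.ndim(x) == 1 else probs


def nll_loss(W: np.ndarray, X: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the labeled batch."""
    probs = softmax_forward(W, np.atleast_2d(X))
    n = probs.shape[0]
    picked = probs[np.arange(n), np.asarray(labels)]
    return float(-np.mean(np.log(picked)))


def softmax_gradient(W: np.ndarray, X: np.ndarray, labels: np.ndarray
                     ) -> np.ndarray:
    """Analytic NLL gradient: ``(1/|D|) sum_i (Y(x_i) - onehot(L_i)) x_i^T``."""
    X = np.atleast_2d(X)
    labels = np.asarray(labels)
    n = X.shape[0]
    probs = softmax_forward(W, X)
    probs[np.arange(n), labels] -= 1.0
    return probs.T @ X / n


def predict(W: np.ndarray, x: np.ndarray) -> int | np.ndarray:
    """Predicted class: argmax of the logits (softmax is monotone); ties go
    to the lowest class index."""
    logits = np.atleast_2d(x) @ W.T
    out = np.argmax(logits, axis=1)
    return int(out[0]) if np.ndim(x) == 1 else out


@dataclass(frozen=True)
class TrainConfig:
    """MSGD settings: fixed learning rate, fixed epoch count."""

    eta: float = 0.1
    epochs: int = 1500
    batch_size: int = 100
    seed: Optional[int] = None

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def train_msgd(frames: np.ndarray, labels: np.ndarray, n_classes: int,
               config: TrainConfig = TrainConfig(),
               loss_every: int = 0) -> tuple[np.ndarray, list[float]]:
    """Mini-batch SGD on the softmax NLL from a zero initialization.

    Each epoch shuffles the sample order (seeded) and sweeps it in
    mini-batches, applying ``W <- W - eta * grad``.  Returns the final
    weight matrix (n_classes, h) and the recorded loss trajectory.
    """
    X = np.asarray(frames, dtype=np.float64)
    y = np.asarray(labels)
    n, h = X.shape
    if len(y) != n:
        raise ValueError("frames and labels disagree in length")
    present = np.bincount(y, minlength=n_classes)
    if (present == 0).any():
        missing = int(np.flatnonzero(present == 0)[0])
        raise ValueError(f"class {missing} has no training sample")
    if config.batch_size > n:
        raise ValueError("batch_size exceeds the number of samples")
    rng = np.random.default_rng(config.seed)
    W = np.zeros((n_classes, h), dtype=np.float64)
    losses: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            W -= config.eta * softmax_gradient(W, X[batch], y[batch])
        if loss_every and (epoch + 1) % loss_every == 0:
            losses.append(nll_loss(W, X, y))
    return W, losses


def scale_weights(W: np.ndarray, k_scale: int = 10_000_000
                  ) -> tuple[np.ndarray, float]:
    """Map the learned real weights to integers: ``W_int = round(K * W)``.

    K doubles as the spiking classifier threshold TH_FC.  Returns the
    integer matrix and the worst-case rounding error on the K-scaled values
    (bounded by 0.5).
    """
    if k_scale <= 0 or int(k_scale) != k_scale:
        raise ValueError("k_scale must be a positive integer")
    scaled = np.asarray(W, dtype=np.float64) * k_scale
    if np.abs(scaled).max(initial=0.0) >= 2**62:
        raise OverflowError("scaled weights overflow the 64-bit range")
    w_int = np.rint(scaled).astype(np.int64)
    max_err = float(np.abs(w_int - scaled).max(initial=0.0))
    return w_int, max_err


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class SoftmaxClassifier:
    """Bias-free softmax regression on normalized spike-count frames.

    Parameters
    ----------
    frames : ndarray (n_samples, h)
        Normalized histograms (values in [0, 1]).
    labels : ndarray (n_samples,)
        Integer class labels in ``[0, n_classes)``.
    n_classes : int, optional
        Defaults to ``labels.max() + 1``.
    """

    def __init__(self, frames: np.ndarray, labels: np.ndarray,
                 n_classes: Optional[int] = None):
        self.frames = np.asarray(frames, dtype=np.float64)
        self.labels = np.asarray(labels, dtype=np.int64)
        if self.frames.ndim != 2:
            raise ValueError("frames must be 2-D (n_samples, h)")
        self.n_classes = int(n_classes if n_classes is not None
                             else self.labels.max() + 1)
        if self.labels.min(initial=0) < 0 or \
                (len(self.labels) and self.labels.max() >= self.n_classes):
            raise ValueError("labels outside [0, n_classes)")

    @classmethod
    def from_flatten_events(cls, streams: Sequence[EventStream],
                            labels: Sequence[int], h: int,
                            n_classes: Optional[int] = None
                            ) -> "SoftmaxClassifier":
        frames = np.stack([build_histogram(s, h) for s in streams])
        return cls(frames, np.asarray(labels), n_classes)

    def fit(self, eta: float = 0.1, epochs: int = 1500,
            batch_size: Optional[int] = None, seed: Optional[int] = None,
            loss_every: int = 0) -> "SoftmaxClassifierResults":
        if batch_size is None:
            batch_size = min(100, len(self.labels))
        cfg = TrainConfig(eta=eta, epochs=epochs, batch_size=batch_size,
                          seed=seed)
        W, losses = train_msgd(self.frames, self.labels, self.n_classes,
                               cfg, loss_every=loss_every)
        return SoftmaxClassifierResults(self, W, cfg, losses)


@dataclass
class SoftmaxClassifierResults:
    """Fitted classifier: weights, fit diagnostics, and the spiking mapping."""

    model: SoftmaxClassifier
    W: np.ndarray
    config: TrainConfig
    loss_history: list[float] = field(default_factory=list)

    def predict(self, frames: Optional[np.ndarray] = None) -> np.ndarray:
        X = self.model.frames if frames is None else np.asarray(frames)
        return np.atleast_1d(predict(self.W, X))

    def predict_proba(self, frames: Optional[np.ndarray] = None) -> np.ndarray:
        X = self.model.frames if frames is None else np.asarray(frames)
        return softmax_forward(self.W, X)

    def accuracy(self, frames: Optional[np.ndarray] = None,
                 labels: Optional[np.ndarray] = None) -> float:
        """Fraction correct, in percent."""
        y = self.model.labels if labels is None else np.asarray(labels)
        return float(100.0 * np.mean(self.predict(frames) == y))

    def final_nll(self) -> float:
        return nll_loss(self.W, self.model.frames, self.model.labels)

    def scale_weights(self, k_scale: int = 10_000_000):
        """Integer-scaled weights and the matching classifier threshold.

        Returns ``(W_int, th_fc, max_rounding_error)`` with
        ``th_fc = k_scale``.
        """
        w_int, err = scale_weights(self.W, k_scale)
        return w_int, int(k_scale), err

    def summary(self) -> str:
        m = self.model
        rows = [
            ("No. samples", len(m.labels)),
            ("No. classes", m.n_classes),
            ("Frame length (h)", m.frames.shape[1]),
            ("Learning rate", self.config.eta),
            ("Epochs", self.config.epochs),
            ("Batch size", self.config.batch_size),
            ("Final NLL", f"{self.final_nll():.6f}"),
            ("Train accuracy (%)", f"{self.accuracy():.2f}"),
            ("|W| max", f"{np.abs(self.W).max(initial=0.0):.4f}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Softmax spike-histogram classifier",
                 "=" * 42]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Weights as a DataFrame (classes x flatten indices)."""
        return pd.DataFrame(self.W)
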