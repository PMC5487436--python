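"""End-to-end experiments on the synthetic fixtures.

One experiment runs the whole methodology on a generated data set:

1. generate labeled samples (oriented-bar images encoded to spikes, or
   DVS-like moving-bar event streams);
2. feed each sample through the Gabor convolution network and build
   normalized spike-count histograms at the Flatten output;
3. fit the bias-free softmax classifier on the training histograms (MSGD);
4. scale the learned weights by K (= the spiking classifier threshold
   TH_FC) and attach the spiking fully-connected layer;
5. re-run the test samples through the full spiking network and score the
   spike-count readout against the frame-domain classifier.

Presentation regimes: **SBS** (sample by sample) runs each sample from a
fresh state with zero leakage; **OP** (one pass) concatenates all samples
into one continuous stream and relies on leakage to fade activity between
samples, with histograms and readout taken per annotated window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .aer import EventStream, concat_op_stream
from .config import NetConfig
from .encoders import EncodingConfig, latency_encode, poisson_encode
from .evaluation import NO_DECISION, RunMetrics, latency_metric, snn_predict
from .fixtures import (BarImageConfig, DVSFixtureConfig, gen_bar_images,
                       gen_dvs_samples)
from .network import ConvNetPipeline
from .training import SoftmaxClassifier

__all__ = ["ExperimentConfig", "ExperimentResult", "default_net_config",
           "make_samples", "collect_flatten", "run_experiment"]


def default_net_config(n_classes: int = 4, input_size: int = 28) -> NetConfig:
    """The fixture-scale network: 28x28 input, 7x7 Gabor bank over 4
    orientations x 2 phases, pooling by 2, integer kernels at scale 10^6.

    The C1 threshold is sized from the kernel arithmetic so that a single
    latency pass of an aligned bar (one spike per pixel, center-stripe taps
    summing to roughly 10 kernel units = 10^7) crosses threshold while
    off-orientation drive stays below it; leak constants carry the
    magnitude used for the synthetic-set study conditions.
    """
    from .config import GaborConfig

    return NetConfig(
        input_size=input_size,
        n_classes=n_classes,
        kernel_size=7,
        kernel_scale=10**6,
        gabor=GaborConfig(thetas=(0.0, 40.0, 80.0, 120.0), psis=(0.0, 1.7)),
        conv_th_plus=5_000_000,
        conv_th_minus=-5_000_000,
        conv_tl_plus=12_000,
        conv_tl_minus=12_000,
        fc_th_plus=10_000_000,
        fc_tl_plus=12_000,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions of one synthetic end-to-end run."""

    encoding: str = "latency"  # latency | poisson | dvs
    mode: str = "sbs"          # sbs | op
    seed: int = 0
    epochs: int = 200
    eta: float = 0.1
    batch_size: int = 100
    k_scale: int = 10_000_000
    # OP inter-sample gap: long enough for the slowest state to fade to
    # rest (worst FC excursion ~2^31 at ~833 units/us needs ~2.6 s)
    gap_us: int = 3_000_000
    samples_per_class: int = 125
    n_classes: int = 4
    net: Optional[NetConfig] = None

    def __post_init__(self):
        if self.encoding not in ("latency", "poisson", "dvs"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.mode not in ("sbs", "op"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def net_config(self) -> NetConfig:
        return self.net if self.net is not None else default_net_config(
            self.n_classes)


@dataclass
class ExperimentResult:
    metrics: RunMetrics
    predictions: np.ndarray
    test_labels: np.ndarray
    W: np.ndarray
    W_int: np.ndarray
    th_fc: int


def make_samples(cfg: ExperimentConfig
                 ) -> tuple[list[tuple[EventStream, int]], np.ndarray,
                            np.ndarray]:
    """Generate the labeled sample streams and the train/test split."""
    if cfg.encoding == "dvs":
        dvs_cfg = DVSFixtureConfig(samples_per_class=cfg.samples_per_class,
                                   gap_us=cfg.gap_us, seed=cfg.seed)
        sample_set, train_idx, test_idx = gen_dvs_samples(dvs_cfg)
        return list(sample_set.items), train_idx, test_idx
    bar_cfg = BarImageConfig(samples_per_class=cfg.samples_per_class,
                             seed=cfg.seed)
    image_set = gen_bar_images(bar_cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    items: list[tuple[EventStream, int]] = []
    for img, label in zip(image_set.images, image_set.labels):
        if cfg.encoding == "latency":
            stream = latency_encode(img)
        else:
            stream = poisson_encode(img, EncodingConfig(), rng=rng)
        items.append((stream, int(label)))
    return items, image_set.train_idx, image_set.test_idx


def collect_flatten(pipe: ConvNetPipeline,
                    samples: Sequence[tuple[EventStream, int]],
                    mode: str, gap_us: int,
                    ) -> tuple[list[dict], np.ndarray]:
    """Run samples through the feature extractor and collect per-sample
    flatten records and tap spike counts.

    SBS resets state before each sample and returns one record per sample;
    OP concatenates everything into one leaky pass and splits the record
    back into per-sample windows afterwards (tap counts per window use the
    flatten record, exact under remap pooling where the convolution, pool
    and flatten stages carry equal event counts).
    """
    if mode == "sbs":
        per_sample = []
        for stream, _ in samples:
            res = pipe.run_compiled(stream, reset=True)
            per_sample.append(res)
        return per_sample, np.asarray([lab for _, lab in samples])
    op_stream = concat_op_stream(list(samples), gap_us=gap_us)
    res = pipe.run_compiled(op_stream, reset=True)
    per_sample = []
    for w in op_stream.samples:
        entry = {
            "input": op_stream.window(w.t_start, w.t_end),
            "flatten": res["flatten"].window(w.t_start, w.t_end),
            "fc": res["fc"].window(w.t_start, w.t_end)
            if res["fc"] is not None else None,
        }
        n_fl = len(entry["flatten"])
        entry["counts"] = {
            "input": len(entry["input"]), "c1": n_fl, "s1": n_fl,
            "flatten": n_fl,
            "fc": len(entry["fc"]) if entry["fc"] is not None else 0,
        }
        per_sample.append(entry)
    return per_sample, np.asarray([w.label for w in op_stream.samples])


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Execute one full synthetic experiment; see the module docstring."""
    from .training import build_histogram

    net_cfg = cfg.net_config
    leak = cfg.mode == "op"
    samples, train_idx, test_idx = make_samples(cfg)
    h = net_cfg.flatten_size
    train_items = [samples[i] for i in train_idx]
    test_items = [samples[i] for i in test_idx]

    # -- histograms for training and ANN evaluation ------------------------
    extractor = ConvNetPipeline(net_cfg, leak=leak)
    train_recs, train_labels = collect_flatten(extractor, train_items,
                                               cfg.mode, cfg.gap_us)
    test_recs, test_labels = collect_flatten(extractor, test_items,
                                             cfg.mode, cfg.gap_us)
    X_train = np.stack([build_histogram(r["flatten"], h) for r in train_recs])
    X_test = np.stack([build_histogram(r["flatten"], h) for r in test_recs])

    # -- frame-domain training ---------------------------------------------
    model = SoftmaxClassifier(X_train, train_labels, n_classes=cfg.n_classes)
    fit = model.fit(eta=cfg.eta, epochs=cfg.epochs,
                    batch_size=min(cfg.batch_size, len(train_labels)),
                    seed=cfg.seed)
    ann_acc = fit.accuracy(X_test, test_labels)

    # -- map to the spiking classifier and re-run the test set -------------
    W_int, th_fc, _ = fit.scale_weights(cfg.k_scale)
    snn_cfg = replace(net_cfg, fc_th_plus=th_fc)
    snn = ConvNetPipeline(snn_cfg, weights=W_int, leak=leak)
    snn_recs, _ = collect_flatten(snn, test_items, cfg.mode, cfg.gap_us)
    preds = []
    latencies = []
    input_counts = []
    total_counts = []
    n_no_decision = 0
    for rec in snn_recs:
        pred = snn_predict(rec["fc"], cfg.n_classes)
        preds.append(pred)
        n_no_decision += int(pred == NO_DECISION)
        lat = latency_metric(rec["input"], rec["fc"]) \
            if len(rec["input"]) else None
        if lat is not None:
            latencies.append(lat)
        input_counts.append(rec["counts"]["input"])
        total_counts.append(sum(rec["counts"].values()))
    preds = np.asarray(preds)
    snn_acc = float(100.0 * np.mean(preds == test_labels))
    metrics = RunMetrics(
        ann_accuracy=ann_acc,
        snn_accuracy=snn_acc,
        mean_input_activity=float(np.mean(input_counts)),
        mean_total_activity=float(np.mean(total_counts)),
        latency_mean_us=float(np.mean(latencies)) if latencies else float("nan"),
        latency_std_us=float(np.std(latencies)) if latencies else float("nan"),
        n_no_decision=n_no_decision,
    )
    return ExperimentResult(metrics, preds, test_labels, fit.W, W_int, th_fc)
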