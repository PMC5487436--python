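"""Network configuration: layer geometry and neuron parameter blocks.

Configuration files (YAML or JSON) use the conventional field names of the
neuron model — ``TH_plus``, ``TH_minus``, ``TL_plus``, ``TL_minus`` — for
the per-layer parameter blocks::

    input_size: 28
    kernel_size: 7
    n_classes: 4
    kernel_scale: 1000000
    gabor: {thetas: [0, 40, 80, 120], psis: [0.0, 1.7],
            sigma: 4, lambda: 8, gamma: 0.5}
    C1: {TH_plus: 5000000, TH_minus: -5000000,
         TL_plus: 12000, TL_minus: 12000}
    FC: {TH_plus: 10000000, TL_plus: 12000}

The ``TL_*`` constants are the One-Pass (leaky) values; the sample-by-sample
regime zeroes all leakages.  A ``TH_minus`` of -2**31 is the sentinel that
disables the negative threshold entirely (positive-only LIF).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .kernels import DEFAULT_PSIS, DEFAULT_THETAS
from .neuron import TH_MINUS_DISABLED, NeuronParams

__all__ = ["NetConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete network configuration."""


def _require(block: dict, key: str, where: str):
    if key not in block:
        raise ConfigError(f"missing config key {key!r} in section {where!r}")
    return block[key]


@dataclass(frozen=True)
class GaborConfig:
    thetas: tuple[float, ...] = DEFAULT_THETAS
    psis: tuple[float, ...] = DEFAULT_PSIS
    sigma: float = 4.0
    lam: float = 8.0
    gamma: float = 0.5


@dataclass(frozen=True)
class NetConfig:
    """Full parameterization of the single-convolution-layer network."""

    input_size: int
    n_classes: int
    kernel_size: int = 7
    pool_factor: int = 2
    pool_mode: str = "remap"
    pool_m: int = 4
    kernel_scale: int = 10**6
    gabor: GaborConfig = field(default_factory=GaborConfig)
    conv_th_plus: int = 5_000_000
    conv_th_minus: int = -5_000_000
    conv_tl_plus: int = 12_000
    conv_tl_minus: int = 12_000
    conv_emit_negative: bool = False
    conv_refractory_us: int = 0
    fc_th_plus: int = 10_000_000
    fc_tl_plus: int = 12_000

    def __post_init__(self):
        c1 = self.input_size - self.kernel_size + 1
        if c1 < 1:
            raise ConfigError("kernel larger than input")
        if self.pool_factor > 1 and c1 % self.pool_factor:
            raise ConfigError(
                f"C1 feature-map side {c1} (= {self.input_size} - "
                f"{self.kernel_size} + 1) is not divisible by the pooling "
                f"factor {self.pool_factor}")

    # -- derived geometry --------------------------------------------------

    @property
    def n_feature_maps(self) -> int:
        return len(self.gabor.thetas) * len(self.gabor.psis)

    @property
    def c1_size(self) -> int:
        """Feature-map side of the convolution layer (pre-pooling)."""
        return self.input_size - self.kernel_size + 1

    @property
    def s1_size(self) -> int:
        return self.c1_size // self.pool_factor

    @property
    def flatten_size(self) -> int:
        return self.n_feature_maps * self.s1_size**2

    # -- neuron parameter blocks ------------------------------------------

    def conv_params(self, leak: bool) -> NeuronParams:
        return NeuronParams(
            th_plus=self.conv_th_plus,
            th_minus=self.conv_th_minus,
            tl_plus=self.conv_tl_plus if leak else 0,
            tl_minus=self.conv_tl_minus if leak else 0,
            refractory_us=self.conv_refractory_us,
            emit_negative=self.conv_emit_negative,
        )

    def fc_params(self, leak: bool) -> NeuronParams:
        return NeuronParams(
            th_plus=self.fc_th_plus,
            th_minus=TH_MINUS_DISABLED,
            tl_plus=self.fc_tl_plus if leak else 0,
            tl_minus=self.fc_tl_plus if leak else 0,
            emit_negative=False,
        )

    # -- parsing -----------------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        g = d.get("gabor", {})
        gabor = GaborConfig(
            thetas=tuple(g.get("thetas", DEFAULT_THETAS)),
            psis=tuple(g.get("psis", DEFAULT_PSIS)),
            sigma=float(g.get("sigma", 4.0)),
            lam=float(g.get("lambda", g.get("lam", 8.0))),
            gamma=float(g.get("gamma", 0.5)),
        )
        c1 = _require(d, "C1", "top level")
        fc = _require(d, "FC", "top level")
        # leakage constants are durations; a negative printed value is a
        # sign typo and is read as its magnitude
        return cls(
            input_size=int(_require(d, "input_size", "top level")),
            n_classes=int(_require(d, "n_classes", "top level")),
            kernel_size=int(d.get("kernel_size", 7)),
            pool_factor=int(d.get("pool_factor", 2)),
            pool_mode=str(d.get("pool_mode", "remap")),
            pool_m=int(d.get("pool_m", 4)),
            kernel_scale=int(d.get("kernel_scale", 10**6)),
            gabor=gabor,
            conv_th_plus=int(_require(c1, "TH_plus", "C1")),
            conv_th_minus=int(c1.get("TH_minus", -int(c1["TH_plus"]))),
            conv_tl_plus=abs(int(c1.get("TL_plus", 0))),
            conv_tl_minus=abs(int(c1.get("TL_minus", c1.get("TL_plus", 0)))),
            conv_emit_negative=bool(c1.get("emit_negative", False)),
            conv_refractory_us=int(c1.get("refractory_us", 0)),
            fc_th_plus=int(_require(fc, "TH_plus", "FC")),
            fc_tl_plus=abs(int(fc.get("TL_plus", 0))),
        )

    @classmethod
    def from_file(cls, path) -> "NetConfig":
        text = open(path, "r", encoding="utf-8").read()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))
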