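"""Gabor kernel bank for the fixed feature-extraction layer.

The convolution layer is programmed, not learned: its 18 feature maps use a
bank of 2-D Gabor kernels covering 9 orientations x 2 phases,

    g(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) * cos(2 pi x' / lambda + psi)
    x' =  x cos(theta) + y sin(theta)
    y' = -x sin(theta) + y cos(theta)

evaluated on integer pixel offsets centred at 0.  Default parameters:
theta in {0, 20, ..., 160} degrees, sigma = 4, lambda = 8,
psi in {0.0, 1.7} radians, gamma = 0.5, kernel side 7.

Because membranes and synaptic weights are integer-valued in the spiking
path, the real-valued bank is quantized by a positive integer scale
(``round(value * scale)`` per tap).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["GaborParams", "KernelBank", "gabor_kernel", "build_bank",
           "quantize_kernels", "DEFAULT_THETAS", "DEFAULT_PSIS"]

DEFAULT_THETAS: tuple[float, ...] = (0, 20, 40, 60, 80, 100, 120, 140, 160)
DEFAULT_PSIS: tuple[float, ...] = (0.0, 1.7)


@dataclass(frozen=True)
class GaborParams:
    """Parameters of a single Gabor kernel.

    theta is in degrees; psi in radians; sigma the Gaussian width; lam the
    sinusoid wavelength; gamma the spatial aspect ratio; size the kernel side.
    """

    theta: float
    sigma: float = 4.0
    lam: float = 8.0
    psi: float = 0.0
    gamma: float = 0.5
    size: int = 7

    def __post_init__(self):
        if self.sigma <= 0 or self.lam <= 0:
            raise ValueError("sigma and lam must be positive")
        if self.size < 1:
            raise ValueError("size must be >= 1")


def gabor_kernel(params: GaborParams) -> np.ndarray:
    """Evaluate the Gabor function on a ``size x size`` integer offset grid.

    Row index is the y offset, column index the x offset, both centred so
    the middle tap sits at (0, 0).
    """
    half = (params.size - 1) / 2.0
    offs = np.arange(params.size) - half
    yy, xx = np.meshgrid(offs, offs, indexing="ij")
    th = np.deg2rad(params.theta)
    xp = xx * np.cos(th) + yy * np.sin(th)
    yp = -xx * np.sin(th) + yy * np.cos(th)
    envelope = np.exp(-(xp**2 + (params.gamma**2) * yp**2) / (2 * params.sigma**2))
    carrier = np.cos(2 * np.pi * xp / params.lam + params.psi)
    return envelope * carrier


@dataclass
class KernelBank:
    """One kernel per feature map, theta-major over (theta, psi)."""

    kernels: np.ndarray  # (n_maps, k, k) float64
    params: list[GaborParams]
    scale: int | None = None
    kernels_int: np.ndarray | None = None  # (n_maps, k, k) int64
    max_quantization_error: float | None = None

    def __len__(self) -> int:
        return self.kernels.shape[0]

    @property
    def size(self) -> int:
        return self.kernels.shape[-1]

    @property
    def spiking_kernels(self) -> np.ndarray:
        if self.kernels_int is None:
            raise ValueError("bank not quantized; call quantize_kernels first")
        return self.kernels_int


def build_bank(theta_list: Sequence[float] = DEFAULT_THETAS,
               psi_list: Sequence[float] = DEFAULT_PSIS,
               sigma: float = 4.0, lam: float = 8.0, gamma: float = 0.5,
               size: int = 7) -> KernelBank:
    """Generate one kernel per (theta, psi) combination, theta-major."""
    if not theta_list or not psi_list:
        raise ValueError("theta_list and psi_list must be non-empty")
    params = [GaborParams(theta=th, sigma=sigma, lam=lam, psi=ps,
                          gamma=gamma, size=size)
              for th in theta_list for ps in psi_list]
    kernels = np.stack([gabor_kernel(p) for p in params])
    return KernelBank(kernels, params)


def quantize_kernels(bank: KernelBank, scale: int) -> KernelBank:
    """Integer-quantize every tap as ``round(value * scale)`` (in place).

    Records the worst-case dequantization error, which is bounded by
    ``0.5 / scale`` per tap.
    """
    if scale <= 0:
        raise ValueError("scale must be a positive integer")
    kernels_int = np.rint(bank.kernels * scale).astype(np.int64)
    err = float(np.max(np.abs(kernels_int / scale - bank.kernels)))
    bank.scale = int(scale)
    bank.kernels_int = kernels_int
    bank.max_quantization_error = err
    return bank
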