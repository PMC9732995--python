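"""Compressed-sensing super-resolution on 9x9 crops.

The measurement model is ``y = A b``: ``b`` lives on a super-resolved
lattice with ``u`` cells per camera pixel, and ``A`` renders a lattice
spike as the (clipped) PSF binned to the 9x9 camera grid.  The sparse
recovery problem

    minimize  1/2 ||A b - y||^2 + lambda ||b||_1,   b >= 0

is solved with FISTA.  The solver is written in terms of autodiff tensors
with a fixed unrolled iteration count, so the soft-threshold weight
``lambda`` — predicted per crop by a small CNN — receives gradients when
the solver is embedded in a network.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

from .config import CSConfig
from .nn import Tensor, Module, Dense, Conv2d
from .psf import airy_psf

__all__ = [
    "MeasurementOperator", "build_measurement_operator", "fista",
    "fista_numpy", "objective", "LambdaNet", "cs_sparsity_loss",
]

CROP = 9


@dataclass
class MeasurementOperator:
    """Dense linear map from the (9u x 9u) lattice to the 9x9 image."""

    A: np.ndarray        # (81, (9u)^2)
    u: int               # lattice cells per camera pixel
    lipschitz: float     # largest eigenvalue of A^T A

    def forward(self, b: np.ndarray) -> np.ndarray:
        return self.A @ b

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        return self.A.T @ y


def _power_iteration(A: np.ndarray, n_iter: int = 20,
                     seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    v = rng.normal(size=A.shape[1])
    v /= np.linalg.norm(v)
    for _ in range(n_iter):
        w = A.T @ (A @ v)
        nv = np.linalg.norm(w)
        if nv == 0:
            return 0.0
        v = w / nv
    return float(v @ (A.T @ (A @ v)))


def build_measurement_operator(psf: np.ndarray, u: int) -> MeasurementOperator:
    """Build ``A`` from a PSF kernel sampled at the lattice resolution.

    Column ``j`` of ``A`` is the PSF centered on lattice cell ``j``,
    clipped to the crop and sum-binned by ``u`` to camera pixels; a unit
    spike therefore maps to the PSF with its in-crop mass preserved.
    """
    if u < 1:
        raise ValueError("u must be >= 1")
    psf = np.asarray(psf, dtype=float)
    ksz = psf.shape[0]
    half = ksz // 2
    m = CROP * u
    A = np.zeros((CROP * CROP, m * m))
    canvas = np.zeros((m, m))
    for iy in range(m):
        y0 = max(iy - half, 0)
        y1 = min(iy + half + 1, m)
        ky0, ky1 = y0 - (iy - half), y1 - (iy - half)
        for ix in range(m):
            x0 = max(ix - half, 0)
            x1 = min(ix + half + 1, m)
            kx0, kx1 = x0 - (ix - half), x1 - (ix - half)
            canvas[...] = 0.0
            canvas[y0:y1, x0:x1] = psf[ky0:ky1, kx0:kx1]
            A[:, iy * m + ix] = canvas.reshape(
                CROP, u, CROP, u).sum(axis=(1, 3)).ravel()
    return MeasurementOperator(A=A, u=u, lipschitz=_power_iteration(A))


@functools.lru_cache(maxsize=8)
def default_operator(u: int = 8, radius_px: float = 5.4) -> MeasurementOperator:
    """Operator for the default Airy PSF (first zero ``radius_px`` pixels)."""
    r_lat = radius_px * u
    size = 2 * int(np.ceil(r_lat)) + 1
    return build_measurement_operator(airy_psf(r_lat, size), u)


def objective(b: np.ndarray, y: np.ndarray, op: MeasurementOperator,
              lam: float) -> float:
    r = op.A @ b - y
    return float(0.5 * r @ r + lam * np.abs(b).sum())


def fista_numpy(y: np.ndarray, op: MeasurementOperator, lam: float,
                config: CSConfig | None = None) -> np.ndarray:
    """Plain-numpy FISTA with optional tolerance-based early stopping."""
    if config is None:
        config = CSConfig()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite input")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    y = np.asarray(y, dtype=float).ravel()
    L = max(op.lipschitz, 1e-12)
    x = np.zeros(op.A.shape[1])
    z = x.copy()
    t = 1.0
    prev_obj = objective(x, y, op, lam)
    for _ in range(config.n_iter):
        grad = op.A.T @ (op.A @ z - y)
        x_new = np.maximum(z - grad / L - lam / L, 0.0)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x, t = x_new, t_new
        if config.tol > 0:
            cur = objective(x, y, op, lam)
            if abs(prev_obj - cur) <= config.tol * max(abs(prev_obj), 1e-12):
                break
            prev_obj = cur
    # FISTA is not monotone; never return an iterate worse than b = 0
    if objective(x, y, op, lam) > objective(np.zeros_like(x), y, op, lam):
        x = np.zeros_like(x)
    return x


def fista(y, op: MeasurementOperator, lam, config: CSConfig | None = None):
    """Unrolled differentiable FISTA.

    Parameters
    ----------
    y : Tensor or ndarray, shape (N, 81) or (81,)
        Flattened crop images.
    lam : Tensor or float, broadcastable to (N, 1)
        Per-crop soft-threshold weight; gradients flow through it.

    Returns a Tensor of shape (N, (9u)^2) (or 1D if the input was 1D).
    """
    if config is None:
        config = CSConfig()
    squeeze = False
    if not isinstance(y, Tensor):
        y = Tensor(np.asarray(y, dtype=float))
    if y.ndim == 1:
        y = y.reshape(1, -1)
        squeeze = True
    if not np.all(np.isfinite(y.data)):
        raise ValueError("non-finite input")
    if not isinstance(lam, Tensor):
        lam = Tensor(np.asarray(lam, dtype=float))
    A = Tensor(op.A)          # (81, M): right-multiply by A.T maps b -> image
    At = Tensor(op.A.T)
    L = max(op.lipschitz, 1e-12)
    if lam.ndim <= 1:
        lam = lam.reshape(1, 1) if lam.ndim == 0 else lam.reshape(-1, 1)
    x = Tensor(np.zeros((y.shape[0], op.A.shape[1])))
    z = x
    t = 1.0
    for _ in range(config.n_iter):
        resid = (z @ At) - y               # (N, 81)
        grad = resid @ A                   # (N, M)
        x_new = (z - grad * (1.0 / L) - lam * (1.0 / L)).relu()
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = x_new + (x_new - x) * ((t - 1.0) / t_new)
        x, t = x_new, t_new
    if squeeze:
        x = x.reshape(-1)
    return x


class LambdaNet(Module):
    """Per-crop soft-threshold estimator: three conv layers, three dense
    layers, sigmoid output scaled to (0, lambda_max).

    Dense weights are initialized from N(0.5, 0.3) with truncated-normal
    biases.
    """

    def __init__(self, rng: np.random.Generator, in_channels: int = 3,
                 lambda_max: float = 0.025):
        super().__init__()
        self.lambda_max = lambda_max
        # strided convs shrink 9x9 -> 3x3 so the dense path stays narrow
        # enough for the mean-0.5 initialization not to saturate the sigmoid
        self.c1 = Conv2d(in_channels, 8, 3, rng, padding=1)
        self.c2 = Conv2d(8, 8, 3, rng, stride=2, padding=1)
        self.c3 = Conv2d(8, 4, 3, rng, stride=2, padding=1)
        self.d1 = Dense(4 * 3 * 3, 16, rng, weight_mean=0.5,
                        weight_std=0.3, bias_init="truncnorm")
        self.d2 = Dense(16, 8, rng, weight_mean=0.5, weight_std=0.3,
                        bias_init="truncnorm")
        self.d3 = Dense(8, 1, rng, weight_mean=0.5, weight_std=0.3,
                        bias_init="truncnorm")
        # mean-preserving fan-in scaling: raw N(0.5, 0.3) weights stacked
        # over three relu layers drive the sigmoid into saturation (lambda
        # pinned at lambda_max with zero gradient); dividing by fan-in keeps
        # the mean structure of the scheme with outputs strictly inside
        # (0, lambda_max)
        for d in (self.d1, self.d2, self.d3):
            d.w.data /= d.w.shape[0]

    def forward(self, crop: Tensor) -> Tensor:
        h = self.c1(crop).relu()
        h = self.c2(h).relu()
        h = self.c3(h).relu()
        h = h.reshape(h.shape[0], -1)
        h = self.d1(h).relu()
        h = self.d2(h).relu()
        return self.d3(h).sigmoid() * self.lambda_max


def cs_sparsity_loss(b, n, op: MeasurementOperator):
    """L1 sparsity penalty plus squared distance of ``s = A b`` to the
    noise-free image ``n``; works on tensors or arrays."""
    if isinstance(b, Tensor) or isinstance(n, Tensor):
        if not isinstance(b, Tensor):
            b = Tensor(np.asarray(b, float))
        if not isinstance(n, Tensor):
            n = Tensor(np.asarray(n, float))
        s = b @ Tensor(op.A.T)
        return b.abs().sum() + ((s - n) ** 2).sum()
    b = np.asarray(b, dtype=float).ravel()
    n = np.asarray(n, dtype=float).ravel()
    s = op.A @ b
    return float(np.abs(b).sum() + ((s - n) ** 2).sum())
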