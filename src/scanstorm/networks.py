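"""Fitter architectures: 9x9x3 crop -> 8-channel feature space.

All four models share the output head: per pixel a probability ``p`` that
the pixel contains an emitter, subpixel offsets ``dx, dy`` relative to the
pixel center, an intensity ``N`` (in units of 10^3 detector counts),
uncertainties ``sx, sy, sN`` and a background estimate ``B``.  Output
activations bound the channels: sigmoid for ``p``, tanh for the offsets,
3 * sigmoid for the uncertainties and softplus for ``N`` and ``B``.

Architectures:

``cs_cnn``
    FISTA on the central frame as a prior; its lattice output is binned
    back to 9x9, concatenated with the crop and convolved to 8 channels.
``cs_inception``
    Two stacked inception blocks, each with a lambda-estimator + CS path
    (low iteration count in the first block, higher in the second), an
    asymmetric-filter path, a bottleneck path and a pass-through path.
``cs_unet``
    CS prior followed by a small encoder-decoder with skip connections.
``rec_unet``
    No explicit CS; a recursive encoder/decoder pair mimics unrolled
    compressed sensing: the feature-space estimate is decoded to image
    space, the residual to the input is encoded back and added to the
    estimate.  Weights are shared across recursions.
"""

from __future__ import annotations

import numpy as np

from .config import CSConfig
from .cs import LambdaNet, MeasurementOperator, default_operator, fista
from .nn import (Tensor, Module, Conv2d, BatchNorm2d, concat, avg_pool2d,
                 upsample_nearest, pad2d)

__all__ = [
    "CHANNELS", "FeatureSpace", "apply_output_activations",
    "CsCnn", "CsInception", "CsUnet", "RecursiveUnet", "build_model",
]

#: feature-space channel order
CHANNELS = {"p": 0, "dx": 1, "dy": 2, "N": 3, "sx": 4, "sy": 5, "sN": 6, "B": 7}

PHOTON_SCALE = 1e3  # N and B are trained in detector counts / 1000


class FeatureSpace:
    """8-channel per-pixel output with activation ranges enforced."""

    def __init__(self, data: Tensor):
        if data.shape[-3:] != (8, 9, 9):
            raise ValueError("feature space must be (..., 8, 9, 9)")
        self.data = data

    def channel(self, name: str) -> Tensor:
        return self.data[:, CHANNELS[name]]

    def numpy(self) -> np.ndarray:
        return self.data.data

    def validate(self):
        a = self.numpy()
        ch = CHANNELS
        assert np.all((a[:, ch["p"]] >= 0) & (a[:, ch["p"]] <= 1))
        for k in ("sx", "sy", "sN"):
            assert np.all((a[:, ch[k]] >= 0) & (a[:, ch[k]] <= 3))
        for k in ("dx", "dy"):
            assert np.all((a[:, ch[k]] >= -1) & (a[:, ch[k]] <= 1))
        assert np.all(a[:, ch["N"]] >= 0) and np.all(a[:, ch["B"]] >= 0)
        return self


def apply_output_activations(raw: Tensor) -> FeatureSpace:
    """Map raw 8-channel network output to the bounded feature space."""
    if not isinstance(raw, Tensor):
        raw = Tensor(np.asarray(raw, dtype=float))
    if raw.ndim == 3:
        raw = raw.reshape(1, *raw.shape)
    p = raw[:, 0:1].sigmoid()
    d = raw[:, 1:3].tanh()
    n = raw[:, 3:4].softplus()
    s = raw[:, 4:7].sigmoid() * 3.0
    b = raw[:, 7:8].softplus()
    return FeatureSpace(concat([p, d, n, s, b], axis=1))


def _normalize(crop: Tensor) -> Tensor:
    """Scale detector counts by the fixed photon scale (counts / 1000).

    A fixed scale (rather than per-crop max) keeps absolute intensity
    information — the mixture loss supervises N in these same units — and
    makes the input distribution independent of the crop's noise level.
    """
    return crop * (1.0 / PHOTON_SCALE)


def _check_crop(crop) -> Tensor:
    if not isinstance(crop, Tensor):
        crop = Tensor(np.asarray(crop, dtype=float))
    if crop.ndim == 3:
        crop = crop.reshape(1, *crop.shape)
    if crop.shape[1:] != (3, 9, 9):
        raise ValueError("crop must be (N, 3, 9, 9)")
    return crop


class _ConvBlock(Module):
    def __init__(self, c_in, c_out, rng, k=3, stride=1):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, rng, stride=stride,
                           padding=(k // 2 if np.isscalar(k) else
                                    (k[0] // 2, k[1] // 2)))

    def forward(self, x):
        return self.conv(x).relu()


class _CsPrior(Module):
    """Shared FISTA-prior front end: lambda estimation, unrolled FISTA on
    the central frame, lattice binned back to one 9x9 channel."""

    def __init__(self, rng, cs: CSConfig):
        super().__init__()
        self.cs = cs
        self.lam_net = LambdaNet(rng, in_channels=3, lambda_max=cs.lambda_max)
        self.op: MeasurementOperator = default_operator(cs.upsampling)

    def forward(self, crop_n: Tensor) -> Tensor:
        lam = self.lam_net(crop_n)
        y = crop_n[:, 1].reshape(crop_n.shape[0], 81)
        b = fista(y, self.op, lam, self.cs)
        m = 9 * self.cs.upsampling
        b_img = b.reshape(b.shape[0], 1, m, m)
        return avg_pool2d(b_img, self.cs.upsampling) * float(self.cs.upsampling ** 2)


class CsCnn(Module):
    """FISTA prior + plain convolutional stack."""

    def __init__(self, rng: np.random.Generator, cs: CSConfig | None = None,
                 width: int = 64):
        super().__init__()
        self.prior = _CsPrior(rng, cs or CSConfig(n_iter=20))
        self.b1 = _ConvBlock(4, width, rng)
        self.b2 = _ConvBlock(width, width, rng)
        self.b3 = _ConvBlock(width, width, rng)
        self.out = Conv2d(width, 8, 3, rng, padding=1)
        self.out.b.data[0] = P_BIAS_INIT

    def forward(self, crop) -> FeatureSpace:
        x = _normalize(_check_crop(crop))
        s = self.prior(x)
        h = concat([x, s], axis=1)
        h = self.b3(self.b2(self.b1(h)))
        return apply_output_activations(self.out(h))


class _InceptionBlock(Module):
    """Four parallel paths: CS, asymmetric filters, bottleneck, pass-through."""

    def __init__(self, c_in, rng, cs: CSConfig, width: int = 16):
        super().__init__()
        self.cs_path = _CsPriorFrom(c_in, rng, cs)
        self.asym_a = _ConvBlock(c_in, width, rng, k=(1, 3))
        self.asym_b = _ConvBlock(width, width, rng, k=(3, 1))
        self.bottleneck = _ConvBlock(c_in, width, rng, k=1)
        self.cs_conv = _ConvBlock(1, width, rng)

    def forward(self, x):
        s = self.cs_conv(self.cs_path(x))
        a = self.asym_b(self.asym_a(x))
        bn = self.bottleneck(x)
        passthrough = x.relu()
        return concat([s, a, bn, passthrough], axis=1)


class _CsPriorFrom(Module):
    """CS path for arbitrary input channels: bottleneck to a single image,
    lambda estimation, FISTA, downsample."""

    def __init__(self, c_in, rng, cs: CSConfig):
        super().__init__()
        self.cs = cs
        self.proj = Conv2d(c_in, 1, 1, rng)
        self.lam_net = LambdaNet(rng, in_channels=c_in, lambda_max=cs.lambda_max)
        self.op = default_operator(cs.upsampling)

    def forward(self, x):
        lam = self.lam_net(x)
        y = self.proj(x).relu().reshape(x.shape[0], 81)
        b = fista(y, self.op, lam, self.cs)
        m = 9 * self.cs.upsampling
        b_img = b.reshape(b.shape[0], 1, m, m)
        return avg_pool2d(b_img, self.cs.upsampling) * float(self.cs.upsampling ** 2)


class CsInception(Module):
    """Two stacked inception blocks; the first runs FISTA at a low
    iteration count, the second at a higher one."""

    def __init__(self, rng: np.random.Generator, cs: CSConfig | None = None,
                 n_iter_first: int = 5, n_iter_second: int = 20,
                 width: int = 16):
        super().__init__()
        base = cs or CSConfig()
        cs1 = CSConfig(lambda_max=base.lambda_max, n_iter=n_iter_first,
                       upsampling=base.upsampling)
        cs2 = CSConfig(lambda_max=base.lambda_max, n_iter=n_iter_second,
                       upsampling=base.upsampling)
        self.block1 = _InceptionBlock(3, rng, cs1, width)
        c_mid = 3 * width + 3
        self.block2 = _InceptionBlock(c_mid, rng, cs2, width)
        c_out = 3 * width + c_mid
        self.head1 = _ConvBlock(c_out, 32, rng)
        self.out = Conv2d(32, 8, 3, rng, padding=1)
        self.out.b.data[0] = P_BIAS_INIT

    def forward(self, crop) -> FeatureSpace:
        x = _normalize(_check_crop(crop))
        h = self.block1(x)
        h = self.block2(h)
        h = self.head1(h)
        return apply_output_activations(self.out(h))

    def debug_first_block(self, crop) -> dict:
        """Functional-test view of the first inception block: the
        estimated lambda, the CS-reconstructed (binned) image and the
        block output, for monitoring the lambda estimation."""
        x = _normalize(_check_crop(crop))
        lam = self.block1.cs_path.lam_net(x)
        cs_img = self.block1.cs_path(x)
        return {"lambda": lam.data.ravel().copy(),
                "cs_reconstruction": cs_img.data.copy(),
                "block_output": self.block1(x).data.copy()}


#: initial bias of the raw p channel: sigmoid(-3) ~ 0.047, so the summed
#: probability mass starts near the typical emitter count instead of 40.5
P_BIAS_INIT = -3.0


class _UNetCore(Module):
    """Two-level encoder-decoder with skip connections on 9x9 inputs
    (padded to 12x12 internally)."""

    def __init__(self, c_in, c_out, rng, width: int = 16):
        super().__init__()
        w = width
        self.enc1 = _ConvBlock(c_in, w, rng)
        self.enc1b = _ConvBlock(w, w, rng)
        self.enc2 = _ConvBlock(w, 2 * w, rng)
        self.bottom = _ConvBlock(2 * w, 2 * w, rng)
        self.dec2 = _ConvBlock(3 * w, w, rng)
        self.dec1 = _ConvBlock(w, w, rng)
        self.out = Conv2d(w, c_out, 3, rng, padding=1)

    def forward(self, x):
        x = pad2d(x, ((1, 2), (1, 2)))            # 9 -> 12
        e1 = self.enc1b(self.enc1(x))             # 12x12, w
        e2 = self.enc2(avg_pool2d(e1, 2))         # 6x6, 2w
        b = self.bottom(avg_pool2d(e2, 2))        # 3x3, 2w
        u2 = upsample_nearest(b, 2)               # 6x6
        d2 = self.dec2(concat([u2, avg_pool2d(e1, 2)], axis=1))
        u1 = upsample_nearest(d2, 2)              # 12x12
        d1 = self.dec1(u1 + e1)
        out = self.out(d1)
        return out[:, :, 1:10, 1:10]              # crop back to 9x9


class CsUnet(Module):
    """FISTA prior concatenated to the crop, then a U-Net."""

    def __init__(self, rng: np.random.Generator, cs: CSConfig | None = None,
                 width: int = 16):
        super().__init__()
        self.prior = _CsPrior(rng, cs or CSConfig(n_iter=20))
        self.core = _UNetCore(4, 8, rng, width)
        self.core.out.b.data[0] = P_BIAS_INIT

    def forward(self, crop) -> FeatureSpace:
        x = _normalize(_check_crop(crop))
        s = self.prior(x)
        return apply_output_activations(self.core(concat([x, s], axis=1)))


class RecursiveUnet(Module):
    """Iterative feature-space refinement with shared weights.

    ``F(0)`` is produced by an encoder U-Net.  Each recursion decodes the
    feature space to image space, adds the background estimate ``F_bg``,
    forms the residual to the input crop (batch-normalized together with
    the initial image state), encodes the residual and adds the update:
    ``F(k+1) = F(k) + F_update``.  The parameter count is independent of
    the number of recursions.
    """

    def __init__(self, rng: np.random.Generator, n_recursions: int = 2,
                 width: int = 16):
        super().__init__()
        self.n_recursions = n_recursions
        self.encoder = _UNetCore(3, 8, rng, width)
        self.encoder.out.b.data[0] = P_BIAS_INIT
        self.res_encoder = _UNetCore(3, 8, rng, width)
        self.decoder_a = _ConvBlock(8, width, rng)
        self.decoder_b = Conv2d(width, 3, 3, rng, padding=1)
        self.bg_head = Conv2d(8, 3, 1, rng)
        self.bn = BatchNorm2d(3)

    def decode(self, F: Tensor) -> Tensor:
        return self.decoder_b(self.decoder_a(F))

    def forward(self, crop, n_recursions: int | None = None) -> FeatureSpace:
        n_rec = self.n_recursions if n_recursions is None else n_recursions
        if n_rec < 1:
            raise ValueError("n_recursions must be >= 1")
        x0 = _normalize(_check_crop(crop))
        F = self.encoder(x0)
        for _ in range(n_rec):
            decoded = self.decode(F) + self.bg_head(F)
            xt = self.bn(decoded + x0)
            resid = x0 - xt
            F = F + self.res_encoder(resid)
        return apply_output_activations(F)


def build_model(architecture: str, rng: np.random.Generator,
                cs: CSConfig | None = None, **kw) -> Module:
    archs = {
        "cs_cnn": lambda: CsCnn(rng, cs, **kw),
        "cs_inception": lambda: CsInception(rng, cs, **kw),
        "cs_unet": lambda: CsUnet(rng, cs, **kw),
        "rec_unet": lambda: RecursiveUnet(rng, **kw),
    }
    if architecture not in archs:
        raise ValueError(f"unknown architecture {architecture!r}; "
                         f"choose from {sorted(archs)}")
    return archs[architecture]()
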