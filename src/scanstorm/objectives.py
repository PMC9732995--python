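"""Composite training loss: Gaussian-mixture localisation term, count term
and background term.

The localisation term treats the per-pixel predictions as a Gaussian
mixture over emitter position and intensity: pixel ``i`` contributes a
component at ``(x_px + dx_i, y_px + dy_i, N_i)`` with weight ``p_i`` and
per-axis spreads ``(sx_i, sy_i, sN_i)``.  For each ground-truth emitter
``t`` the mixture density is

    mix_t = sum_i p_i exp(-[(x_i-x_t)^2/sx_i^2 + (y_i-y_t)^2/sy_i^2
                            + (N_i-N_t)^2/sN_i^2])
            / ((2 pi)^(3/2) sx_i sy_i sN_i) / sum_m p_m

and the minimized loss is ``-sum_t log(mix_t + eps)``.  The count term is
a Gaussian likelihood of the summed probability mass against the true
emitter count with variance ``sigma_c = sum_i p_i (1 - p_i)``; the
background term is the mean absolute deviation of the predicted background
from the noise-free image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import CHANNELS, FeatureSpace, PHOTON_SCALE
from .nn import Tensor
from .simulate import RoiCrop

__all__ = [
    "GroundTruthBatch", "localisation_mixture", "localisation_loss",
    "count_loss", "background_loss", "total_loss",
]

EPS = 1e-6

# pixel-center coordinates of the 9x9 grid, flattened row-major
_XPX = (np.tile(np.arange(9), 9) + 0.5)
_YPX = (np.repeat(np.arange(9), 9) + 0.5)


@dataclass
class GroundTruthBatch:
    """Padded per-crop ground truth.

    ``x``, ``y`` in crop-local pixel units, ``N`` in units of
    ``PHOTON_SCALE`` detector counts; ``mask`` flags valid emitters;
    ``count`` is the emitter count per crop; ``noiseless`` is the
    pre-noise central frame in the same units as ``N``.
    """

    x: np.ndarray          # (B, K)
    y: np.ndarray          # (B, K)
    N: np.ndarray          # (B, K)
    mask: np.ndarray       # (B, K) float 0/1
    count: np.ndarray      # (B,)
    noiseless: np.ndarray  # (B, 9, 9)

    def __post_init__(self):
        if not np.array_equal(self.mask.sum(axis=1), self.count):
            raise ValueError("count must equal the number of valid emitters")

    @classmethod
    def from_crops(cls, crops: list[RoiCrop]) -> "GroundTruthBatch":
        B = len(crops)
        K = max(1, max(len(c.truth) for c in crops))
        x = np.zeros((B, K))
        y = np.zeros((B, K))
        n = np.zeros((B, K))
        mask = np.zeros((B, K))
        for i, c in enumerate(crops):
            for j, t in enumerate(c.truth):
                x[i, j] = t.x_px
                y[i, j] = t.y_px
                n[i, j] = t.photons / PHOTON_SCALE
                mask[i, j] = 1.0
        noiseless = np.stack([
            c.noiseless if c.noiseless is not None else np.zeros((9, 9))
            for c in crops]) / PHOTON_SCALE
        return cls(x=x, y=y, N=n, mask=mask, count=mask.sum(axis=1),
                   noiseless=noiseless)


def _fs_tensor(fs) -> Tensor:
    if isinstance(fs, FeatureSpace):
        return fs.data
    if not isinstance(fs, Tensor):
        fs = Tensor(np.asarray(fs, dtype=float))
    if fs.ndim == 3:
        fs = fs.reshape(1, *fs.shape)
    return fs


def _flat(t: Tensor, ch: str) -> Tensor:
    return t[:, CHANNELS[ch]].reshape(t.shape[0], 1, 81)


def localisation_mixture(fs, gt: GroundTruthBatch) -> Tensor:
    """Per-emitter mixture densities, shape (B, K) (printed form, higher =
    better; invalid padding slots return 0)."""
    t = _fs_tensor(fs)
    p = _flat(t, "p")
    xi = _flat(t, "dx") + _XPX.reshape(1, 1, 81)
    yi = _flat(t, "dy") + _YPX.reshape(1, 1, 81)
    Ni = _flat(t, "N")
    sx = _flat(t, "sx") + EPS
    sy = _flat(t, "sy") + EPS
    sN = _flat(t, "sN") + EPS
    xt = Tensor(gt.x[:, :, None])
    yt = Tensor(gt.y[:, :, None])
    Nt = Tensor(gt.N[:, :, None])
    expo = (((xi - xt) ** 2) / (sx ** 2)
            + ((yi - yt) ** 2) / (sy ** 2)
            + ((Ni - Nt) ** 2) / (sN ** 2))
    norm = (2.0 * np.pi) ** 1.5
    comp = p * (-expo).exp() / (sx * sy * sN * norm)
    psum = p.sum(axis=2) + EPS                     # (B, 1)
    mix = comp.sum(axis=2) / psum                  # (B, K)
    return mix * Tensor(gt.mask)


def localisation_loss(fs, gt: GroundTruthBatch) -> Tensor:
    """Negative log mixture density summed over true emitters, averaged
    over the batch; crops without emitters contribute 0.

    Computed in the log domain (log-sum-exp over mixture components) so
    the gradient stays finite when every component is far from the truth.
    """
    t = _fs_tensor(fs)
    p = _flat(t, "p")
    xi = _flat(t, "dx") + _XPX.reshape(1, 1, 81)
    yi = _flat(t, "dy") + _YPX.reshape(1, 1, 81)
    Ni = _flat(t, "N")
    sx = _flat(t, "sx") + EPS
    sy = _flat(t, "sy") + EPS
    sN = _flat(t, "sN") + EPS
    xt = Tensor(gt.x[:, :, None])
    yt = Tensor(gt.y[:, :, None])
    Nt = Tensor(gt.N[:, :, None])
    expo = (((xi - xt) ** 2) / (sx ** 2)
            + ((yi - yt) ** 2) / (sy ** 2)
            + ((Ni - Nt) ** 2) / (sN ** 2))
    lognorm = (sx * sy * sN * (2.0 * np.pi) ** 1.5).log()
    arg = (p + 1e-300).log() - expo - lognorm          # (B, K, 81)
    shift = Tensor(arg.data.max(axis=2, keepdims=True))  # constant, no grad
    lse = ((arg - shift).exp().sum(axis=2, keepdims=True)).log() + shift
    log_psum = (p.sum(axis=2) + EPS).log()             # (B, 1)
    logmix = lse.reshape(*lse.shape[:2]) - log_psum    # (B, K)
    return -((logmix * Tensor(gt.mask)).sum(axis=1)).mean()


def count_loss(fs, gt: GroundTruthBatch, form: str = "printed",
               var_floor: float | None = None) -> Tensor:
    """Count term: quadratic misfit of total probability mass versus the
    true count, with variance ``sigma_c = sum p_i (1 - p_i)``.

    ``form="printed"`` uses the sign convention ``... - ln(sqrt(2 pi
    sigma_c))``; ``form="nll"`` is the Gaussian negative log-likelihood
    (``+ ln``), the variant used for training, which rewards confident
    (near 0/1) probability maps.

    ``var_floor`` bounds ``sigma_c`` from below.  The training path uses
    1e-2: once the probabilities saturate, a single miscounted crop would
    otherwise contribute a quadratic term scaled by 1/(2e-6) whose clipped
    gradient still dominates whole batches and can collapse the model into
    a degenerate optimum (all mass at a fixed corner with maximal sigma).
    """
    if var_floor is None:
        var_floor = EPS if form == "printed" else 1e-2
    t = _fs_tensor(fs)
    p = t[:, CHANNELS["p"]].reshape(t.shape[0], 81)
    psum = p.sum(axis=1)
    sigma_c = (p * (1.0 - p)).sum(axis=1) + var_floor
    quad = ((psum - Tensor(gt.count)) ** 2) / (2.0 * sigma_c)
    logterm = ((2.0 * np.pi) * sigma_c).sqrt().log()
    if form == "printed":
        out = quad - logterm
    elif form == "nll":
        out = quad + logterm
    else:
        raise ValueError("form must be 'printed' or 'nll'")
    return out.mean()


def background_loss(fs, gt: GroundTruthBatch) -> Tensor:
    """Mean absolute deviation of the background channel from the
    noise-free image."""
    t = _fs_tensor(fs)
    B = t[:, CHANNELS["B"]]
    diff = ((B - Tensor(gt.noiseless)) ** 2 + 1e-12).sqrt()
    return diff.mean()


def total_loss(fs, gt: GroundTruthBatch, count_form: str = "nll",
               include_components: bool = False):
    """Sum of the three loss terms (training form by default)."""
    l_loc = localisation_loss(fs, gt)
    l_cnt = count_loss(fs, gt, form=count_form)
    l_bg = background_loss(fs, gt)
    total = l_loc + l_cnt + l_bg
    if include_components:
        return total, {"loc": float(l_loc.data), "count": float(l_cnt.data),
                       "bg": float(l_bg.data)}
    return total
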