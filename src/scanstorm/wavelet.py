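"""Trainable orthogonal wavelet filter bank, ROI detection and cropping.

The filter bank shares its taps between analysis (decompose) and synthesis
(reconstruct).  Orthogonality of the high-pass and low-pass taps is
maintained by a Gram-Schmidt coupling step applied before every use, so it
holds throughout training.  A per-subband bias followed by ReLU acts as a
learned soft threshold on the decomposed frequency images; trained against
noise-free simulated frames, the bank learns to keep PSF-like frequency
content and suppress the rest.  Candidate emitters are strict local maxima
of the denoised image and are cropped to 9x9x3 patches with their temporal
neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .nn import Tensor, Module, Adam, conv2d, pad2d
from .simulate import FrameStack, RoiCrop

__all__ = [
    "FilterBank", "PeakList", "gram_schmidt_couple", "decompose",
    "reconstruct", "detect_peaks", "crop_rois", "train_wavelet_denoiser",
    "robust_threshold", "denoise_frame",
]

_HAAR_LP = np.array([1.0, 1.0]) / np.sqrt(2.0)
_HAAR_HP = np.array([1.0, -1.0]) / np.sqrt(2.0)


def gram_schmidt_couple(hp, lp):
    """Couple the taps: ``hp_n = hp``; ``lp_n = lp - proj_hp(lp)``.

    Works on numpy arrays or autodiff tensors; the returned pair satisfies
    ``<hp_n, lp_n> = 0``.
    """
    if isinstance(hp, Tensor) or isinstance(lp, Tensor):
        num = (hp * lp).sum()
        den = (hp * hp).sum()
        return hp, lp - hp * (num / den)
    hp = np.asarray(hp, dtype=float)
    lp = np.asarray(lp, dtype=float)
    den = float(hp @ hp)
    if den == 0.0:
        raise ValueError("degenerate filter: hp must be nonzero")
    return hp, lp - (float(hp @ lp) / den) * hp


class FilterBank(Module):
    """Trainable two-tap (by default) orthogonal filter bank.

    Parameters are the raw high-pass and low-pass taps plus one bias per
    subband and level; the coupled taps are recomputed from the raw taps on
    every call, so orthogonality survives any gradient update.
    """

    def __init__(self, taps: int = 2, levels: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if taps % 2:
            raise ValueError("tap count must be even")
        self.levels = levels
        self.taps = taps
        if rng is None:
            hp, lp = _HAAR_HP.copy(), _HAAR_LP.copy()
            if taps > 2:
                hp = np.pad(hp, (0, taps - 2))
                lp = np.pad(lp, (0, taps - 2))
        else:
            hp = rng.normal(0, 1, taps)
            lp = rng.normal(0, 1, taps)
        self.hp = Tensor(hp, requires_grad=True)
        self.lp = Tensor(lp, requires_grad=True)
        # biases: (levels, 3) for LH/HL/HH plus one for the final LL
        self.bias = Tensor(np.zeros((levels, 3)), requires_grad=True)
        self.bias_ll = Tensor(np.zeros(1), requires_grad=True)
        # intensity scale the biases were trained at (see denoise_frame)
        self.scale = 1.0

    def coupled(self):
        if float((self.hp.data ** 2).sum()) == 0.0:
            raise ValueError("degenerate filter: hp must be nonzero")
        return gram_schmidt_couple(self.hp, self.lp)


def _row_kernel(t: Tensor) -> Tensor:
    return t.reshape(1, 1, 1, t.shape[0])


def _col_kernel(t: Tensor) -> Tensor:
    return t.reshape(1, 1, t.shape[0], 1)


def _analysis_level(x: Tensor, lp: Tensor, hp: Tensor):
    lo = conv2d(x, _row_kernel(lp), stride=(1, 2))
    hi = conv2d(x, _row_kernel(hp), stride=(1, 2))
    ll = conv2d(lo, _col_kernel(lp), stride=(2, 1))
    lh = conv2d(lo, _col_kernel(hp), stride=(2, 1))
    hl = conv2d(hi, _col_kernel(lp), stride=(2, 1))
    hh = conv2d(hi, _col_kernel(hp), stride=(2, 1))
    return ll, (lh, hl, hh)


def _synthesis_1d(a: Tensor, d: Tensor, lp_s: Tensor, hp_s: Tensor, axis: int):
    """Invert one stride-2 analysis step along rows (axis=3) or cols (axis=2)."""
    L = lp_s.shape[0]
    rev = slice(None, None, -1)

    def up(z, taps):
        k = taps[rev]
        zd = _dilate_axis(z, 2, axis)
        if axis == 3:
            zd = pad2d(zd, ((0, 0), (L - 1, 0)))
            return conv2d(zd, _row_kernel(k))
        zd = pad2d(zd, ((L - 1, 0), (0, 0)))
        return conv2d(zd, _col_kernel(k))

    return up(a, lp_s) + up(d, hp_s)


def _dilate_axis(x: Tensor, k: int, axis: int) -> Tensor:
    """Insert k-1 zeros between samples along one spatial axis."""
    n, c, h, w = x.shape
    if axis == 3:
        shape = (n, c, h, w * k)
        idx = (slice(None), slice(None), slice(None), slice(None, None, k))
    else:
        shape = (n, c, h * k, w)
        idx = (slice(None), slice(None), slice(None, None, k), slice(None))
    out = Tensor(np.zeros(shape))

    def bw(g):
        x._accum(g[idx])

    out.data[idx] = x.data
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = bw
    return out


def _as_batch(image) -> Tensor:
    t = image if isinstance(image, Tensor) else Tensor(np.asarray(image, float))
    if t.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    return t


def decompose(image, bank: FilterBank, activation: bool = True):
    """Separable 2D analysis: per level the LL band is split into four
    subbands; bias + ReLU act on each detail band (and the final LL) when
    ``activation`` is on.  Returns ``(ll, [(lh, hl, hh), ...])``.
    """
    hp_n, lp_n = bank.coupled()
    x = _as_batch(image)
    h, w = x.shape[2:]
    if h % (2 ** bank.levels) or w % (2 ** bank.levels):
        raise ValueError("image dims must be divisible by 2^levels (pad first)")
    details = []
    for lev in range(bank.levels):
        x, (lh, hl, hh) = _analysis_level(x, lp_n, hp_n)
        if activation:
            lh = (lh + bank.bias[lev, 0]).relu()
            hl = (hl + bank.bias[lev, 1]).relu()
            hh = (hh + bank.bias[lev, 2]).relu()
        details.append((lh, hl, hh))
    if activation:
        x = (x + bank.bias_ll[0]).relu()
    return x, details


def reconstruct(ll, details, bank: FilterBank):
    """Synthesis with the same (coupled) taps, normalized by their energy.

    With zero bias and no ReLU clipping this inverts :func:`decompose`
    exactly for the default two-tap bank.
    """
    hp_n, lp_n = bank.coupled()
    lp_s = lp_n / (lp_n * lp_n).sum()
    hp_s = hp_n / (hp_n * hp_n).sum()
    x = ll if isinstance(ll, Tensor) else Tensor(np.asarray(ll, float))
    for lh, hl, hh in reversed(details):
        lo = _synthesis_1d(x, lh, lp_s, hp_s, axis=2)
        hi = _synthesis_1d(hl, hh, lp_s, hp_s, axis=2)
        x = _synthesis_1d(lo, hi, lp_s, hp_s, axis=3)
    return x


@dataclass
class PeakList:
    """Detected candidate emitters: integer positions and their scores."""

    peaks: list = field(default_factory=list)    # (frame, row, col)
    scores: list = field(default_factory=list)   # denoised value at the peak


def robust_threshold(image: np.ndarray, k: float = 3.0) -> float:
    """k times the MAD-based robust standard deviation, above the median."""
    med = np.median(image)
    mad = np.median(np.abs(image - med))
    return float(med + k * 1.4826 * mad)


def detect_peaks(denoised: np.ndarray, threshold: float) -> PeakList:
    """Strict 8-neighborhood local maxima above ``threshold``.

    Plateau ties are broken by row-major first occurrence.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    img = np.asarray(denoised, dtype=float)
    frames = img[None] if img.ndim == 2 else img
    out = PeakList()
    foot = np.ones((3, 3), bool)
    foot[1, 1] = False
    for f, frame in enumerate(frames):
        hi = ndimage.maximum_filter(frame, footprint=foot, mode="constant",
                                    cval=-np.inf)
        lo = ndimage.minimum_filter(frame, footprint=foot, mode="constant",
                                    cval=np.inf)
        # at least as high as every neighbour and strictly above one of
        # them: flat plateaus (constant regions) are not maxima
        cand = np.argwhere((frame > threshold) & (frame >= hi) & (frame > lo))
        taken: list[tuple[int, int]] = []
        for r, c in cand:
            if frame[r, c] == hi[r, c]:
                # tie with an equal neighbour: keep row-major first occurrence
                if any(abs(r - tr) <= 1 and abs(c - tc) <= 1 for tr, tc in taken):
                    continue
            taken.append((r, c))
            out.peaks.append((f, int(r), int(c)))
            out.scores.append(float(frame[r, c]))
    return out


def crop_rois(stack: FrameStack | np.ndarray, peaks: PeakList) -> list[RoiCrop]:
    """9x9x3 patches centered on each peak; out-of-bounds regions and
    missing temporal neighbours are zero-padded."""
    frames = stack.frames if isinstance(stack, FrameStack) else np.asarray(stack)
    T, H, W = frames.shape
    crops = []
    for (f, r, c) in peaks.peaks:
        patch = np.zeros((3, 9, 9))
        for k, ff in enumerate((f - 1, f, f + 1)):
            if not 0 <= ff < T:
                continue
            r0, r1 = r - 4, r + 5
            c0, c1 = c - 4, c + 5
            sr0, sc0 = max(r0, 0), max(c0, 0)
            sr1, sc1 = min(r1, H), min(c1, W)
            patch[k, sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = \
                frames[ff, sr0:sr1, sc0:sc1]
        crops.append(RoiCrop(pixels=patch, origin=(f, r - 4, c - 4)))
    return crops


def _pad_to_multiple(img: np.ndarray, m: int) -> tuple[np.ndarray, tuple]:
    h, w = img.shape
    ph, pw = (-h) % m, (-w) % m
    return np.pad(img, ((0, ph), (0, pw)), mode="reflect"), (h, w)


def denoise_frame(frame: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Run one frame through the filter bank (pad, decompose with bias+ReLU,
    reconstruct, crop).

    The frame is divided by the bank's training scale first — the learned
    biases act as soft thresholds and are only meaningful at that scale.
    For an untrained bank (all biases zero) the bias+ReLU stage is skipped:
    clipping negative detail coefficients without a learned threshold only
    introduces blocking artifacts, whereas the linear bank reconstructs
    the frame exactly.
    """
    trained = bool(np.any(bank.bias.data) or np.any(bank.bias_ll.data))
    padded, (h, w) = _pad_to_multiple(np.asarray(frame, float) / bank.scale,
                                      2 ** bank.levels)
    ll, det = decompose(padded, bank, activation=trained)
    rec = reconstruct(ll, det, bank)
    return rec.data[0, 0, :h, :w] * bank.scale


def train_wavelet_denoiser(crops: list[RoiCrop], epochs: int = 40,
                           lr: float = 1e-2, bank: FilterBank | None = None,
                           batch_size: int = 64,
                           rng: np.random.Generator | int | None = None):
    """Fit taps and biases to minimize the MSE between the reconstructed
    central frame of each crop and its noise-free target.

    Returns ``(bank, losses)`` with one mean loss per epoch.  Raises if the
    loss diverges.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(0 if rng is None else rng)
    if bank is None:
        bank = FilterBank()
    noisy = np.stack([c.pixels[1] for c in crops])[:, None]
    clean = np.stack([c.noiseless for c in crops])[:, None]
    scale = max(clean.max(), 1.0)
    noisy, clean = noisy / scale, clean / scale
    bank.scale = float(scale)
    pad = (-noisy.shape[-1]) % (2 ** bank.levels)
    if pad:
        noisy = np.pad(noisy, ((0, 0), (0, 0), (0, pad), (0, pad)), mode="reflect")
        clean = np.pad(clean, ((0, 0), (0, 0), (0, pad), (0, pad)), mode="reflect")
    opt = Adam(bank.parameters(), lr=lr)
    losses = []
    n = len(crops)
    for _ in range(epochs):
        order = rng.permutation(n)
        ep = []
        for i0 in range(0, n, batch_size):
            idx = order[i0:i0 + batch_size]
            x = Tensor(noisy[idx])
            ll, det = decompose(x, bank, activation=True)
            rec = reconstruct(ll, det, bank)
            loss = ((rec - Tensor(clean[idx])) ** 2).mean()
            if not np.isfinite(loss.data):
                raise FloatingPointError("wavelet training diverged (NaN loss)")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep.append(float(loss.data))
        losses.append(float(np.mean(ep)))
    return bank, losses
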