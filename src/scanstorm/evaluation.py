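"""Quantitative evaluation: emitter matching, Jaccard index, RMSE and
Fourier ring correlation.

Predictions and ground truth are matched per frame by minimum-cost
one-to-one assignment (Hungarian algorithm) within a distance tolerance;
matched pairs are true positives, unmatched predictions false positives,
unmatched truths false negatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MatchResult", "match_localisations", "jaccard_index", "rmse",
    "frc", "frc_from_table", "evaluate_crops",
]

#: default matching radius [nm] (2.5 px at 100 nm pixels)
DEFAULT_TOLERANCE_NM = 250.0


@dataclass
class MatchResult:
    """One-to-one matching outcome."""

    pairs: list = field(default_factory=list)  # (pred_idx, truth_idx, dist_nm)
    TP: int = 0
    FP: int = 0
    FN: int = 0


def _match_frame(pred_xy: np.ndarray, truth_xy: np.ndarray,
                 tolerance_nm: float):
    """Hungarian assignment within tolerance; returns index pairs+distances."""
    if len(pred_xy) == 0 or len(truth_xy) == 0:
        return []
    d = np.linalg.norm(pred_xy[:, None, :] - truth_xy[None, :, :], axis=2)
    cost = np.where(d <= tolerance_nm, d, 1e9)
    ri, ci = linear_sum_assignment(cost)
    return [(int(i), int(j), float(d[i, j]))
            for i, j in zip(ri, ci) if d[i, j] <= tolerance_nm]


def match_localisations(pred, truth, tolerance_nm: float = DEFAULT_TOLERANCE_NM,
                        pixel_size_nm: float = 100.0) -> MatchResult:
    """Match predicted to true emitters per frame.

    ``pred`` and ``truth`` are DataFrames with columns frame, x_px, y_px
    (or arrays of shape (n, 3) = [frame, x_px, y_px]).
    """
    if tolerance_nm <= 0:
        raise ValueError("tolerance_nm must be > 0")

    def to_df(t):
        if isinstance(t, pd.DataFrame):
            return t
        t = np.asarray(t, dtype=float).reshape(-1, 3)
        return pd.DataFrame(t, columns=["frame", "x_px", "y_px"])

    pred, truth = to_df(pred), to_df(truth)
    result = MatchResult()
    frames = sorted(set(pred["frame"]).union(truth["frame"]))
    for f in frames:
        p = pred[pred["frame"] == f]
        t = truth[truth["frame"] == f]
        pxy = p[["x_px", "y_px"]].to_numpy() * pixel_size_nm
        txy = t[["x_px", "y_px"]].to_numpy() * pixel_size_nm
        pairs = _match_frame(pxy, txy, tolerance_nm)
        result.pairs.extend((int(p.index[i]), int(t.index[j]), dist)
                            for i, j, dist in pairs)
        result.TP += len(pairs)
        result.FP += len(p) - len(pairs)
        result.FN += len(t) - len(pairs)
    return result


def jaccard_index(m: MatchResult) -> float:
    """TP / (TP + FP + FN); 1 when all three are zero."""
    denom = m.TP + m.FP + m.FN
    if denom == 0:
        return 1.0
    return m.TP / denom


def rmse(m: MatchResult) -> float:
    """Root mean squared matched-pair distance [nm]; NaN if no matches."""
    if m.TP == 0:
        warnings.warn("RMSE undefined with zero matched pairs", stacklevel=2)
        return float("nan")
    d = np.array([dist for _, _, dist in m.pairs])
    return float(np.sqrt(np.mean(d ** 2)))


def frc(I1: np.ndarray, I2: np.ndarray):
    """Fourier ring correlation curve and its mean up to Nyquist.

    Returns ``(curve, mean_coefficient)``; ring ``r`` collects spatial
    frequencies with ``r <= |k| < r + 1`` (in FFT pixels).
    """
    I1 = np.asarray(I1, dtype=float)
    I2 = np.asarray(I2, dtype=float)
    if I1.shape != I2.shape or I1.shape[0] != I1.shape[1]:
        raise ValueError("images must be square and of identical shape")
    n = I1.shape[0]
    F1 = np.fft.fftshift(np.fft.fft2(I1))
    F2 = np.fft.fftshift(np.fft.fft2(I2))
    c = n // 2
    yy, xx = np.indices((n, n))
    r = np.hypot(yy - c, xx - c).astype(int)
    n_rings = n // 2
    num = np.zeros(n_rings)
    d1 = np.zeros(n_rings)
    d2 = np.zeros(n_rings)
    mask = r < n_rings
    np.add.at(num, r[mask], (F1 * np.conj(F2)).real[mask])
    np.add.at(d1, r[mask], (np.abs(F1) ** 2)[mask])
    np.add.at(d2, r[mask], (np.abs(F2) ** 2)[mask])
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = num / np.sqrt(d1 * d2)
    curve = np.nan_to_num(curve, nan=0.0)
    return curve, float(curve.mean())


def _render_half(table: pd.DataFrame, bin_nm: float, extent, pixel_size_nm):
    from .postprocess import render_histogram
    img = render_histogram(table, bin_nm, extent, pixel_size_nm)
    n = 1 << int(np.ceil(np.log2(max(img.shape))))
    out = np.zeros((n, n))
    out[:img.shape[0], :img.shape[1]] = img
    return out


def frc_from_table(table: pd.DataFrame, bin_nm: float = 10.0,
                   pixel_size_nm: float = 100.0):
    """Split the localization table into first/second half of the frame
    sequence, render both halves and compute their FRC."""
    frames = table["frame"].to_numpy()
    mid = np.median(frames)
    first = table[frames <= mid]
    second = table[frames > mid]
    x1 = table["x_px"].max() * pixel_size_nm
    y1 = table["y_px"].max() * pixel_size_nm
    extent = (0.0, float(x1), 0.0, float(y1))
    I1 = _render_half(first, bin_nm, extent, pixel_size_nm)
    I2 = _render_half(second, bin_nm, extent, pixel_size_nm)
    return frc(I1, I2)


def evaluate_crops(model, crops, t_cls: float = 0.3, t_re: float = 0.7,
                   tolerance_nm: float = DEFAULT_TOLERANCE_NM,
                   pixel_size_nm: float = 100.0, batch_size: int = 64):
    """Run a fitter over crops, extract localizations and score them
    against the crop ground truth.  Returns (JI, RMSE_nm, MatchResult)."""
    from .postprocess import extract_localisations

    pred_rows = []
    truth_rows = []
    for i0 in range(0, len(crops), batch_size):
        batch = crops[i0:i0 + batch_size]
        x = np.stack([c.pixels for c in batch])
        fs = model(x)
        origins = [(i0 + k, 0, 0) for k in range(len(batch))]
        pred_rows.append(extract_localisations(fs, origins, t_cls, t_re))
        for k, c in enumerate(batch):
            for t in c.truth:
                truth_rows.append((i0 + k, t.x_px, t.y_px))
    pred = pd.concat(pred_rows, ignore_index=True) if pred_rows else \
        pd.DataFrame(columns=["frame", "x_px", "y_px"])
    truth = pd.DataFrame(truth_rows, columns=["frame", "x_px", "y_px"])
    m = match_localisations(pred, truth, tolerance_nm, pixel_size_nm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return jaccard_index(m), rmse(m), m
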