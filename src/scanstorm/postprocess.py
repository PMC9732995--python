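"""Deterministic extraction of localizations from the feature space.

An emitter sitting near a pixel edge spreads its probability mass over two
adjacent pixels, so thresholding single pixels misses it.  The extraction
rule therefore convolves the probability map with a cross-shaped filter
and decides per formation: if the cross sum at a candidate pixel exceeds
``t_re`` the highest-probability pixel of the formation is accepted; if it
exceeds ``2 * t_re`` the second-highest pixel is accepted as well.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .networks import CHANNELS, FeatureSpace, PHOTON_SCALE

__all__ = [
    "CROSS_FILTER", "cross_filter", "extract_localisations",
    "extract_from_feature_map", "apply_linear_drift", "render_histogram",
    "table_to_thunderstorm", "thunderstorm_to_table",
]

CROSS_FILTER = np.array([[0, 1, 0],
                         [1, 1, 1],
                         [0, 1, 0]], dtype=float)

#: localization table columns, camera-pixel units
COLUMNS = ["frame", "x_px", "y_px", "photons",
           "sigma_x", "sigma_y", "sigma_N", "p_score"]


def cross_filter(p_map: np.ndarray) -> np.ndarray:
    """Convolve the probability map with the cross filter (zero-padded)."""
    p_map = np.asarray(p_map, dtype=float)
    if p_map.ndim != 2:
        raise ValueError("p_map must be 2D")
    return ndimage.convolve(p_map, CROSS_FILTER, mode="constant", cval=0.0)


def _cross_members(p_map: np.ndarray, r: int, c: int):
    h, w = p_map.shape
    for dr, dc in ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)):
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w:
            yield rr, cc


def extract_from_feature_map(fm: np.ndarray, origin=(0, 0, 0),
                             t_cls: float = 0.3, t_re: float = 0.7) -> list:
    """Extraction rule on a single (8, H, W) feature map.

    Returns rows ``[frame, x_px, y_px, photons, sx, sy, sN, p]`` with
    coordinates in global pixel units (pixel center + subpixel offset,
    shifted by the origin).  Each pixel emits at most one localization.
    """
    if not 0 < t_cls <= 1:
        raise ValueError("t_cls must be in (0, 1]")
    p = fm[CHANNELS["p"]]
    filt = cross_filter(p)
    frame, row0, col0 = origin
    accepted: set[tuple[int, int]] = set()
    for r, c in np.argwhere(p > t_cls):
        if filt[r, c] <= t_re:
            continue
        members = sorted(_cross_members(p, r, c),
                         key=lambda rc: (-p[rc], rc))
        accepted.add(members[0])
        if filt[r, c] > 2.0 * t_re and len(members) > 1:
            accepted.add(members[1])
    rows = []
    for r, c in sorted(accepted):
        x = col0 + c + 0.5 + fm[CHANNELS["dx"], r, c]
        y = row0 + r + 0.5 + fm[CHANNELS["dy"], r, c]
        rows.append([frame, x, y,
                     fm[CHANNELS["N"], r, c] * PHOTON_SCALE,
                     fm[CHANNELS["sx"], r, c], fm[CHANNELS["sy"], r, c],
                     fm[CHANNELS["sN"], r, c], p[r, c]])
    return rows


def extract_localisations(fs, origins=None, t_cls: float = 0.3,
                          t_re: float = 0.7) -> pd.DataFrame:
    """Run the extraction rule on a batch of feature maps.

    ``fs`` is a FeatureSpace or an (N, 8, 9, 9) array; ``origins`` is an
    optional list of (frame, row, col) patch corners.
    """
    arr = fs.numpy() if isinstance(fs, FeatureSpace) else np.asarray(fs)
    if arr.ndim == 3:
        arr = arr[None]
    rows = []
    for i, fm in enumerate(arr):
        origin = origins[i] if origins is not None else (i, 0, 0)
        rows.extend(extract_from_feature_map(fm, origin, t_cls, t_re))
    return pd.DataFrame(rows, columns=COLUMNS)


def apply_linear_drift(table: pd.DataFrame, vx: float, vy: float) -> pd.DataFrame:
    """Subtract a linear drift of (vx, vy) pixels/frame."""
    out = table.copy()
    out["x_px"] = out["x_px"] - vx * out["frame"]
    out["y_px"] = out["y_px"] - vy * out["frame"]
    return out


def render_histogram(table: pd.DataFrame, bin_nm: float,
                     extent_nm: tuple, pixel_size_nm: float = 100.0) -> np.ndarray:
    """2D count histogram of localizations in nm at the given bin size.

    ``extent_nm`` = (x_min, x_max, y_min, y_max).
    """
    if bin_nm <= 0:
        raise ValueError("bin_nm must be > 0")
    x = table["x_px"].to_numpy() * pixel_size_nm
    y = table["y_px"].to_numpy() * pixel_size_nm
    x0, x1, y0, y1 = extent_nm
    bins_x = max(1, int(round((x1 - x0) / bin_nm)))
    bins_y = max(1, int(round((y1 - y0) / bin_nm)))
    h, _, _ = np.histogram2d(y, x, bins=(bins_y, bins_x),
                             range=((y0, y1), (x0, x1)))
    return h


def table_to_thunderstorm(table: pd.DataFrame,
                          pixel_size_nm: float = 100.0) -> pd.DataFrame:
    """Convert to the ThunderSTORM CSV dialect (nm units, 1-based frames)."""
    return pd.DataFrame({
        "frame": table["frame"].astype(int) + 1,
        "x [nm]": table["x_px"] * pixel_size_nm,
        "y [nm]": table["y_px"] * pixel_size_nm,
        "intensity [photon]": table["photons"],
        "uncertainty_x [nm]": table["sigma_x"] * pixel_size_nm,
        "uncertainty_y [nm]": table["sigma_y"] * pixel_size_nm,
    })


def thunderstorm_to_table(df: pd.DataFrame,
                          pixel_size_nm: float = 100.0) -> pd.DataFrame:
    """Inverse of :func:`table_to_thunderstorm` (missing columns -> 0)."""
    n = len(df)
    return pd.DataFrame({
        "frame": df["frame"].astype(int) - 1,
        "x_px": df["x [nm]"] / pixel_size_nm,
        "y_px": df["y [nm]"] / pixel_size_nm,
        "photons": df.get("intensity [photon]", pd.Series(np.zeros(n))),
        "sigma_x": df.get("uncertainty_x [nm]", pd.Series(np.zeros(n))) / pixel_size_nm,
        "sigma_y": df.get("uncertainty_y [nm]", pd.Series(np.zeros(n))) / pixel_size_nm,
        "sigma_N": np.zeros(n),
        "p_score": np.ones(n),
    })
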