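"""Reading and writing movies, truth tables and localization tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .simulate import FrameStack

__all__ = [
    "write_stack_tiff", "read_stack_tiff", "write_truth_csv",
    "read_truth_csv", "write_locs_csv", "read_locs_csv",
]


def write_stack_tiff(stack: FrameStack | np.ndarray, path) -> None:
    """Write frames as multi-page 16-bit unsigned TIFF (clipped at 0)."""
    frames = stack.frames if isinstance(stack, FrameStack) else np.asarray(stack)
    data = np.clip(np.round(frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")


def read_stack_tiff(path) -> np.ndarray:
    """Read a multi-page TIFF into a (T, H, W) float array."""
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - error path
        raise IOError(f"cannot read TIFF stack {path!r}: {exc}") from exc
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise IOError(f"TIFF stack {path!r} has unsupported shape {arr.shape}")
    return arr


def write_truth_csv(stack: FrameStack, path) -> None:
    """Ground truth as CSV: frame, x_px, y_px, photons (0-based pixels)."""
    rows = [(f, t.x_px, t.y_px, t.photons)
            for f, emitters in enumerate(stack.ground_truth)
            for t in emitters]
    pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "photons"]).to_csv(
        path, index=False)


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_locs_csv(table: pd.DataFrame, path, pixel_size_nm: float = 100.0,
                   dialect: str = "thunderstorm") -> None:
    """Write a localization table; 'thunderstorm' dialect uses nm units and
    1-based frames, 'native' writes pixel units as-is."""
    if dialect == "thunderstorm":
        from .postprocess import table_to_thunderstorm
        table_to_thunderstorm(table, pixel_size_nm).to_csv(path, index=False)
    elif dialect == "native":
        table.to_csv(path, index=False)
    else:
        raise ValueError("dialect must be 'thunderstorm' or 'native'")


def read_locs_csv(path, pixel_size_nm: float = 100.0) -> pd.DataFrame:
    """Read a localization table; ThunderSTORM headers are converted to
    the native pixel-unit columns."""
    df = pd.read_csv(path)
    if "x [nm]" in df.columns:
        from .postprocess import thunderstorm_to_table
        return thunderstorm_to_table(df, pixel_size_nm)
    return df
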