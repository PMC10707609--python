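"""File I/O: grayscale images, label-mask PNGs and cohort CSV tables.

Images are normalized to float in [0, 1] on read (8- and 16-bit integer
inputs are rescaled by their full bit-depth range); masks round-trip
losslessly as single-channel PNGs with values {0, 1, 2, 3}; cohort
tables round-trip as CSV with missing cells parsed as NaN.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import MaskFormatError
from .segmentation import SegmentationMask


def read_image(path, allow_rgb: bool = False) -> np.ndarray:
    """Read a PNG/TIFF image as grayscale float in [0, 1].

    RGB input is rejected unless ``allow_rgb`` is set, in which case the
    luma average of identical-or-not channels is taken — single-eye IR
    captures are single-channel by construction and a color file usually
    signals the wrong export.
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        if not allow_rgb and not (arr == arr[..., :1]).all():
            raise ValueError(f"{path}: RGB image; pass allow_rgb=True to average channels")
        arr = arr.mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        scale = 255.0 if arr.dtype.itemsize == 1 else 65535.0
        return arr.astype(np.float64) / scale
    return arr.astype(np.float64)


def write_image(path, image: np.ndarray) -> None:
    """Write a grayscale image as 8-bit PNG/TIFF (floats taken as [0,1])."""
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), img)


def read_mask(path) -> SegmentationMask:
    """Read a label PNG; values must be exactly {0, 1, 2, 3}."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        if not (arr == arr[..., :1]).all():
            raise MaskFormatError(f"{path}: mask PNG has non-identical channels")
        arr = arr[..., 0]
    return SegmentationMask(arr, provenance="injected")


def write_mask(path, mask: SegmentationMask) -> None:
    iio.imwrite(Path(path), mask.labels.astype(np.uint8))


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV; empty cells become NaN (the row stays, flagged
    later by the exclusion filter)."""
    df = pd.read_csv(path)
    if "mrd1_manual" not in df.columns:
        rep = [c for c in df.columns if c.startswith("mrd1_manual_r")]
        if not rep:
            raise ValueError(f"{path}: no mrd1_manual or replicate columns found")
        df["mrd1_manual"] = df[rep].mean(axis=1)
    return df


def write_cohort(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)
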