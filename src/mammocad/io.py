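"""Reading and writing grayscale images and score maps."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from imageio.v3 import imread, imwrite

logger = logging.getLogger(__name__)

__all__ = ["load_image", "save_image", "save_score_map"]


def load_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image (PNG/TIFF/PGM, 8- or 16-bit).

    Multi-channel input is converted by averaging the channels (luminance
    average) with a logged warning.
    """
    arr = np.asarray(imread(Path(path)))
    if arr.ndim == 3:
        logger.warning("multi-channel image %s converted to grayscale by channel average", path)
        arr = arr[..., :3].mean(axis=-1)
        arr = np.round(arr).astype(np.uint8)
    if arr.ndim != 2:
        raise ValueError(f"unsupported image shape {arr.shape} in {path}")
    return arr


def save_image(path: str | Path, image: np.ndarray) -> None:
    imwrite(Path(path), np.asarray(image))


def save_score_map(path: str | Path, values: np.ndarray) -> None:
    """Export a distance/degree map as 32-bit float TIFF for debugging."""
    import tifffile

    tifffile.imwrite(Path(path), np.asarray(values, dtype=np.float32))
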