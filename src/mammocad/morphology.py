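"""Grayscale morphological highlighting of suspected mass regions.

Mammographic masses appear as locally bright, roughly elliptical regions.
The preprocessing stage runs a grayscale erosion with a small elliptical
structuring element (removes isolated bright noise) followed by a dilation
with a large elliptical element (normalises every surviving bright region
to a near-elliptical plateau of roughly the dilating element's footprint),
which makes the regions easy to find with a circular template.

Note the two stages deliberately use *different* structuring elements
(7x7 erode, 50x50 dilate by default), so the composite is not a standard
morphological opening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "StructuringElement",
    "make_elliptical_se",
    "gray_erode",
    "gray_dilate",
    "preprocess",
    "DEFAULT_ERODE_SIZE",
    "DEFAULT_DILATE_SIZE",
]

DEFAULT_ERODE_SIZE = (7, 7)
DEFAULT_DILATE_SIZE = (50, 50)


@dataclass(frozen=True)
class StructuringElement:
    """Binary neighbourhood over which morphological min/max are taken.

    Attributes
    ----------
    mask : np.ndarray
        2-D boolean array; at least one cell is True.
    anchor : tuple[int, int]
        (row, col) of the reference cell, the centre of the mask.
    """

    mask: np.ndarray
    anchor: tuple[int, int]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 2 or not mask.any():
            raise ValueError("structuring element must be 2-D with at least one True cell")
        r, c = self.anchor
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
            raise ValueError("anchor must lie inside the mask")


def make_elliptical_se(width: int, height: int) -> StructuringElement:
    """Build an elliptical structuring element inscribed in width x height.

    A cell (r, c) belongs to the element iff its centre satisfies
    (dc/a)^2 + (dr/b)^2 <= 1 with a = (width-1)/2, b = (height-1)/2 measured
    from the central anchor cell.  Degenerate 1-pixel axes produce a line or
    a single cell.  The mask is symmetric under 180-degree rotation and the
    anchor cell is always True.
    """
    if width < 1 or height < 1:
        raise ValueError(f"structuring element dimensions must be >= 1, got {width}x{height}")
    a = (width - 1) / 2.0
    b = (height - 1) / 2.0
    rr, cc = np.mgrid[0:height, 0:width]
    dr = rr - b
    dc = cc - a
    # Degenerate axes: only the zero offset qualifies along that axis.
    with np.errstate(divide="ignore", invalid="ignore"):
        term_c = np.where(a > 0, (dc / max(a, 1e-12)) ** 2, np.where(dc == 0, 0.0, np.inf))
        term_r = np.where(b > 0, (dr / max(b, 1e-12)) ** 2, np.where(dr == 0, 0.0, np.inf))
    mask = term_c + term_r <= 1.0 + 1e-12
    return StructuringElement(mask=mask, anchor=(int(round(b)), int(round(a))))


def _check_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    return arr


def gray_erode(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Sliding minimum over the structuring element, edge-replicated borders."""
    arr = _check_image(image)
    return ndimage.grey_erosion(arr, footprint=se.mask, mode="nearest")


def gray_dilate(image: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Sliding maximum over the structuring element, edge-replicated borders."""
    arr = _check_image(image)
    return ndimage.grey_dilation(arr, footprint=se.mask, mode="nearest")


def preprocess(
    image: np.ndarray,
    erode_se: StructuringElement | None = None,
    dilate_se: StructuringElement | None = None,
) -> np.ndarray:
    """Erode with a small elliptical element, then dilate with a large one.

    Defaults: 7x7 erosion (kills isolated bright pixels), 50x50 dilation
    (expands each surviving bright region to a near-elliptical plateau).
    """
    if erode_se is None:
        erode_se = make_elliptical_se(*DEFAULT_ERODE_SIZE)
    if dilate_se is None:
        dilate_se = make_elliptical_se(*DEFAULT_DILATE_SIZE)
    return gray_dilate(gray_erode(image, erode_se), dilate_se)
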