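"""Circular breast-mass template and sliding-window squared-difference matching.

The template is a filled ellipse whose intensity ramps linearly from a bright
centre (117 by default) down to the edge value (104) on the inscribed-ellipse
boundary; pixels outside the ellipse keep the edge value.  Matching scans the
template over every position of the (morphologically preprocessed) image and
scores each patch P against the template T with the squared-difference
distance

    D(i, j) = sum_m sum_n [P(m, n) - T(m, n)]^2

(no square root).  A normalized similarity in [0, 1], the *matching degree*

    degree(i, j) = 1 - D(i, j) / sqrt(sum P^2 * sum T^2)

is thresholded (0.7 by default) at its local maxima to produce candidate
boxes of the template's size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image as _PILImage
from scipy import ndimage
from scipy.signal import fftconvolve

from .boxes import BoundingBox, Candidate

__all__ = [
    "Template",
    "ScoreMap",
    "generate_mass_template",
    "ssd_distance_map",
    "matching_degree_map",
    "extract_candidates",
    "save_template",
    "load_template",
]

DEFAULT_TEMPLATE_SIZE = (68, 60)  # (width M, height N)
DEFAULT_CENTER_VALUE = 117
DEFAULT_EDGE_VALUE = 104
DEFAULT_MATCH_THRESHOLD = 0.7


@dataclass(frozen=True)
class Template:
    """Parametric circular mass template.

    pixels[n, m] holds T(m, n) (row-major); width/height are M and N.
    """

    pixels: np.ndarray
    center_value: int
    edge_value: int

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def size(self) -> tuple[int, int]:
        """(width, height)."""
        return (self.width, self.height)


@dataclass(frozen=True)
class ScoreMap:
    """Result of sliding-window matching.

    values[i, j] scores the patch whose TOP-LEFT corner is (row i, col j).
    ``kind`` is "distance" for raw D(i, j) >= 0 or "degree" for the
    normalized similarity in [0, 1].
    """

    values: np.ndarray
    kind: str

    def __post_init__(self):
        if self.kind not in ("distance", "degree"):
            raise ValueError("kind must be 'distance' or 'degree'")


def generate_mass_template(
    width: int = DEFAULT_TEMPLATE_SIZE[0],
    height: int = DEFAULT_TEMPLATE_SIZE[1],
    center_value: int = DEFAULT_CENTER_VALUE,
    edge_value: int = DEFAULT_EDGE_VALUE,
) -> Template:
    """Synthesize the circular mass template.

    Pixel value at normalized elliptical radius rho (0 at centre, 1 on the
    inscribed-ellipse boundary) is

        round(center_value - (center_value - edge_value) * rho)

    clipped to [edge_value, center_value]; pixels outside the inscribed
    ellipse take edge_value, so the template is a filled bright disc on a
    uniform edge-valued surround, radially non-increasing from the centre.
    """
    if width < 3 or height < 3:
        raise ValueError("template must be at least 3x3")
    if center_value < edge_value:
        raise ValueError("center_value must be >= edge_value")
    a = (width - 1) / 2.0
    b = (height - 1) / 2.0
    rr, cc = np.mgrid[0:height, 0:width]
    rho = np.sqrt(((cc - a) / a) ** 2 + ((rr - b) / b) ** 2)
    ramp = np.round(center_value - (center_value - edge_value) * rho)
    vals = np.clip(ramp, edge_value, center_value)
    vals[rho > 1.0] = edge_value
    return Template(pixels=vals.astype(np.float64), center_value=int(center_value),
                    edge_value=int(edge_value))


def _is_integer_valued(arr: np.ndarray) -> bool:
    if np.issubdtype(arr.dtype, np.integer):
        return True
    return bool(np.all(arr == np.round(arr)))


def _window_sums(sq: np.ndarray, th: int, tw: int) -> np.ndarray:
    """Sum of ``sq`` over every th x tw window (valid positions), via an
    integral image (exact for integer-valued input below 2^53)."""
    ii = np.zeros((sq.shape[0] + 1, sq.shape[1] + 1), dtype=np.float64)
    ii[1:, 1:] = sq.cumsum(axis=0).cumsum(axis=1)
    return (
        ii[th:, tw:]
        - ii[:-th, tw:]
        - ii[th:, :-tw]
        + ii[:-th, :-tw]
    )


def ssd_distance_map(image: np.ndarray, template: Template) -> ScoreMap:
    """Squared-difference distance D(i, j) at every valid top-left offset.

    Computed as sum(P^2) - 2*corr(P, T) + sum(T^2) with an FFT
    cross-correlation; when both inputs are integer-valued the map is rounded
    back to the exact integer result.
    """
    arr = np.asarray(image, dtype=np.float64)
    t = template.pixels.astype(np.float64)
    th, tw = t.shape
    if arr.ndim != 2 or arr.shape[0] < th or arr.shape[1] < tw:
        raise ValueError(
            f"image {arr.shape} must be at least as large as the template {(th, tw)}"
        )
    p_sq = _window_sums(arr * arr, th, tw)
    cross = fftconvolve(arr, t[::-1, ::-1], mode="valid")
    t_sq = float(np.sum(t * t))
    d = p_sq - 2.0 * cross + t_sq
    if _is_integer_valued(np.asarray(image)) and _is_integer_valued(template.pixels):
        d = np.round(d)
    np.maximum(d, 0.0, out=d)
    return ScoreMap(values=d, kind="distance")


def matching_degree_map(image: np.ndarray, template: Template) -> ScoreMap:
    """Normalized squared-difference similarity in [0, 1].

    degree = 1 - D / sqrt(sum P^2 * sum T^2), clipped to [0, 1]; an exact
    match scores 1.  If both patch and template are all-zero the degree is 1
    (identical); if exactly one is all-zero it is 0.
    """
    arr = np.asarray(image, dtype=np.float64)
    t = template.pixels.astype(np.float64)
    th, tw = t.shape
    d = ssd_distance_map(image, template).values
    p_sq = _window_sums(arr * arr, th, tw)
    t_sq = float(np.sum(t * t))
    denom = np.sqrt(p_sq * t_sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        degree = 1.0 - d / denom
    if t_sq == 0.0:
        # all-zero template: identical to all-zero patches only
        degree = np.where(p_sq == 0.0, 1.0, 0.0)
    else:
        degree = np.where(p_sq == 0.0, 0.0, degree)
    np.clip(degree, 0.0, 1.0, out=degree)
    return ScoreMap(values=degree, kind="degree")


def extract_candidates(
    degree_map: ScoreMap,
    threshold: float = DEFAULT_MATCH_THRESHOLD,
    template_size: tuple[int, int] = DEFAULT_TEMPLATE_SIZE,
) -> list[Candidate]:
    """Candidates at local maxima of the degree map above ``threshold``.

    A cell is a peak if its value is >= all of its 8 neighbours; a plateau of
    equal-valued peak cells contributes a single candidate at its centroid.
    Each candidate's box has the template's width/height anchored at the
    peak offset (top-left corner).  Candidates are sorted by descending
    degree, ties by (x, y).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0,1]")
    if degree_map.kind != "degree":
        raise ValueError("extract_candidates requires a degree map")
    vals = degree_map.values
    w, h = template_size
    local_max = vals >= ndimage.maximum_filter(vals, size=3, mode="nearest")
    mask = local_max & (vals >= threshold)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    cands: list[Candidate] = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        cy = int(round(ys.mean()))
        cx = int(round(xs.mean()))
        degree = float(vals[ys, xs].max())
        cands.append(Candidate(box=BoundingBox(cx, cy, w, h), degree=min(degree, 1.0)))
    cands.sort(key=lambda c: (-c.degree, c.box.x, c.box.y))
    return cands


def save_template(template: Template, path: str | Path) -> None:
    """Write the template as PGM plus a JSON parameter sidecar."""
    path = Path(path)
    img = _PILImage.fromarray(template.pixels.astype(np.uint8), mode="L")
    img.save(path, format="PPM")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "width": template.width,
                "height": template.height,
                "center_value": template.center_value,
                "edge_value": template.edge_value,
            }
        )
    )


def load_template(path: str | Path) -> Template:
    path = Path(path)
    pixels = np.asarray(_PILImage.open(path), dtype=np.float64)
    params = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return Template(pixels=pixels, center_value=int(params["center_value"]),
                    edge_value=int(params["edge_value"]))
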