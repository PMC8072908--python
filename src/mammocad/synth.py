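"""Seeded synthetic mammogram-like phantoms with known ground truth.

A phantom emulates the gross appearance of a screening mammogram that the
detection pipeline relies on: a dark background, smooth low-frequency
tissue-like texture, additive Gaussian noise, and a few bright, roughly
elliptical masses with blurred edges planted at known, non-overlapping
locations.  It makes every pipeline stage testable end-to-end with exact
ground truth; it does not attempt physically realistic breast-tissue
simulation (no ductal structure, no pectoral muscle, no labels/artifacts).

Default intensities are 8-bit.  The defaults put mass plateaus in the
~110-135 range after morphological preprocessing (squarely inside the
template's 104-117 regime) and the dilated background around 50-60, so the
0.7 matching-degree threshold separates the two regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .boxes import BoundingBox, Candidate, crop_patch, iou, save_candidates_csv
from .bdcnn import PatchDataset

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "generate_patch_dataset",
    "save_phantom",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic mammogram-like image.

    mass_axes gives ((a_min, a_max), (b_min, b_max)) semi-axis ranges in
    pixels; mass_intensity the peak intensity above background.
    """

    width: int = 512
    height: int = 384
    n_masses: int = 2
    mass_axes: tuple[tuple[int, int], tuple[int, int]] = ((26, 33), (22, 29))
    mass_intensity: tuple[float, float] = (70.0, 95.0)
    background_level: float = 40.0
    texture_scale: float = 48.0
    texture_amplitude: float = 8.0
    edge_blur_sigma: float = 3.0
    noise_sigma: float = 4.0
    # Placement respects the detector's resolution geometry: the 50x50
    # dilating kernel expands every mass footprint by ~25 px per side, so
    # masses whose expanded footprints touch are highlighted as ONE region
    # and are unresolvable by a single-template matcher; similarly a mass
    # closer to the border than the template half-size plus the dilation
    # radius produces a clipped, biased score plateau.  min_separation is
    # the edge-to-edge gap enforced between mass boxes (~2 dilation radii);
    # margin keeps masses clear of the border (34 + 25 ~ 60).
    min_separation: int = 50
    margin: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.width < 1 or self.height < 1 or self.n_masses < 0:
            raise ValueError("invalid phantom dimensions")
        if self.mass_intensity[0] <= 0:
            raise ValueError("mass peak intensity must exceed the background level")


@dataclass(frozen=True)
class Ellipse:
    cx: int
    cy: int
    a: int
    b: int

    @property
    def box(self) -> BoundingBox:
        """Tight box of the unblurred ellipse (pixel-centre membership)."""
        return BoundingBox(self.cx - self.a, self.cy - self.b, 2 * self.a + 1, 2 * self.b + 1)


@dataclass(frozen=True)
class GroundTruth:
    ellipses: tuple[Ellipse, ...]

    @property
    def boxes(self) -> list[BoundingBox]:
        return [e.box for e in self.ellipses]


class PhantomGenerationError(RuntimeError):
    pass


def _inflate(box: BoundingBox, pad: float) -> BoundingBox:
    return BoundingBox(box.x - pad, box.y - pad, box.w + 2 * pad, box.h + 2 * pad)


_MAX_PLACEMENT_TRIES = 2000


def _place_masses(spec: PhantomSpec, rng: np.random.Generator) -> list[Ellipse]:
    (a_lo, a_hi), (b_lo, b_hi) = spec.mass_axes
    ellipses: list[Ellipse] = []
    for _ in range(spec.n_masses):
        for _try in range(_MAX_PLACEMENT_TRIES):
            a = int(rng.integers(a_lo, a_hi + 1))
            b = int(rng.integers(b_lo, b_hi + 1))
            lo_x, hi_x = spec.margin + a, spec.width - spec.margin - a
            lo_y, hi_y = spec.margin + b, spec.height - spec.margin - b
            if hi_x <= lo_x or hi_y <= lo_y:
                raise PhantomGenerationError("image too small for the requested masses")
            cand = Ellipse(
                cx=int(rng.integers(lo_x, hi_x)),
                cy=int(rng.integers(lo_y, hi_y)),
                a=a,
                b=b,
            )
            pad = spec.min_separation / 2.0
            if all(iou(_inflate(cand.box, pad), _inflate(e.box, pad)) == 0.0
                   for e in ellipses):
                ellipses.append(cand)
                break
        else:
            raise PhantomGenerationError(
                f"could not place {spec.n_masses} non-overlapping masses"
            )
    return ellipses


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a phantom: background + texture + blurred ellipses + noise.

    Returns (uint8 image, GroundTruth); fully determined by spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    img = np.full((spec.height, spec.width), spec.background_level, dtype=np.float64)

    if spec.texture_amplitude > 0 and spec.texture_scale > 0:
        white = rng.standard_normal((spec.height, spec.width))
        texture = ndimage.gaussian_filter(white, sigma=spec.texture_scale / 4.0)
        std = texture.std()
        if std > 0:
            texture *= spec.texture_amplitude / std
        img += texture

    ellipses = _place_masses(spec, rng)
    if ellipses:
        mass_layer = np.zeros_like(img)
        yy, xx = np.mgrid[0:spec.height, 0:spec.width]
        for e in ellipses:
            peak = rng.uniform(*spec.mass_intensity)
            inside = ((xx - e.cx) / e.a) ** 2 + ((yy - e.cy) / e.b) ** 2 <= 1.0
            mass_layer[inside] = np.maximum(mass_layer[inside], peak)
        if spec.edge_blur_sigma > 0:
            mass_layer = ndimage.gaussian_filter(mass_layer, sigma=spec.edge_blur_sigma)
        img += mass_layer

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)

    return np.clip(img, 0, 255).astype(np.uint8), GroundTruth(ellipses=tuple(ellipses))


def _jitter_box(box: BoundingBox, rng: np.random.Generator, frac: float = 0.10) -> BoundingBox:
    dx = rng.uniform(-frac, frac) * box.w
    dy = rng.uniform(-frac, frac) * box.h
    sw = 1.0 + rng.uniform(-frac, frac)
    sh = 1.0 + rng.uniform(-frac, frac)
    cx, cy = box.center
    return BoundingBox.from_center(cx + dx, cy + dy, box.w * sw, box.h * sh)


def _bright_background_centers(image: np.ndarray, truth_boxes, rng) -> list[tuple[float, float]]:
    """Centres of bright mass-free structure, brightest first.

    These mimic the hard negatives a template-matching front end produces:
    bright regions that are not masses.  A classifier trained only on flat
    background cannot rank partially-aligned crops, which the PSO fitness
    requires."""
    smooth = ndimage.gaussian_filter(np.asarray(image, dtype=np.float64), 6.0)
    peaks = (smooth == ndimage.maximum_filter(smooth, size=41)) & (smooth > 0)
    ys, xs = np.nonzero(peaks)
    order = np.argsort(-smooth[ys, xs])
    return [(float(xs[i]), float(ys[i])) for i in order]


def generate_patch_dataset(
    spec: PhantomSpec,
    n_mass: int,
    n_background: int,
    patch_size: tuple[int, int] = (200, 200),
) -> PatchDataset:
    """Build a labeled 200x200 patch dataset from a stream of phantoms.

    Mass patches are the ground-truth boxes with random jitter of up to 10%
    of the box size.  Background patches are boxes of comparable size from
    mass-free locations (IoU 0 with every ground-truth box): half centred
    on the brightest mass-free structure (hard negatives, mimicking a
    template-matcher's false candidates), half uniform.  Phantoms are
    generated from spec.seed, spec.seed + 1, ... until both quotas are met.
    All patches are cropped from the original (noisy) image.
    """
    if n_mass < 1 or n_background < 1:
        raise ValueError("need at least one patch per class")
    patches: list[np.ndarray] = []
    labels: list[int] = []
    provenance: list[tuple[str, tuple]] = []
    rng = np.random.default_rng(spec.seed + 10_000)
    got_mass = got_bg = 0
    phantom_idx = 0
    masses_per_phantom = max(spec.n_masses, 1)
    max_phantoms = 20 + (n_mass // masses_per_phantom + 1) * 3
    while (got_mass < n_mass or got_bg < n_background) and phantom_idx < max_phantoms:
        sub = replace(spec, seed=spec.seed + phantom_idx)
        image, truth = generate_phantom(sub)
        image_id = f"phantom-{sub.seed}"
        for e in truth.ellipses:
            if got_mass >= n_mass:
                break
            box = _jitter_box(e.box, rng)
            patches.append(crop_patch(image, box, patch_size))
            labels.append(1)
            provenance.append((image_id, (box.x, box.y, box.w, box.h)))
            got_mass += 1
        bg_quota = min(n_background - got_bg, 2 * masses_per_phantom)
        hard_centers = iter(_bright_background_centers(image, truth.boxes, rng))
        want_hard = True
        tries = 0
        while bg_quota > 0 and tries < 500:
            tries += 1
            w = float(rng.uniform(40, 80))
            h = float(rng.uniform(40, 80))
            if want_hard:
                center = next(hard_centers, None)
                if center is None:
                    want_hard = False
                    continue
                box = BoundingBox.from_center(center[0], center[1], w, h)
                try:
                    box = box.clip(spec.width, spec.height)
                except ValueError:
                    continue
            else:
                x = float(rng.uniform(0, spec.width - w))
                y = float(rng.uniform(0, spec.height - h))
                box = BoundingBox(x, y, w, h)
            if any(iou(box, tb) > 0.0 for tb in truth.boxes):
                continue
            patches.append(crop_patch(image, box, patch_size))
            labels.append(0)
            provenance.append((image_id, (box.x, box.y, box.w, box.h)))
            got_bg += 1
            bg_quota -= 1
            want_hard = not want_hard
        phantom_idx += 1
    if got_mass < n_mass or got_bg < n_background:
        raise PhantomGenerationError(
            f"could not sample the requested patches (got {got_mass} mass, {got_bg} background)"
        )
    return PatchDataset(
        patches=np.stack(patches),
        labels=np.array(labels, dtype=np.int64),
        provenance=provenance,
    )


def save_phantom(image: np.ndarray, truth: GroundTruth, stem: str | Path) -> None:
    """Write the phantom as PNG plus a ground-truth CSV in the candidate
    box schema."""
    from imageio.v3 import imwrite

    stem = Path(stem)
    imwrite(stem.with_suffix(".png"), image)
    records = [
        (stem.name, Candidate(box=b, degree=1.0)) for b in GroundTruth(truth.ellipses).boxes
    ]
    save_candidates_csv(stem.with_suffix(".csv"), records)
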