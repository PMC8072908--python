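"""Particle-swarm refinement of a rough mass bounding box.

Each particle encodes a box as (cx, cy, w, h) — centre coordinates, width,
height.  Velocities evolve as

    V <- V + cp * rand() * (pbest_pos - X) + cg * rand() * (gbest_pos - X)
    X <- X + V

with rand() drawn independently per coordinate, per term, per particle, per
iteration.  Fitness is the classifier's P(mass) for the decoded box cropped
from the image; the swarm's best box is returned.  The search is confined to
the rough box expanded by 30% of its width/height on every side.

The canonical-PSO reading is used: personal/global best *positions* drive
the velocity update while best *fitnesses* decide replacement.  Particle 0
starts at the rough box (so the result is never worse than the input);
the remaining particles are scattered uniformly over the search region with
small random initial velocities, because a swarm started entirely at the
rough box with zero velocity can never move under the update rule above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes import BoundingBox, crop_patch

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "Particle",
    "search_region",
    "encode",
    "decode",
    "pso_refine",
    "save_trace_csv",
]

MIN_BOX_SIZE = 8.0


@dataclass(frozen=True)
class SwarmConfig:
    """PSO hyperparameters; defaults are the published settings
    (20 particles, 20 iterations, cp = cg = 0.5, +-30% search region)."""

    n_particles: int = 20
    max_iterations: int = 20
    cp: float = 0.5
    cg: float = 0.5
    expansion: float = 0.30
    seed: int = 0
    # "local": particles scattered around the rough box (default; refinement
    # is a local regression).  "scatter": uniform over the search region.
    # "rough": every particle at the rough box with zero velocity.
    init: str = "local"
    init_spread: float = 0.25  # fraction of box size, "local" mode
    init_velocity_frac: float = 0.10
    velocity_clamp_frac: float = 0.15
    early_stop_fitness: float | None = 1.0 - 1e-6
    # stop after this many consecutive sweeps in which gbest improved by
    # less than stagnation_tol (None = always run max_iterations)
    stagnation_patience: int | None = None
    stagnation_tol: float = 1e-3
    patch_size: tuple[int, int] = (200, 200)

    def __post_init__(self):
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if self.cp < 0 or self.cg < 0 or self.expansion < 0:
            raise ValueError("cp, cg and expansion must be non-negative")
        if self.init not in ("local", "scatter", "rough"):
            raise ValueError("init must be 'local', 'scatter' or 'rough'")


@dataclass
class Particle:
    position: np.ndarray  # (cx, cy, w, h)
    velocity: np.ndarray
    best_position: np.ndarray
    best_fitness: float


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int = 0
    trace: list[float] = field(default_factory=list)
    trace_boxes: list[BoundingBox] = field(default_factory=list)


def search_region(rough: BoundingBox, expansion: float = 0.30,
                  image_size: tuple[int, int] | None = None) -> BoundingBox:
    """Expand the rough box by ``expansion`` of its width/height on every
    side; optionally clip to (width, height) image bounds."""
    region = BoundingBox(
        rough.x - expansion * rough.w,
        rough.y - expansion * rough.h,
        (1 + 2 * expansion) * rough.w,
        (1 + 2 * expansion) * rough.h,
    )
    if image_size is not None:
        region = region.clip(image_size[0], image_size[1])
    return region


def encode(box: BoundingBox) -> np.ndarray:
    """Corner box -> particle position (cx, cy, w, h)."""
    cx, cy = box.center
    return np.array([cx, cy, box.w, box.h], dtype=np.float64)


def decode(position: np.ndarray, region: BoundingBox | None = None,
           min_size: float = MIN_BOX_SIZE) -> BoundingBox:
    """Particle position -> corner box, clamped to the search region.

    Width/height are floored at ``min_size`` and capped at the region size;
    the centre is clamped so it stays inside the region.
    """
    cx, cy, w, h = (float(v) for v in np.asarray(position, dtype=np.float64))
    if region is not None:
        w = float(np.clip(w, min_size, region.w))
        h = float(np.clip(h, min_size, region.h))
        cx = float(np.clip(cx, region.x, region.x2))
        cy = float(np.clip(cy, region.y, region.y2))
    else:
        w = max(w, min_size)
        h = max(h, min_size)
    return BoundingBox.from_center(cx, cy, w, h)


def _int_key(box: BoundingBox) -> tuple[int, int, int, int]:
    return (int(round(box.x)), int(round(box.y)), int(round(box.w)), int(round(box.h)))


def save_trace_csv(path, trace: list[float], boxes: list[BoundingBox] | None = None) -> None:
    """Write a refinement trace as CSV (iteration, gbest fitness, gbest box)."""
    from pathlib import Path

    lines = ["iteration,gbest_fitness,x,y,w,h"]
    for i, f in enumerate(trace, start=1):
        if boxes is not None and i - 1 < len(boxes):
            b = boxes[i - 1]
            lines.append(f"{i},{f},{b.x},{b.y},{b.w},{b.h}")
        else:
            lines.append(f"{i},{f},,,,")
    Path(path).write_text("\n".join(lines) + "\n")


def pso_refine(
    image: np.ndarray,
    rough: BoundingBox,
    fitness,
    config: SwarmConfig = SwarmConfig(),
    batch_fitness=None,
    return_state: bool = False,
):
    """Refine ``rough`` by PSO with ``fitness``: patch -> [0, 1].

    ``fitness`` receives a patch cropped from ``image`` and resized to
    ``config.patch_size``; ``batch_fitness``, if given, receives a stacked
    (N, h, w) array and returns N fitnesses in one call (used to batch the
    classifier's forward passes).  Fitness values are memoized per
    integer-rounded box, and iteration stops early once the swarm's best
    fitness reaches ``config.early_stop_fitness`` (further iterations could
    improve it by less than 1e-6).

    Returns (best_box, best_fitness, trace) where trace[i] is the swarm-best
    fitness after iteration i (non-decreasing).
    """
    arr = np.asarray(image)
    img_h, img_w = arr.shape
    region = search_region(rough, config.expansion, image_size=(img_w, img_h))
    rng = np.random.default_rng(config.seed)
    cache: dict[tuple[int, int, int, int], float] = {}

    def eval_positions(positions: list[np.ndarray]) -> list[float]:
        boxes = [decode(p, region) for p in positions]
        keys = [_int_key(b) for b in boxes]
        todo = [(k, b) for k, b in zip(keys, boxes) if k not in cache]
        # drop duplicate keys within the batch
        seen = set()
        uniq = []
        for k, b in todo:
            if k not in seen:
                seen.add(k)
                uniq.append((k, b))
        if uniq:
            patches = [crop_patch(arr, b, config.patch_size) for _k, b in uniq]
            if batch_fitness is not None:
                vals = np.asarray(batch_fitness(np.stack(patches)), dtype=np.float64)
            else:
                vals = np.array([fitness(p) for p in patches], dtype=np.float64)
            if np.any((vals < 0.0) | (vals > 1.0)):
                raise ValueError("fitness returned a value outside [0, 1]")
            for (k, _b), v in zip(uniq, vals):
                cache[k] = float(v)
        return [cache[k] for k in keys]

    # --- initialization
    positions = [encode(decode(encode(rough), region))]
    velocities = [np.zeros(4)]
    span = np.array([region.w, region.h, region.w, region.h], dtype=np.float64)
    rough_vec = positions[0]
    for _ in range(config.n_particles - 1):
        if config.init == "rough":
            positions.append(rough_vec.copy())
            velocities.append(np.zeros(4))
            continue
        if config.init == "local":
            spread = config.init_spread * np.array([rough.w, rough.h, rough.w, rough.h])
            pos = rough_vec + rng.normal(0.0, 1.0, size=4) * spread
        else:  # scatter
            pos = np.array([
                rng.uniform(region.x, region.x2),
                rng.uniform(region.y, region.y2),
                rng.uniform(MIN_BOX_SIZE, region.w),
                rng.uniform(MIN_BOX_SIZE, region.h),
            ])
        positions.append(pos)
        velocities.append(rng.uniform(-1.0, 1.0, size=4) * config.init_velocity_frac * span)
    fits = eval_positions(positions)
    particles = [
        Particle(position=p.copy(), velocity=v.copy(), best_position=p.copy(), best_fitness=f)
        for p, v, f in zip(positions, velocities, fits)
    ]
    g_idx = int(np.argmax(fits))
    state = SwarmState(
        particles=particles,
        gbest_position=particles[g_idx].best_position.copy(),
        gbest_fitness=particles[g_idx].best_fitness,
    )
    vmax = config.velocity_clamp_frac * span
    stagnant = 0

    for _it in range(config.max_iterations):
        saturated = (config.early_stop_fitness is not None
                     and state.gbest_fitness >= config.early_stop_fitness)
        stalled = (config.stagnation_patience is not None
                   and stagnant >= config.stagnation_patience)
        if saturated or stalled:
            state.trace.append(state.gbest_fitness)
            state.trace_boxes.append(decode(state.gbest_position, region))
            continue
        for part in particles:
            r_p = rng.random(4)
            r_g = rng.random(4)
            part.velocity = (
                part.velocity
                + config.cp * r_p * (part.best_position - part.position)
                + config.cg * r_g * (state.gbest_position - part.position)
            )
            np.clip(part.velocity, -vmax, vmax, out=part.velocity)
            part.position = part.position + part.velocity
        fits = eval_positions([p.position for p in particles])
        gbest_before = state.gbest_fitness
        for part, f in zip(particles, fits):
            if f > part.best_fitness:
                part.best_fitness = f
                part.best_position = part.position.copy()
            if f > state.gbest_fitness:
                state.gbest_fitness = f
                state.gbest_position = part.position.copy()
        improved = state.gbest_fitness - gbest_before >= config.stagnation_tol
        stagnant = 0 if improved else stagnant + 1
        state.iteration += 1
        state.trace.append(state.gbest_fitness)
        state.trace_boxes.append(decode(state.gbest_position, region))

    best_box = decode(state.gbest_position, region)
    if return_state:
        return best_box, state.gbest_fitness, state.trace, state
    return best_box, state.gbest_fitness, state.trace
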