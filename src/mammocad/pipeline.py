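"""End-to-end detection pipeline and evaluation metrics.

detect() chains the stages: optional resize -> morphological highlighting
-> template matching -> candidate extraction and IoU merging -> patch
classification -> PSO bounding-box refinement of accepted candidates.
evaluate() computes detection-level TPR / FPI / mean IoU via greedy
one-to-one matching, plus accuracy / precision / recall / F1 at the
candidate-classification level (was each suspected region correctly called
mass or background).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize as _sk_resize

from . import morphology, template as templ
from .bdcnn import MASS, Model, predict_proba
from .boxes import BoundingBox, crop_patch, iou, merge_candidates
from .pso import SwarmConfig, pso_refine

__all__ = [
    "PipelineConfig",
    "Detection",
    "Metrics",
    "detect",
    "evaluate",
    "kfold_split",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage's knobs in one place; defaults are the published values."""

    resize_to: tuple[int, int] | None = (1500, 2000)  # (width, height); None = keep
    erode_size: tuple[int, int] = (7, 7)
    dilate_size: tuple[int, int] = (50, 50)
    template_size: tuple[int, int] = (68, 60)  # (width, height)
    template_center_value: int = 117
    template_edge_value: int = 104
    match_threshold: float = 0.7
    merge_iou_threshold: float = 0.3
    decision_threshold: float = 0.5
    tp_iou_threshold: float = 0.5
    swarm: SwarmConfig = field(default_factory=lambda: SwarmConfig(stagnation_patience=5))
    refine: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("match_threshold", "merge_iou_threshold", "decision_threshold",
                     "tp_iou_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class Detection:
    """One scored candidate region on an image.

    ``accepted`` candidates (probability >= decision threshold) also carry a
    PSO-refined box and its fitness; rejected ones do not.
    """

    image_id: str
    box: BoundingBox
    degree: float
    probability: float
    refined_box: BoundingBox | None = None
    refined_probability: float | None = None

    @property
    def final_box(self) -> BoundingBox:
        return self.refined_box if self.refined_box is not None else self.box


@dataclass
class Metrics:
    tpr: float
    fpi: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    mean_iou: float
    n_images: int
    n_truths: int
    n_true_positives: int
    n_false_positives: int
    per_image: dict = field(default_factory=dict)


def _resize_image(image: np.ndarray, size_wh: tuple[int, int]) -> np.ndarray:
    w, h = size_wh
    out = _sk_resize(np.asarray(image, dtype=np.float64), (h, w), order=1,
                     preserve_range=True, anti_aliasing=False)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        out = np.round(out)
    return out.astype(np.asarray(image).dtype)


def detect(
    image: np.ndarray,
    model: Model,
    config: PipelineConfig = PipelineConfig(),
    image_id: str = "image",
) -> list[Detection]:
    """Run the full pipeline on one grayscale image.

    Returns one Detection per merged candidate (all carry a classifier
    probability); candidates at or above the decision threshold are refined
    by PSO when config.refine is set.  Coordinates are in the (optionally
    resized) working frame.
    """
    arr = np.asarray(image)
    if config.resize_to is not None and arr.shape[::-1] != tuple(config.resize_to):
        arr = _resize_image(arr, config.resize_to)
    highlighted = morphology.preprocess(
        arr,
        morphology.make_elliptical_se(*config.erode_size),
        morphology.make_elliptical_se(*config.dilate_size),
    )
    mass_template = templ.generate_mass_template(
        *config.template_size, config.template_center_value, config.template_edge_value
    )
    if highlighted.shape[0] < mass_template.height or highlighted.shape[1] < mass_template.width:
        raise ValueError("image is smaller than the matching template")
    degree = templ.matching_degree_map(highlighted, mass_template)
    cands = templ.extract_candidates(degree, config.match_threshold, config.template_size)
    merged = merge_candidates(cands, config.merge_iou_threshold)
    if not merged:
        return []

    patch_size = model.config.input_size
    patches = np.stack([crop_patch(arr, c.box, patch_size) for c in merged])
    probs = predict_proba(model, patches)[:, MASS]

    def batch_fitness(batch: np.ndarray) -> np.ndarray:
        return predict_proba(model, batch)[:, MASS]

    detections: list[Detection] = []
    for cand, prob in zip(merged, probs):
        det = Detection(image_id=image_id, box=cand.box, degree=cand.degree,
                        probability=float(prob))
        if config.refine and prob >= config.decision_threshold:
            swarm = replace(config.swarm, patch_size=patch_size)
            best_box, best_fit, _trace = pso_refine(
                arr, cand.box, fitness=None, config=swarm, batch_fitness=batch_fitness
            )
            det.refined_box = best_box
            det.refined_probability = float(best_fit)
        detections.append(det)
    return detections


def _greedy_match(dets: list[Detection], truths: list[BoundingBox],
                  tp_iou_threshold: float):
    """Greedy one-to-one matching by descending probability, then IoU.

    Returns (matches, unmatched_dets) where matches is a list of
    (detection, truth index, iou).
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].probability)
    claimed: set[int] = set()
    matches = []
    unmatched = []
    for i in order:
        det = dets[i]
        best_j, best_iou = None, -1.0
        for j, tb in enumerate(truths):
            if j in claimed:
                continue
            v = iou(det.final_box, tb)
            if v >= tp_iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j is not None:
            claimed.add(best_j)
            matches.append((det, best_j, best_iou))
        else:
            unmatched.append(det)
    return matches, unmatched


def evaluate(
    detections: dict[str, list[Detection]],
    ground_truths: dict[str, list[BoundingBox]],
    tp_iou_threshold: float = 0.5,
    decision_threshold: float = 0.5,
) -> Metrics:
    """Score detections against ground truth.

    Detection level (accepted detections only, refined boxes when present):
    a detection is a true positive iff greedily matched one-to-one to an
    unclaimed truth box with IoU >= tp_iou_threshold; TPR = matched truths /
    all truths, FPI = unmatched accepted detections / number of images,
    mean_iou averages over true positives.

    Classification level (all candidates): a candidate's true label is
    whether its rough box overlaps any truth at IoU >= tp_iou_threshold; the
    predicted label is probability >= decision_threshold; accuracy /
    precision / recall / F1 summarize that confusion matrix.
    """
    if set(detections) != set(ground_truths):
        raise ValueError("detections and ground truths must cover the same image ids")
    n_images = len(ground_truths)
    n_truths = sum(len(v) for v in ground_truths.values())
    tp = fp = 0
    ious: list[float] = []
    cls_tp = cls_fp = cls_tn = cls_fn = 0
    per_image: dict[str, dict] = {}
    for image_id in sorted(ground_truths):
        truths = ground_truths[image_id]
        dets = detections[image_id]
        accepted = [d for d in dets if d.probability >= decision_threshold]
        matches, unmatched = _greedy_match(accepted, truths, tp_iou_threshold)
        tp += len(matches)
        fp += len(unmatched)
        ious.extend(v for _d, _j, v in matches)
        for det in dets:
            is_mass = any(iou(det.box, tb) >= tp_iou_threshold for tb in truths)
            said_mass = det.probability >= decision_threshold
            if is_mass and said_mass:
                cls_tp += 1
            elif is_mass:
                cls_fn += 1
            elif said_mass:
                cls_fp += 1
            else:
                cls_tn += 1
        per_image[image_id] = {
            "n_truths": len(truths),
            "n_detections": len(accepted),
            "true_positives": len(matches),
            "false_positives": len(unmatched),
        }
    n_cls = cls_tp + cls_fp + cls_tn + cls_fn
    precision = cls_tp / (cls_tp + cls_fp) if (cls_tp + cls_fp) else 0.0
    recall = cls_tp / (cls_tp + cls_fn) if (cls_tp + cls_fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return Metrics(
        tpr=tp / n_truths if n_truths else 0.0,
        fpi=fp / n_images if n_images else 0.0,
        accuracy=(cls_tp + cls_tn) / n_cls if n_cls else 0.0,
        precision=precision,
        recall=recall,
        f1=f1,
        mean_iou=float(np.mean(ious)) if ious else 0.0,
        n_images=n_images,
        n_truths=n_truths,
        n_true_positives=tp,
        n_false_positives=fp,
        per_image=per_image,
    )


def kfold_split(image_ids: list[str], k: int, seed: int = 0) -> list[tuple[list[str], list[str]]]:
    """Generic k-fold split of image ids into (train, test) lists."""
    if k < 2 or k > len(image_ids):
        raise ValueError("k must be between 2 and the number of images")
    rng = np.random.default_rng(seed)
    ids = list(image_ids)
    rng.shuffle(ids)
    folds = [ids[i::k] for i in range(k)]
    out = []
    for i in range(k):
        test = folds[i]
        train = [x for j, f in enumerate(folds) if j != i for x in f]
        out.append((train, sorted(test)))
    return out
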