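"""Slide-level inference from patch predictions.

A trained patch classifier emits a six-class probability vector per
sliding window.  Slide labels are produced by a threshold-and-count
heuristic:

1. each patch is assigned to its argmax class and kept only if that
   class's confidence clears a per-class threshold (low-confidence
   predictions are discarded outright, never reassigned);
2. classes comprising less than 5% of the surviving patch predictions,
   and the benign class, are dropped;
3. the most frequent surviving class becomes the predominant label, all
   other survivors become minor labels.  If no cancer class survives the
   slide is called benign.

Per-class thresholds are fitted by a coordinate-wise grid search on a
development set, optimizing predominant accuracy plus minor-set Jaccard.
A probability-averaging baseline (mean patch probability vector, argmax
over cancer classes) is provided for comparison, as is a color-coded dot
overlay for visual review.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .patterns import (
    ALL_CLASSES,
    CANCER_CLASSES,
    N_CLASSES,
    PatternClass,
    SlideLabel,
    jaccard,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_FRACTION = 0.05


@dataclass
class PatchPrediction:
    """A probability vector over the six classes, tied to a patch location."""

    origin: Tuple[int, int]
    source_id: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        if p.shape != (N_CLASSES,):
            raise ValueError(f"probs must have {N_CLASSES} entries, got {p.shape}")
        if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probs must be nonnegative and sum to 1")
        self.probs = p

    @property
    def argmax(self) -> PatternClass:
        return PatternClass(int(np.argmax(self.probs)))

    @property
    def confidence(self) -> float:
        return float(self.probs.max())


@dataclass(frozen=True)
class ThresholdSet:
    """Per-class confidence cutoffs in [0, 1]."""

    values: Tuple[float, ...] = (0.0,) * N_CLASSES

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) != N_CLASSES:
            raise ValueError(f"need {N_CLASSES} thresholds, got {len(vals)}")
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("thresholds must lie in [0, 1]")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, cls: PatternClass) -> float:
        return self.values[int(cls)]

    def replace(self, cls: PatternClass, value: float) -> "ThresholdSet":
        vals = list(self.values)
        vals[int(cls)] = value
        return ThresholdSet(tuple(vals))

    def to_dict(self) -> Dict[str, float]:
        return {c.label: self.values[int(c)] for c in ALL_CLASSES}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ThresholdSet":
        return cls(tuple(float(d[c.label]) for c in ALL_CLASSES))

    @classmethod
    def uniform(cls, value: float) -> "ThresholdSet":
        return cls((float(value),) * N_CLASSES)


@dataclass(frozen=True)
class ClassCountDistribution:
    """Counts of thresholded patch predictions per class."""

    counts: Mapping[PatternClass, int]

    def __post_init__(self) -> None:
        counts = {c: int(self.counts.get(c, 0)) for c in ALL_CLASSES}
        if any(v < 0 for v in counts.values()):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, cls: PatternClass) -> int:
        return self.counts[cls]


def apply_thresholds(
    predictions: Sequence[PatchPrediction], thresholds: ThresholdSet
) -> ClassCountDistribution:
    """Count patches per argmax class, discarding low-confidence predictions.

    A patch counts toward its argmax class iff the winning confidence is
    ``>=`` that class's threshold (boundary inclusive); otherwise the patch
    is discarded entirely.
    """
    if len(predictions) == 0:
        raise ValueError("empty prediction list")
    counts = {c: 0 for c in ALL_CLASSES}
    for pred in predictions:
        c = pred.argmax
        if pred.probs[int(c)] >= thresholds[c]:
            counts[c] += 1
    return ClassCountDistribution(counts)


def label_from_weights(
    weights: Mapping[PatternClass, float], min_fraction: float = DEFAULT_MIN_FRACTION
) -> SlideLabel:
    """The three-step heuristic on arbitrary nonnegative class weights.

    Fractions are computed on the total weight *before* dropping anything
    (benign included in the denominator).  Ties for predominant go to the
    lowest canonical ordinal.
    """
    total = float(sum(weights.get(c, 0.0) for c in ALL_CLASSES))
    if total <= 0:
        raise ValueError("total weight must be positive")
    surviving = [
        c
        for c in CANCER_CLASSES
        if weights.get(c, 0.0) / total >= min_fraction and weights.get(c, 0.0) > 0
    ]
    if not surviving:
        return SlideLabel.benign()
    best = max(weights.get(c, 0.0) for c in surviving)
    top = [c for c in surviving if weights.get(c, 0.0) == best]
    if len(top) > 1:
        logger.info(
            "predominant tie between %s; lowest ordinal wins",
            ", ".join(c.label for c in top),
        )
    predominant = min(top)
    minors = frozenset(c for c in surviving if c is not predominant)
    return SlideLabel(predominant, minors)


def infer_slide_label(
    dist: ClassCountDistribution, min_fraction: float = DEFAULT_MIN_FRACTION
) -> SlideLabel:
    """Predominant/minor slide label from a thresholded count distribution."""
    if dist.total < 1:
        raise ValueError("count distribution is empty")
    return label_from_weights(dict(dist.counts), min_fraction=min_fraction)


def classify_slide(
    predictions: Sequence[PatchPrediction],
    thresholds: ThresholdSet,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> SlideLabel:
    """Threshold then aggregate; falls back to benign if nothing survives."""
    dist = apply_thresholds(predictions, thresholds)
    if dist.total == 0:
        return SlideLabel.benign()
    return infer_slide_label(dist, min_fraction=min_fraction)


def label_correspondence(predicted: SlideLabel, reference: SlideLabel) -> float:
    """Per-slide objective: predominant match (0/1) plus minor-set Jaccard."""
    predom = 1.0 if predicted.predominant == reference.predominant else 0.0
    return predom + jaccard(predicted.minors, reference.minors)


def _dev_objective(
    dev_predictions: Sequence[Sequence[PatchPrediction]],
    dev_labels: Sequence[SlideLabel],
    thresholds: ThresholdSet,
    min_fraction: float,
) -> float:
    scores = [
        label_correspondence(
            classify_slide(preds, thresholds, min_fraction=min_fraction), ref
        )
        for preds, ref in zip(dev_predictions, dev_labels)
    ]
    return float(np.mean(scores))


DEFAULT_GRID: Tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0, 0.05), 10))


def fit_thresholds(
    dev_predictions: Sequence[Sequence[PatchPrediction]],
    dev_labels: Sequence[SlideLabel],
    grid: Sequence[float] = DEFAULT_GRID,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    sweeps: int = 1,
    include_benign: bool = True,
) -> Tuple[ThresholdSet, float]:
    """Coordinate-wise grid search for per-class confidence thresholds.

    Classes are visited in canonical order; each class's threshold is
    optimized over the grid while the others are held fixed.  Ties in the
    dev objective prefer the lower threshold.  ``sweeps > 1`` repeats the
    pass, stopping early when a sweep changes nothing.  Benign's threshold
    is fitted too by default — it never appears in labels but modulates the
    5% denominator; ``include_benign=False`` pins it at 0.

    Returns the fitted set together with the dev objective it achieves.
    """
    grid = sorted(set(float(g) for g in grid))
    if not grid:
        raise ValueError("threshold grid is empty")
    if any(not 0.0 <= g <= 1.0 for g in grid):
        raise ValueError("grid values must lie in [0, 1]")
    if len(dev_predictions) != len(dev_labels) or not dev_labels:
        raise ValueError("need matching, non-empty dev predictions and labels")

    current = ThresholdSet.uniform(grid[0])
    best_obj = _dev_objective(dev_predictions, dev_labels, current, min_fraction)
    classes = ALL_CLASSES if include_benign else CANCER_CLASSES
    for _ in range(max(1, sweeps)):
        changed = False
        for cls in classes:
            best_val = current[cls]
            for g in grid:  # ascending: ties keep the lower threshold
                cand = current.replace(cls, g)
                obj = _dev_objective(dev_predictions, dev_labels, cand, min_fraction)
                if obj > best_obj + 1e-12:
                    best_obj = obj
                    best_val = g
                    changed = True
            current = current.replace(cls, best_val)
        if not changed:
            break
    return current, best_obj


def baseline_infer(
    predictions: Sequence[PatchPrediction], minor_cutoff: float = 0.05
) -> SlideLabel:
    """Probability-averaging baseline (mean patch probability vector).

    Predominant is the argmax over cancer-class means; minors are cancer
    classes whose mean probability clears ``minor_cutoff``.  The slide is
    called benign when benign's mean tops every cancer mean and no cancer
    mean reaches the cutoff.
    """
    if len(predictions) == 0:
        raise ValueError("empty prediction list")
    mean = np.mean([p.probs for p in predictions], axis=0)
    cancer_means = {c: float(mean[int(c)]) for c in CANCER_CLASSES}
    benign_mean = float(mean[int(PatternClass.BENIGN)])
    best = max(cancer_means.values())
    if benign_mean > best and best < minor_cutoff:
        return SlideLabel.benign()
    predominant = min(c for c, v in cancer_means.items() if v == best)
    minors = frozenset(
        c
        for c, v in cancer_means.items()
        if c is not predominant and v >= minor_cutoff
    )
    return SlideLabel(predominant, minors)


DEFAULT_PALETTE: Dict[PatternClass, Tuple[int, int, int]] = {
    PatternClass.LEPIDIC: (31, 119, 180),
    PatternClass.ACINAR: (255, 127, 14),
    PatternClass.PAPILLARY: (44, 160, 44),
    PatternClass.MICROPAPILLARY: (214, 39, 40),
    PatternClass.SOLID: (148, 103, 189),
}


def render_overlay(
    slide: np.ndarray,
    predictions: Sequence[PatchPrediction],
    thresholds: ThresholdSet,
    palette: Optional[Mapping[PatternClass, Tuple[int, int, int]]] = None,
    patch_size: int = 224,
    radius: int = 8,
) -> Tuple[np.ndarray, Dict[str, Tuple[int, int, int]]]:
    """Overlay a color-coded dot at each surviving non-benign patch center.

    Returns the annotated image (input is not modified) and a legend
    mapping class names to their dot colors.
    """
    from skimage.draw import disk

    palette = dict(palette or DEFAULT_PALETTE)
    out = np.asarray(slide).copy()
    h, w = out.shape[:2]
    for pred in predictions:
        x, y = pred.origin
        if not (0 <= x <= w - patch_size and 0 <= y <= h - patch_size):
            raise ValueError(
                f"patch origin {pred.origin} of {pred.source_id} out of slide bounds"
            )
        c = pred.argmax
        if not c.is_cancer or pred.probs[int(c)] < thresholds[c]:
            continue
        cy, cx = y + patch_size // 2, x + patch_size // 2
        rr, cc = disk((cy, cx), radius, shape=(h, w))
        out[rr, cc] = palette[c]
    legend = {c.label: tuple(v) for c, v in palette.items()}
    return out, legend
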