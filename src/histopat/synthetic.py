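"""Synthetic slides, crop sets, prediction tables, and annotation sets.

Real whole-slide collections with pathologist annotations are private,
so every downstream stage is exercised against generated data with
known ground truth.  Slides are mosaics of contiguous single-class
regions (seeded Voronoi cells, merged to match requested area fractions
to the pixel), textured by a parametric recipe per class — a base color
plus a spatial motif and pixel noise.  The textures are deliberately
not histology-realistic; they are distinct enough that a trivial
mean-color classifier separates them, which guarantees the patch-CNN
test surface is learnable at desk scale.

Crop sizes emulate the annotated-crop regime of real training sets:
lognormal per dimension, calibrated so the median is ~429x473 and the
mean ~718x771 pixels, floored at the 224-pixel patch size.

Prediction tables let slide-level aggregation be tested without images
or a trained model: true patch classes are drawn from a slide
composition, predicted classes through a row-stochastic confusion
matrix, and winning-class confidences from a Beta distribution.

Annotation sets with *planted* pairwise disagreement rates provide
exact expected values for the agreement statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .agreement import AnnotationSet
from .inference import PatchPrediction, label_from_weights
from .patches import Crop, DEFAULT_PATCH_SIZE
from .patterns import ALL_CLASSES, CANCER_CLASSES, N_CLASSES, PatternClass, SlideLabel

DEFAULT_SLIDE_SIZE = 2048


# ---------------------------------------------------------------------------
# textures


@dataclass(frozen=True)
class TextureSpec:
    """Parametric appearance of one tissue class."""

    pattern: PatternClass
    base_color: Tuple[int, int, int]
    noise_sd: float = 12.0
    structure: str = "plain"  # rings | blobs | speckle | sheets | plain
    scale: int = 32
    amplitude: float = 25.0


DEFAULT_TEXTURES: Dict[PatternClass, TextureSpec] = {
    PatternClass.LEPIDIC: TextureSpec(
        PatternClass.LEPIDIC, (235, 170, 190), structure="rings", scale=24
    ),
    PatternClass.ACINAR: TextureSpec(
        PatternClass.ACINAR, (170, 110, 200), structure="blobs", scale=32
    ),
    PatternClass.PAPILLARY: TextureSpec(
        PatternClass.PAPILLARY, (120, 190, 170), structure="sheets", scale=20
    ),
    PatternClass.MICROPAPILLARY: TextureSpec(
        PatternClass.MICROPAPILLARY, (90, 90, 180), structure="speckle", scale=16
    ),
    PatternClass.SOLID: TextureSpec(
        PatternClass.SOLID, (150, 60, 90), structure="plain"
    ),
    PatternClass.BENIGN: TextureSpec(
        PatternClass.BENIGN, (245, 240, 232), structure="sheets", scale=48, amplitude=8.0
    ),
}


def _motif_field(structure: str, scale: int, shape: Tuple[int, int], rng) -> np.ndarray:
    """Spatial modulation in [-1, 1] for one texture."""
    h, w = shape
    if structure == "plain":
        return np.zeros(shape, dtype=np.float32)
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float32)
    if structure == "sheets":
        theta = rng.uniform(0, math.pi)
        phase = rng.uniform(0, 2 * math.pi)
        return np.sin(
            2 * math.pi * (xs * math.cos(theta) + ys * math.sin(theta)) / scale + phase
        ).astype(np.float32)
    if structure == "rings":
        g = 4 * scale
        cx, cy = rng.uniform(0, g, 2)
        dx = (xs - cx) % g - g / 2
        dy = (ys - cy) % g - g / 2
        return np.sin(2 * math.pi * np.sqrt(dx * dx + dy * dy) / scale).astype(
            np.float32
        )
    if structure in ("blobs", "speckle"):
        ch = max(2, math.ceil(h / scale))
        cw = max(2, math.ceil(w / scale))
        coarse = rng.standard_normal((ch, cw)).astype(np.float32)
        fine = ndimage.zoom(coarse, (h / ch, w / cw), order=1, grid_mode=True, mode="nearest")
        fine = fine[:h, :w]
        if structure == "speckle":
            return np.where(fine > 1.0, -1.0, 0.0).astype(np.float32)
        return np.tanh(fine).astype(np.float32)
    raise ValueError(f"unknown texture structure {structure!r}")


def render_texture(spec: TextureSpec, shape: Tuple[int, int], rng) -> np.ndarray:
    """Render one class's texture as an HxWx3 uint8 raster."""
    h, w = shape
    motif = _motif_field(spec.structure, spec.scale, shape, rng)
    img = np.empty((h, w, 3), dtype=np.float32)
    for ch in range(3):
        img[..., ch] = spec.base_color[ch] + spec.amplitude * motif
    img += rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# slide composition and ground truth


@dataclass(frozen=True)
class SlideComposition:
    """Requested per-class area fractions of a synthetic slide."""

    fractions: Mapping[PatternClass, float]
    slide_width: int = DEFAULT_SLIDE_SIZE
    slide_height: int = DEFAULT_SLIDE_SIZE

    def __post_init__(self) -> None:
        fr = {c: float(v) for c, v in self.fractions.items() if v != 0}
        if any(v < 0 for v in fr.values()):
            raise ValueError("fractions must be nonnegative")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fr.values())}")
        object.__setattr__(self, "fractions", fr)

    @property
    def present(self) -> List[PatternClass]:
        return [c for c in ALL_CLASSES if self.fractions.get(c, 0) > 0]

    def label(self, min_fraction: float = 0.05) -> SlideLabel:
        """Slide label implied by the area fractions (same rule as inference)."""
        return label_from_weights(dict(self.fractions), min_fraction=min_fraction)


def composition_label(
    composition: SlideComposition, min_fraction: float = 0.05
) -> SlideLabel:
    return composition.label(min_fraction=min_fraction)


@dataclass
class GroundTruth:
    """Per-pixel class raster plus the slide label it implies."""

    region_map: np.ndarray  # HxW uint8 of PatternClass ordinals
    slide_label: SlideLabel
    composition: SlideComposition
    seed: int

    def realized_fractions(self) -> Dict[PatternClass, float]:
        counts = np.bincount(self.region_map.ravel(), minlength=N_CLASSES)
        total = counts.sum()
        return {c: counts[int(c)] / total for c in ALL_CLASSES if counts[int(c)]}


def _region_map(
    composition: SlideComposition, rng, cells_per_class: int = 24, coarse: int = 4
) -> np.ndarray:
    """Contiguous single-class regions whose areas match the fractions exactly.

    Voronoi cells are computed on a coarse grid (``coarse``-pixel blocks) and
    walked in random order against per-class pixel quotas; the cell that
    crosses a quota boundary is split along x, so realized fractions match the
    request to the rounding of a single pixel.
    """
    w, h = composition.slide_width, composition.slide_height
    present = composition.present
    n_cells = max(cells_per_class * len(present), 8 * len(present))
    seeds = np.column_stack(
        [rng.uniform(0, w, n_cells), rng.uniform(0, h, n_cells)]
    )
    ch, cw = math.ceil(h / coarse), math.ceil(w / coarse)
    cys, cxs = np.mgrid[0:ch, 0:cw]
    pts = np.column_stack(
        [(cxs.ravel() + 0.5) * coarse, (cys.ravel() + 0.5) * coarse]
    )
    cell_coarse = cKDTree(seeds).query(pts)[1].reshape(ch, cw)
    cellmap = np.repeat(np.repeat(cell_coarse, coarse, axis=0), coarse, axis=1)[:h, :w]

    n_px = h * w
    quotas = {c: int(math.floor(composition.fractions[c] * n_px)) for c in present}
    remainder = n_px - sum(quotas.values())
    order_by_part = sorted(
        present,
        key=lambda c: composition.fractions[c] * n_px - quotas[c],
        reverse=True,
    )
    for c in order_by_part[:remainder]:
        quotas[c] += 1

    rank = np.empty(n_cells, dtype=np.int64)
    rank[rng.permutation(n_cells)] = np.arange(n_cells)
    idx = np.arange(n_px)
    ys, xs = idx // w, idx % w
    key = np.lexsort((ys, xs, rank[cellmap.ravel()]))
    labels_flat = np.empty(n_px, dtype=np.uint8)
    start = 0
    for c in present:
        labels_flat[key[start : start + quotas[c]]] = int(c)
        start += quotas[c]
    return labels_flat.reshape(h, w)


def generate_slide(
    composition: SlideComposition,
    textures: Optional[Mapping[PatternClass, TextureSpec]] = None,
    seed: int = 0,
    min_fraction: float = 0.05,
) -> Tuple[np.ndarray, GroundTruth]:
    """Render a synthetic slide and its ground truth.

    Deterministic: identical arguments and seed give a byte-identical image.
    The slide label is derived from the realized pixel fractions with the
    same 5%/benign-drop rule used at inference time.
    """
    textures = dict(textures or DEFAULT_TEXTURES)
    missing = [c for c in composition.present if c not in textures]
    if missing:
        raise ValueError(f"no texture for classes {[c.label for c in missing]}")
    rng = np.random.default_rng(seed)
    region_map = _region_map(composition, rng)
    h, w = region_map.shape
    slide = np.zeros((h, w, 3), dtype=np.uint8)
    for c in composition.present:
        mask = region_map == int(c)
        tex = render_texture(textures[c], (h, w), rng)
        slide[mask] = tex[mask]
    counts = np.bincount(region_map.ravel(), minlength=N_CLASSES)
    label = label_from_weights(
        {c: int(counts[int(c)]) for c in ALL_CLASSES}, min_fraction=min_fraction
    )
    return slide, GroundTruth(region_map, label, composition, seed)


# ---------------------------------------------------------------------------
# crop sets

# lognormal size parameters calibrated to annotated-crop statistics
# (median 429x473, mean 718x771): sigma^2 = 2 ln(mean/median)
_CROP_MU = (math.log(429), math.log(473))
_CROP_SIGMA = (
    math.sqrt(2 * math.log(718 / 429)),
    math.sqrt(2 * math.log(771 / 473)),
)
_CROP_MAX = 4096


def default_crop_size_sampler(rng) -> Tuple[int, int]:
    w = int(round(rng.lognormal(_CROP_MU[0], _CROP_SIGMA[0])))
    h = int(round(rng.lognormal(_CROP_MU[1], _CROP_SIGMA[1])))
    return w, h


def generate_crop_set(
    n_per_class: int,
    textures: Optional[Mapping[PatternClass, TextureSpec]] = None,
    seed: int = 0,
    patch_size: int = DEFAULT_PATCH_SIZE,
    size_sampler=None,
) -> List[Crop]:
    """Single-class labeled crops, ``n_per_class`` for each of the six classes.

    Sizes are drawn from ``size_sampler`` (default: calibrated lognormal) and
    redrawn until both dimensions are in [patch_size, 4096] — undersized
    crops are never emitted.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    textures = dict(textures or DEFAULT_TEXTURES)
    sampler = size_sampler or default_crop_size_sampler
    rng = np.random.default_rng(seed)
    crops: List[Crop] = []
    for c in ALL_CLASSES:
        for i in range(n_per_class):
            while True:
                w, h = sampler(rng)
                if patch_size <= w <= _CROP_MAX and patch_size <= h <= _CROP_MAX:
                    break
            image = render_texture(textures[c], (h, w), rng)
            crops.append(Crop(image=image, label=c, source_id=f"{c.label}_{i:04d}"))
    return crops


# ---------------------------------------------------------------------------
# prediction tables


@dataclass(frozen=True)
class ConfidenceModel:
    """Distribution of the winning-class probability.

    Confidence is Beta(mean*strength, (1-mean)*strength) clipped to
    [min_conf, 1]; the residual mass is split over the other five classes
    by a symmetric Dirichlet, falling back to a uniform split whenever a
    competitor would overtake the winner.  ``mean=1`` gives one-hot vectors.
    """

    mean: float = 0.9
    strength: float = 20.0
    min_conf: float = 0.35

    def draw(self, rng) -> float:
        if self.mean >= 1.0:
            return 1.0
        c = rng.beta(self.mean * self.strength, (1 - self.mean) * self.strength)
        return float(np.clip(c, self.min_conf, 1.0))


IDENTITY_CONFUSION = np.eye(N_CLASSES)


def generate_prediction_table(
    composition: SlideComposition,
    n_patches: int,
    confusion: Optional[np.ndarray] = None,
    confidence_model: Optional[ConfidenceModel] = None,
    seed: int = 0,
    source_id: str = "synthetic",
    patch_size: int = DEFAULT_PATCH_SIZE,
    return_truth: bool = False,
):
    """Simulated patch predictions for one slide (no images involved).

    Each patch's true class is drawn from the composition fractions, its
    predicted class from the confusion row, and its probability vector from
    the confidence model with the predicted class as argmax.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    confusion = np.asarray(
        IDENTITY_CONFUSION if confusion is None else confusion, dtype=np.float64
    )
    if confusion.shape != (N_CLASSES, N_CLASSES) or np.any(confusion < 0):
        raise ValueError("confusion must be a nonnegative 6x6 matrix")
    if not np.allclose(confusion.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("confusion rows must sum to 1")
    model = confidence_model or ConfidenceModel()
    rng = np.random.default_rng(seed)

    classes = list(composition.fractions)
    weights = np.array([composition.fractions[c] for c in classes])
    grid_side = math.ceil(math.sqrt(n_patches))
    preds: List[PatchPrediction] = []
    truths: List[PatternClass] = []
    for i in range(n_patches):
        true = classes[rng.choice(len(classes), p=weights)]
        predicted = int(rng.choice(N_CLASSES, p=confusion[int(true)]))
        c = model.draw(rng)
        probs = np.zeros(N_CLASSES)
        if c >= 1.0:
            probs[predicted] = 1.0
        else:
            rest = (1.0 - c) * rng.dirichlet(np.ones(N_CLASSES - 1))
            if rest.max() >= c:
                rest = np.full(N_CLASSES - 1, (1.0 - c) / (N_CLASSES - 1))
            probs[predicted] = c
            probs[[k for k in range(N_CLASSES) if k != predicted]] = rest
        origin = ((i % grid_side) * patch_size, (i // grid_side) * patch_size)
        preds.append(PatchPrediction(origin=origin, source_id=source_id, probs=probs))
        truths.append(true)
    if return_truth:
        return preds, truths
    return preds


def random_composition(
    rng,
    min_cancer_fraction: float = 0.075,
    gap: float = 0.075,
    benign_min: float = 0.05,
    max_cancer_classes: int = 3,
    slide_width: int = DEFAULT_SLIDE_SIZE,
    slide_height: int = DEFAULT_SLIDE_SIZE,
) -> SlideComposition:
    """A random composition that keeps the implied label unambiguous.

    Every included cancer class receives a fraction of at least
    ``min_cancer_fraction`` (1.5x the 5% rule's cutoff by default) and
    consecutive cancer fractions differ by at least ``gap``, so neither the
    5% boundary nor the predominant ordering is decided by sampling noise
    downstream.  The benign class absorbs the remainder (at least
    ``benign_min``).
    """
    k = int(rng.integers(1, max_cancer_classes + 1))
    chosen = [CANCER_CLASSES[i] for i in rng.choice(len(CANCER_CLASSES), size=k, replace=False)]
    base = np.array([min_cancer_fraction + gap * (k - 1 - i) for i in range(k)])
    headroom = 1.0 - base.sum() - benign_min
    if headroom < 0:
        raise ValueError("floor/gap settings leave no room for benign")
    extras = np.sort(rng.dirichlet(np.ones(k)))[::-1] * headroom * rng.uniform(0.2, 1.0)
    fractions = {c: float(b + e) for c, b, e in zip(chosen, base, extras)}
    fractions[PatternClass.BENIGN] = 1.0 - sum(fractions.values())
    return SlideComposition(
        fractions, slide_width=slide_width, slide_height=slide_height
    )


# ---------------------------------------------------------------------------
# annotation sets with planted disagreement


def random_slide_label(rng, p_benign: float = 0.1, max_minors: int = 2) -> SlideLabel:
    if rng.random() < p_benign:
        return SlideLabel.benign()
    predominant = CANCER_CLASSES[rng.integers(len(CANCER_CLASSES))]
    others = [c for c in CANCER_CLASSES if c is not predominant]
    k = int(rng.integers(0, max_minors + 1))
    minors = frozenset(
        others[j] for j in rng.choice(len(others), size=k, replace=False)
    )
    return SlideLabel(predominant, minors)


def _flip_predominant(label: SlideLabel, shift: int) -> SlideLabel:
    """Deterministically change the predominant pattern (never a no-op)."""
    if label.predominant is None:
        new = CANCER_CLASSES[(shift - 1) % len(CANCER_CLASSES)]
    else:
        new = CANCER_CLASSES[
            (int(label.predominant) + shift) % len(CANCER_CLASSES)
        ]
    return SlideLabel(new, frozenset(m for m in label.minors if m is not new))


def generate_annotation_sets(
    n_slides: int,
    disagreement: Sequence[float] = (0.1, 0.2, 0.3),
    seed: int = 0,
    annotator_ids: Sequence[str] = ("pathologist1", "pathologist2", "pathologist3", "model"),
) -> Tuple[List[AnnotationSet], Dict[Tuple[str, str], float]]:
    """Four annotation sets with exactly known pairwise predominant agreement.

    Annotator 0 holds the base labels; annotator j > 0 deviates on a planted,
    pairwise-disjoint set of round(disagreement[j-1] * n) slides, where its
    predominant label is shifted to a class no other annotator uses on that
    slide.  Pairwise agreement is then exact: 1 - r_j against the base and
    1 - r_j - r_k between two deviating annotators.

    Returns the sets and the expected pairwise predominant-agreement matrix.
    """
    if len(annotator_ids) != len(disagreement) + 1:
        raise ValueError("need one disagreement rate per non-base annotator")
    if sum(disagreement) > 1.0 + 1e-12:
        raise ValueError("disagreement rates must sum to at most 1")
    rng = np.random.default_rng(seed)
    base = {f"slide_{i:04d}": random_slide_label(rng) for i in range(n_slides)}
    ids = sorted(base)

    counts = [round(r * n_slides) for r in disagreement]
    if sum(counts) > n_slides:
        raise ValueError("disagreement rates leave no room for disjoint flip sets")
    perm = rng.permutation(n_slides)
    flip_sets: List[List[str]] = []
    start = 0
    for k in counts:
        flip_sets.append([ids[j] for j in perm[start : start + k]])
        start += k

    sets = [AnnotationSet(annotator_ids[0], dict(base))]
    for j, flips in enumerate(flip_sets, start=1):
        labels = dict(base)
        for s in flips:
            labels[s] = _flip_predominant(base[s], shift=j)
        sets.append(AnnotationSet(annotator_ids[j], labels))

    rates = [0.0] + [len(f) / n_slides for f in flip_sets]
    expected: Dict[Tuple[str, str], float] = {}
    for i in range(len(annotator_ids)):
        for j in range(i + 1, len(annotator_ids)):
            key = tuple(sorted((annotator_ids[i], annotator_ids[j])))
            expected[key] = 1.0 - rates[i] - rates[j]
    return sets, expected
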