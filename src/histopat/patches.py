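"""Sliding-window patch extraction from crops and whole slides.

Training data arrives as variable-size rectangular crops, each annotated
with a single tissue class; the classifier consumes fixed-size square
patches (default 224x224).  Two extraction regimes are provided:

* **crop extraction** — a per-class stride is chosen so the window counts
  balance the class distribution (classes with fewer crops get more
  overlap);
* **slide tiling** — a fixed overlap of one-fifth of the patch side
  between adjacent windows, the regime used at whole-slide inference.

Coordinates are 0-based, x rightward, y downward; a window is the
half-open square ``[x, x+patch) x [y, y+patch)``.  The right/bottom
remainder smaller than a stride is dropped by default (``edge="drop"``);
``edge="keep-last"`` re-anchors a final window flush with the border.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .patterns import PatternClass

logger = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 224
DEFAULT_OVERLAP = 1 / 5


@dataclass
class Crop:
    """A variable-size, single-class annotated rectangle of tissue."""

    image: np.ndarray  # HxWx3 uint8
    label: PatternClass
    source_id: str = "crop"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("crop image must be HxWx3")

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


@dataclass
class Patch:
    """A fixed-size square sub-image with its provenance.

    ``origin`` is the (x, y) of the top-left corner in the source image;
    ``label`` is present for training patches and absent for inference
    patches cut from an unlabeled slide.
    """

    image: np.ndarray
    origin: Tuple[int, int]
    source_id: str
    label: Optional[PatternClass] = None

    @property
    def size(self) -> int:
        return self.image.shape[0]

    def __post_init__(self) -> None:
        h, w = self.image.shape[:2]
        if h != w:
            raise ValueError(f"patch must be square, got {w}x{h}")


def window_count(extent: int, patch_size: int, stride: int) -> int:
    """Number of sliding windows along one dimension (closed form)."""
    if extent < patch_size:
        return 0
    return (extent - patch_size) // stride + 1


@dataclass(frozen=True)
class TilingPlan:
    """Window geometry of a sliding-window pass over a rectangle."""

    patch_size: int
    stride: int
    n_windows_x: int
    n_windows_y: int

    @classmethod
    def for_extent(cls, width: int, height: int, patch_size: int, stride: int) -> "TilingPlan":
        if not 1 <= stride <= patch_size:
            raise ValueError(f"stride must be in [1, patch_size], got {stride}")
        return cls(
            patch_size=patch_size,
            stride=stride,
            n_windows_x=window_count(width, patch_size, stride),
            n_windows_y=window_count(height, patch_size, stride),
        )

    @property
    def n_windows(self) -> int:
        return self.n_windows_x * self.n_windows_y

    def origins(self, width: int, height: int, edge: str = "drop") -> List[Tuple[int, int]]:
        """Row-major (x, y) origins; ``keep-last`` re-anchors edge windows."""
        xs = [i * self.stride for i in range(self.n_windows_x)]
        ys = [j * self.stride for j in range(self.n_windows_y)]
        if edge == "keep-last":
            if xs and xs[-1] + self.patch_size < width:
                xs.append(width - self.patch_size)
            if ys and ys[-1] + self.patch_size < height:
                ys.append(height - self.patch_size)
        elif edge != "drop":
            raise ValueError(f"edge must be 'drop' or 'keep-last', got {edge!r}")
        return [(x, y) for y in ys for x in xs]


def extract_patches_from_crop(
    crop: Crop, patch_size: int = DEFAULT_PATCH_SIZE, stride: int = DEFAULT_PATCH_SIZE
) -> List[Patch]:
    """Cut all sliding windows out of a crop; each inherits the crop label.

    A crop smaller than the patch size yields an empty list with a logged
    warning rather than an error — undersized crops are skipped, not fatal.
    """
    if not 1 <= stride <= patch_size:
        raise ValueError(f"stride must be in [1, patch_size], got {stride}")
    if crop.width < patch_size or crop.height < patch_size:
        logger.warning(
            "crop %s (%dx%d) smaller than patch size %d; skipped",
            crop.source_id, crop.width, crop.height, patch_size,
        )
        return []
    plan = TilingPlan.for_extent(crop.width, crop.height, patch_size, stride)
    out = []
    for x, y in plan.origins(crop.width, crop.height):
        out.append(
            Patch(
                image=crop.image[y : y + patch_size, x : x + patch_size],
                origin=(x, y),
                source_id=crop.source_id,
                label=crop.label,
            )
        )
    return out


@dataclass(frozen=True)
class BalancePlan:
    """Chosen stride for one class, with the window count it achieves."""

    stride: int
    achieved: int
    under_target: bool


def _count_for_stride(dims: Sequence[Tuple[int, int]], patch_size: int, stride: int) -> int:
    return sum(
        window_count(w, patch_size, stride) * window_count(h, patch_size, stride)
        for w, h in dims
    )


def plan_class_balancing(
    crop_inventory: Mapping[PatternClass, Sequence[Tuple[int, int]]],
    patch_size: int = DEFAULT_PATCH_SIZE,
    target_per_class: int = 8000,
) -> Dict[PatternClass, BalancePlan]:
    """Pick, per class, the largest stride whose total window count meets the target.

    Classes with many/large crops get large strides (little overlap); sparse
    classes get small strides.  If even stride 1 cannot reach the target the
    class is flagged ``under_target`` (augmentation makes up the difference
    downstream).  Strides are searched by integer enumeration from
    ``patch_size`` down — inventories are small, exactness beats cleverness.
    """
    plans: Dict[PatternClass, BalancePlan] = {}
    for cls, dims in crop_inventory.items():
        usable = [(w, h) for w, h in dims if w >= patch_size and h >= patch_size]
        if not usable:
            raise ValueError(f"no usable crops for class {cls.label}")
        chosen = None
        for stride in range(patch_size, 0, -1):
            n = _count_for_stride(usable, patch_size, stride)
            if n >= target_per_class:
                chosen = BalancePlan(stride=stride, achieved=n, under_target=False)
                break
        if chosen is None:
            n1 = _count_for_stride(usable, patch_size, 1)
            chosen = BalancePlan(stride=1, achieved=n1, under_target=True)
        plans[cls] = chosen
    return plans


def tile_slide(
    slide: np.ndarray,
    patch_size: int = DEFAULT_PATCH_SIZE,
    overlap_fraction: float = DEFAULT_OVERLAP,
    source_id: str = "slide",
    edge: str = "drop",
) -> List[Patch]:
    """Tile a whole slide with windows overlapping by ``overlap_fraction``.

    The stride is ``round(patch_size * (1 - overlap_fraction))``; at the
    default one-fifth overlap and 224-pixel patches, adjacent windows share
    45 pixel columns (stride 179).
    """
    slide = np.asarray(slide)
    if not 0 <= overlap_fraction < 1:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    h, w = slide.shape[:2]
    if w < patch_size:
        raise ValueError(f"slide width {w} smaller than patch size {patch_size}")
    if h < patch_size:
        raise ValueError(f"slide height {h} smaller than patch size {patch_size}")
    stride = max(1, round(patch_size * (1 - overlap_fraction)))
    plan = TilingPlan.for_extent(w, h, patch_size, stride)
    return [
        Patch(
            image=slide[y : y + patch_size, x : x + patch_size],
            origin=(x, y),
            source_id=source_id,
        )
        for x, y in plan.origins(w, h, edge=edge)
    ]


def brightness_tissue_mask(
    slide: np.ndarray, white_threshold: int = 230
) -> np.ndarray:
    """Optional boolean mask of non-background pixels (off by default everywhere).

    Background in brightfield scans is near-white; pixels whose channel mean
    exceeds ``white_threshold`` are flagged as background.  The pipeline does
    not apply this by default: non-tissue is handled by the benign class and
    confidence thresholding.
    """
    slide = np.asarray(slide, dtype=np.float64)
    return slide.mean(axis=2) < white_threshold
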