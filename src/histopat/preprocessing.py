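"""Channel normalization and the training augmentation stack.

Color statistics are pooled over every pixel of the raw training
patches (population standard deviation — the pixel counts are huge) and
frozen; model inputs are standardized channel-wise to those statistics,
neutralizing color differences between slides.

Augmentation, applied in order: color jitter on brightness, contrast,
saturation and hue with factors drawn uniformly from configured
half-ranges; rotation by a uniformly drawn multiple of 90 degrees; then
horizontal/vertical flips by their probabilities.  Every augmented copy
is fully determined by ``(policy.seed, draw)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from skimage import color as skcolor

from .patches import Patch
from .patterns import PatternClass

_CHANNELS = ("red", "green", "blue")


@dataclass(frozen=True)
class ChannelStats:
    """Pooled per-channel mean/std over a patch collection."""

    mean: Tuple[float, float, float]
    std: Tuple[float, float, float]
    n_pixels: int

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.std):
            bad = [_CHANNELS[i] for i, s in enumerate(self.std) if s <= 0]
            raise ValueError(f"degenerate (constant) channel(s): {', '.join(bad)}")

    def to_dict(self) -> dict:
        return {"mean": list(self.mean), "std": list(self.std), "n_pixels": self.n_pixels}

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelStats":
        return cls(tuple(d["mean"]), tuple(d["std"]), int(d["n_pixels"]))


def compute_channel_stats(patches: Iterable[Patch]) -> ChannelStats:
    """Streaming pooled mean and population std over all pixels of all patches.

    Raises if the collection is empty or any channel is constant (a constant
    channel cannot be standardized).
    """
    n = 0
    s = np.zeros(3, dtype=np.float64)
    ss = np.zeros(3, dtype=np.float64)
    for patch in patches:
        img = np.asarray(patch.image, dtype=np.float64).reshape(-1, 3)
        n += img.shape[0]
        s += img.sum(axis=0)
        ss += (img * img).sum(axis=0)
    if n == 0:
        raise ValueError("empty patch collection")
    mean = s / n
    var = np.maximum(ss / n - mean * mean, 0.0)
    std = np.sqrt(var)
    return ChannelStats(tuple(mean), tuple(std), n)


def normalize(patch: Patch, stats: ChannelStats) -> np.ndarray:
    """Standardize a patch channel-wise: (x - mean) / std (float output)."""
    img = np.asarray(patch.image, dtype=np.float64)
    return (img - np.asarray(stats.mean)) / np.asarray(stats.std)


def denormalize(array: np.ndarray, stats: ChannelStats) -> np.ndarray:
    """Inverse of :func:`normalize` (float output, not re-quantized)."""
    return array * np.asarray(stats.std) + np.asarray(stats.mean)


@dataclass(frozen=True)
class AugmentPolicy:
    """Jitter half-ranges, rotation/flip settings, and the base seed."""

    brightness: float = 0.2
    contrast: float = 0.2
    saturation: float = 0.2
    hue: float = 0.05
    rotate_90: bool = True
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("brightness", "contrast", "saturation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} half-range must be nonnegative")
        if not 0 <= self.hue <= 0.5:
            raise ValueError("hue half-range must be in [0, 0.5] cycles")
        for name in ("hflip_prob", "vflip_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def identity(cls, seed: int = 0) -> "AugmentPolicy":
        return cls(0.0, 0.0, 0.0, 0.0, rotate_90=False, hflip_prob=0.0, vflip_prob=0.0, seed=seed)


def _jitter(img: np.ndarray, rng, policy: AugmentPolicy) -> np.ndarray:
    """Brightness/contrast/saturation/hue jitter in raw color space."""
    out = img.astype(np.float64)
    if policy.brightness > 0:
        out = out * (1.0 + rng.uniform(-policy.brightness, policy.brightness))
    if policy.contrast > 0:
        f = 1.0 + rng.uniform(-policy.contrast, policy.contrast)
        out = out.mean() + (out - out.mean()) * f
    if policy.saturation > 0:
        f = 1.0 + rng.uniform(-policy.saturation, policy.saturation)
        gray = out.mean(axis=2, keepdims=True)
        out = gray + (out - gray) * f
    if policy.hue > 0:
        shift = rng.uniform(-policy.hue, policy.hue)
        hsv = skcolor.rgb2hsv(np.clip(out, 0, 255).astype(np.uint8))
        hsv[..., 0] = (hsv[..., 0] + shift) % 1.0
        out = skcolor.hsv2rgb(hsv) * 255.0
    return np.clip(out, 0, 255).astype(np.uint8)


def augment(patch: Patch, policy: AugmentPolicy, draw: int) -> Patch:
    """One augmented copy, fully determined by (policy.seed, draw).

    Order of operations: color jitter, rotation by a multiple of 90°,
    horizontal flip, vertical flip.  Size and label are preserved.
    """
    rng = np.random.default_rng(np.random.SeedSequence([policy.seed, draw]))
    img = _jitter(patch.image, rng, policy)
    if policy.rotate_90:
        k = int(rng.integers(0, 4))
        img = np.rot90(img, k)
    if policy.hflip_prob > 0 and rng.random() < policy.hflip_prob:
        img = img[:, ::-1]
    if policy.vflip_prob > 0 and rng.random() < policy.vflip_prob:
        img = img[::-1, :]
    return Patch(
        image=np.ascontiguousarray(img),
        origin=patch.origin,
        source_id=patch.source_id,
        label=patch.label,
    )


def expand_dataset(
    patches: Sequence[Patch], policy: AugmentPolicy, target_per_class: int
) -> List[Patch]:
    """Augment round-robin until every class holds exactly ``target_per_class``.

    Classes already at or above the target pass through unaugmented (truncated
    to the target so the output histogram is exactly uniform).  Each augmented
    copy uses a distinct draw index.
    """
    by_class: Dict[PatternClass, List[Patch]] = {}
    for p in patches:
        if p.label is None:
            raise ValueError("expand_dataset requires labeled patches")
        by_class.setdefault(p.label, []).append(p)
    if not by_class:
        raise ValueError("empty patch collection")
    for cls, members in by_class.items():
        if not members:
            raise ValueError(f"class {cls.label} has no patches")

    out: List[Patch] = []
    draw = 0
    for cls in sorted(by_class):
        members = by_class[cls]
        if len(members) >= target_per_class:
            out.extend(members[:target_per_class])
            continue
        out.extend(members)
        need = target_per_class - len(members)
        for i in range(need):
            src = members[i % len(members)]
            out.append(augment(src, policy, draw))
            draw += 1
    return out
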