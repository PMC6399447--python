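"""File-format plumbing: PNG rasters, CSV manifests, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .inference import PatchPrediction, ThresholdSet
from .patches import Crop, Patch
from .patterns import ALL_CLASSES, PatternClass, SlideLabel

PROB_COLUMNS = [f"p_{c.label}" for c in ALL_CLASSES]


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image))


def read_image(path) -> np.ndarray:
    img = iio.imread(Path(path))
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[..., :3]
    return img


def write_slide_bundle(out_dir, slide: np.ndarray, ground_truth) -> None:
    """Slide PNG, ordinal-coded region-map PNG, and a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(out / "slide.png", slide)
    write_image(out / "region_map.png", ground_truth.region_map.astype(np.uint8))
    sidecar = {
        "composition": {
            c.label: v for c, v in ground_truth.composition.fractions.items()
        },
        "slide_label": ground_truth.slide_label.to_dict(),
        "seed": ground_truth.seed,
    }
    (out / "slide.json").write_text(json.dumps(sidecar, indent=2))


def write_crops(out_dir, crops: Sequence[Crop]) -> Path:
    """Crop PNGs plus a CSV manifest (path, class, width, height)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for crop in crops:
        name = f"{crop.source_id}.png"
        write_image(out / name, crop.image)
        rows.append(
            {
                "path": name,
                "class": crop.label.label,
                "width": crop.width,
                "height": crop.height,
            }
        )
    manifest = out / "crops.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_crops(manifest_path) -> List[Crop]:
    manifest = Path(manifest_path)
    base = manifest.parent
    df = pd.read_csv(manifest)
    return [
        Crop(
            image=read_image(base / row["path"]),
            label=PatternClass.from_label(row["class"]),
            source_id=Path(row["path"]).stem,
        )
        for _, row in df.iterrows()
    ]


def write_patches(out_dir, patches: Sequence[Patch]) -> Path:
    """Patch PNGs in class/ subdirectories plus a CSV manifest."""
    out = Path(out_dir)
    rows = []
    for i, p in enumerate(patches):
        sub = p.label.label if p.label is not None else "unlabeled"
        (out / sub).mkdir(parents=True, exist_ok=True)
        name = f"{sub}/{i:06d}.png"
        write_image(out / name, p.image)
        rows.append(
            {
                "path": name,
                "class": sub,
                "source_id": p.source_id,
                "x": p.origin[0],
                "y": p.origin[1],
            }
        )
    manifest = out / "patches.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_patches(manifest_path) -> List[Patch]:
    manifest = Path(manifest_path)
    base = manifest.parent
    df = pd.read_csv(manifest)
    out = []
    for _, row in df.iterrows():
        label = (
            None if row["class"] == "unlabeled" else PatternClass.from_label(row["class"])
        )
        out.append(
            Patch(
                image=read_image(base / row["path"]),
                origin=(int(row["x"]), int(row["y"])),
                source_id=str(row["source_id"]),
                label=label,
            )
        )
    return out


def write_predictions_csv(path, predictions: Sequence[PatchPrediction]) -> None:
    rows = []
    for p in predictions:
        row = {"source_id": p.source_id, "x": p.origin[0], "y": p.origin[1]}
        row.update({col: p.probs[i] for i, col in enumerate(PROB_COLUMNS)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_predictions_csv(path) -> List[PatchPrediction]:
    df = pd.read_csv(path)
    return [
        PatchPrediction(
            origin=(int(row["x"]), int(row["y"])),
            source_id=str(row["source_id"]),
            probs=np.array([row[c] for c in PROB_COLUMNS], dtype=np.float64),
        )
        for _, row in df.iterrows()
    ]


def write_thresholds(path, thresholds: ThresholdSet, objective: Optional[float] = None) -> None:
    payload = {"thresholds": thresholds.to_dict()}
    if objective is not None:
        payload["dev_objective"] = objective
    Path(path).write_text(json.dumps(payload, indent=2))


def read_thresholds(path) -> ThresholdSet:
    payload = json.loads(Path(path).read_text())
    return ThresholdSet.from_dict(payload["thresholds"])


def write_slide_labels(path, labels: Mapping[str, SlideLabel], extra: Optional[dict] = None) -> None:
    payload = {
        "slides": {sid: lab.to_dict() for sid, lab in labels.items()},
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_slide_labels(path) -> Dict[str, SlideLabel]:
    payload = json.loads(Path(path).read_text())
    return {sid: SlideLabel.from_dict(d) for sid, d in payload["slides"].items()}
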