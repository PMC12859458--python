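"""Shared readers/writers and overlay rendering.

Images: PNG and TIFF, 8- or 16-bit grayscale (color inputs are reduced to
one channel by luminance average on load).  Instance sets round-trip
through per-well label-image TIFFs (0 = background, k = instance id).
Overlays tint each organoid with a color drawn deterministically from its
id and a seed, and print the id at the centroid.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
from PIL import Image, ImageDraw

from .core import (
    DetectionSet,
    OrgquantError,
    WellImage,
    instance_from_mask,
)


def read_image(path, source_id: Optional[str] = None) -> WellImage:
    p = Path(path)
    if not p.exists():
        raise OrgquantError(f"no such image: {p}")
    if p.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(p)
    else:
        px = np.asarray(Image.open(p))
    return WellImage(pixels=px, source_id=source_id or p.name)


def write_image(image: np.ndarray, path) -> None:
    p = Path(path)
    arr = np.asarray(image)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(p, arr)
    else:
        Image.fromarray(arr).save(p)


def detections_to_label_image(dets: DetectionSet) -> np.ndarray:
    """Render a detection set as a label image (0 background, k = id)."""
    labels = np.zeros((dets.image_height, dets.image_width), dtype=np.uint32)
    for inst in dets.instances:
        ys, xs = inst.pixel_coords()
        labels[ys, xs] = inst.id
    return labels


def label_image_to_detections(
    labels: np.ndarray, deduplicated: bool = False
) -> DetectionSet:
    """Inverse of :func:`detections_to_label_image` (lossless for disjoint
    masks, which a label image enforces by construction)."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise OrgquantError(f"label image must be 2-D, got shape {labels.shape}")
    instances = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        instances.append(
            instance_from_mask(labels == lab, id=int(lab), check_connectivity=False)
        )
    return DetectionSet(
        instances=instances,
        image_width=labels.shape[1],
        image_height=labels.shape[0],
        deduplicated=deduplicated,
    )


def write_label_tiff(dets: DetectionSet, path) -> None:
    tifffile.imwrite(Path(path), detections_to_label_image(dets))


def read_label_tiff(path, deduplicated: bool = False) -> DetectionSet:
    p = Path(path)
    if not p.exists():
        raise OrgquantError(f"no such label image: {p}")
    return label_image_to_detections(tifffile.imread(p), deduplicated=deduplicated)


def _id_color(instance_id: int, seed: int) -> tuple[int, int, int]:
    rng = np.random.default_rng((seed, instance_id))
    # Bright, saturated-ish colors: at least one strong channel.
    c = rng.integers(0, 256, size=3)
    c[int(rng.integers(0, 3))] = rng.integers(180, 256)
    return tuple(int(v) for v in c)


def render_overlay(image: WellImage, dets: DetectionSet, seed: int = 0) -> np.ndarray:
    """RGB overlay: instances tinted by a per-id deterministic color, ids
    printed at centroids, background untouched."""
    if not dets.deduplicated:
        raise OrgquantError("overlay rendering expects a deduplicated detection set")
    px = image.pixels
    scale = 255.0 / px.max() if px.max() > 255 else 1.0
    gray = np.clip(px * scale, 0, 255).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=2)
    for inst in dets.instances:
        color = np.array(_id_color(inst.id, seed), dtype=float)
        ys, xs = inst.pixel_coords()
        rgb[ys, xs] = np.clip(
            0.5 * rgb[ys, xs] + 0.5 * color, 0, 255
        ).astype(np.uint8)
    pil = Image.fromarray(rgb)
    drawer = ImageDraw.Draw(pil)
    for inst in dets.instances:
        cx, cy = inst.centroid
        drawer.text((cx, cy), str(inst.id), fill=(255, 255, 255), anchor="mm")
    return np.asarray(pil)
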