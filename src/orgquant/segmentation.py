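"""Per-tile instance-segmentation backends and mask ingestion.

A segmentation backend is simply a callable taking a T x T single-channel
pixel array and returning ``[(mask, confidence), ...]`` in tile
coordinates.  Three sources are supported:

* :func:`reference_detect` — a classical detector (threshold + watershed)
  so the whole pipeline runs with no trained weights and no GPU.  In
  bright-field, organoids show a dark rim around a bright lumen on a mid
  grey background, so the detector thresholds dark structures and fills
  their interiors.
* :func:`load_external_masks` — masks produced elsewhere (a trained CNN,
  or manual VGG Image Annotator polygons) loaded from label-image TIFF or
  VIA project JSON.
* an oracle backend built from synthetic ground truth (see ``synthgen``).

Confidence semantics: the reference detector scores shape quality —
circularity 4*pi*A/P^2 for cystic (spherical) mode, convex-hull solidity
for budded (lobed) mode — which lives on the same [0, 1] scale as a CNN's
learned confidence but is not a probability.  The default thresholds
(0.795 cystic, 0.836 budded) are carried as configuration constants for
the threshold machinery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import shapely
import tifffile
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import feature, measure, segmentation as _sks

from .core import OrgquantError, mask_perimeter

#: Default confidence thresholds per morphology mode.
CYSTIC_DEFAULT_THRESHOLD = 0.795
BUDDED_DEFAULT_THRESHOLD = 0.836

MaskList = list[tuple[np.ndarray, float]]


@dataclass(frozen=True)
class SegmentationConfig:
    """Detector configuration for one morphology mode.

    ``confidence_threshold`` defaults to the mode-specific constant above
    when left unset.  The global dark-structure threshold is placed
    ``dark_sigmas`` noise standard deviations below the tile's median
    intensity, where the noise sd is estimated structure-free from the
    smoothing residual — on a blank noise tile essentially no pixel
    clears it, which is the blank-tile guard.  ``split_min_distance`` is
    the minimum separation (px) between watershed seeds when splitting
    touching blobs; per blob the effective separation is at least 1.5x
    the blob's inscribed radius so single convex blobs are not split.
    """

    morphology_mode: str = "cystic"
    confidence_threshold: Optional[float] = None
    min_area: int = 50
    smoothing_sigma: float = 2.0
    dark_sigmas: float = 5.0
    split_min_distance: int = 15

    def __post_init__(self) -> None:
        if self.morphology_mode not in ("cystic", "budded"):
            raise OrgquantError(f"unknown morphology mode {self.morphology_mode!r}")
        if self.confidence_threshold is not None and not (
            0.0 <= self.confidence_threshold <= 1.0
        ):
            raise OrgquantError("confidence threshold must lie in [0, 1]")
        if self.min_area < 1:
            raise OrgquantError("min_area must be >= 1")

    @property
    def threshold(self) -> float:
        if self.confidence_threshold is not None:
            return self.confidence_threshold
        return (
            CYSTIC_DEFAULT_THRESHOLD
            if self.morphology_mode == "cystic"
            else BUDDED_DEFAULT_THRESHOLD
        )


def _shape_confidence(mask: np.ndarray, mode: str) -> float:
    if mode == "cystic":
        area = float(mask.sum())
        perim = mask_perimeter(mask, "crofton")
        if perim <= 0:
            return 0.0
        return float(np.clip(4.0 * math.pi * area / perim**2, 0.0, 1.0))
    # budded: solidity
    props = measure.regionprops(mask.astype(np.uint8))[0]
    return float(np.clip(props.solidity, 0.0, 1.0))


def reference_detect(tile_pixels: np.ndarray, config: SegmentationConfig) -> MaskList:
    """Classical bright-field organoid detector for one tile.

    Gaussian smoothing, a robust global threshold on dark structures
    (organoid rims sit well below the background median; bright lumens do
    not disturb it), hole filling to recover lumens, connected
    components, then a distance-transform watershed to split touching
    blobs; components below ``min_area`` are dropped.  Returns
    ``(mask, confidence)`` pairs with pairwise-disjoint masks; a blank
    tile returns an empty list.  Assumes background-majority tiles, as
    produced by sparse organoid cultures.
    """
    px = np.asarray(tile_pixels, dtype=float)
    if px.ndim != 2:
        raise OrgquantError("reference_detect expects a single-channel tile")
    smoothed = ndimage.gaussian_filter(px, config.smoothing_sigma)
    span = smoothed.max() - smoothed.min()
    if span <= 0:
        return []
    # Structure-free noise estimate from the smoothing residual; Gaussian
    # smoothing attenuates white-noise sd by 1 / (2 sqrt(pi) sigma).
    residual = px - smoothed
    sigma_noise = 1.4826 * float(np.median(np.abs(residual - np.median(residual))))
    sigma_smoothed = sigma_noise / (2.0 * math.sqrt(math.pi) * config.smoothing_sigma)
    background = float(np.median(smoothed))
    thr = background - max(config.dark_sigmas * sigma_smoothed, 0.05 * span)
    dark = smoothed < thr
    if not dark.any():
        return []
    filled = ndimage.binary_fill_holes(dark)

    labels = measure.label(filled, connectivity=2)
    distance = ndimage.distance_transform_edt(filled)
    markers = np.zeros_like(labels)
    next_marker = 1
    for region in measure.regionprops(labels, intensity_image=distance):
        r0, c0, r1, c1 = region.bbox
        sub = distance[r0:r1, c0:c1] * region.image
        dmax = sub.max()
        min_dist = max(config.split_min_distance, int(math.ceil(1.5 * dmax)))
        peaks = feature.peak_local_max(sub, min_distance=min_dist, exclude_border=False)
        if len(peaks) == 0:
            peaks = [np.unravel_index(np.argmax(sub), sub.shape)]
        for r, c in peaks:
            markers[r0 + r, c0 + c] = next_marker
            next_marker += 1
    split = _sks.watershed(-distance, markers, mask=filled)

    out: MaskList = []
    for region in measure.regionprops(split):
        if region.area < config.min_area:
            continue
        mask = np.zeros(px.shape, dtype=bool)
        mask[tuple(region.coords.T)] = True
        out.append((mask, _shape_confidence(mask, config.morphology_mode)))
    return out


def make_reference_backend(config: SegmentationConfig) -> Callable[[np.ndarray], MaskList]:
    """Bind the reference detector and its confidence filter into a backend
    callable usable by :func:`orgquant.dedup.mosaic`."""

    def backend(tile_pixels: np.ndarray) -> MaskList:
        return filter_by_confidence(reference_detect(tile_pixels, config), config)

    return backend


def filter_by_confidence(detections: MaskList, config: SegmentationConfig) -> MaskList:
    """Keep detections with confidence >= threshold and area >= min_area,
    preserving order.  Idempotent; raising the threshold never increases
    the survivor count."""
    out = []
    for mask, conf in detections:
        if not (0.0 <= conf <= 1.0):
            raise OrgquantError(f"confidence {conf} outside [0, 1]")
        if conf >= config.threshold and int(np.asarray(mask).sum()) >= config.min_area:
            out.append((mask, conf))
    return out


# ---------------------------------------------------------------------------
# External mask ingestion


def _load_label_tiff(path: Path) -> MaskList:
    labels = tifffile.imread(path)
    if labels.ndim != 2:
        raise OrgquantError(f"label image must be 2-D, got shape {labels.shape}")
    out: MaskList = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        out.append((labels == lab, 1.0))
    return out


def rasterize_polygon(
    xs: Sequence[float], ys: Sequence[float], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize a polygon with the pixel-center-inside rule.

    Pixel (row r, col c) covers [c, c+1) x [r, r+1); it belongs to the
    polygon iff its center (c + 0.5, r + 0.5) lies inside.
    """
    poly = Polygon(zip(xs, ys))
    h, w = shape
    c0 = max(0, int(math.floor(min(xs))))
    c1 = min(w, int(math.ceil(max(xs))) + 1)
    r0 = max(0, int(math.floor(min(ys))))
    r1 = min(h, int(math.ceil(max(ys))) + 1)
    mask = np.zeros(shape, dtype=bool)
    if c0 >= c1 or r0 >= r1:
        return mask
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = shapely.contains_xy(poly, cc.ravel() + 0.5, rr.ravel() + 0.5)
    mask[r0:r1, c0:c1] = inside.reshape(rr.shape)
    return mask


def _load_via_json(path: Path, shape: Optional[tuple[int, int]]) -> MaskList:
    if shape is None:
        raise OrgquantError("loading VIA JSON requires the target image shape")
    with open(path) as fh:
        doc = json.load(fh)
    if "_via_img_metadata" in doc:
        doc = doc["_via_img_metadata"]
    out: MaskList = []
    unknown: list[str] = []
    idx = 0
    for entry in doc.values():
        for region in entry.get("regions", []):
            sa = region["shape_attributes"]
            name = sa.get("name")
            if name not in ("polygon", "polyline"):
                unknown.append(str(name))
                idx += 1
                continue
            xs = sa["all_points_x"]
            ys = sa["all_points_y"]
            poly = Polygon(zip(xs, ys))
            if not poly.is_valid:
                raise OrgquantError(f"region {idx}: self-intersecting polygon")
            out.append((rasterize_polygon(xs, ys, shape), 1.0))
            idx += 1
    if unknown:
        raise OrgquantError(
            f"unsupported VIA region shape types: {sorted(set(unknown))}"
        )
    return out


def load_external_masks(
    path, format: str, image_shape: Optional[tuple[int, int]] = None
) -> MaskList:
    """Load externally produced instance masks.

    ``format`` is ``"label_tiff"`` (0 = background, k = instance id) or
    ``"via_json"`` (VGG Image Annotator project export; polygon/polyline
    regions only, rasterized with the pixel-center rule).  All loaded
    masks carry confidence 1.0.
    """
    p = Path(path)
    if not p.exists():
        raise OrgquantError(f"no such file: {p}")
    if format == "label_tiff":
        return _load_label_tiff(p)
    if format == "via_json":
        return _load_via_json(p, image_shape)
    raise OrgquantError(f"unknown external mask format {format!r}")


# ---------------------------------------------------------------------------
# Deterministic augmentation operators

AUGMENTATIONS = ("hflip", "vflip", "zoom_crop", "blur", "brightness_contrast")


def augment(image: np.ndarray, spec: Sequence[str], seed: int) -> np.ndarray:
    """Apply a list of augmentation operators, deterministically per seed.

    ``hflip``/``vflip`` mirror the image; ``zoom_crop`` crops a random
    sub-window (70-100% of each side) and rescales it back to the original
    size; ``blur`` applies a random Gaussian blur (sigma in [0.5, 2.5]);
    ``brightness_contrast`` applies a random affine intensity map, clamped
    to the input's valid range (dtype range for integers).
    """
    from skimage.transform import resize

    rng = np.random.default_rng(seed)
    out = np.asarray(image)
    orig_dtype = out.dtype
    if np.issubdtype(orig_dtype, np.integer):
        lo, hi = 0.0, float(np.iinfo(orig_dtype).max)
    else:
        lo, hi = float(out.min()), float(out.max())
    out = out.astype(float)
    for name in spec:
        if name == "hflip":
            out = out[:, ::-1]
        elif name == "vflip":
            out = out[::-1, :]
        elif name == "zoom_crop":
            h, w = out.shape[:2]
            fy, fx = rng.uniform(0.7, 1.0, size=2)
            ch, cw = max(1, int(round(h * fy))), max(1, int(round(w * fx)))
            r0 = rng.integers(0, h - ch + 1)
            c0 = rng.integers(0, w - cw + 1)
            out = resize(out[r0 : r0 + ch, c0 : c0 + cw], (h, w), order=1,
                         preserve_range=True, anti_aliasing=False)
        elif name == "blur":
            out = ndimage.gaussian_filter(out, rng.uniform(0.5, 2.5))
        elif name == "brightness_contrast":
            alpha = rng.uniform(0.8, 1.2)
            beta = rng.uniform(-0.1, 0.1) * (hi - lo)
            out = alpha * out + beta
        else:
            raise OrgquantError(
                f"unknown augmentation {name!r}; choose from {AUGMENTATIONS}"
            )
    out = np.clip(out, lo, hi)
    if np.issubdtype(orig_dtype, np.integer):
        out = np.round(out)
    return np.ascontiguousarray(out.astype(orig_dtype))
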