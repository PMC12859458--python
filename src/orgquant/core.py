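"""Domain types and coordinate conventions shared by every pipeline stage.

Coordinate convention: 0-based, ``x`` = column, ``y`` = row, origin at the
top-left of the image.  A tile anchored at ``(ox, oy)`` with size ``T``
covers the half-open region ``[ox, ox + T) x [oy, oy + T)``, which makes
pixel membership in a tile unambiguous.

Instance masks are stored cropped to their bounding box together with a
global ``(x, y)`` offset, so a well with hundreds of detections does not
hold hundreds of full-frame boolean arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from skimage import measure


class OrgquantError(Exception):
    """Base class for errors raised by this package."""


@dataclass(frozen=True)
class TilingConfig:
    """Sliding-window geometry: square tiles of side ``tile_size`` placed
    every ``stride`` pixels.  The defaults (512 / 256) give a half-tile
    overlap so every object far from the image border lands at least once
    in the central half of some tile."""

    tile_size: int = 512
    stride: int = 256

    def __post_init__(self) -> None:
        if not (1 <= self.stride <= self.tile_size):
            raise OrgquantError(
                f"stride must satisfy 1 <= stride <= tile_size, "
                f"got stride={self.stride}, tile_size={self.tile_size}"
            )


@dataclass(frozen=True)
class DedupConfig:
    """Duplicate predicate configuration for cross-tile suppression.

    Two instances from different, overlapping tiles are duplicates when the
    area of their mask intersection exceeds ``overlap_threshold`` as a
    fraction of at least one ("max" rule) or both ("min" rule) of the two
    instance areas.  The comparison is strict (> threshold).
    """

    overlap_threshold: float = 0.30
    rule: str = "max"  # "max": either ratio suffices; "min": both must exceed

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_threshold < 1.0):
            raise OrgquantError(
                f"overlap_threshold must lie in (0, 1), got {self.overlap_threshold}"
            )
        if self.rule not in ("max", "min"):
            raise OrgquantError(f"unknown duplicate rule {self.rule!r}")


@dataclass
class WellImage:
    """A single-channel whole-well image.

    pixel_size, when given, is the physical edge length of one pixel in
    micrometres and is only carried through to reports.
    """

    pixels: np.ndarray
    pixel_size: Optional[float] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 3:
            # Multi-channel input is reduced to one channel by luminance
            # average before any processing.
            px = px.mean(axis=2)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise OrgquantError(f"well image must be 2-D and non-empty, got shape {px.shape}")
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise OrgquantError("well image intensities must be finite and non-negative")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Tile:
    """One T x T window cut from a well image, anchored at a global origin."""

    origin_x: int
    origin_y: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.origin_x < 0 or self.origin_y < 0:
            raise OrgquantError("tile origin coordinates must be >= 0")
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise OrgquantError(f"tile pixels must be square 2-D, got {self.pixels.shape}")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def origin(self) -> tuple[int, int]:
        return (self.origin_x, self.origin_y)


def pixel_edge_perimeter(mask: np.ndarray) -> float:
    """Exact boundary length of a binary mask counted as exposed pixel edges.

    Every unit edge between a foreground pixel and background (or the array
    border) contributes 1.  This over-estimates smooth contours (a disc of
    radius r yields ~8r, not 2*pi*r) but is exactly testable.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return 0.0
    p = np.pad(m, 1)
    edges = 0
    for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        edges += int(np.logical_and(p, ~np.roll(p, shift, axis=ax)).sum())
    return float(edges)


def crofton_perimeter(mask: np.ndarray) -> float:
    """Crofton-style multi-directional boundary-length estimate (4 directions).

    Reduces the square-vs-diagonal bias of edge counting; the default
    estimator for instance perimeters.
    """
    m = np.pad(np.asarray(mask, dtype=bool), 1)
    return float(measure.perimeter_crofton(m, directions=4))


_PERIMETER_ESTIMATORS = {
    "crofton": crofton_perimeter,
    "edges": pixel_edge_perimeter,
}


def mask_perimeter(mask: np.ndarray, method: str = "crofton") -> float:
    """Boundary length of a binary mask under the chosen estimator."""
    try:
        return _PERIMETER_ESTIMATORS[method](mask)
    except KeyError:
        raise OrgquantError(
            f"unknown perimeter method {method!r}; choose from {sorted(_PERIMETER_ESTIMATORS)}"
        ) from None


@dataclass
class OrganoidInstance:
    """One detected organoid.

    ``mask`` is cropped to the instance's bounding box; ``offset`` is the
    global (x, y) position of the mask's top-left corner.  ``centroid`` is
    the (x, y) mean of the mask's pixel coordinates in global coordinates.
    """

    id: int
    mask: np.ndarray
    offset: tuple[int, int]
    area: int
    perimeter: float
    centroid: tuple[float, float]
    confidence: float = 1.0
    source_tile: Optional[tuple[int, int]] = None

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """Half-open global bounding box (x0, y0, x1, y1)."""
        x0, y0 = self.offset
        h, w = self.mask.shape
        return (x0, y0, x0 + w, y0 + h)

    def full_mask(self, height: int, width: int) -> np.ndarray:
        """Render the mask into a full-frame boolean array."""
        out = np.zeros((height, width), dtype=bool)
        x0, y0, x1, y1 = self.bbox
        out[y0:y1, x0:x1] = self.mask
        return out

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Global (ys, xs) of all mask pixels."""
        ys, xs = np.nonzero(self.mask)
        return ys + self.offset[1], xs + self.offset[0]

    def intersection_area(self, other: "OrganoidInstance") -> int:
        """Pixel count of the mask intersection, via bounding-box clipping."""
        ax0, ay0, ax1, ay1 = self.bbox
        bx0, by0, bx1, by1 = other.bbox
        x0, y0 = max(ax0, bx0), max(ay0, by0)
        x1, y1 = min(ax1, bx1), min(ay1, by1)
        if x0 >= x1 or y0 >= y1:
            return 0
        a = self.mask[y0 - ay0 : y1 - ay0, x0 - ax0 : x1 - ax0]
        b = other.mask[y0 - by0 : y1 - by0, x0 - bx0 : x1 - bx0]
        return int(np.logical_and(a, b).sum())

    def translated(self, dx: int, dy: int) -> "OrganoidInstance":
        cx, cy = self.centroid
        return replace(
            self,
            offset=(self.offset[0] + dx, self.offset[1] + dy),
            centroid=(cx + dx, cy + dy),
        )


def _crop_to_bbox(mask: np.ndarray) -> tuple[np.ndarray, int, int]:
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    return np.ascontiguousarray(mask[y0:y1, x0:x1]), int(x0), int(y0)


def instance_from_mask(
    mask: np.ndarray,
    id: int,
    confidence: float = 1.0,
    offset: tuple[int, int] = (0, 0),
    source_tile: Optional[tuple[int, int]] = None,
    perimeter_method: str = "crofton",
    check_connectivity: bool = True,
) -> OrganoidInstance:
    """Build an :class:`OrganoidInstance` from a binary mask.

    ``offset`` positions the given mask array in global coordinates.  The
    mask must be non-empty and, unless ``check_connectivity`` is disabled,
    a single 8-connected component.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise OrgquantError("cannot build an instance from an empty mask")
    if check_connectivity:
        n_comp = int(measure.label(m, connectivity=2).max())
        if n_comp != 1:
            raise OrgquantError(
                f"instance mask must be a single connected component, found {n_comp}"
            )
    cropped, bx, by = _crop_to_bbox(m)
    ys, xs = np.nonzero(cropped)
    x0 = offset[0] + bx
    y0 = offset[1] + by
    return OrganoidInstance(
        id=int(id),
        mask=cropped,
        offset=(x0, y0),
        area=int(cropped.sum()),
        perimeter=mask_perimeter(cropped, perimeter_method),
        centroid=(float(xs.mean()) + x0, float(ys.mean()) + y0),
        confidence=float(confidence),
        source_tile=source_tile,
    )


@dataclass
class DetectionSet:
    """All organoid instances detected in one well, in global coordinates."""

    instances: list[OrganoidInstance] = field(default_factory=list)
    image_width: int = 0
    image_height: int = 0
    deduplicated: bool = False

    def __post_init__(self) -> None:
        ids = [inst.id for inst in self.instances]
        if len(ids) != len(set(ids)):
            raise OrgquantError("instance ids must be unique within a detection set")

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)

    def get(self, instance_id: int) -> OrganoidInstance:
        for inst in self.instances:
            if inst.id == instance_id:
                return inst
        raise OrgquantError(f"no instance with id {instance_id}")

    def areas(self) -> np.ndarray:
        return np.array([inst.area for inst in self.instances], dtype=int)


def renumber_raster(
    instances: Sequence[OrganoidInstance],
) -> list[OrganoidInstance]:
    """Assign ids 1..n in raster order of centroid (top-to-bottom, then
    left-to-right), breaking exact ties by the previous id."""
    ordered = sorted(instances, key=lambda i: (i.centroid[1], i.centroid[0], i.id))
    return [replace(inst, id=k) for k, inst in enumerate(ordered, start=1)]
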