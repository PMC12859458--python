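"""Sliding-window tiling of large well images.

A well image (typically 2,000-5,000 px per side) is cut into overlapping
square tiles — by default 512 px tiles every 256 px, i.e. a half-tile
stride — so that every organoid sufficiently far from the image border
appears at least once in the central half of a tile rather than clipped at
a tile edge.  Per-tile detections are later reprojected into global image
coordinates by translating them by the tile origin.

Edge handling: along each axis the origins are the multiples of the stride
that keep the tile fully inside the image; when the image dimension is not
stride-aligned the final origin is clamped to ``dim - T`` (duplicating some
coverage) instead of padding the image, so tiles never contain synthetic
border pixels.  Images smaller than one tile are the only padded case: they
are zero-padded up to T and the padding is stripped on reprojection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    OrganoidInstance,
    OrgquantError,
    Tile,
    TilingConfig,
    WellImage,
    instance_from_mask,
)


@dataclass
class TileSet:
    """The tiles cut from one well image, raster-ordered (y-major)."""

    tiles: list[Tile]
    config: TilingConfig
    image_width: int
    image_height: int
    padded_width: int
    padded_height: int

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)

    def origins(self) -> list[tuple[int, int]]:
        return [t.origin for t in self.tiles]


def _axis_origins(dim: int, tile: int, stride: int) -> list[int]:
    if dim <= tile:
        return [0]
    last = dim - tile
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)
    return origins


def tile_origins(
    width: int, height: int, config: TilingConfig = TilingConfig()
) -> list[tuple[int, int]]:
    """Global (origin_x, origin_y) of every tile, in raster order.

    Per axis the origins are {0, s, 2s, ...} up to ``dim - T``, with
    ``dim - T`` appended when the dimension is not stride-aligned; an image
    smaller than one tile gets the single origin 0.
    """
    if width < 1 or height < 1:
        raise OrgquantError(f"image dimensions must be positive, got {width}x{height}")
    xs = _axis_origins(width, config.tile_size, config.stride)
    ys = _axis_origins(height, config.tile_size, config.stride)
    return [(x, y) for y in ys for x in xs]


def cut_tiles(image: WellImage, config: TilingConfig = TilingConfig()) -> TileSet:
    """Cut a well image into overlapping T x T tiles.

    Sub-tile images are zero-padded on the right/bottom up to T; the
    padded dimensions are recorded so reprojection can strip the padding.
    """
    T = config.tile_size
    px = image.pixels
    pad_h = max(image.height, T)
    pad_w = max(image.width, T)
    if (pad_h, pad_w) != px.shape:
        padded = np.zeros((pad_h, pad_w), dtype=px.dtype)
        padded[: image.height, : image.width] = px
        px = padded
    tiles = [
        Tile(origin_x=ox, origin_y=oy, pixels=px[oy : oy + T, ox : ox + T])
        for ox, oy in tile_origins(image.width, image.height, config)
    ]
    return TileSet(
        tiles=tiles,
        config=config,
        image_width=image.width,
        image_height=image.height,
        padded_width=pad_w,
        padded_height=pad_h,
    )


def to_global(
    instance: OrganoidInstance,
    tile: Tile,
    image_width: Optional[int] = None,
    image_height: Optional[int] = None,
) -> Optional[OrganoidInstance]:
    """Reproject a tile-local instance into global image coordinates.

    The mask is translated by the tile origin; pixels that fall outside the
    real image (possible only for padded sub-tile images) are cropped off
    and area/perimeter/centroid are recomputed.  Returns ``None`` when the
    instance lies entirely in padding (a discard, not an error).
    """
    T = tile.size
    x0, y0, x1, y1 = instance.bbox
    if x0 < 0 or y0 < 0 or x1 > T or y1 > T:
        raise OrgquantError(
            f"instance bbox {instance.bbox} exceeds tile extent [0, {T})^2"
        )
    gx = tile.origin_x + x0
    gy = tile.origin_y + y0
    mask = instance.mask
    if image_width is not None and image_height is not None:
        # Crop away any part that lies in right/bottom zero-padding.
        keep_w = max(0, min(mask.shape[1], image_width - gx))
        keep_h = max(0, min(mask.shape[0], image_height - gy))
        mask = mask[:keep_h, :keep_w]
        if not mask.any():
            return None
    return instance_from_mask(
        mask,
        id=instance.id,
        confidence=instance.confidence,
        offset=(gx, gy),
        source_tile=tile.origin,
        check_connectivity=False,
    )


def adjacent_tiles(tile: Tile, tileset: TileSet) -> list[Tile]:
    """All *other* tiles of the set whose half-open regions intersect the
    query tile's region."""
    if tile.origin not in {t.origin for t in tileset.tiles}:
        raise OrgquantError(f"tile with origin {tile.origin} is not in the tile set")
    T = tileset.config.tile_size
    out = []
    for other in tileset.tiles:
        if other.origin == tile.origin:
            continue
        if (
            tile.origin_x < other.origin_x + T
            and other.origin_x < tile.origin_x + T
            and tile.origin_y < other.origin_y + T
            and other.origin_y < tile.origin_y + T
        ):
            out.append(other)
    return out
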