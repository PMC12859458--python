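"""Cross-tile duplicate suppression (modified non-maximum suppression).

Tiling with a half-tile stride means one physical organoid can be detected
in several overlapping tiles.  Duplicates are found by comparing every
instance in a tile against the instances of tiles whose regions overlap
it: two instances are the same organoid when their mask intersection
exceeds 30% (configurable) of at least one of the two instance areas.  The
"at least one" (max-ratio) rule matters: a small fragment clipped at a
tile edge overlaps its full-size counterpart by far more than 30% of its
own area while possibly far less than 30% of the larger one, and removing
exactly such fragments is the point of the procedure.

Suppression is formulated over connected components of the duplicate
graph: within each component only the largest-area instance survives.
This is order-free (independent of tile processing order) and, for the
fragments-of-one-object graphs the tiling produces, reaches the same fixed
point as repeatedly deleting the smaller member of any duplicate pair.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    DedupConfig,
    DetectionSet,
    OrganoidInstance,
    OrgquantError,
    TilingConfig,
    WellImage,
    renumber_raster,
)
from .tiling import TileSet, cut_tiles, to_global


@dataclass(frozen=True)
class DuplicatePair:
    """Two instances from overlapping tiles flagged as the same organoid.

    ratio_a / ratio_b are the intersection area as a fraction of each
    instance's own area.
    """

    id_a: int
    id_b: int
    overlap_area: int
    ratio_a: float
    ratio_b: float


def _regions_overlap(a: tuple[int, int], b: tuple[int, int], T: int) -> bool:
    return a[0] < b[0] + T and b[0] < a[0] + T and a[1] < b[1] + T and b[1] < a[1] + T


def is_duplicate(ratio_a: float, ratio_b: float, config: DedupConfig) -> bool:
    """The duplicate predicate: strict comparison against the threshold."""
    combined = max(ratio_a, ratio_b) if config.rule == "max" else min(ratio_a, ratio_b)
    return combined > config.overlap_threshold


def find_duplicates(
    dets: DetectionSet,
    tileset: TileSet,
    config: DedupConfig = DedupConfig(),
) -> list[DuplicatePair]:
    """All unordered instance pairs from overlapping tiles that satisfy the
    duplicate predicate.  Instances from the same tile are never duplicates."""
    T = tileset.config.tile_size
    valid_origins = {t.origin for t in tileset.tiles}
    by_tile: dict[tuple[int, int], list[OrganoidInstance]] = {}
    for inst in dets.instances:
        if inst.source_tile is None:
            raise OrgquantError(f"instance {inst.id} has no source_tile")
        if inst.source_tile not in valid_origins:
            raise OrgquantError(
                f"instance {inst.id} has source_tile {inst.source_tile} "
                f"not present in the tile set"
            )
        by_tile.setdefault(inst.source_tile, []).append(inst)

    pairs: list[DuplicatePair] = []
    origins = sorted(by_tile)
    for i, oa in enumerate(origins):
        for ob in origins[i + 1 :]:
            if not _regions_overlap(oa, ob, T):
                continue
            for a in by_tile[oa]:
                for b in by_tile[ob]:
                    inter = a.intersection_area(b)
                    if inter == 0:
                        continue
                    ra = inter / a.area
                    rb = inter / b.area
                    if is_duplicate(ra, rb, config):
                        pairs.append(
                            DuplicatePair(
                                id_a=a.id, id_b=b.id,
                                overlap_area=inter, ratio_a=ra, ratio_b=rb,
                            )
                        )
    return pairs


class _UnionFind:
    def __init__(self, keys):
        self.parent = {k: k for k in keys}

    def find(self, k):
        while self.parent[k] != k:
            self.parent[k] = self.parent[self.parent[k]]
            k = self.parent[k]
        return k

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _keep_key(inst: OrganoidInstance) -> tuple:
    # Largest area wins; ties broken toward the smaller (origin_y, origin_x, id).
    tile = inst.source_tile if inst.source_tile is not None else (0, 0)
    return (-inst.area, tile[1], tile[0], inst.id)


def suppress(dets: DetectionSet, pairs: list[DuplicatePair]) -> DetectionSet:
    """Retain one instance per duplicate-graph component (the largest by
    area) and renumber survivors 1..n in raster order of centroid."""
    uf = _UnionFind([inst.id for inst in dets.instances])
    known = set(uf.parent)
    for p in pairs:
        if p.id_a not in known or p.id_b not in known:
            raise OrgquantError(f"pair ({p.id_a}, {p.id_b}) references unknown instances")
        uf.union(p.id_a, p.id_b)

    best: dict[int, OrganoidInstance] = {}
    for inst in dets.instances:
        root = uf.find(inst.id)
        cur = best.get(root)
        if cur is None or _keep_key(inst) < _keep_key(cur):
            best[root] = inst
    survivors = renumber_raster(list(best.values()))
    return DetectionSet(
        instances=survivors,
        image_width=dets.image_width,
        image_height=dets.image_height,
        deduplicated=True,
    )


def mosaic(
    image: WellImage,
    backend,
    tiling: TilingConfig = TilingConfig(),
    dedup: DedupConfig = DedupConfig(),
) -> DetectionSet:
    """Run the full tiled-detection pipeline on one well image.

    ``backend`` is any callable mapping a T x T single-channel pixel array
    to a list of ``(mask, confidence)`` in tile coordinates.  Tiles are
    segmented independently, detections are reprojected into global
    coordinates, duplicates across overlapping tiles are found and
    suppressed, and the surviving instances are renumbered.
    """
    from .core import instance_from_mask  # local import to avoid cycle noise

    tileset = cut_tiles(image, tiling)
    instances: list[OrganoidInstance] = []
    next_id = 1
    for tile in tileset:
        try:
            outputs = backend(tile.pixels)
        except Exception as exc:  # noqa: BLE001 - tile context is the point
            raise OrgquantError(
                f"segmentation backend failed on tile at origin {tile.origin}: {exc}"
            ) from exc
        for mask, confidence in outputs:
            local = instance_from_mask(
                mask, id=next_id, confidence=confidence, check_connectivity=False
            )
            glob = to_global(local, tile, image.width, image.height)
            if glob is None:
                continue  # instance lay entirely in padding
            instances.append(glob)
            next_id += 1
    dets = DetectionSet(
        instances=instances,
        image_width=image.width,
        image_height=image.height,
        deduplicated=False,
    )
    pairs = find_duplicates(dets, tileset, dedup)
    return suppress(dets, pairs)
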