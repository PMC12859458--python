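"""Shared helpers for duplicate-suppression tests: random blob layouts,
per-tile clipping, and the independent iterative-deletion oracle."""

import numpy as np

from orgquant.core import DedupConfig, DetectionSet, TilingConfig, WellImage, instance_from_mask
from orgquant.dedup import _keep_key, is_duplicate
from orgquant.tiling import cut_tiles


def random_disjoint_discs(rng, n_max=50, width=1024, height=1024, r_lo=8, r_hi=40):
    """Up to n_max non-overlapping discs: (cx, cy, r) triples."""
    discs = []
    n = int(rng.integers(1, n_max + 1))
    for _ in range(n):
        for _attempt in range(50):
            r = int(rng.integers(r_lo, r_hi + 1))
            cx = int(rng.integers(r, width - r))
            cy = int(rng.integers(r, height - r))
            if all((cx - x) ** 2 + (cy - y) ** 2 > (r + q + 2) ** 2 for x, y, q in discs):
                discs.append((cx, cy, r))
                break
    return discs


def disc_local_mask(r):
    side = 2 * r + 1
    yy, xx = np.mgrid[:side, :side]
    return (yy - r) ** 2 + (xx - r) ** 2 <= r**2


def clip_blobs_to_tiles(discs, width=1024, height=1024, config=TilingConfig()):
    """Simulate per-tile detections: every blob clipped to every tile whose
    region it intersects, as global instances tagged with the source tile."""
    tileset = cut_tiles(WellImage(pixels=np.zeros((height, width))), config)
    T = config.tile_size
    instances = []
    next_id = 1
    for tile in tileset:
        ox, oy = tile.origin
        for cx, cy, r in discs:
            local = disc_local_mask(r)
            x0, y0 = cx - r, cy - r
            ix0, iy0 = max(x0, ox), max(y0, oy)
            ix1 = min(x0 + local.shape[1], ox + T)
            iy1 = min(y0 + local.shape[0], oy + T)
            if ix0 >= ix1 or iy0 >= iy1:
                continue
            clipped = local[iy0 - y0 : iy1 - y0, ix0 - x0 : ix1 - x0]
            if not clipped.any():
                continue
            instances.append(
                instance_from_mask(
                    clipped, id=next_id, offset=(ix0, iy0),
                    source_tile=tile.origin, check_connectivity=False,
                )
            )
            next_id += 1
    dets = DetectionSet(instances=instances, image_width=width, image_height=height)
    return dets, tileset


def _window_intersection(a, b):
    """Pixel overlap of two instances, recomputed from scratch on the
    common bounding-box window."""
    ax0, ay0, ax1, ay1 = a.bbox
    bx0, by0, bx1, by1 = b.bbox
    x0, x1 = max(ax0, bx0), min(ax1, bx1)
    y0, y1 = max(ay0, by0), min(ay1, by1)
    if x0 >= x1 or y0 >= y1:
        return 0
    wa = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    wb = np.zeros_like(wa)
    ys, xs = np.nonzero(a.mask)
    sel = (
        (ys + ay0 >= y0) & (ys + ay0 < y1) & (xs + ax0 >= x0) & (xs + ax0 < x1)
    )
    wa[ys[sel] + ay0 - y0, xs[sel] + ax0 - x0] = True
    ys, xs = np.nonzero(b.mask)
    sel = (
        (ys + by0 >= y0) & (ys + by0 < y1) & (xs + bx0 >= x0) & (xs + bx0 < x1)
    )
    wb[ys[sel] + by0 - y0, xs[sel] + bx0 - x0] = True
    return int(np.logical_and(wa, wb).sum())


def brute_force_pairs(instances, tile_size, config=DedupConfig()):
    """All-pairs duplicate search restricted to overlapping source tiles,
    written independently of find_duplicates."""
    pairs = set()
    for i, a in enumerate(instances):
        for b in instances[i + 1 :]:
            if a.source_tile == b.source_tile:
                continue
            ax, ay = a.source_tile
            bx, by = b.source_tile
            T = tile_size
            if not (ax < bx + T and bx < ax + T and ay < by + T and by < ay + T):
                continue
            inter = _window_intersection(a, b)
            if inter == 0:
                continue
            if is_duplicate(inter / a.area, inter / b.area, config):
                pairs.add(frozenset((a.id, b.id)))
    return pairs


def iterative_deletion_oracle(instances, tile_size, config=DedupConfig()):
    """Repeatedly delete the smallest-area instance involved in any
    duplicate pair (ties resolved opposite the keep preference) until no
    pair remains; returns the surviving instances."""
    current = list(instances)
    while True:
        pairs = brute_force_pairs(current, tile_size, config)
        if not pairs:
            return current
        involved = {i for p in pairs for i in p}
        by_id = {inst.id: inst for inst in current}
        victim = max((by_id[i] for i in involved), key=_keep_key)
        current = [inst for inst in current if inst.id != victim.id]


def mask_signature(inst):
    """Hashable identity of an instance's pixels, ignoring its id."""
    return (inst.offset, inst.mask.shape, inst.mask.tobytes())
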