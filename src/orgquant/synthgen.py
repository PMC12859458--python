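"""Seeded generator of synthetic bright-field-like wells with ground truth.

Each synthetic well emulates what the pipeline sees in practice: tens to
hundreds of roughly elliptical organoids with log-normally distributed
areas scattered without overlap across a large grayscale image, each
rendered as a dark rim around a bright lumen on a noisy mid-grey
background (the characteristic bright-field appearance at low
magnification).  Budded organoids get 2-5 lobed protrusions on the base
ellipse.  Every organoid's true mask is kept, and its "real" nuclei count
is drawn from the same log-linear law the count model fits:

    N = max(1, round(exp(b0 + bA * ln A + bS * S + bM * M + eps))),
    eps ~ Normal(0, sigma_eps)

The default law (b0 = 0.5, bA = 1.0, bS = -0.2, bM = -0.3,
sigma_eps = 0.2, natural-log space) is a synthetic, plausible setting —
no published coefficients exist for real organoids — chosen so counts
scale essentially linearly with area and tumor/budded organoids are
somewhat denser per pixel of area, mirroring the reported direction of
those covariates.

What the generator does NOT emulate: Matrigel texture, debris, touching
or overlapping organoids, uneven illumination, and out-of-focus blur
gradients.  Tests passing on this material therefore validate the
geometry and bookkeeping of the pipeline, not detector robustness on
real wells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .core import (
    DetectionSet,
    OrganoidInstance,
    OrgquantError,
    WellImage,
    instance_from_mask,
)
from .cellcount import CountRecord


@dataclass(frozen=True)
class CountLaw:
    """Log-linear cell-count law in natural-log space."""

    beta0: float = 0.5
    beta_area: float = 1.0
    beta_sample: float = -0.2
    beta_morph: float = -0.3
    sigma: float = 0.2


@dataclass(frozen=True)
class Appearance:
    """Rendering parameters on an 8-bit intensity scale."""

    background: float = 128.0
    ring_contrast: float = 70.0  # rim darkening below background
    lumen_brightness: float = 40.0  # lumen brightening above background
    noise_sd: float = 6.0
    blur_sd: float = 1.2
    rim_fraction: float = 0.15  # rim width as a fraction of the mean radius


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic well.

    Defaults give a 2048 px well (the low end of real whole-well images)
    with ~80 organoids whose areas are log-normal with median e^8 ~ 3000
    px (diameter ~60 px at the 4x-magnification scale the pipeline
    targets).
    """

    width: int = 2048
    height: int = 2048
    n_organoids: int = 80
    area_log_mean: float = 8.0
    area_log_sd: float = 0.5
    morphology: str = "cystic"  # "cystic" or "budded"
    sample_type: str = "healthy"  # "healthy" or "tumor"
    count_law: CountLaw = field(default_factory=CountLaw)
    appearance: Appearance = field(default_factory=Appearance)
    seed: int = 0
    min_gap: int = 4  # minimum pixel gap between organoid bounding boxes
    max_attempts_per_organoid: int = 200

    def __post_init__(self) -> None:
        if self.n_organoids < 0:
            raise OrgquantError("n_organoids must be >= 0")
        if self.width < 1 or self.height < 1:
            raise OrgquantError("well dimensions must be positive")
        if self.area_log_sd <= 0 or self.count_law.sigma < 0:
            raise OrgquantError("scale parameters must be positive")
        if self.morphology not in ("cystic", "budded"):
            raise OrgquantError(f"unknown morphology {self.morphology!r}")
        if self.sample_type not in ("healthy", "tumor"):
            raise OrgquantError(f"unknown sample type {self.sample_type!r}")


@dataclass
class SynthWell:
    """One generated well: image, pixel-perfect truth, and count records."""

    image: WellImage
    truth: DetectionSet
    counts: list[CountRecord]
    achieved_n: int


def _ellipse_mask(area: float, aspect: float, angle: float) -> np.ndarray:
    """Local boolean mask of a rotated ellipse of roughly the given area."""
    # pi * a * b = area with b = aspect * a
    a = math.sqrt(area / (math.pi * aspect))
    b = aspect * a
    half = int(math.ceil(max(a, b))) + 2
    side = 2 * half + 1
    rr, cc = skdraw.ellipse(half, half, b, a, shape=(side, side), rotation=angle)
    mask = np.zeros((side, side), dtype=bool)
    mask[rr, cc] = True
    return mask


def _budded_mask(area: float, aspect: float, angle: float, rng) -> np.ndarray:
    """Base ellipse plus 2-5 lobes centred on its boundary."""
    base_area = 0.7 * area
    a = math.sqrt(base_area / (math.pi * aspect))
    b = aspect * a
    n_lobes = int(rng.integers(2, 6))
    lobe_r = math.sqrt((0.3 * area) / (n_lobes * math.pi))
    half = int(math.ceil(max(a, b) + 2 * lobe_r)) + 2
    side = 2 * half + 1
    mask = np.zeros((side, side), dtype=bool)
    rr, cc = skdraw.ellipse(half, half, b, a, shape=(side, side), rotation=angle)
    mask[rr, cc] = True
    for theta in rng.uniform(0, 2 * math.pi, size=n_lobes):
        # boundary point of the (unrotated-frame) ellipse, then rotate
        ex, ey = a * math.cos(theta), b * math.sin(theta)
        lx = ex * math.cos(angle) - ey * math.sin(angle)
        ly = ex * math.sin(angle) + ey * math.cos(angle)
        rr, cc = skdraw.disk(
            (half + ly, half + lx), lobe_r, shape=(side, side)
        )
        mask[rr, cc] = True
    return mask


def _crop_local(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return mask[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]


def _draw_count(law: CountLaw, area: int, s: int, m: int, rng) -> int:
    eps = rng.normal(0.0, law.sigma) if law.sigma > 0 else 0.0
    log_n = law.beta0 + law.beta_area * math.log(area) + law.beta_sample * s \
        + law.beta_morph * m + eps
    return max(1, int(round(math.exp(log_n))))


def generate_well(config: SynthConfig, render: bool = True) -> SynthWell:
    """Generate one synthetic well, deterministically per seed.

    Organoid shapes are placed by rejection sampling with a minimum
    bounding-box gap so truth masks are pairwise disjoint; placement
    gives up after a bounded number of attempts per organoid and raises
    if fewer than 90% of the requested organoids fit.  With
    ``render=False`` the image is a flat, noise-free background — a fast
    path when only geometry and counts are needed.
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.height, config.width
    s_code = 1 if config.sample_type == "tumor" else 0
    m_code = 1 if config.morphology == "budded" else 0

    areas = np.exp(rng.normal(config.area_log_mean, config.area_log_sd,
                              size=config.n_organoids))
    placed: list[tuple[np.ndarray, int, int]] = []  # (local mask, x0, y0)
    boxes: list[tuple[int, int, int, int]] = []
    gap = config.min_gap
    for target_area in areas:
        aspect = rng.uniform(0.6, 0.95)
        angle = rng.uniform(0, math.pi)
        if config.morphology == "budded":
            local = _budded_mask(float(target_area), aspect, angle, rng)
        else:
            local = _ellipse_mask(float(target_area), aspect, angle)
        local = _crop_local(local)
        mh, mw = local.shape
        if mh >= H or mw >= W:
            continue  # cannot fit this organoid at all
        for _ in range(config.max_attempts_per_organoid):
            x0 = int(rng.integers(0, W - mw))
            y0 = int(rng.integers(0, H - mh))
            x1, y1 = x0 + mw, y0 + mh
            ok = all(
                x0 - gap >= bx1 or bx0 >= x1 + gap or y0 - gap >= by1 or by0 >= y1 + gap
                for bx0, by0, bx1, by1 in boxes
            )
            if ok:
                placed.append((local, x0, y0))
                boxes.append((x0, y0, x1, y1))
                break

    achieved = len(placed)
    if config.n_organoids > 0 and achieved < 0.9 * config.n_organoids:
        raise OrgquantError(
            f"infeasible packing: placed only {achieved} of "
            f"{config.n_organoids} requested organoids"
        )

    ap = config.appearance
    canvas = np.full((H, W), ap.background, dtype=float)
    instances: list[OrganoidInstance] = []
    counts: list[CountRecord] = []
    well_id = f"synth-{config.seed}"
    for k, (local, x0, y0) in enumerate(placed, start=1):
        inst = instance_from_mask(
            local, id=k, confidence=1.0, offset=(x0, y0), check_connectivity=False
        )
        instances.append(inst)
        n = _draw_count(config.count_law, inst.area, s_code, m_code, rng)
        counts.append(
            CountRecord(
                area=inst.area,
                perimeter=inst.perimeter,
                sample_type=s_code,
                morphology=m_code,
                real_nuclei=n,
                well_id=well_id,
                organoid_id=k,
            )
        )
        if render:
            mean_radius = math.sqrt(inst.area / math.pi)
            rim_w = max(2, int(round(ap.rim_fraction * mean_radius)))
            interior = ndimage.binary_erosion(local, iterations=rim_w)
            rim = local & ~interior
            region = canvas[y0 : y0 + local.shape[0], x0 : x0 + local.shape[1]]
            region[rim] = ap.background - ap.ring_contrast
            region[interior] = ap.background + ap.lumen_brightness

    if render:
        if ap.blur_sd > 0:
            canvas = ndimage.gaussian_filter(canvas, ap.blur_sd)
        if ap.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, ap.noise_sd, size=canvas.shape)
    pixels = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

    truth = DetectionSet(
        instances=instances, image_width=W, image_height=H, deduplicated=True
    )
    return SynthWell(
        image=WellImage(pixels=pixels, source_id=well_id),
        truth=truth,
        counts=counts,
        achieved_n=achieved,
    )


def generate_training_table(config: SynthConfig, n_wells: int) -> list[CountRecord]:
    """Count records concatenated over ``n_wells`` independent wells.

    Well k uses a seed derived deterministically from ``config.seed``;
    organoid ids restart per well, well ids are unique.  Uses the
    no-render fast path since only geometry and counts are needed.
    """
    if n_wells < 1:
        raise OrgquantError("n_wells must be >= 1")
    records: list[CountRecord] = []
    for k in range(n_wells):
        sub = replace(config, seed=int(config.seed) + 10_000 * (k + 1))
        well = generate_well(sub, render=False)
        records.extend(well.counts)
    return records


class TruthBackend:
    """Oracle backend over a ground-truth detection set.

    ``mosaic`` calls backends with bare pixel arrays, so this object is
    primed with the tiling layout: calls are answered in raster-tile
    order, clipping every truth mask to the current tile's region.
    """

    def __init__(self, truth: DetectionSet, tile_origins: list[tuple[int, int]],
                 tile_size: int):
        self._truth = truth
        self._origins = list(tile_origins)
        self._size = tile_size
        self._cursor = 0

    def reset(self) -> None:
        self._cursor = 0

    def __call__(self, tile_pixels: np.ndarray) -> list[tuple[np.ndarray, float]]:
        if self._cursor >= len(self._origins):
            raise OrgquantError("oracle backend called more times than there are tiles")
        ox, oy = self._origins[self._cursor]
        self._cursor += 1
        T = self._size
        out = []
        for inst in self._truth.instances:
            x0, y0, x1, y1 = inst.bbox
            ix0, iy0 = max(x0, ox), max(y0, oy)
            ix1, iy1 = min(x1, ox + T), min(y1, oy + T)
            if ix0 >= ix1 or iy0 >= iy1:
                continue
            clipped = inst.mask[iy0 - y0 : iy1 - y0, ix0 - x0 : ix1 - x0]
            if not clipped.any():
                continue
            tile_mask = np.zeros((T, T), dtype=bool)
            tile_mask[iy0 - oy : iy1 - oy, ix0 - ox : ix1 - ox] = clipped
            out.append((tile_mask, 1.0))
        return out
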