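"""Synthetic immunohistochemistry slide generator with full ground truth.

Real scanned tumour sections come without pixel-level truth: nobody knows the
exact stained-area fraction or the exact set of vessel outlines.  This module
provides a forward model that emulates the statistical structure whole-slide
quantification has to cope with — a red chromogen (fast-red-like) on a
hematoxylin counterstain, vessels rendered as elongated elliptical rings and
immunoreactive cells as disks, placed either by a homogeneous Poisson process
("scattered" marker distribution) or by a Thomas-type parent–offspring cluster
process ("hot-spot" distribution) — and returns, next to the rendered RGB
raster, the exact ground truth the downstream estimators are judged against.

The RGB image is formed by Beer–Lambert composition: per-pixel optical density
``OD = c_counter * v_counter + c_chrom * v_chrom`` (unit stain vectors in OD
space), transmitted intensity ``I = I0 * 10**(-OD)``, plus small additive
sensor noise, quantized to 8 bit.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import shapely
import shapely.affinity
from shapely.geometry import Point, Polygon

from ._raster import mm_per_px, rasterize_polygon

__all__ = [
    "SpatialPatternParams",
    "StainModelParams",
    "RenderParams",
    "SlideImage",
    "GroundTruth",
    "MarkerCohortSpec",
    "sample_point_pattern",
    "render_slide",
    "generate_cohort",
    "iter_cohort",
    "cohort_manifest",
    "vessel_marker_spec",
    "nuclear_cell_marker_spec",
    "surface_cell_marker_spec",
    "expected_vessel_area_mm2",
    "slide_seed",
    "default_stain_model",
]

#: raster size guard for :func:`render_slide` (pixels)
DEFAULT_PIXEL_BUDGET = 20_000_000

# Optical-density stain vectors (unit norm).  Hematoxylin from the standard
# color-deconvolution literature; fast-red-like chromogen vector as published
# for red alkaline-phosphatase chromogens.
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
FAST_RED_OD = (0.214, 0.851, 0.478)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class SpatialPatternParams:
    """Parameters of the spatial process placing vessels or cells.

    ``intensity`` is the expected number of objects per mm² (for the clustered
    kind it equals ``parent_intensity * offspring_per_parent`` and is kept as
    the authoritative overall rate).
    """

    pattern_kind: str  # "homogeneous" | "clustered"
    intensity: float  # objects per mm^2
    object_kind: str = "vessel"  # "vessel" | "cell"
    parent_intensity: float = 0.0  # parents per mm^2 (clustered only)
    offspring_per_parent: float = 0.0  # mean offspring count (clustered only)
    cluster_sigma: float = 0.0  # mm, isotropic offspring dispersion
    vessel_radius_range: Tuple[float, float] = (0.015, 0.040)  # mm
    vessel_elongation_range: Tuple[float, float] = (1.0, 2.5)
    cell_radius: float = 0.008  # mm

    def __post_init__(self):
        if self.pattern_kind not in ("homogeneous", "clustered"):
            raise ValueError(f"unknown pattern_kind {self.pattern_kind!r}")
        if self.object_kind not in ("vessel", "cell"):
            raise ValueError(f"unknown object_kind {self.object_kind!r}")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.pattern_kind == "clustered":
            if self.cluster_sigma <= 0:
                raise ValueError("cluster_sigma must be > 0 for clustered patterns")
            if self.parent_intensity < 0 or self.offspring_per_parent < 0:
                raise ValueError("clustered intensities must be >= 0")
        lo, hi = self.vessel_radius_range
        if not (0 < lo <= hi):
            raise ValueError("vessel_radius_range must satisfy 0 < min <= max")
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be > 0")

    @staticmethod
    def homogeneous(intensity: float, object_kind: str = "vessel", **kw) -> "SpatialPatternParams":
        return SpatialPatternParams("homogeneous", intensity, object_kind, **kw)

    @staticmethod
    def clustered(parent_intensity: float, offspring_per_parent: float,
                  cluster_sigma: float, object_kind: str = "vessel", **kw) -> "SpatialPatternParams":
        return SpatialPatternParams(
            "clustered", parent_intensity * offspring_per_parent, object_kind,
            parent_intensity=parent_intensity,
            offspring_per_parent=offspring_per_parent,
            cluster_sigma=cluster_sigma, **kw)


@dataclass(frozen=True)
class StainModelParams:
    """Forward stain model: stain vectors, chromogen intensity range, optics."""

    counterstain: Tuple[float, float, float] = HEMATOXYLIN_OD
    chromogen: Tuple[float, float, float] = FAST_RED_OD
    chromogen_od_range: Tuple[float, float] = (0.6, 1.4)  # per-slide base OD
    background_rgb: Tuple[float, float, float] = (250.0, 250.0, 252.0)
    mpp: float = 4.0  # microns per pixel

    def __post_init__(self):
        if self.mpp <= 0:
            raise ValueError("mpp must be > 0")
        lo, hi = self.chromogen_od_range
        if not (0 < lo <= hi <= 3):
            raise ValueError("chromogen_od_range must lie within (0, 3]")
        c = _unit(self.counterstain)
        h = _unit(self.chromogen)
        if np.linalg.norm(np.cross(c, h)) < 1e-6:
            raise ValueError("stain vectors must be linearly independent")

    @property
    def counterstain_unit(self) -> np.ndarray:
        return _unit(self.counterstain)

    @property
    def chromogen_unit(self) -> np.ndarray:
        return _unit(self.chromogen)


def default_stain_model(mpp: float = 4.0) -> StainModelParams:
    return StainModelParams(mpp=mpp)


@dataclass(frozen=True)
class RenderParams:
    """Rendering knobs shared by all synthetic slides.

    ``wall_fraction`` is the stained vessel-wall thickness relative to the
    outer radius (the lumen stays unstained); ``gap_probability`` is the chance
    a vessel ring carries an unstained arc, emulating interruptions of the
    endothelial lining by tissue tears or weak staining.
    """

    wall_fraction: float = 0.45
    gap_probability: float = 0.15
    gap_angle_range: Tuple[float, float] = (math.radians(20), math.radians(60))
    counterstain_od_mean: float = 0.25
    counterstain_od_sigma: float = 0.04
    noise_sigma: float = 1.5  # additive RGB sensor noise, 8-bit counts
    object_od_jitter: Tuple[float, float] = (0.85, 1.15)
    tissue_scale: float = 0.98  # tissue ellipse semi-axes / half-canvas


@dataclass
class SlideImage:
    """A calibrated RGB raster standing in for a scanned stained section."""

    pixels: np.ndarray  # (H, W, 3) uint8
    mpp: float  # microns per pixel
    tissue_mask: np.ndarray  # (H, W) bool
    slide_id: str

    def __post_init__(self):
        if self.mpp <= 0:
            raise ValueError("mpp must be > 0")
        if self.pixels.shape[:2] != self.tissue_mask.shape:
            raise ValueError("tissue_mask must match pixel raster dimensions")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.tissue_mask.shape

    @property
    def tissue_area_mm2(self) -> float:
        return float(np.count_nonzero(self.tissue_mask)) * mm_per_px(self.mpp) ** 2


@dataclass
class GroundTruth:
    """Generator-side truth for one synthetic slide.

    ``true_area_fraction`` is the percentage of tissue pixels covered by
    chromogen-positive objects, computed from the rasterized object polygons
    intersected with the tissue mask (pixel-centre containment), so it is
    recomputable exactly from ``object_polygons``.
    """

    object_polygons: List[Polygon]
    cell_centroids: Dict[str, np.ndarray]  # marker -> (N, 2) mm
    true_area_fraction: float  # percent of tissue area
    pattern_kind: str
    seed: int
    painted_mask: Optional[np.ndarray] = None  # (H, W) bool, chromogen-positive
    target_value: Optional[float] = None  # generator target (marker units)
    marker: Optional[str] = None


# ---------------------------------------------------------------------------
# point patterns
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _uniform_in_region(region, n: int, rng: np.random.Generator) -> np.ndarray:
    """n points uniform in a shapely polygon, by rejection from its bbox."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = region.bounds
    shapely.prepare(region)
    out = []
    got = 0
    # acceptance rate = area / bbox area; bounded below for sane regions
    while got < n:
        m = max(32, int(1.6 * (n - got) * (maxx - minx) * (maxy - miny) / region.area))
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(region, xs, ys)
        pts = np.column_stack([xs[keep], ys[keep]])
        out.append(pts[: n - got])
        got += len(out[-1])
    return np.concatenate(out, axis=0)


def sample_point_pattern(params: SpatialPatternParams, region, seed) -> np.ndarray:
    """Sample object centres (mm) from the configured spatial process.

    ``homogeneous``: homogeneous Poisson process with the stated intensity
    restricted to ``region``.  ``clustered``: Thomas-type process — parents
    are Poisson with ``parent_intensity`` on the region buffered by
    4·``cluster_sigma`` (so the offspring intensity is stationary inside the
    window, without edge depletion), offspring counts are Poisson with mean
    ``offspring_per_parent``, displaced by an isotropic Gaussian with sd
    ``cluster_sigma``, and restricted to ``region``.

    Deterministic given ``seed``; returns an ``(N, 2)`` array.
    """
    rng = _as_rng(seed)
    if region.area <= 0:
        raise ValueError(
            f"point-pattern region has non-positive area (bounds={region.bounds})")
    if params.pattern_kind == "homogeneous":
        n = rng.poisson(params.intensity * region.area)
        return _uniform_in_region(region, n, rng)
    # clustered
    buffered = region.buffer(4.0 * params.cluster_sigma)
    n_parents = rng.poisson(params.parent_intensity * buffered.area)
    parents = _uniform_in_region(buffered, n_parents, rng)
    chunks = []
    for p in parents:
        k = rng.poisson(params.offspring_per_parent)
        if k:
            chunks.append(p + rng.normal(0.0, params.cluster_sigma, (k, 2)))
    if not chunks:
        return np.empty((0, 2))
    pts = np.concatenate(chunks, axis=0)
    shapely.prepare(region)
    keep = shapely.contains_xy(region, pts[:, 0], pts[:, 1])
    return pts[keep]


# ---------------------------------------------------------------------------
# object geometry
# ---------------------------------------------------------------------------

def _vessel_ring_polygon(center, radius, elongation, angle, wall_fraction,
                         gap: Optional[Tuple[float, float]] = None) -> Polygon:
    """Elliptical ring (stained wall, unstained lumen), optional arc gap.

    ``gap`` is ``(start_angle, width)`` in radians in the object's local frame.
    """
    a = radius * elongation
    b = radius
    outer = shapely.affinity.scale(Point(0, 0).buffer(1.0, quad_segs=48), a, b)
    inner = shapely.affinity.scale(
        Point(0, 0).buffer(1.0, quad_segs=48), a * (1 - wall_fraction), b * (1 - wall_fraction))
    ring = outer.difference(inner)
    if gap is not None:
        t0, width = gap
        big = 2.0 * a
        arc = np.linspace(t0, t0 + width, 16)
        wedge = Polygon(
            [(0.0, 0.0)] + [(big * math.cos(t), big * math.sin(t)) for t in arc])
        ring = ring.difference(wedge)
    ring = shapely.affinity.rotate(ring, angle, origin=(0, 0), use_radians=True)
    return shapely.affinity.translate(ring, center[0], center[1])


def _cell_disk_polygon(center, radius) -> Polygon:
    return Point(center[0], center[1]).buffer(radius, quad_segs=24)


def expected_vessel_area_mm2(params: SpatialPatternParams,
                             render: RenderParams = RenderParams()) -> float:
    """Expected painted area of one vessel ring under the render defaults.

    Used to convert a target area fraction into a placement intensity;
    ignores overlap between vessels (the measured ground truth is
    authoritative, this only positions the regime).
    """
    lo, hi = params.vessel_radius_range
    er2 = (lo * lo + lo * hi + hi * hi) / 3.0  # E[r^2] for U(lo, hi)
    ee = 0.5 * sum(params.vessel_elongation_range)
    ring_frac = 1.0 - (1.0 - render.wall_fraction) ** 2
    g0, g1 = render.gap_angle_range
    gap_frac = render.gap_probability * 0.5 * (g0 + g1) / (2 * math.pi)
    return math.pi * er2 * ee * ring_frac * (1.0 - gap_frac)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _tissue_ellipse(canvas_mm, scale) -> Polygon:
    cx, cy = canvas_mm[0] / 2.0, canvas_mm[1] / 2.0
    return shapely.affinity.scale(
        Point(cx, cy).buffer(1.0, quad_segs=128), cx * scale, cy * scale)


def _tissue_raster(canvas_mm, scale, shape, mpp) -> np.ndarray:
    s = mm_per_px(mpp)
    cx, cy = canvas_mm[0] / 2.0, canvas_mm[1] / 2.0
    a, b = cx * scale, cy * scale
    xs = (np.arange(shape[1]) + 0.5) * s
    ys = (np.arange(shape[0]) + 0.5) * s
    nx = (xs - cx)[None, :] / a
    ny = (ys - cy)[:, None] / b
    return nx * nx + ny * ny <= 1.0


def render_slide(vessel_pattern: Optional[SpatialPatternParams],
                 cell_patterns: Optional[Dict[str, SpatialPatternParams]] = None,
                 stain: StainModelParams = StainModelParams(),
                 canvas_mm: Tuple[float, float] = (8.0, 8.0),
                 seed: int = 0,
                 *,
                 render: RenderParams = RenderParams(),
                 pixel_budget: int = DEFAULT_PIXEL_BUDGET,
                 slide_id: Optional[str] = None,
                 pattern_kind: Optional[str] = None) -> Tuple[SlideImage, GroundTruth]:
    """Render one synthetic slide and its exact ground truth.

    Vessels are elongated elliptical rings, cells are disks; each object's
    chromogen OD derives from a per-slide base drawn from
    ``stain.chromogen_od_range`` with ±15% per-object jitter.  The RGB image
    is the Beer–Lambert composition of counterstain and chromogen OD.
    Identical seed ⇒ bit-identical output.
    """
    if canvas_mm[0] * canvas_mm[1] < 1.0:
        raise ValueError("canvas area must be at least 1 mm^2")
    mpp = stain.mpp
    s = mm_per_px(mpp)
    W = int(round(canvas_mm[0] / s))
    H = int(round(canvas_mm[1] / s))
    if H * W > pixel_budget:
        min_mpp = 1000.0 * math.sqrt(canvas_mm[0] * canvas_mm[1] / pixel_budget)
        raise ValueError(
            f"raster {H}x{W} exceeds the pixel budget ({pixel_budget}); "
            f"use mpp >= {min_mpp:.2f} um/px for this canvas")

    ss = np.random.SeedSequence(seed)
    rng_vessel, rng_cells, rng_obj, rng_stain = (
        np.random.default_rng(c) for c in ss.spawn(4))

    region = _tissue_ellipse(canvas_mm, render.tissue_scale)
    tissue = _tissue_raster(canvas_mm, render.tissue_scale, (H, W), mpp)

    chrom_od = np.zeros((H, W), dtype=np.float64)
    painted = np.zeros((H, W), dtype=bool)
    polygons: List[Polygon] = []
    centroids: Dict[str, np.ndarray] = {}

    base_od = rng_stain.uniform(*stain.chromogen_od_range)
    jit_lo, jit_hi = render.object_od_jitter
    od_lo = stain.chromogen_od_range[0]

    def paint(poly: Polygon):
        od = base_od * rng_obj.uniform(jit_lo, jit_hi)
        od = max(od, 0.5 * od_lo)
        rs, cs, inside = rasterize_polygon(poly, (H, W), mpp)
        if inside.size:
            painted[rs, cs] |= inside
            sub = chrom_od[rs, cs]
            chrom_od[rs, cs] = np.where(inside, np.maximum(sub, od), sub)
        polygons.append(poly)

    kind = pattern_kind
    if vessel_pattern is not None and vessel_pattern.intensity > 0:
        kind = kind or vessel_pattern.pattern_kind
        centers = sample_point_pattern(vessel_pattern, region, rng_vessel)
        lo_r, hi_r = vessel_pattern.vessel_radius_range
        lo_e, hi_e = vessel_pattern.vessel_elongation_range
        for cxy in centers:
            r = rng_obj.uniform(lo_r, hi_r)
            e = rng_obj.uniform(lo_e, hi_e)
            ang = rng_obj.uniform(0.0, math.pi)
            gap = None
            if rng_obj.random() < render.gap_probability:
                gap = (rng_obj.uniform(0, 2 * math.pi),
                       rng_obj.uniform(*render.gap_angle_range))
            paint(_vessel_ring_polygon(cxy, r, e, ang, render.wall_fraction, gap))

    for marker, cp in (cell_patterns or {}).items():
        if cp.intensity <= 0:
            centroids[marker] = np.empty((0, 2))
            continue
        kind = kind or cp.pattern_kind
        centers = sample_point_pattern(cp, region, rng_cells)
        centroids[marker] = centers
        for cxy in centers:
            paint(_cell_disk_polygon(cxy, cp.cell_radius))

    counter_od = np.zeros((H, W))
    counter_od[tissue] = np.clip(
        rng_stain.normal(render.counterstain_od_mean,
                         render.counterstain_od_sigma, int(tissue.sum())),
        0.0, None)

    od_rgb = (counter_od[..., None] * stain.counterstain_unit[None, None, :]
              + chrom_od[..., None] * stain.chromogen_unit[None, None, :])
    rgb = np.asarray(stain.background_rgb)[None, None, :] * np.power(10.0, -od_rgb)
    rgb = rgb + rng_stain.normal(0.0, render.noise_sigma, rgb.shape)
    pixels = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    tissue_px = int(tissue.sum())
    frac = 100.0 * int(np.count_nonzero(painted & tissue)) / tissue_px

    sid = slide_id or f"slide-{seed}"
    slide = SlideImage(pixels=pixels, mpp=mpp, tissue_mask=tissue, slide_id=sid)
    gt = GroundTruth(object_polygons=polygons, cell_centroids=centroids,
                     true_area_fraction=frac, pattern_kind=kind or "homogeneous",
                     seed=int(seed), painted_mask=painted)
    return slide, gt


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerCohortSpec:
    """Cohort-level description of one marker's staining and spatial regime.

    ``target_range``: per-slide target drawn log-/uniformly — area-fraction %
    for vessels, objects per mm² for cells.  The clustered regime keeps the
    per-slide overall intensity of the homogeneous one but concentrates it
    into clusters of a fixed mean size (``cluster_size`` objects), so denser
    slides carry *more* clusters of similar local density — the regime in
    which hot-spot readings stop tracking the whole slide.
    """

    name: str
    object_kind: str  # "vessel" | "cell"
    target_range: Tuple[float, float]
    log_uniform_target: bool = False
    cluster_size: float = 25.0  # mean objects per cluster in the clustered regime
    cluster_sigma: float = 0.12  # mm
    # when set, cluster geometry is drawn per slide from these ranges: the
    # local density of a tumour's hot spots then varies independently of its
    # overall marker load
    cluster_size_range: Optional[Tuple[float, float]] = None
    cluster_sigma_range: Optional[Tuple[float, float]] = None
    vessel_radius_range: Tuple[float, float] = (0.015, 0.040)
    vessel_elongation_range: Tuple[float, float] = (1.0, 2.5)
    cell_radius: float = 0.008
    stain: StainModelParams = field(default_factory=StainModelParams)
    render: RenderParams = field(default_factory=RenderParams)


def vessel_marker_spec(mpp: float = 4.0) -> MarkerCohortSpec:
    """CD31-like endothelial marker: area fractions spanning 1.17–12.77%."""
    return MarkerCohortSpec(
        name="cd31", object_kind="vessel", target_range=(1.17, 12.77),
        cluster_size=40.0, cluster_sigma=0.25,
        cluster_size_range=(20.0, 80.0), cluster_sigma_range=(0.15, 0.40),
        stain=StainModelParams(mpp=mpp))


def nuclear_cell_marker_spec(mpp: float = 4.0) -> MarkerCohortSpec:
    """FOXP3-like nuclear marker: 1.3–41 cells/mm² log-uniform
    (0.13–4.1 cells per 0.1 mm², median 0.73)."""
    return MarkerCohortSpec(
        name="foxp3", object_kind="cell", target_range=(1.3, 41.0),
        log_uniform_target=True, cluster_size=15.0, cluster_sigma=0.10,
        stain=StainModelParams(mpp=mpp))


def surface_cell_marker_spec(mpp: float = 4.0) -> MarkerCohortSpec:
    """CD8-like surface marker: denser infiltrate than FOXP3."""
    return MarkerCohortSpec(
        name="cd8", object_kind="cell", target_range=(5.0, 120.0),
        log_uniform_target=True, cluster_size=15.0, cluster_sigma=0.10,
        stain=StainModelParams(mpp=mpp))


def slide_seed(master_seed: int, index: int) -> int:
    """Stated mixing function: per-slide seed from master seed and index.

    ``SeedSequence(master_seed, spawn_key=(index,))`` hashed to a 31-bit
    integer, so any slide is regenerable in isolation.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2 ** 31))


def _pattern_for_slide(spec: MarkerCohortSpec, clustered: bool,
                       target: float,
                       rng: Optional[np.random.Generator] = None
                       ) -> Tuple[SpatialPatternParams, float]:
    if spec.object_kind == "vessel":
        lam = (target / 100.0) / expected_vessel_area_mm2(
            SpatialPatternParams.homogeneous(
                1.0, "vessel",
                vessel_radius_range=spec.vessel_radius_range,
                vessel_elongation_range=spec.vessel_elongation_range),
            spec.render)
    else:
        lam = target
    kw = dict(object_kind=spec.object_kind,
              vessel_radius_range=spec.vessel_radius_range,
              vessel_elongation_range=spec.vessel_elongation_range,
              cell_radius=spec.cell_radius)
    if clustered:
        size = spec.cluster_size
        sigma = spec.cluster_sigma
        if rng is not None and spec.cluster_size_range is not None:
            size = float(rng.uniform(*spec.cluster_size_range))
        if rng is not None and spec.cluster_sigma_range is not None:
            sigma = float(rng.uniform(*spec.cluster_sigma_range))
        params = SpatialPatternParams.clustered(lam / size, size, sigma, **kw)
    else:
        params = SpatialPatternParams.homogeneous(lam, **kw)
    return params, lam


def iter_cohort(n_slides: int, heterogeneous_fraction: float,
                marker_spec: MarkerCohortSpec, master_seed: int,
                canvas_mm: Tuple[float, float] = (8.0, 8.0)):
    """Yield ``(SlideImage, GroundTruth)`` pairs for a synthetic cohort.

    Exactly ``round(n_slides * heterogeneous_fraction)`` slides carry the
    clustered pattern; the assignment is a seeded permutation so pattern kind
    is not confounded with slide index.  Per-slide seeds come from
    :func:`slide_seed`.
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    if not 0.0 <= heterogeneous_fraction <= 1.0:
        raise ValueError("heterogeneous_fraction must lie in [0, 1]")
    n_clustered = int(round(n_slides * heterogeneous_fraction))
    assign_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(1 << 20,)))
    perm = assign_rng.permutation(n_slides)
    clustered_idx = set(perm[:n_clustered].tolist())

    for i in range(n_slides):
        seed_i = slide_seed(master_seed, i)
        rng_i = np.random.default_rng(seed_i)
        lo, hi = marker_spec.target_range
        if marker_spec.log_uniform_target:
            target = float(np.exp(rng_i.uniform(np.log(lo), np.log(hi))))
        else:
            target = float(rng_i.uniform(lo, hi))
        clustered = i in clustered_idx
        params, _ = _pattern_for_slide(marker_spec, clustered, target, rng_i)
        sid = f"{marker_spec.name}-{i:03d}"
        if marker_spec.object_kind == "vessel":
            slide, gt = render_slide(params, None, marker_spec.stain, canvas_mm,
                                     seed_i, render=marker_spec.render, slide_id=sid)
        else:
            slide, gt = render_slide(None, {marker_spec.name: params},
                                     marker_spec.stain, canvas_mm, seed_i,
                                     render=marker_spec.render, slide_id=sid)
        gt.target_value = target
        gt.marker = marker_spec.name
        yield slide, gt


def generate_cohort(n_slides: int, heterogeneous_fraction: float,
                    marker_spec: MarkerCohortSpec, master_seed: int,
                    canvas_mm: Tuple[float, float] = (8.0, 8.0)) -> List[Tuple[SlideImage, GroundTruth]]:
    """Materialized version of :func:`iter_cohort`."""
    return list(iter_cohort(n_slides, heterogeneous_fraction, marker_spec,
                            master_seed, canvas_mm))


def cohort_manifest(cohort: Sequence[Tuple[SlideImage, GroundTruth]],
                    marker_spec: MarkerCohortSpec, master_seed: int):
    """Cohort parameter record (one row per slide) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for slide, gt in cohort:
        rows.append({
            "slide_id": slide.slide_id,
            "marker": marker_spec.name,
            "object_kind": marker_spec.object_kind,
            "pattern_kind": gt.pattern_kind,
            "seed": gt.seed,
            "master_seed": int(master_seed),
            "mpp_um": slide.mpp,
            "tissue_area_mm2": slide.tissue_area_mm2,
            "target_value": gt.target_value,
            "true_area_fraction_pct": gt.true_area_fraction,
            "n_objects": len(gt.object_polygons),
        })
    return pd.DataFrame(rows)
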