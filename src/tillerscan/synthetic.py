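"""Synthetic TLS scans of tillering rice plants with known ground truth.

The generator emulates what a tripod laser scanner sees after registration
and cleaning: a single plant whose 5-25 culms (tillers) radiate and lean
outward from a basal crown, each culm a thin curved tube bearing ribbon-like
leaves that arch out to the canopy radius. Surfaces are sampled at roughly
the scan's point spacing (~1-3 mm), and additive Gaussian range noise with a
default sigma of 1 mm — inside the 0.1-1.3 mm error band of the reference
scanner — is applied to every point. Occlusion is not simulated; robustness
to incomplete clouds is exercised with random point dropout instead.

Randomness is split into two independent streams derived from the spec seed:
a geometry stream (culm placement, heights, leaf angles) and a sampling
stream (sub-spacing jitter, range noise, outliers). Ground truth is computed
from the noiseless parametric geometry through a dense deterministic sample,
so it depends on the geometry only — regenerating with a different noise
level leaves it unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from shapely.geometry import MultiPoint

from .cloud_io import PointCloud, write_point_cloud
from .errors import SpecError

__all__ = [
    "PlantSpec",
    "GroundTruth",
    "generate_plant",
    "add_outliers",
    "random_dropout",
    "study_spec",
    "make_fixture_suite",
    "MANIFEST_COLUMNS",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

MANIFEST_COLUMNS = [
    "file", "tiller_count", "height_m", "crown_radius_m", "stem_perimeter_m",
    "surface_area_m2", "volume_m3", "pla_pct", "seed",
]


@dataclass(frozen=True)
class PlantSpec:
    """Parameters of one synthetic plant.

    Defaults describe a mid-season plant: 12 tillers, 0.9 m tall, 0.3 m
    canopy radius, 3 mm culm radius, 2 mm point spacing and 1 mm range
    noise.
    """

    tiller_count: int = 12
    height: float = 0.9
    crown_radius: float = 0.3
    culm_radius: float = 0.003
    leaves_per_culm: int = 2
    leaf_width: float = 0.012
    point_spacing: float = 0.002
    noise_sigma: float = 0.001
    outlier_fraction: float = 0.0
    basal_radius: float = 0.05
    min_culm_separation: float = 0.012
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.tiller_count <= 60:
            raise SpecError(f"tiller_count {self.tiller_count} out of range")
        for name in ("height", "crown_radius", "culm_radius", "leaf_width",
                     "point_spacing", "basal_radius"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        if self.noise_sigma < 0 or not 0 <= self.outlier_fraction <= 1:
            raise SpecError("noise_sigma must be >= 0, outlier_fraction in [0, 1]")
        if self.crown_radius <= self.basal_radius:
            raise SpecError(
                f"crown_radius ({self.crown_radius}) must exceed the basal "
                f"disk radius ({self.basal_radius})"
            )
        if self.leaves_per_culm < 0:
            raise SpecError("leaves_per_culm must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless-geometry truth for one generated plant.

    ``stem_perimeter_at(z)`` gives the circumference of the circle enclosing
    all culm cross-sections at height z around their common centroid — the
    quantity the stepped radius search estimates. ``reference_pla`` applies
    the same grid rules as the extraction (axis-aligned grid anchored at the
    min corner, upper boundary clamped) to the noiseless projection.
    """

    tiller_count: int
    height: float
    crown_radius: float
    stem_perimeter_at: Callable[[float], float]
    reference_surface_area: float
    reference_volume: float
    reference_pla: Callable[[float], float]
    culm_axes_at: Callable[[float], np.ndarray]


# ---------------------------------------------------------------------------
# parametric geometry
# ---------------------------------------------------------------------------

@dataclass
class _Culm:
    base: np.ndarray         # (2,) xy at z = 0
    direction: np.ndarray    # (2,) unit outward lean direction
    bend: float              # xy offset = bend * z^2 along direction
    height: float
    radius: float

    def axis_xy(self, z) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=np.float64))
        return self.base[None, :] + self.direction[None, :] * (self.bend * z * z)[:, None]


@dataclass
class _Leaf:
    attach: np.ndarray       # (3,) point on culm axis
    tip_xy: np.ndarray       # (2,)
    rise: float
    drop: float
    width0: float

    def centerline(self, t: np.ndarray) -> np.ndarray:
        xy = self.attach[None, :2] + t[:, None] * (self.tip_xy - self.attach[:2])[None, :]
        z = self.attach[2] + 4.0 * self.rise * t * (1.0 - t) - self.drop * t ** 2
        return np.column_stack([xy, z])

    def width(self, t: np.ndarray) -> np.ndarray:
        return self.width0 * (1.0 - 0.7 * t)


def _sunflower_layout(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Near-uniform deterministic packing of n culm bases in a disk, with a
    small seeded jitter; gives close to the densest achievable pairwise
    separation for the disk size."""
    i = np.arange(1, n + 1, dtype=np.float64)
    r = radius * np.sqrt((i - 0.5) / n)
    th = i * _GOLDEN_ANGLE + rng.uniform(0, 2 * math.pi)
    pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
    if n > 1:
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        jitter_scale = 0.04 * d[d > 0].min()
        pts += rng.uniform(-jitter_scale, jitter_scale, size=pts.shape)
    return pts


def _build_geometry(spec: PlantSpec, rng: np.random.Generator
                    ) -> tuple[list[_Culm], list[_Leaf]]:
    bases = _sunflower_layout(spec.tiller_count, spec.basal_radius, rng)
    if spec.tiller_count > 1:
        d = np.linalg.norm(bases[:, None] - bases[None, :], axis=2)
        sep = d[d > 0].min()
        if sep < spec.min_culm_separation:
            raise SpecError(
                f"cannot place {spec.tiller_count} culms with pairwise "
                f"separation >= {spec.min_culm_separation} m inside a basal "
                f"disk of radius {spec.basal_radius} m (achieved {sep:.4f} m); "
                "enlarge basal_radius or lower min_culm_separation"
            )

    culms: list[_Culm] = []
    heights = np.concatenate([
        [spec.height],
        rng.uniform(0.80, 0.98, size=spec.tiller_count - 1) * spec.height,
    ])
    for b, h in zip(bases, heights):
        norm = np.linalg.norm(b)
        if norm > 1e-9:
            direction = b / norm
        else:
            phi = rng.uniform(0, 2 * math.pi)
            direction = np.array([math.cos(phi), math.sin(phi)])
        lean = rng.uniform(0.15, 0.35) * (spec.crown_radius - spec.basal_radius)
        culms.append(_Culm(base=b, direction=direction, bend=lean / h ** 2,
                           height=float(h), radius=spec.culm_radius))

    leaves: list[_Leaf] = []
    for ci, culm in enumerate(culms):
        for li in range(spec.leaves_per_culm):
            frac = rng.uniform(0.50, 0.85)
            z_a = frac * culm.height
            attach_xy = culm.axis_xy(z_a)[0]
            az = math.atan2(culm.direction[1], culm.direction[0]) \
                + rng.normal(0.0, 0.45)
            if ci == 0 and li == 0:
                reach = spec.crown_radius       # the crown-defining leaf
            else:
                reach = rng.uniform(0.55, 0.95) * spec.crown_radius
            tip_xy = np.array([reach * math.cos(az), reach * math.sin(az)])
            rise = rng.uniform(0.05, 0.10) * spec.height
            drop = rng.uniform(0.15, 0.30) * z_a
            leaves.append(_Leaf(
                attach=np.array([attach_xy[0], attach_xy[1], z_a]),
                tip_xy=tip_xy, rise=float(rise), drop=float(drop),
                width0=spec.leaf_width,
            ))
    return culms, leaves


# ---------------------------------------------------------------------------
# surface sampling
# ---------------------------------------------------------------------------

_BASAL_HEIGHT = 0.012
_BASAL_PAD = 0.008


def _sample_culm(culm: _Culm, spacing: float,
                 rng: np.random.Generator | None) -> np.ndarray:
    n_z = max(2, int(round(culm.height / spacing)))
    z = np.linspace(0.0, culm.height, n_z)
    axis = culm.axis_xy(z)
    n_c = max(6, int(round(2 * math.pi * culm.radius / spacing)))
    if rng is None:
        offsets = np.zeros(n_z)
    else:
        offsets = rng.uniform(0, 2 * math.pi, size=n_z)
    th = offsets[:, None] + np.linspace(0, 2 * math.pi, n_c, endpoint=False)[None, :]
    x = axis[:, 0:1] + culm.radius * np.cos(th)
    y = axis[:, 1:2] + culm.radius * np.sin(th)
    zz = np.broadcast_to(z[:, None], th.shape)
    return np.column_stack([x.ravel(), y.ravel(), zz.ravel()])


def _sample_leaf(leaf: _Leaf, spacing: float,
                 rng: np.random.Generator | None, faces: int = 2) -> np.ndarray:
    chord = leaf.centerline(np.array([0.0, 1.0]))
    length = float(np.linalg.norm(chord[1] - chord[0])) * 1.15  # arch slack
    n_t = max(3, int(round(length / spacing)))
    n_w = max(2, int(round(leaf.width0 / spacing)) + 1)
    t = np.linspace(0.0, 1.0, n_t)
    center = leaf.centerline(t)
    w = leaf.width(t)
    horiz = leaf.tip_xy - leaf.attach[:2]
    h_norm = np.linalg.norm(horiz)
    lateral = (np.array([-horiz[1], horiz[0]]) / h_norm if h_norm > 1e-9
               else np.array([1.0, 0.0]))
    u = np.linspace(-0.5, 0.5, n_w)
    pts = []
    for _ in range(faces):
        off = u[None, :] * w[:, None]                       # (n_t, n_w)
        xy = center[:, None, :2] + off[:, :, None] * lateral[None, None, :]
        zz = np.broadcast_to(center[:, None, 2:3], off.shape + (1,))
        grid = np.concatenate([xy, zz], axis=2).reshape(-1, 3)
        if rng is not None:
            grid = grid + rng.uniform(-spacing / 4, spacing / 4, size=grid.shape)
        pts.append(grid)
    return np.vstack(pts)


def _sample_basal_crown(spec: PlantSpec, spacing: float) -> np.ndarray:
    """Squat cylinder at the base joining all culms (the root crown)."""
    radius = spec.basal_radius + _BASAL_PAD
    pts = []
    for z in (0.0, _BASAL_HEIGHT):
        n_r = max(2, int(round(radius / spacing)))
        for r in np.linspace(0.0, radius, n_r):
            n_c = max(1, int(round(2 * math.pi * max(r, 1e-6) / spacing)))
            th = np.linspace(0, 2 * math.pi, n_c, endpoint=False)
            pts.append(np.column_stack(
                [r * np.cos(th), r * np.sin(th), np.full(n_c, z)]))
    n_z = max(2, int(round(_BASAL_HEIGHT / spacing)))
    n_c = max(6, int(round(2 * math.pi * radius / spacing)))
    th = np.linspace(0, 2 * math.pi, n_c, endpoint=False)
    for z in np.linspace(0.0, _BASAL_HEIGHT, n_z):
        pts.append(np.column_stack(
            [radius * np.cos(th), radius * np.sin(th), np.full(n_c, z)]))
    return np.vstack(pts)


def _sample_plant(spec: PlantSpec, culms: list[_Culm], leaves: list[_Leaf],
                  spacing: float, rng: np.random.Generator | None) -> np.ndarray:
    parts = [_sample_basal_crown(spec, spacing)]
    parts += [_sample_culm(c, spacing, rng) for c in culms]
    parts += [_sample_leaf(lf, spacing, rng) for lf in leaves]
    return np.vstack(parts)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _pla_oracle(xy: np.ndarray, cell_size: float) -> float:
    """Independent PLA evaluation on a noiseless projection, sharing the
    grid contract (min-corner anchor, clamped upper boundary) but not the
    extraction code path."""
    origin = xy.min(axis=0)
    extent = xy.max(axis=0) - origin
    n_cells = np.maximum(1, np.ceil(extent / cell_size - 1e-12).astype(np.int64))
    idx = np.minimum(np.floor((xy - origin) / cell_size).astype(np.int64),
                     n_cells - 1)
    occupied = len({(int(a), int(b)) for a, b in idx})
    area = occupied * cell_size ** 2
    mbr = max(MultiPoint(xy).minimum_rotated_rectangle.area, cell_size ** 2)
    return min(100.0, 100.0 * area / mbr)


def _compute_ground_truth(spec: PlantSpec, culms: list[_Culm],
                          leaves: list[_Leaf]) -> GroundTruth:
    dense_spacing = min(spec.point_spacing, 0.002)
    dense = _sample_plant(spec, culms, leaves, dense_spacing, rng=None)

    # crown radius: max horizontal reach from the stem-slice centroid
    sl = dense[(dense[:, 2] >= 0.03) & (dense[:, 2] < 0.04)]
    centroid = sl[:, :2].mean(axis=0)
    crown = float(np.sqrt(((dense[:, :2] - centroid) ** 2).sum(axis=1).max()))

    def stem_perimeter_at(z: float) -> float:
        alive = [c for c in culms if c.height >= z]
        if not alive:
            raise ValueError(f"no culm reaches z = {z}")
        axes = np.vstack([c.axis_xy(z) for c in alive])
        center = axes.mean(axis=0)
        radius = float(np.linalg.norm(axes - center, axis=1).max()) \
            + spec.culm_radius
        return 2.0 * math.pi * radius

    # analytic surface area: tube laterals + basal cylinder + 2-sided ribbons
    area = 0.0
    t_fine = np.linspace(0.0, 1.0, 512)
    for c in culms:
        z = np.linspace(0.0, c.height, 512)
        seg = np.diff(np.column_stack([c.axis_xy(z), z]), axis=0)
        arc = np.linalg.norm(seg, axis=1).sum()
        area += 2 * math.pi * c.radius * arc
    rb = spec.basal_radius + _BASAL_PAD
    area += 2 * math.pi * rb * rb + 2 * math.pi * rb * _BASAL_HEIGHT
    for lf in leaves:
        cl = lf.centerline(t_fine)
        seg = np.linalg.norm(np.diff(cl, axis=0), axis=1)
        w_mid = 0.5 * (lf.width(t_fine[:-1]) + lf.width(t_fine[1:]))
        area += 2.0 * float((seg * w_mid).sum())

    volume = float(ConvexHull(dense).volume)

    def reference_pla(cell_size: float) -> float:
        return _pla_oracle(dense[:, :2], cell_size)

    def culm_axes_at(z: float) -> np.ndarray:
        alive = [c for c in culms if c.height >= z]
        return np.vstack([c.axis_xy(z) for c in alive])

    return GroundTruth(
        tiller_count=spec.tiller_count,
        height=spec.height,
        crown_radius=crown,
        stem_perimeter_at=stem_perimeter_at,
        reference_surface_area=float(area),
        reference_volume=volume,
        reference_pla=reference_pla,
        culm_axes_at=culm_axes_at,
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_plant(spec: PlantSpec = PlantSpec()) -> tuple[PointCloud, GroundTruth]:
    """Sample a synthetic plant scan and its ground truth.

    Fully reproducible: the same spec (including its seed) yields a
    bit-identical cloud and identical truth values.
    """
    ss = np.random.SeedSequence(spec.seed)
    geom_ss, samp_ss, outlier_ss = ss.spawn(3)
    geom_rng = np.random.default_rng(geom_ss)
    samp_rng = np.random.default_rng(samp_ss)

    culms, leaves = _build_geometry(spec, geom_rng)
    pts = _sample_plant(spec, culms, leaves, spec.point_spacing, samp_rng)
    if spec.noise_sigma > 0:
        pts = pts + samp_rng.normal(0.0, spec.noise_sigma, size=pts.shape)
    cloud = PointCloud(pts)
    if spec.outlier_fraction > 0:
        cloud = add_outliers(cloud, spec.outlier_fraction,
                             seed=np.random.default_rng(outlier_ss)
                             .integers(2 ** 31))
    truth = _compute_ground_truth(spec, culms, leaves)
    return cloud, truth


def add_outliers(cloud: PointCloud, fraction: float, radius_scale: float = 3.0,
                 seed: int = 0) -> PointCloud:
    """Append round(fraction * N) uniform points inside a bounding sphere
    inflated by ``radius_scale``; original points are unchanged and keep
    their positions at the front of the array."""
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    n_out = int(round(fraction * cloud.n))
    if n_out == 0:
        return cloud
    rng = np.random.default_rng(seed)
    center = cloud.points.mean(axis=0)
    radius = float(np.linalg.norm(cloud.points - center, axis=1).max())
    direction = rng.normal(size=(n_out, 3))
    direction /= np.linalg.norm(direction, axis=1)[:, None]
    r = radius * radius_scale * rng.uniform(0, 1, size=n_out) ** (1 / 3)
    extra = center + direction * r[:, None]
    return PointCloud(np.vstack([cloud.points, extra]),
                      source_path=cloud.source_path)


def random_dropout(cloud: PointCloud, fraction: float, seed: int = 0) -> PointCloud:
    """Remove a random fraction of points (stands in for occlusion)."""
    if not 0 <= fraction < 1:
        raise ValueError("dropout fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    keep = rng.random(cloud.n) >= fraction
    if not keep.any():
        keep[rng.integers(cloud.n)] = True
    return PointCloud(cloud.points[keep], source_path=cloud.source_path)


def study_spec(rng: np.random.Generator, plant_seed: int,
               point_spacing: float = 0.0025,
               noise_sigma: float = 0.001) -> PlantSpec:
    """Draw one plant of the synthetic study cohort.

    Plant-to-plant variation mimics a small field sample: tiller count 8-18,
    height 0.7-1.1 m, canopy radius 0.25-0.35 m, and a basal crown that
    widens with the tiller count (so stem girth genuinely varies across the
    cohort, as it does between real plants).
    """
    tillers = int(rng.integers(8, 19))
    return PlantSpec(
        tiller_count=tillers,
        height=float(rng.uniform(0.7, 1.1)),
        crown_radius=float(rng.uniform(0.25, 0.35)),
        basal_radius=0.040 + 0.010 * (tillers - 8) / 10.0,
        point_spacing=point_spacing,
        noise_sigma=noise_sigma,
        seed=plant_seed,
    )


def make_fixture_suite(out_dir, n_plants: int = 6, seed: int = 42,
                       point_spacing: float = 0.0025,
                       noise_sigma: float = 0.001,
                       cell_size: float = 0.01,
                       stem_z: float = 0.035,
                       binary: bool = True) -> pd.DataFrame:
    """Write ``n_plants`` PCD clouds plus a ground-truth manifest CSV.

    The manifest is the synthetic analogue of a manual measurement table and
    feeds the evaluation pipeline end-to-end. Plant-to-plant variation:
    tiller count 8-18, height 0.7-1.1 m, crown radius 0.25-0.35 m.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_plants):
        plant_seed = int((seed * 100003 + i * 7919) % (2 ** 31))
        spec = study_spec(rng, plant_seed, point_spacing=point_spacing,
                          noise_sigma=noise_sigma)
        cloud, truth = generate_plant(spec)
        fname = f"plant_{i:02d}.pcd"
        write_point_cloud(cloud, out / fname, format="pcd", binary=binary)
        rows.append({
            "file": fname,
            "tiller_count": truth.tiller_count,
            "height_m": truth.height,
            "crown_radius_m": truth.crown_radius,
            "stem_perimeter_m": truth.stem_perimeter_at(stem_z),
            "surface_area_m2": truth.reference_surface_area,
            "volume_m3": truth.reference_volume,
            "pla_pct": truth.reference_pla(cell_size),
            "seed": plant_seed,
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
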