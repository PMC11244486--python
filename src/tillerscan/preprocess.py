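"""Basic cloud processing: outlier filtering, base normalization, horizontal
slicing and XY projection.

These are the steps every trait extractor builds on: the scan is first
translated so the plant base sits at z = 0, cleaned with statistical outlier
removal (SOR), and then sliced or projected depending on the trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud_io import PointCloud
from .errors import EmptySliceError, FilterError

__all__ = [
    "SorParams",
    "SliceSpec",
    "Projection2D",
    "sor_filter",
    "normalize_base",
    "crop_below",
    "horizontal_slice",
    "project_xy",
]


@dataclass(frozen=True)
class SorParams:
    """Statistical-outlier-removal parameters.

    A point is kept when its mean distance to its ``k_neighbors`` nearest
    neighbors is at most mu + std_ratio * sigma, where mu and sigma are the
    mean and standard deviation of that statistic over the whole cloud.
    Defaults (20 neighbors, 2 standard deviations) are the conventional
    values of the point-cloud processing ecosystem.
    """

    k_neighbors: int = 20
    std_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be a positive integer")
        if self.std_ratio <= 0:
            raise ValueError("std_ratio must be positive")


@dataclass(frozen=True)
class SliceSpec:
    """A half-open vertical interval [z_min, z_max) in meters."""

    z_min: float
    z_max: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.z_min) and np.isfinite(self.z_max)):
            raise ValueError("slice bounds must be finite")
        if not self.z_min < self.z_max:
            raise ValueError(f"slice needs z_min < z_max, got [{self.z_min}, {self.z_max})")


@dataclass(frozen=True)
class Projection2D:
    """XY projection of a cloud with its centroid (the unweighted mean)."""

    points: np.ndarray       # (N, 2)
    centroid: tuple[float, float]
    n: int

    @classmethod
    def from_points(cls, xy: np.ndarray) -> "Projection2D":
        xy = np.asarray(xy, dtype=np.float64)
        if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 1:
            raise ValueError(f"projection needs an (N, 2) array, got {xy.shape}")
        c = xy.mean(axis=0)
        return cls(points=xy, centroid=(float(c[0]), float(c[1])), n=xy.shape[0])


def sor_filter(cloud: PointCloud, params: SorParams = SorParams(),
               return_mask: bool = False):
    """Statistical outlier removal.

    Keeps exactly the points whose mean k-nearest-neighbor distance is
    ``<= mu + std_ratio * sigma``. Raises :class:`FilterError` when the cloud
    has too few points for the neighbor count or when nothing survives.
    """
    n = cloud.n
    if n <= params.k_neighbors:
        raise FilterError(
            f"SOR needs more points ({n}) than k_neighbors ({params.k_neighbors})"
        )
    tree = cKDTree(cloud.points)
    # k+1 because the nearest neighbor of a point is itself
    dists, _ = tree.query(cloud.points, k=params.k_neighbors + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    threshold = mean_d.mean() + params.std_ratio * mean_d.std()
    mask = mean_d <= threshold
    if not mask.any():
        raise FilterError("SOR removed every point; check std_ratio")
    out = PointCloud(cloud.points[mask], source_path=cloud.source_path)
    if return_mask:
        return out, mask
    return out


def normalize_base(cloud: PointCloud) -> PointCloud:
    """Translate vertically so the lowest point sits at z = 0 (the reference
    point for plant height). XY is unchanged; idempotent."""
    z0 = cloud.points[:, 2].min()
    if z0 == 0.0:
        return cloud
    return PointCloud(cloud.points - np.array([0.0, 0.0, z0]),
                      source_path=cloud.source_path)


def crop_below(cloud: PointCloud, z_cut: float) -> PointCloud:
    """Drop every point with z < z_cut (manual root/pot removal helper)."""
    mask = cloud.points[:, 2] >= z_cut
    if not mask.any():
        lo, hi = cloud.z_extent()
        raise EmptySliceError(
            f"cropping below z={z_cut} removes all points (cloud z in [{lo:.4f}, {hi:.4f}])"
        )
    return PointCloud(cloud.points[mask], source_path=cloud.source_path)


def horizontal_slice(cloud: PointCloud, spec: SliceSpec) -> PointCloud:
    """Select the points with z_min <= z < z_max (half-open, so adjacent
    slices partition the cloud)."""
    z = cloud.points[:, 2]
    mask = (z >= spec.z_min) & (z < spec.z_max)
    if not mask.any():
        lo, hi = cloud.z_extent()
        raise EmptySliceError(
            f"slice [{spec.z_min}, {spec.z_max}) is empty; cloud z spans "
            f"[{lo:.4f}, {hi:.4f}]"
        )
    return PointCloud(cloud.points[mask], source_path=cloud.source_path)


def project_xy(cloud: PointCloud) -> Projection2D:
    """Project onto the horizontal plane, keeping every point, and record the
    centroid (arithmetic mean) used as the search center of the radius
    neighborhood algorithm."""
    return Projection2D.from_points(cloud.points[:, :2])
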