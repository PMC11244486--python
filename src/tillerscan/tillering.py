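"""Tiller counting by density clustering of a stem slice.

A rice plant's tillers appear in a low stem cross-section as compact,
well-separated tubes of points. The count is obtained by slicing the stem a
few centimeters above the base, cleaning the slice with statistical
filtering, and clustering it with HDBSCAN; the number of stable clusters is
the tiller number. Clustering runs on the 3D slice coordinates rather than
the 2D projection: the vertical continuity of a culm helps separate tubes
whose projections almost touch.

HDBSCAN operates on the mutual reachability distance

    d_k(p, q) = max(c_k(p), c_k(q), d(p, q))

where the core distance c_k(p) is the distance from p to its k-th nearest
neighbor. :func:`mutual_reachability` / :func:`mutual_reachability_matrix`
expose that metric directly so it can be checked against the library's
clustering behavior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import HDBSCAN

from .cloud_io import PointCloud
from .errors import FilterError, TillerscanError
from .preprocess import SliceSpec, SorParams, horizontal_slice, sor_filter

__all__ = [
    "HdbscanParams",
    "ClusterResult",
    "DEFAULT_TILLER_SLICE",
    "mutual_reachability",
    "mutual_reachability_matrix",
    "core_distances",
    "default_min_cluster_size",
    "cluster_stem_slice",
    "tiller_count",
]

# above root clutter (stems are measured ~3 cm above the base), below leaf
# emergence; 3 cm thick so each culm shows a dense vertical run
DEFAULT_TILLER_SLICE = SliceSpec(0.03, 0.06)

# used by the adaptive minimum cluster size: a rice plant rarely exceeds
# ~25 tillers, so a fifth of an even split is a conservative floor
EXPECTED_MAX_TILLERS = 25


@dataclass(frozen=True)
class HdbscanParams:
    """HDBSCAN tunables.

    ``min_cluster_size=None`` selects the adaptive default
    max(10, round(0.2 * N_slice / 25)), which scales with slice density.
    ``min_samples`` is the k of the core distance; the default of 5 keeps
    the core distance local enough to preserve the density valley between
    adjacent culm tubes (larger k smooths over it and merges neighbors).
    """

    min_cluster_size: int | None = None
    min_samples: int = 5
    cluster_selection: Literal["excess_of_mass", "leaf"] = "excess_of_mass"
    merge_radius: float = 0.006

    def __post_init__(self) -> None:
        if self.min_cluster_size is not None and self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.cluster_selection not in ("excess_of_mass", "leaf"):
            raise ValueError("cluster_selection must be excess_of_mass or leaf")
        if self.merge_radius < 0:
            raise ValueError("merge_radius must be >= 0")


@dataclass(frozen=True)
class ClusterResult:
    """Per-point labels (-1 = noise) and the cluster count."""

    labels: np.ndarray
    n_clusters: int
    noise_count: int


def mutual_reachability(p, q, core_p: float, core_q: float) -> float:
    """max(c_k(p), c_k(q), d(p, q)) for a single pair."""
    d = float(np.linalg.norm(np.asarray(p, float) - np.asarray(q, float)))
    return max(float(core_p), float(core_q), d)


def core_distances(points: np.ndarray, k: int) -> np.ndarray:
    """Distance from each point to its k-th nearest neighbor (self excluded)."""
    points = np.asarray(points, dtype=np.float64)
    if k >= points.shape[0]:
        raise TillerscanError(
            f"core distance needs k ({k}) < number of points ({points.shape[0]})"
        )
    tree = cKDTree(points)
    d, _ = tree.query(points, k=k + 1)
    return d[:, k]


def mutual_reachability_matrix(points: np.ndarray, k: int) -> np.ndarray:
    """Full pairwise mutual-reachability matrix (the metric HDBSCAN builds
    its minimum spanning tree in). The diagonal equals each point's core
    distance, since d(p, p) = 0."""
    points = np.asarray(points, dtype=np.float64)
    core = core_distances(points, k)
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    return np.maximum(dist, np.maximum(core[:, None], core[None, :]))


def default_min_cluster_size(n_slice: int) -> int:
    return max(10, round(0.2 * n_slice / EXPECTED_MAX_TILLERS))


def cluster_stem_slice(slice_cloud: PointCloud,
                       params: HdbscanParams = HdbscanParams()) -> ClusterResult:
    """HDBSCAN clustering of a stem slice; deterministic for fixed input."""
    pts = slice_cloud.points
    mcs = params.min_cluster_size or default_min_cluster_size(pts.shape[0])
    if pts.shape[0] <= mcs:
        raise TillerscanError(
            f"stem slice has {pts.shape[0]} points, need more than "
            f"min_cluster_size = {mcs}"
        )
    def _fit(allow_single: bool) -> np.ndarray:
        model = HDBSCAN(
            min_cluster_size=mcs,
            min_samples=min(params.min_samples, pts.shape[0] - 1),
            cluster_selection_method={"excess_of_mass": "eom",
                                      "leaf": "leaf"}[params.cluster_selection],
            allow_single_cluster=allow_single,
            copy=True,
        )
        return model.fit(pts).labels_.astype(np.int64)

    labels = _fit(allow_single=False)
    if labels.max() < 0:
        # Excess-of-mass never selects the hierarchy root, so a slice that
        # is one dense tuft (a single-tiller plant) can come back all-noise.
        # Retry allowing the root; accept the single cluster only when it
        # actually captures most of the slice — a diffuse scatter with no
        # density structure stays at zero tillers.
        single = _fit(allow_single=True)
        if single.max() == 0 and (single == 0).sum() >= 0.5 * pts.shape[0]:
            labels = single
    labels = _merge_coaxial_clusters(pts, labels, params.merge_radius)
    n_clusters = int(len(set(labels[labels >= 0])))
    return ClusterResult(labels=labels, n_clusters=n_clusters,
                         noise_count=int((labels == -1).sum()))


def _merge_coaxial_clusters(pts: np.ndarray, labels: np.ndarray,
                            merge_radius: float) -> np.ndarray:
    """Merge clusters whose horizontal centroids nearly coincide.

    A tiller is a distinct stem position in the horizontal plane. Density
    clustering of a sparse tube occasionally splits one culm into vertically
    stacked segments that share the same XY location (the hierarchy root is
    never selectable, so an isolated culm is always returned as its
    sub-segments); such co-axial fragments are one tiller, while true
    neighboring culms sit at least a couple of centimeters apart.
    """
    ids = np.unique(labels[labels >= 0])
    if merge_radius <= 0 or ids.size <= 1:
        return labels
    centroids = np.vstack([pts[labels == i, :2].mean(axis=0) for i in ids])
    # single-linkage union of centroids within the merge radius
    parent = np.arange(ids.size)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(ids.size):
        for b in range(a + 1, ids.size):
            if np.hypot(*(centroids[a] - centroids[b])) < merge_radius:
                parent[find(b)] = find(a)
    roots = {i: find(i) for i in range(ids.size)}
    compact = {r: k for k, r in enumerate(sorted(set(roots.values())))}
    out = labels.copy()
    for idx, cluster_id in enumerate(ids):
        out[labels == cluster_id] = compact[roots[idx]]
    return out


def tiller_count(plant: PointCloud,
                 slice_spec: SliceSpec = DEFAULT_TILLER_SLICE,
                 sor: SorParams | None = SorParams(),
                 params: HdbscanParams = HdbscanParams(),
                 return_clusters: bool = False):
    """Slice -> statistical filter -> density clustering -> cluster count.

    Noise points do not count toward any tiller; zero clusters is reported as
    a count of 0, not an error.
    """
    sl = horizontal_slice(plant, slice_spec)
    if sor is not None:
        try:
            sl = sor_filter(sl, sor)
        except FilterError:
            # slices thinner than the neighbor count are used as-is
            pass
    result = cluster_stem_slice(sl, params)
    if return_clusters:
        return result.n_clusters, result, sl
    return result.n_clusters


def export_cluster_labels(slice_cloud: PointCloud, result: ClusterResult,
                          path) -> None:
    """Write x,y,z,label CSV for cluster visualization."""
    data = np.column_stack([slice_cloud.points, result.labels])
    np.savetxt(path, data, fmt=["%.6f", "%.6f", "%.6f", "%d"],
               delimiter=",", header="x,y,z,label", comments="")
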