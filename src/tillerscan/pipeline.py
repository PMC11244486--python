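"""End-to-end trait extraction: read -> normalize -> filter -> per-trait
operations -> result record.

:class:`ExtractionConfig` gathers every tunable of the pipeline with its
documented default; :func:`extract_phenotypes` runs the extraction on one
cloud and embeds the full parameter record in the result, so any output can
be re-derived deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .cloud_io import PhenotypeResult, PointCloud
from .preprocess import (SliceSpec, SorParams, crop_below, horizontal_slice,
                         normalize_base, project_xy, sor_filter)
from .projection_metrics import GridSpec, projected_leaf_area
from .radius_search import (RadiusSearchParams, crown_radius, plant_height,
                            stem_perimeter)
from .surface_volume import (AlphaSweepParams, alpha_shape_mesh, auto_alpha,
                             convex_hull_volume, mesh_surface_area)
from .tillering import (DEFAULT_TILLER_SLICE, HdbscanParams, tiller_count)

__all__ = ["ExtractionConfig", "ALL_TRAITS", "BASIC_TRAITS", "extract_phenotypes"]

ALL_TRAITS = ("crown_radius", "stem_perimeter", "plant_height",
              "surface_area", "volume", "pla", "tiller_count")
# the traits that avoid surface reconstruction (cheap on large clouds)
BASIC_TRAITS = ("crown_radius", "stem_perimeter", "plant_height",
                "pla", "tiller_count")


@dataclass
class ExtractionConfig:
    """Every tunable of the pipeline.

    ``alpha`` is either a probe-ball radius in meters or the string "auto",
    which sweeps :class:`AlphaSweepParams` for the smallest alpha giving a
    single well-covered component.
    """

    stem_slice: SliceSpec = field(default_factory=lambda: SliceSpec(0.03, 0.04))
    tiller_slice: SliceSpec = field(default_factory=lambda: DEFAULT_TILLER_SLICE)
    crown_search: RadiusSearchParams = field(
        default_factory=lambda: RadiusSearchParams(step=0.02))
    stem_search: RadiusSearchParams = field(
        default_factory=lambda: RadiusSearchParams(step=0.005))
    alpha: float | str = "auto"
    alpha_sweep: AlphaSweepParams = field(default_factory=AlphaSweepParams)
    grid: GridSpec = field(default_factory=GridSpec)
    sor: SorParams = field(default_factory=SorParams)
    hdbscan: HdbscanParams = field(default_factory=HdbscanParams)
    unit_scale: float = 1.0
    crop_below_z: float | None = None
    apply_sor: bool = True
    seed: int = 0

    def params_record(self) -> dict:
        rec = {
            "stem_slice": [self.stem_slice.z_min, self.stem_slice.z_max],
            "tiller_slice": [self.tiller_slice.z_min, self.tiller_slice.z_max],
            "crown_search": self.crown_search.as_dict(),
            "stem_search": self.stem_search.as_dict(),
            "alpha": self.alpha,
            "alpha_sweep": {
                "alpha_min": self.alpha_sweep.alpha_min,
                "alpha_step": self.alpha_sweep.alpha_step,
                "alpha_max": self.alpha_sweep.alpha_max,
                "min_component_share": self.alpha_sweep.min_component_share,
            },
            "grid_cell_size": self.grid.cell_size,
            "sor": {"k_neighbors": self.sor.k_neighbors,
                    "std_ratio": self.sor.std_ratio,
                    "applied": self.apply_sor},
            "hdbscan": {"min_cluster_size": self.hdbscan.min_cluster_size,
                        "min_samples": self.hdbscan.min_samples,
                        "cluster_selection": self.hdbscan.cluster_selection,
                        "merge_radius": self.hdbscan.merge_radius},
            "unit_scale": self.unit_scale,
            "crop_below_z": self.crop_below_z,
            "seed": self.seed,
        }
        return rec


def extract_phenotypes(cloud: PointCloud,
                       config: ExtractionConfig | None = None,
                       traits: Sequence[str] = ALL_TRAITS) -> PhenotypeResult:
    """Extract the requested traits from one plant cloud.

    The cloud is normalized so its base sits at z = 0, optionally cropped,
    cleaned with SOR, and then each trait runs on the shared intermediates
    (stem-slice centroid, XY projection).
    """
    config = config or ExtractionConfig()
    unknown = set(traits) - set(ALL_TRAITS)
    if unknown:
        raise ValueError(f"unknown traits {sorted(unknown)}; valid: {ALL_TRAITS}")

    if config.unit_scale != 1.0:
        cloud = cloud.scaled(config.unit_scale)
    cloud = normalize_base(cloud)
    if config.crop_below_z is not None:
        cloud = normalize_base(crop_below(cloud, config.crop_below_z))
    if config.apply_sor:
        cloud = sor_filter(cloud, config.sor)

    result = PhenotypeResult(params_used=config.params_record(),
                             source=cloud.source_path)

    stem_centroid = None
    if {"crown_radius", "stem_perimeter"} & set(traits):
        stem = horizontal_slice(cloud, config.stem_slice)
        stem_proj = project_xy(stem)
        stem_centroid = stem_proj.centroid
        if "stem_perimeter" in traits:
            result.stem_perimeter = stem_perimeter(stem, config.stem_search)
    if "crown_radius" in traits:
        result.crown_radius = crown_radius(cloud, stem_centroid,
                                           config.crown_search)
    if "plant_height" in traits:
        result.plant_height = plant_height(cloud)
    if "pla" in traits:
        result.pla = projected_leaf_area(project_xy(cloud), config.grid).pla
    if "surface_area" in traits:
        if config.alpha == "auto":
            alpha = auto_alpha(cloud, config.alpha_sweep)
        else:
            alpha = float(config.alpha)
        mesh = alpha_shape_mesh(cloud, alpha)
        result.surface_area = mesh_surface_area(mesh)
        result.params_used["alpha_used"] = mesh.alpha_used
    if "volume" in traits:
        result.volume = convex_hull_volume(cloud)
    if "tiller_count" in traits:
        result.tiller_count = tiller_count(
            cloud, config.tiller_slice,
            config.sor if config.apply_sor else None,
            config.hdbscan,
        )
    return result
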