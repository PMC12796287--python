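"""Cell-type vocabularies and spatial-analysis configuration.

Segmentation toolkits emit nuclei with one of eight merged cell-type labels
(three epithelial subtypes, inflammatory cells, lymphocytes, neutrophils,
connective cells and dead cells).  Composition features are computed on the
full eight-type vocabulary; spatial features operate on a coarser grouping of
five labels in which sparse subtypes are folded into their parent class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

BASE_TYPES: tuple[str, ...] = (
    "neoplastic_epithelial",
    "non_neoplastic_epithelial",
    "uncategorized_epithelial",
    "inflammatory",
    "lymphocyte",
    "neutrophil",
    "connective",
    "dead",
)

SPATIAL_GROUPS: tuple[str, ...] = (
    "epithelial",
    "inflammatory",
    "lymphocyte",
    "connective",
    "dead",
)

#: Default folding of the 8 base types into 5 spatial groups: the three
#: epithelial subtypes merge, neutrophils join the inflammatory class, and
#: lymphocytes, connective and dead cells stand alone.  This grouping is a
#: package default and is fully configurable.
DEFAULT_GROUP_MAP: Mapping[str, str] = {
    "neoplastic_epithelial": "epithelial",
    "non_neoplastic_epithelial": "epithelial",
    "uncategorized_epithelial": "epithelial",
    "inflammatory": "inflammatory",
    "neutrophil": "inflammatory",
    "lymphocyte": "lymphocyte",
    "connective": "connective",
    "dead": "dead",
}


@dataclass(frozen=True)
class CellTypeScheme:
    """Base cell-type vocabulary plus its folding into spatial groups.

    Parameters
    ----------
    base_types:
        Ordered labels of the fine-grained vocabulary (8 by default).
    group_map:
        Total mapping from every base type to a spatial-group label.
    spatial_groups:
        Ordered labels of the coarse vocabulary (5 by default); must equal
        the image of ``group_map``.
    """

    base_types: tuple[str, ...] = BASE_TYPES
    group_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUP_MAP))
    spatial_groups: tuple[str, ...] = SPATIAL_GROUPS

    def __post_init__(self) -> None:
        missing = [t for t in self.base_types if t not in self.group_map]
        if missing:
            raise ValueError(f"group_map is not total; missing base types: {missing}")
        image = {self.group_map[t] for t in self.base_types}
        if image != set(self.spatial_groups):
            raise ValueError(
                f"image of group_map {sorted(image)} != spatial_groups "
                f"{sorted(self.spatial_groups)}"
            )
        if len(set(self.base_types)) != len(self.base_types):
            raise ValueError("duplicate base type labels")
        if len(set(self.spatial_groups)) != len(self.spatial_groups):
            raise ValueError("duplicate spatial group labels")

    @classmethod
    def default(cls) -> "CellTypeScheme":
        return cls()


@dataclass(frozen=True)
class SpatialConfig:
    """Tunable parameters of the spatial feature extractors.

    Attributes
    ----------
    iqr_multiplier:
        Tukey inner-fence multiplier for Voronoi-area outlier exclusion.
    diversity_radius:
        Euclidean radius (coordinate units, i.e. pixels) defining the
        neighborhood for the Shannon diversity index.
    max_neighbors:
        Cap on neighbors entering a diversity neighborhood.
    log_base:
        Base of the Shannon logarithm; ``None`` means natural log.
    voronoi_scope:
        ``"per_type"`` tessellates each spatial group's points separately;
        ``"pooled"`` tessellates all nuclei together and attributes cells to
        their seed's group.
    min_points:
        Below this many points (or fence survivors) a per-group geometric
        feature is reported missing.
    knn_summary:
        Summary statistic over per-nucleus k-th neighbor distances used by
        the distance-threshold derivation: ``"mean"`` or ``"median"``.
    """

    iqr_multiplier: float = 1.5
    diversity_radius: float = 100.0
    max_neighbors: int = 15
    log_base: float | None = None
    voronoi_scope: str = "per_type"
    min_points: int = 4
    knn_summary: str = "mean"

    def __post_init__(self) -> None:
        if self.iqr_multiplier <= 0:
            raise ValueError("iqr_multiplier must be > 0")
        if self.diversity_radius <= 0:
            raise ValueError("diversity_radius must be > 0")
        if self.max_neighbors < 1:
            raise ValueError("max_neighbors must be >= 1")
        if self.voronoi_scope not in ("per_type", "pooled"):
            raise ValueError("voronoi_scope must be 'per_type' or 'pooled'")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")
        if self.knn_summary not in ("mean", "median"):
            raise ValueError("knn_summary must be 'mean' or 'median'")
        if self.log_base is not None and self.log_base <= 1:
            raise ValueError("log_base must be > 1")

    def log(self, x):
        """Logarithm in the configured base (natural when log_base is None)."""
        import numpy as np

        if self.log_base is None:
            return np.log(x)
        return np.log(x) / math.log(self.log_base)
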