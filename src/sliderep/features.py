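"""Composition and spatial features of a single slide's nuclei table.

A nuclei table is a :class:`pandas.DataFrame` with columns ``nucleus_id``,
``x``, ``y`` and ``cell_type`` (one row per segmented nucleus, coordinates in
pixels, origin top-left).  From it the extractor derives

* 16 composition features: a count and a proportion per base cell type;
* 15 tessellation features: the coefficient of variation of Voronoi polygon
  areas per spatial group (5) and the mean and standard deviation of Delaunay
  edge lengths per spatial group (10);
* 25 neighborhood features: the 5x5 matrix counting, for every nucleus, the
  spatial group of its single nearest neighbor;
* 5 diversity features: the mean Shannon index of the cell-type mix in each
  nucleus's capped neighborhood (radius ``diversity_radius``, at most
  ``max_neighbors`` neighbors), averaged per center group.

Unbounded Voronoi regions at the tissue periphery are dropped and the
remaining areas filtered by Tukey's inner fence (quartiles +/- 1.5 IQR) before
the CV is computed.  Per-group features for groups with too few points are
reported missing (NaN), never silently zero.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, KDTree, QhullError, Voronoi

from .schemes import CellTypeScheme, SpatialConfig

logger = logging.getLogger(__name__)

NUCLEI_COLUMNS = ("nucleus_id", "x", "y", "cell_type")

# relative tolerance used when declaring two neighbor distances tied
_TIE_RTOL = 1e-9


def validate_nuclei(table: pd.DataFrame, scheme: CellTypeScheme | None = None) -> pd.DataFrame:
    """Validate a nuclei table and return it (unchanged) on success.

    Checks column presence, finiteness of coordinates, uniqueness of
    ``nucleus_id`` and, when a scheme is given, membership of every label in
    the base vocabulary.  Duplicate coordinates are permitted but flagged
    with a warning.
    """
    missing = [c for c in NUCLEI_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"nuclei table missing columns: {missing}")
    xy = table[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        bad = np.nonzero(~np.isfinite(xy).all(axis=1))[0]
        raise ValueError(f"non-finite coordinates at rows {bad[:5].tolist()}")
    if table["nucleus_id"].duplicated().any():
        dup = table.loc[table["nucleus_id"].duplicated(), "nucleus_id"].iloc[0]
        raise ValueError(f"duplicate nucleus_id {dup!r}")
    if scheme is not None:
        unknown = set(table["cell_type"]) - set(scheme.base_types)
        if unknown:
            rows = table.index[table["cell_type"].isin(unknown)][:5].tolist()
            raise ValueError(
                f"unknown cell_type label(s) {sorted(unknown)} (rows {rows})"
            )
    if len(table) and table.duplicated(subset=["x", "y"]).any():
        logger.warning("nuclei table contains duplicate coordinates")
    return table


def count_by_type(table: pd.DataFrame, scheme: CellTypeScheme) -> pd.Series:
    """Nuclei counts per base cell type (absent types reported as 0)."""
    validate_nuclei(table, scheme)
    counts = table["cell_type"].value_counts()
    out = pd.Series(0, index=list(scheme.base_types), dtype=int)
    out.update(counts)
    return out.astype(int)


def proportions(counts: pd.Series) -> pd.Series:
    """Per-type proportions; all-missing (NaN) when the total count is zero."""
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        logger.warning("empty slide: proportions undefined")
        return pd.Series(np.nan, index=counts.index, dtype=float)
    return counts / total


def group_types(table: pd.DataFrame, scheme: CellTypeScheme) -> pd.DataFrame:
    """Replace base cell types by their spatial-group label (rows preserved)."""
    unmapped = set(table["cell_type"]) - set(scheme.group_map)
    if unmapped:
        raise ValueError(f"unmapped cell_type label(s): {sorted(unmapped)}")
    out = table.copy()
    out["cell_type"] = out["cell_type"].map(scheme.group_map)
    return out


def _polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a polygon given by its vertices in order."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _finite_voronoi_areas(points: np.ndarray) -> np.ndarray:
    """Areas of bounded Voronoi cells, aligned with the subset of seeds that
    own one; unbounded peripheral cells are dropped."""
    vor = Voronoi(points)
    areas = []
    for point_idx, region_idx in enumerate(vor.point_region):
        region = vor.regions[region_idx]
        if len(region) == 0 or -1 in region:
            continue  # unbounded cell at the periphery
        areas.append(_polygon_area(vor.vertices[region]))
    return np.asarray(areas, dtype=float)


def tukey_fence_filter(values: np.ndarray, multiplier: float = 1.5) -> np.ndarray:
    """Keep values inside [Q1 - m*IQR, Q3 + m*IQR] (Tukey's inner fence)."""
    values = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    return values[(values >= lo) & (values <= hi)]


def _voronoi_cv_one(areas: np.ndarray, config: SpatialConfig) -> float:
    kept = tukey_fence_filter(areas, config.iqr_multiplier)
    if len(kept) < config.min_points:
        return np.nan
    mean = kept.mean()
    if mean == 0:
        return np.nan
    return kept.std(ddof=1) / mean


def voronoi_area_cv(
    grouped: pd.DataFrame, scheme: CellTypeScheme, config: SpatialConfig
) -> pd.Series:
    """CV of (Tukey-filtered, bounded) Voronoi polygon areas per spatial group.

    ``voronoi_scope="per_type"`` tessellates each group's points separately;
    ``"pooled"`` tessellates all nuclei and attributes each bounded cell to
    its seed's group.  Groups with fewer than ``min_points`` usable areas are
    missing.
    """
    out = pd.Series(np.nan, index=list(scheme.spatial_groups), dtype=float)
    if config.voronoi_scope == "per_type":
        for group in scheme.spatial_groups:
            pts = grouped.loc[grouped["cell_type"] == group, ["x", "y"]].to_numpy(float)
            if len(pts) < max(4, config.min_points):
                continue
            try:
                areas = _finite_voronoi_areas(pts)
            except QhullError:
                logger.info("degenerate Voronoi input for group %s", group)
                continue
            if len(areas):
                out[group] = _voronoi_cv_one(areas, config)
    else:  # pooled
        pts = grouped[["x", "y"]].to_numpy(float)
        if len(pts) < 4:
            return out
        try:
            vor = Voronoi(pts)
        except QhullError:
            return out
        labels = grouped["cell_type"].to_numpy()
        per_group: dict[str, list[float]] = {g: [] for g in scheme.spatial_groups}
        for i, region_idx in enumerate(vor.point_region):
            region = vor.regions[region_idx]
            if len(region) == 0 or -1 in region:
                continue
            per_group[labels[i]].append(_polygon_area(vor.vertices[region]))
        for group, areas in per_group.items():
            if len(areas) >= config.min_points:
                out[group] = _voronoi_cv_one(np.asarray(areas), config)
    return out


def delaunay_edges(points: np.ndarray) -> np.ndarray:
    """Unique undirected edges (index pairs) of the Delaunay triangulation."""
    tri = Delaunay(points)
    edges = set()
    for simplex in tri.simplices:
        a, b, c = sorted(simplex)
        edges.update([(a, b), (a, c), (b, c)])
    return np.array(sorted(edges), dtype=int)


def delaunay_edge_stats(
    grouped: pd.DataFrame, scheme: CellTypeScheme, config: SpatialConfig
) -> tuple[pd.Series, pd.Series]:
    """Mean and sample SD of Delaunay edge lengths per spatial group.

    Collinear or too-small (<3 points) groups are missing.
    """
    means = pd.Series(np.nan, index=list(scheme.spatial_groups), dtype=float)
    sds = pd.Series(np.nan, index=list(scheme.spatial_groups), dtype=float)
    for group in scheme.spatial_groups:
        pts = grouped.loc[grouped["cell_type"] == group, ["x", "y"]].to_numpy(float)
        if len(pts) < 3:
            continue
        try:
            edges = delaunay_edges(pts)
        except QhullError:
            logger.info("degenerate Delaunay input (collinear?) for group %s", group)
            continue
        lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
        means[group] = lengths.mean()
        sds[group] = lengths.std(ddof=1) if len(lengths) > 1 else 0.0
    return means, sds


def _nearest_other(table: pd.DataFrame) -> np.ndarray:
    """Index (positional) of each nucleus's nearest other nucleus.

    Exact search; distance ties are broken by the smallest ``nucleus_id`` of
    the tied candidates.
    """
    pts = table[["x", "y"]].to_numpy(float)
    ids = table["nucleus_id"].to_numpy()
    n = len(pts)
    tree = KDTree(pts)
    k = min(n, 16)
    dist, idx = tree.query(pts, k=k)
    nearest = np.empty(n, dtype=int)
    for i in range(n):
        d_i, j_i = dist[i], idx[i]
        mask = j_i != i  # exclude self (duplicates of self's coords remain)
        d_i, j_i = d_i[mask], j_i[mask]
        best = d_i[0]
        tied = j_i[d_i <= best * (1 + _TIE_RTOL) + 1e-300]
        if len(tied) == 1:
            nearest[i] = tied[0]
        else:
            nearest[i] = tied[np.argmin([ids[j] for j in tied])]
    return nearest


def nn_count_matrix(grouped: pd.DataFrame, scheme: CellTypeScheme) -> pd.DataFrame:
    """5x5 matrix of nearest-neighbor counts between spatial groups.

    Entry [g, h] counts nuclei of group g whose single nearest other nucleus
    belongs to group h.  Row sums therefore equal per-group nucleus counts.
    With fewer than two nuclei the matrix is all zero (warned).
    """
    groups = list(scheme.spatial_groups)
    mat = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    if len(grouped) < 2:
        logger.warning("nn_count_matrix: fewer than 2 nuclei; all-zero matrix")
        return mat
    nearest = _nearest_other(grouped)
    labels = grouped["cell_type"].to_numpy()
    gi = {g: i for i, g in enumerate(groups)}
    rows = np.fromiter((gi[g] for g in labels), dtype=int, count=len(labels))
    cols = rows[nearest]
    counts = np.zeros((len(groups), len(groups)), dtype=int)
    np.add.at(counts, (rows, cols), 1)
    return pd.DataFrame(counts, index=groups, columns=groups)


def neighbor_sets(
    table: pd.DataFrame, radius: float, max_neighbors: int
) -> list[np.ndarray]:
    """Per-nucleus neighbor sets: up to ``max_neighbors`` nearest other nuclei
    within ``radius`` (positional indices), distance-ordered with ties broken
    by nucleus_id."""
    pts = table[["x", "y"]].to_numpy(float)
    ids = table["nucleus_id"].to_numpy()
    n = len(pts)
    tree = KDTree(pts)
    out: list[np.ndarray] = []
    lists = tree.query_ball_point(pts, r=radius)
    for i in range(n):
        cand = [j for j in lists[i] if j != i]
        if not cand:
            out.append(np.empty(0, dtype=int))
            continue
        d = np.linalg.norm(pts[cand] - pts[i], axis=1)
        order = sorted(range(len(cand)), key=lambda t: (d[t], ids[cand[t]]))
        out.append(np.array([cand[t] for t in order[:max_neighbors]], dtype=int))
    return out


def shannon_diversity(
    grouped: pd.DataFrame, scheme: CellTypeScheme, config: SpatialConfig
) -> pd.Series:
    """Mean Shannon diversity of neighborhood composition per center group.

    For each nucleus, H = -sum_g p_g log p_g over the spatial-group mix of its
    neighbor set (radius- and count-capped); nuclei with empty neighbor sets
    are excluded from the group mean.  Natural log unless configured.
    """
    groups = list(scheme.spatial_groups)
    out = pd.Series(np.nan, index=groups, dtype=float)
    n = len(grouped)
    if n == 0:
        return out
    sets = neighbor_sets(grouped, config.diversity_radius, config.max_neighbors)
    labels = grouped["cell_type"].to_numpy()
    gi = {g: i for i, g in enumerate(groups)}
    lab_idx = np.fromiter((gi[g] for g in labels), dtype=int, count=n)
    h = np.full(n, np.nan)
    for i, nb in enumerate(sets):
        if len(nb) == 0:
            continue
        counts = np.bincount(lab_idx[nb], minlength=len(groups)).astype(float)
        p = counts[counts > 0] / counts.sum()
        h[i] = float(-(p * config.log(p)).sum())
    for g in groups:
        vals = h[(lab_idx == gi[g]) & ~np.isnan(h)]
        if len(vals):
            out[g] = vals.mean()
    return out


def distance_for_k_neighbors(
    table: pd.DataFrame, k: int, summary: str = "mean"
) -> float:
    """Summary over nuclei of the distance to the k-th nearest neighbor.

    This is the procedure used to derive a radius threshold guaranteeing
    (on average) at least k neighbors per nucleus.
    """
    n = len(table)
    if n <= k:
        raise ValueError(f"table size {n} must exceed k={k}")
    pts = table[["x", "y"]].to_numpy(float)
    tree = KDTree(pts)
    dist, _ = tree.query(pts, k=k + 1)
    kth = dist[:, k]
    if summary == "mean":
        return float(kth.mean())
    if summary == "median":
        return float(np.median(kth))
    raise ValueError(f"unknown summary {summary!r}")


def feature_names(scheme: CellTypeScheme) -> list[str]:
    """Canonical feature ordering: count.*, prop.*, vor_cv.*, del_mean.*,
    del_sd.*, nn.<center>.<neighbor>, shannon.*"""
    names = [f"count.{t}" for t in scheme.base_types]
    names += [f"prop.{t}" for t in scheme.base_types]
    names += [f"vor_cv.{g}" for g in scheme.spatial_groups]
    names += [f"del_mean.{g}" for g in scheme.spatial_groups]
    names += [f"del_sd.{g}" for g in scheme.spatial_groups]
    names += [
        f"nn.{a}.{b}" for a in scheme.spatial_groups for b in scheme.spatial_groups
    ]
    names += [f"shannon.{g}" for g in scheme.spatial_groups]
    return names


def extract_all_features(
    table: pd.DataFrame,
    scheme: CellTypeScheme | None = None,
    config: SpatialConfig | None = None,
) -> pd.Series:
    """All 61 features (16 composition + 45 spatial) of one slide.

    Missingness propagates as NaN; feature order is deterministic and
    independent of record order.
    """
    scheme = scheme or CellTypeScheme.default()
    config = config or SpatialConfig()
    counts = count_by_type(table, scheme)
    props = proportions(counts)
    grouped = group_types(table, scheme)
    vor = voronoi_area_cv(grouped, scheme, config)
    del_mean, del_sd = delaunay_edge_stats(grouped, scheme, config)
    nn = nn_count_matrix(grouped, scheme)
    sh = shannon_diversity(grouped, scheme, config)

    values: dict[str, float] = {}
    for t in scheme.base_types:
        values[f"count.{t}"] = float(counts[t])
    for t in scheme.base_types:
        values[f"prop.{t}"] = float(props[t])
    for g in scheme.spatial_groups:
        values[f"vor_cv.{g}"] = float(vor[g])
    for g in scheme.spatial_groups:
        values[f"del_mean.{g}"] = float(del_mean[g])
    for g in scheme.spatial_groups:
        values[f"del_sd.{g}"] = float(del_sd[g])
    for a in scheme.spatial_groups:
        for b in scheme.spatial_groups:
            values[f"nn.{a}.{b}"] = float(nn.loc[a, b])
    for g in scheme.spatial_groups:
        values[f"shannon.{g}"] = float(sh[g])
    return pd.Series(values, index=feature_names(scheme), dtype=float)


def extract_cohort_features(
    tables: Mapping[tuple[str, str], pd.DataFrame],
    scheme: CellTypeScheme | None = None,
    config: SpatialConfig | None = None,
) -> pd.DataFrame:
    """Feature table for a cohort: one row per (sample_id, section) slide."""
    rows = {}
    for (sample_id, section), table in tables.items():
        rows[(sample_id, section)] = extract_all_features(table, scheme, config)
    out = pd.DataFrame(rows).T
    out.index.names = ["sample_id", "section"]
    return out
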