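"""Distribution-level comparison of slide tile-embedding sets.

Each slide is represented by an m x d matrix of tile embeddings from a
pretrained vision encoder.  Two slides are compared as empirical
distributions over R^d:

* **MMD** — the unbiased (diagonal-excluded) squared maximum mean
  discrepancy with a Gaussian (RBF) kernel whose bandwidth defaults to the
  median pairwise distance of the pooled tiles (median heuristic).
* **Wasserstein** — by default the sliced distance: the Monte-Carlo average
  over random unit projections of the 1-D order-2 Wasserstein distance
  between projected tile sets; an exact assignment-based variant on
  (sub-sampled) equal-size point clouds is also available.

From the slide-by-slide distance matrix, related pairs (sections of the same
sample) are compared against unrelated pairs (cross-sample) via medians and a
one-sided permutation test that shuffles the slide-to-sample assignment.

Before metric computation the embeddings may be reduced to a common lower
dimension with a single reducer fitted on the pooled cohort tiles; reduction
quality is assessed by trustworthiness, pairwise-distance monotonicity and
inter-slide MMD across candidate dimensions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist
from sklearn import manifold
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingSet:
    """Per-slide tile-embedding matrices with slide-to-sample labels."""

    slide_ids: list[str]
    sample_ids: list[str]
    sections: list[str]
    matrices: list[np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.slide_ids)
        if not (len(self.sample_ids) == len(self.sections) == len(self.matrices) == n):
            raise ValueError("parallel lists must have equal length")
        dims = {m.shape[1] for m in self.matrices}
        if len(dims) > 1:
            raise ValueError(f"inconsistent embedding dimensions: {sorted(dims)}")
        for sid, m in zip(self.slide_ids, self.matrices):
            if m.shape[0] < 2:
                raise ValueError(f"slide {sid}: need >= 2 tiles")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"slide {sid}: non-finite embedding values")

    @property
    def d(self) -> int:
        return self.matrices[0].shape[1]

    @property
    def n_slides(self) -> int:
        return len(self.slide_ids)

    def pooled(self) -> np.ndarray:
        return np.vstack(self.matrices)


@dataclass
class DistanceMatrix:
    """Symmetric slide x slide metric matrix with provenance."""

    values: np.ndarray
    slide_ids: list[str]
    sample_ids: list[str]
    sections: list[str]
    metric: str
    params: dict = field(default_factory=dict)
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.slide_ids, columns=self.slide_ids)


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    n_perm: int
    seed: int
    alternative: str
    n_related: int
    n_unrelated: int


@dataclass
class ReductionDiagnostics:
    candidate_dims: list[int]
    trustworthiness: list[float]
    monotonicity: list[float]
    inter_slide_mmd: list[float]
    chosen_dim: int


# ---------------------------------------------------------------------------
# metrics


def median_heuristic_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """Median pairwise Euclidean distance of the pooled sample."""
    pooled = np.vstack([x, y])
    d = pdist(pooled)
    return float(np.median(d))


@dataclass
class MMDResult:
    value: float  # sqrt(max(mmd2, 0))
    mmd2: float
    bandwidth: float


def mmd_rbf(x: np.ndarray, y: np.ndarray, bandwidth: float | None = None) -> MMDResult:
    """Unbiased squared MMD with a Gaussian kernel.

    ``k(a, b) = exp(-||a-b||^2 / (2 s^2))`` with ``s`` the median-heuristic
    bandwidth unless given.  The unbiased estimator excludes the diagonal of
    the within-sample kernel sums and may be negative; both the raw MMD^2 and
    ``sqrt(max(MMD^2, 0))`` are reported.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    m, n = len(x), len(y)
    if m < 2 or n < 2:
        raise ValueError("need >= 2 rows in each sample")
    if bandwidth is None:
        bandwidth = median_heuristic_bandwidth(x, y)
    if bandwidth <= 0:
        raise ValueError("zero bandwidth: all pooled points identical")
    g = 1.0 / (2.0 * bandwidth**2)
    kxx = np.exp(-g * cdist(x, x, "sqeuclidean"))
    kyy = np.exp(-g * cdist(y, y, "sqeuclidean"))
    kxy = np.exp(-g * cdist(x, y, "sqeuclidean"))
    sxx = (kxx.sum() - np.trace(kxx)) / (m * (m - 1))
    syy = (kyy.sum() - np.trace(kyy)) / (n * (n - 1))
    sxy = kxy.mean()
    mmd2 = float(sxx + syy - 2.0 * sxy)
    return MMDResult(value=float(np.sqrt(max(mmd2, 0.0))), mmd2=mmd2, bandwidth=float(bandwidth))


def _quantile_grid(m: int, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared quantile segmentation for two empirical CDFs of sizes m, n.

    Returns segment widths ``w`` and, per segment, the index of the sorted
    observation of each sample whose quantile-function value applies.
    """
    breaks = np.union1d(np.arange(1, m) / m, np.arange(1, n) / n)
    edges = np.concatenate([[0.0], breaks, [1.0]])
    w = np.diff(edges)
    mid = (edges[:-1] + edges[1:]) / 2
    ia = np.minimum((mid * m).astype(int), m - 1)
    ib = np.minimum((mid * n).astype(int), n - 1)
    return w, ia, ib


def _w2_1d_sorted(a_sorted: np.ndarray, b_sorted: np.ndarray,
                  grid: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Order-2 1-D Wasserstein distance between sorted samples.

    Accepts stacked sorted samples of shape (..., m) and (..., n);
    vectorized over leading axes.
    """
    m = a_sorted.shape[-1]
    n = b_sorted.shape[-1]
    if grid is None:
        grid = _quantile_grid(m, n)
    w, ia, ib = grid
    diff2 = (a_sorted[..., ia] - b_sorted[..., ib]) ** 2
    return np.sqrt((diff2 * w).sum(axis=-1))


def sliced_directions(d: int, n_proj: int, seed: int) -> np.ndarray:
    """(n_proj, d) unit vectors drawn uniformly on the sphere."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_proj, d))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def wasserstein(
    x: np.ndarray,
    y: np.ndarray,
    variant: str = "sliced",
    n_proj: int = 128,
    seed: int = 0,
    max_points: int = 2000,
) -> float:
    """Wasserstein distance between two point clouds.

    ``variant="sliced"``: mean over ``n_proj`` seeded random unit projections
    of the 1-D order-2 Wasserstein distance of the projected samples.
    ``variant="exact"``: order-2 optimal-transport distance by minimum-cost
    assignment on equal-size clouds (the larger cloud is seeded-subsampled to
    the smaller; both capped at ``max_points``).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if len(x) < 1 or len(y) < 1:
        raise ValueError("need >= 1 row in each sample")
    if variant == "sliced":
        if n_proj < 1:
            raise ValueError("n_proj must be >= 1")
        thetas = sliced_directions(x.shape[1], n_proj, seed)
        px = np.sort(x @ thetas.T, axis=0).T  # (n_proj, m)
        py = np.sort(y @ thetas.T, axis=0).T
        return float(_w2_1d_sorted(px, py).mean())
    if variant == "exact":
        rng = np.random.default_rng(seed)
        nx = min(len(x), len(y), max_points)
        xs = x if len(x) == nx else x[rng.choice(len(x), nx, replace=False)]
        ys = y if len(y) == nx else y[rng.choice(len(y), nx, replace=False)]
        cost = cdist(xs, ys, "sqeuclidean")
        r, c = linear_sum_assignment(cost)
        return float(np.sqrt(cost[r, c].mean()))
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# cohort-level operations


def _subsample(m: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    if len(m) <= cap:
        return m
    return m[rng.choice(len(m), cap, replace=False)]


def pairwise_distance_matrix(
    eset: EmbeddingSet,
    metric: str = "mmd",
    n_proj: int = 128,
    seed: int = 0,
    max_tiles: int = 2000,
    mmd_value: str = "mmd",
) -> DistanceMatrix:
    """Symmetric slide x slide distance matrix under one metric.

    ``metric`` is ``"mmd"`` (``mmd_value`` selects ``"mmd"`` = sqrt scale or
    ``"mmd2"`` = squared) or ``"swd"`` (sliced Wasserstein).  Tiles per slide
    are capped at ``max_tiles`` (seeded subsample); a metric failure on a
    pair leaves a NaN entry and the run continues.
    """
    s = eset.n_slides
    if s < 2:
        raise ValueError("need >= 2 slides")
    rng = np.random.default_rng(seed)
    mats = [_subsample(np.asarray(m, float), max_tiles, rng) for m in eset.matrices]
    values = np.zeros((s, s), dtype=float)
    n_failed = 0
    params: dict = dict(metric=metric, max_tiles=max_tiles, seed=seed)
    if metric == "swd":
        params["n_proj"] = n_proj
        thetas = sliced_directions(eset.d, n_proj, seed)
        sorted_proj = [np.sort(m @ thetas.T, axis=0).T for m in mats]
        grids: dict[tuple[int, int], tuple] = {}
        for i, j in itertools.combinations(range(s), 2):
            a, b = sorted_proj[i], sorted_proj[j]
            key = (a.shape[-1], b.shape[-1])
            if key not in grids:
                grids[key] = _quantile_grid(*key)
            v = float(_w2_1d_sorted(a, b, grids[key]).mean())
            values[i, j] = values[j, i] = v
    elif metric == "mmd":
        params["bandwidth"] = "median-heuristic (per pair)"
        params["mmd_value"] = mmd_value
        for i, j in itertools.combinations(range(s), 2):
            try:
                r = mmd_rbf(mats[i], mats[j])
                v = r.value if mmd_value == "mmd" else r.mmd2
            except ValueError:
                logger.warning("MMD failed for pair (%s, %s)", eset.slide_ids[i], eset.slide_ids[j])
                v = np.nan
                n_failed += 1
            values[i, j] = values[j, i] = v
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if n_failed:
        logger.warning("%d pair(s) failed; entries set to NaN", n_failed)
    return DistanceMatrix(
        values=values,
        slide_ids=list(eset.slide_ids),
        sample_ids=list(eset.sample_ids),
        sections=list(eset.sections),
        metric=metric,
        params=params,
        n_failed=n_failed,
    )


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def related_unrelated_summary(dm: DistanceMatrix) -> dict[str, dict[str, float]]:
    """Median [Q1, Q3] of related (same-sample) vs unrelated pair distances.

    Self-pairs (the diagonal) are excluded by construction.
    """
    i, j = _pair_indices(len(dm.slide_ids))
    samples = np.asarray(dm.sample_ids)
    related = samples[i] == samples[j]
    if not related.any():
        raise ValueError("no related pairs: need >= 2 sections for some sample")
    vals = dm.values[i, j]
    out = {}
    for name, mask in (("related", related), ("unrelated", ~related)):
        v = vals[mask]
        v = v[np.isfinite(v)]
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        out[name] = dict(median=float(med), q1=float(q1), q3=float(q3), n=int(mask.sum()))
    return out


def permutation_test(
    dm: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "within_less",
) -> PermutationResult:
    """Permutation test of median(related) - median(unrelated).

    The null is generated by shuffling the slide-to-sample assignment with
    the matrix fixed; with ``alternative="within_less"`` the p-value is
    ``(1 + #{T_perm <= T_obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative != "within_less":
        raise ValueError("only alternative='within_less' is supported")
    i, j = _pair_indices(len(dm.slide_ids))
    samples = np.asarray(dm.sample_ids)
    vals = dm.values[i, j]
    ok = np.isfinite(vals)
    i, j, vals = i[ok], j[ok], vals[ok]

    def statistic(lab: np.ndarray) -> float:
        rel = lab[i] == lab[j]
        if not rel.any() or rel.all():
            return np.nan
        return float(np.median(vals[rel]) - np.median(vals[~rel]))

    t_obs = statistic(samples)
    if not np.isfinite(t_obs):
        raise ValueError("degenerate labels: no related or no unrelated pairs")
    rng = np.random.default_rng(seed)
    count = 0
    rel_obs = (samples[i] == samples[j]).sum()
    for _ in range(n_perm):
        perm = rng.permutation(samples)
        t = statistic(perm)
        if np.isfinite(t) and t <= t_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermutationResult(
        observed=t_obs,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        alternative=alternative,
        n_related=int(rel_obs),
        n_unrelated=int(len(vals) - rel_obs),
    )


def pair_metrics_by_comparison(dm: DistanceMatrix) -> dict[str, list[float]]:
    """Per-sample metric values keyed by section-pair comparison label.

    For every sample with sections a, b present, the distance between its
    two slides contributes to group ``"{a}v{b}"`` (sections in cohort order).
    """
    order = {s: k for k, s in enumerate(pd.unique(np.asarray(dm.sections)))}
    by_sample: dict[str, dict[str, int]] = {}
    for idx, (samp, sec) in enumerate(zip(dm.sample_ids, dm.sections)):
        by_sample.setdefault(samp, {})[sec] = idx
    groups: dict[str, list[float]] = {}
    for samp, secs in by_sample.items():
        for a, b in itertools.combinations(sorted(secs, key=order.get), 2):
            v = dm.values[secs[a], secs[b]]
            if np.isfinite(v):
                groups.setdefault(f"{a}v{b}", []).append(float(v))
    return groups


def metric_group_bootstrap(dm: DistanceMatrix, n_boot: int = 10_000, seed: int = 0):
    """Cluster bootstrap of mean metric values across comparison groups."""
    from .icc import cluster_bootstrap_groups

    groups = pair_metrics_by_comparison(dm)
    if len(groups) < 2:
        raise ValueError("need >= 2 comparison groups with related pairs")
    return cluster_bootstrap_groups(groups, n_boot=n_boot, seed=seed, mode="metric_values")


# ---------------------------------------------------------------------------
# dimensionality reduction and its diagnostics


def reduce_embeddings(
    eset: EmbeddingSet, d_out: int = 100, method: str = "pca", seed: int = 0
) -> EmbeddingSet:
    """Reduce all slides into a common ``d_out``-dimensional space.

    A single reducer is fitted on the pooled tiles of all slides and applied
    per slide, so reduced coordinates are comparable across the cohort.
    ``method="pca"`` is the deterministic linear projection; ``method="umap"``
    uses the neighbor-embedding reducer (optional dependency).
    """
    if d_out >= eset.d:
        raise ValueError(f"d_out={d_out} must be < d={eset.d}")
    pooled = eset.pooled()
    if len(pooled) < d_out:
        raise ValueError("pooled tile count smaller than d_out")
    if method == "pca":
        reducer = PCA(n_components=d_out, random_state=seed)
        reducer.fit(pooled)
        transformed = [reducer.transform(m) for m in eset.matrices]
    elif method == "umap":
        import umap  # heavyweight optional dependency

        reducer = umap.UMAP(n_components=d_out, random_state=seed)
        pooled_red = reducer.fit_transform(pooled)
        splits = np.cumsum([len(m) for m in eset.matrices])[:-1]
        transformed = list(np.split(pooled_red, splits))
    else:
        raise ValueError(f"unknown method {method!r}")
    return EmbeddingSet(
        slide_ids=list(eset.slide_ids),
        sample_ids=list(eset.sample_ids),
        sections=list(eset.sections),
        matrices=[np.asarray(t, float) for t in transformed],
    )


def trustworthiness(original: np.ndarray, reduced: np.ndarray, k: int = 15) -> float:
    """Neighborhood-fidelity score of a reduction (1 = perfect).

    Penalizes points that enter a k-neighborhood only after reduction.
    """
    original = np.asarray(original, float)
    reduced = np.asarray(reduced, float)
    if len(original) != len(reduced):
        raise ValueError("row counts differ")
    m = len(original)
    if not 1 <= k < m / 2:
        raise ValueError(f"k={k} out of range [1, m/2) for m={m}")
    return float(manifold.trustworthiness(original, reduced, n_neighbors=k))


def distance_monotonicity(
    original: np.ndarray,
    reduced: np.ndarray,
    n_pairs: int = 10_000,
    seed: int = 0,
) -> float:
    """Spearman rank correlation of original vs reduced pairwise distances
    over sampled non-identical tile pairs (duplicate pairs excluded)."""
    original = np.asarray(original, float)
    reduced = np.asarray(reduced, float)
    m = len(original)
    if m < 2:
        raise ValueError("need >= 2 rows")
    total = m * (m - 1) // 2
    if n_pairs >= total:
        i, j = _pair_indices(m)
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, m, size=n_pairs)
        j = rng.integers(0, m, size=n_pairs)
        keep = i != j
        i, j = i[keep], j[keep]
    d0 = np.linalg.norm(original[i] - original[j], axis=1)
    d1 = np.linalg.norm(reduced[i] - reduced[j], axis=1)
    keep = d0 > 0
    if not keep.any():
        logger.warning("all sampled pairs identical; monotonicity undefined")
        return float("nan")
    rho = stats.spearmanr(d0[keep], d1[keep]).statistic
    return float(rho)


def reduction_diagnostics(
    eset: EmbeddingSet,
    candidate_dims: Sequence[int],
    method: str = "pca",
    k: int = 15,
    n_pairs: int = 2000,
    max_mmd_pairs: int = 30,
    max_tiles: int = 1000,
    seed: int = 0,
    plateau_tol: float = 0.02,
) -> ReductionDiagnostics:
    """Evaluate candidate output dimensions and pick the smallest adequate one.

    For each candidate the cohort is reduced once; trustworthiness and
    distance monotonicity are scored on a pooled tile subsample and
    inter-slide dissimilarity as the mean MMD over sampled slide pairs.  The
    chosen dimension is the smallest whose trustworthiness and monotonicity
    are within ``plateau_tol`` of the best candidate's.
    """
    rng = np.random.default_rng(seed)
    pooled = eset.pooled()
    sub = _subsample(pooled, max_tiles, rng)
    tw, mono, mmds = [], [], []
    pairs = list(itertools.combinations(range(eset.n_slides), 2))
    if len(pairs) > max_mmd_pairs:
        pairs = [pairs[t] for t in rng.choice(len(pairs), max_mmd_pairs, replace=False)]
    for d_out in candidate_dims:
        red = reduce_embeddings(eset, d_out=d_out, method=method, seed=seed)
        red_pooled = red.pooled()
        idx = rng.choice(len(pooled), min(len(pooled), max_tiles), replace=False)
        tw.append(trustworthiness(pooled[idx], red_pooled[idx], k=k))
        mono.append(distance_monotonicity(pooled[idx], red_pooled[idx], n_pairs=n_pairs, seed=seed))
        vals = [
            mmd_rbf(
                _subsample(red.matrices[i], max_tiles, rng),
                _subsample(red.matrices[j], max_tiles, rng),
            ).value
            for i, j in pairs
        ]
        mmds.append(float(np.mean(vals)))
    best_tw, best_mono = max(tw), max(mono)
    chosen = candidate_dims[-1]
    for t, (d_out, a, b) in enumerate(zip(candidate_dims, tw, mono)):
        if a >= best_tw - plateau_tol and b >= best_mono - plateau_tol:
            chosen = d_out
            break
    return ReductionDiagnostics(
        candidate_dims=list(candidate_dims),
        trustworthiness=tw,
        monotonicity=mono,
        inter_slide_mmd=mmds,
        chosen_dim=int(chosen),
    )
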