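"""Intraclass correlation and cluster-bootstrap comparisons between sections.

Agreement of a feature between two cross sections of the same sample is
quantified by the single-measures intraclass correlation coefficient (ICC),
assembled from the two-way crossed ANOVA mean squares.  Three classical forms
are available (Shrout-Fleiss / McGraw-Wong nomenclature):

* ``icc1``  - one-way random effects, absolute agreement, ICC(1,1);
* ``icc2``  - two-way random effects, absolute agreement, ICC(2,1) [default];
* ``icc3``  - two-way mixed effects, consistency, ICC(3,1).

95% confidence intervals come from the corresponding F-distribution pivots.
Estimates are interpreted with the Cicchetti bands: poor < 0.40, fair
0.40-0.59, good 0.60-0.74, excellent 0.75-1.00 (negative estimates are
reported as computed and classified poor).

Group-level differences between comparison groups (e.g. distant C1vC3 versus
neighboring C1vC2) are assessed by a cluster bootstrap: observations are
resampled with replacement within each group, group means recomputed per
resample, and two-tailed p-values read off the difference distribution.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ICC_FORMS = ("icc1", "icc2", "icc3")


def anova_mean_squares(matrix: np.ndarray) -> tuple[float, float, float, float]:
    """Two-way crossed ANOVA mean squares of an n x k ratings matrix.

    Returns ``(MS_between_subjects, MS_within, MS_raters, MS_error)``.
    ``MS_within`` pools the rater and residual sums of squares.  A constant
    matrix yields all-zero mean squares (flagged via log).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x raters)")
    n, k = m.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >=3 subjects and >=2 raters, got {n}x{k}")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains non-finite values")
    msr, msw, msc, mse = _mean_squares(m)
    if msr == 0 and msc == 0 and mse == 0:
        logger.warning("constant ratings matrix: all mean squares are zero")
    return float(msr), float(msw), float(msc), float(mse)


def _mean_squares(m: np.ndarray):
    """Vectorized mean squares for arrays of shape (..., n, k)."""
    n, k = m.shape[-2], m.shape[-1]
    grand = m.mean(axis=(-1, -2), keepdims=True)
    row_means = m.mean(axis=-1, keepdims=True)
    col_means = m.mean(axis=-2, keepdims=True)
    ssr = k * ((row_means - grand) ** 2).sum(axis=(-1, -2))
    ssc = n * ((col_means - grand) ** 2).sum(axis=(-1, -2))
    sst = ((m - grand) ** 2).sum(axis=(-1, -2))
    sse = np.maximum(sst - ssr - ssc, 0.0)
    # snap components that are pure floating-point residue of the
    # subtraction (e.g. identical columns) to exact zero
    tol = 1e-10 * sst
    ssc = np.where(ssc <= tol, 0.0, ssc)
    sse = np.where(sse <= tol, 0.0, sse)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    msw = (ssc + sse) / (n * (k - 1))
    return msr, msw, msc, mse


def icc_value(matrix: np.ndarray, form: str = "icc2"):
    """ICC point estimate(s) for arrays of shape (..., n, k).

    Vectorized over leading axes (used by the bootstrap); degenerate inputs
    (zero total variance) yield NaN.
    """
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape[-2], m.shape[-1]
    msr, msw, msc, mse = _mean_squares(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        if form == "icc1":
            est = (msr - msw) / (msr + (k - 1) * msw)
        elif form == "icc2":
            est = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        elif form == "icc3":
            est = (msr - mse) / (msr + (k - 1) * mse)
        else:
            raise ValueError(f"unknown ICC form {form!r}; choose from {ICC_FORMS}")
    return est


def icc(
    matrix: np.ndarray, form: str = "icc2", confidence: float = 0.95
) -> tuple[float, float, float]:
    """ICC estimate with an F-pivot confidence interval.

    Returns ``(estimate, ci_low, ci_high)``; for a degenerate (constant)
    matrix all three are NaN.  Perfect agreement (identical columns) gives
    estimate 1 with ci_high 1.
    """
    m = np.asarray(matrix, dtype=float)
    msr, msw, msc, mse = anova_mean_squares(m)
    n, k = m.shape
    if msr == 0 and msc == 0 and mse == 0:
        return (np.nan, np.nan, np.nan)
    est = float(icc_value(m, form))
    alpha = 1.0 - confidence
    if form == "icc1":
        denom, df2 = msw, n * (k - 1)
        if denom == 0:
            return (est, _f_band_low(np.inf, k, alpha, n - 1, df2), 1.0)
        fobs = msr / denom
        fl = fobs / stats.f.ppf(1 - alpha / 2, n - 1, df2)
        fu = fobs * stats.f.ppf(1 - alpha / 2, df2, n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    elif form == "icc3":
        denom, df2 = mse, (n - 1) * (k - 1)
        if denom == 0:
            return (est, _f_band_low(np.inf, k, alpha, n - 1, df2), 1.0)
        fobs = msr / denom
        fl = fobs / stats.f.ppf(1 - alpha / 2, n - 1, df2)
        fu = fobs * stats.f.ppf(1 - alpha / 2, df2, n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    else:  # icc2: Satterthwaite pivot (Shrout & Fleiss)
        if mse == 0 and msc == 0:
            return (est, est, 1.0) if est == 1.0 else (est, np.nan, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = k * est / (n * (1 - est)) if est < 1 else np.inf
            b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else np.inf
            if np.isfinite(a) and np.isfinite(b):
                num = (a * msc + b * mse) ** 2
                den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
                v = num / den if den > 0 else (n - 1) * (k - 1)
            else:
                v = (n - 1) * (k - 1)
        fl = stats.f.ppf(1 - alpha / 2, n - 1, v)
        fu = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - fl * mse) / (
            fl * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (fu * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * fu * msr
        )
    lo = float(min(lo, est))
    hi = float(np.clip(max(hi, est), -1.0, 1.0))
    lo = float(np.clip(lo, -1.0, 1.0))
    return (est, lo, hi)


def _f_band_low(fobs, k, alpha, df1, df2) -> float:
    if not np.isfinite(fobs):
        return 1.0
    fl = fobs / stats.f.ppf(1 - alpha / 2, df1, df2)
    return (fl - 1) / (fl + k - 1)


def classify_icc(estimate: float) -> str:
    """Cicchetti interpretation band; boundaries belong to the upper band."""
    if not np.isfinite(estimate):
        raise ValueError("estimate must be finite")
    if estimate < 0.40:
        return "poor"
    if estimate < 0.60:
        return "fair"
    if estimate < 0.75:
        return "good"
    return "excellent"


def comparison_pairs(manifest: pd.DataFrame) -> list[tuple[str, str, str]]:
    """Unordered section pairs (label, section_a, section_b) ordered by axial
    gap within the natural section order, e.g. C1vC2, C2vC3, C1vC3."""
    secs = (
        manifest[["section", "axial_offset_um"]]
        .drop_duplicates()
        .sort_values("axial_offset_um")
    )
    labels = secs["section"].tolist()
    pairs = []
    for a, b in itertools.combinations(labels, 2):
        pairs.append((f"{a}v{b}", a, b))
    # order by axial gap (neighboring pairs first), stable on label
    offs = dict(zip(secs["section"], secs["axial_offset_um"]))
    pairs.sort(key=lambda p: (offs[p[2]] - offs[p[1]]))
    return pairs


def paired_matrix(
    features: pd.DataFrame, feature: str, section_a: str, section_b: str
) -> np.ndarray:
    """n x 2 pairwise-complete matrix of one feature across two sections."""
    wide = features[feature].unstack("section")
    cols = wide[[section_a, section_b]].dropna()
    return cols.to_numpy(dtype=float)


def icc_table(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    form: str = "icc2",
    confidence: float = 0.95,
    min_subjects: int = 3,
) -> pd.DataFrame:
    """Per-feature, per-comparison ICC results.

    ``features`` is a wide table indexed by (sample_id, section).  Returns a
    DataFrame with columns feature, comparison, estimate, ci_low, ci_high,
    icc_form, n_used, category; combinations with fewer than ``min_subjects``
    complete pairs are omitted (logged).
    """
    missing = set(features.index.get_level_values("section")) - set(manifest["section"])
    if missing:
        raise ValueError(f"sections in features absent from manifest: {sorted(missing)}")
    rows = []
    for label, sa, sb in comparison_pairs(manifest):
        for feat in features.columns:
            m = paired_matrix(features, feat, sa, sb)
            if len(m) < min_subjects:
                logger.info("skipping %s %s: only %d complete pairs", feat, label, len(m))
                continue
            est, lo, hi = icc(m, form=form, confidence=confidence)
            if not np.isfinite(est):
                logger.info("degenerate variance for %s %s; excluded", feat, label)
                continue
            rows.append(
                dict(
                    feature=feat,
                    comparison=label,
                    estimate=est,
                    ci_low=lo,
                    ci_high=hi,
                    icc_form=form,
                    n_used=len(m),
                    category=classify_icc(est),
                )
            )
    return pd.DataFrame(rows)


def summarize_median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear-interpolation quantiles."""
    v = np.asarray(list(values), dtype=float)
    if len(v) == 0:
        raise ValueError("empty value set")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


@dataclass
class BootstrapResult:
    """Cluster-bootstrap group means and pairwise difference tests."""

    group_means: dict[str, float]
    differences: dict[tuple[str, str], dict[str, float]]  # mean_diff, p
    n_boot: int
    seed: int
    mode: str
    group_sizes: dict[str, int] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Long table mirroring the shape of a group-comparison report."""
        rows = [
            dict(comparison=g, mean_icc=m, mean_difference=np.nan, p_value=np.nan)
            for g, m in self.group_means.items()
        ]
        for (g1, g2), d in self.differences.items():
            rows.append(
                dict(
                    comparison=f"{g1} vs {g2}",
                    mean_icc=np.nan,
                    mean_difference=d["mean_diff"],
                    p_value=d["p"],
                )
            )
        return pd.DataFrame(rows)


def _two_tailed_p(diffs: np.ndarray, n_boot: int) -> float:
    p = 2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean())
    return float(np.clip(p, 1.0 / n_boot, 1.0))


def cluster_bootstrap_groups(
    values_by_group: Mapping[str, Sequence[float]],
    n_boot: int = 10_000,
    seed: int = 0,
    mode: str = "feature_level_values",
) -> BootstrapResult:
    """Cluster bootstrap of group means and their pairwise differences.

    Within each group, observations are resampled with replacement (same
    size) ``n_boot`` times; the reported group value is the mean over
    resample means, and each pairwise difference distribution (built from the
    same resample stream) yields a two-tailed p-value with a 1/B floor.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    boot_means: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    for g in groups:
        vals = np.asarray(list(values_by_group[g]), dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has < 2 finite observations")
        sizes[g] = len(vals)
        # label-keyed substream: results do not depend on group ordering
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(g.encode()),))
        )
        idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
        boot_means[g] = vals[idx].mean(axis=1)
    group_means = {g: float(bm.mean()) for g, bm in boot_means.items()}
    differences: dict[tuple[str, str], dict[str, float]] = {}
    for g1, g2 in itertools.permutations(groups, 2):
        d = boot_means[g1] - boot_means[g2]
        differences[(g1, g2)] = dict(mean_diff=float(d.mean()), p=_two_tailed_p(d, n_boot))
    return BootstrapResult(
        group_means=group_means,
        differences=differences,
        n_boot=n_boot,
        seed=seed,
        mode=mode,
        group_sizes=sizes,
    )


def _resample_indices(
    rng: np.random.Generator, n: int, n_boot: int, min_distinct: int = 3, max_retries: int = 100
) -> np.ndarray:
    """(n_boot, n) resample index matrix; rows with fewer than
    ``min_distinct`` distinct subjects are redrawn (bounded retries)."""
    idx = rng.integers(0, n, size=(n_boot, n))
    for _ in range(max_retries):
        srt = np.sort(idx, axis=1)
        distinct = 1 + (np.diff(srt, axis=1) > 0).sum(axis=1)
        bad = distinct < min_distinct
        if not bad.any():
            return idx
        logger.info("redrawing %d degenerate bootstrap resamples", int(bad.sum()))
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    return idx


def cluster_bootstrap_per_feature(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    form: str = "icc2",
    alpha: float = 0.05,
    min_subjects: int = 3,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Subject-resampling cluster bootstrap of ICC differences per feature.

    For every feature, the clusters (samples, each carrying all its
    sections) are resampled with replacement; per resample the ICC of every
    comparison group is recomputed on the same resampled clusters —
    preserving the grouping structure and the between-group correlation
    induced by shared subjects — and two-tailed p-values are derived for
    each pair of comparison groups from the difference distributions.

    Samples missing any section for a feature are dropped for that feature
    (logged).  Returns a long DataFrame (feature, group_1, group_2,
    mean_diff, p_value) and a summary dict: per distant-vs-neighboring pair
    the fraction of features with p < alpha, plus ``fraction_significant`` —
    the fraction of features whose distant comparison differs significantly
    (p < alpha) from *both* neighboring comparisons with a lower ICC — and
    its denominator.
    """
    pairs = comparison_pairs(manifest)
    labels = [p[0] for p in pairs]
    rng = np.random.default_rng(seed)
    rows = []
    for feat in features.columns:
        wide = features[feat].unstack("section").dropna()
        n = len(wide)
        if n < min_subjects:
            logger.info("skipping %s: only %d complete samples", feat, n)
            continue
        idx = _resample_indices(rng, n, n_boot, min_distinct=min_subjects)
        boot: dict[str, np.ndarray] = {}
        for label, sa, sb in pairs:
            m = wide[[sa, sb]].to_numpy(dtype=float)
            boot[label] = icc_value(m[idx], form=form)
        for g1, g2 in itertools.combinations(boot, 2):
            d = boot[g1] - boot[g2]
            ok = np.isfinite(d)
            if ok.sum() < n_boot:
                logger.info("%s %s-%s: %d degenerate resamples dropped", feat, g1, g2, n_boot - int(ok.sum()))
            d = d[ok]
            if len(d) == 0:
                logger.info("%s %s-%s: no usable resamples; skipped", feat, g1, g2)
                continue
            rows.append(
                dict(
                    feature=feat,
                    group_1=g1,
                    group_2=g2,
                    mean_diff=float(d.mean()),
                    p_value=_two_tailed_p(d, n_boot),
                )
            )
    out = pd.DataFrame(rows)
    summary: dict[str, float] = {"alpha": alpha, "n_boot": n_boot}
    if len(out) == 0:
        return out, summary
    # distant comparison = widest axial gap (last element of comparison_pairs)
    distant = labels[-1]
    neighbors = [l for l in labels[:-1]]
    sig_all = None
    for nb in neighbors:
        mask = (
            ((out["group_1"] == distant) & (out["group_2"] == nb))
            | ((out["group_1"] == nb) & (out["group_2"] == distant))
        )
        sub = out[mask].set_index("feature")
        signed = np.where(
            sub["group_1"] == distant, sub["mean_diff"], -sub["mean_diff"]
        )
        sig = (sub["p_value"] < alpha) & (signed < 0)
        summary[f"fraction_significant[{distant} vs {nb}]"] = float(sig.mean())
        sig_all = sig if sig_all is None else (sig_all & sig.reindex(sig_all.index, fill_value=False))
    if sig_all is not None:
        summary["fraction_significant"] = float(sig_all.mean())
        summary["n_features"] = int(len(sig_all))
    return out, summary
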