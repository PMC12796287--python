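"""Synthetic serial-section cohort generator.

Stands in for a cohort of tissue samples each contributing several physically
adjacent H&E sections (e.g. C1/C2/C3 at axial offsets 0/55/105 um).  The
generator produces the two inputs the analysis pipeline consumes — per-slide
nuclei tables and per-slide tile-embedding matrices — with the statistical
structure the analysis assumes:

* **Nuclei.**  Each cell type follows a Thomas cluster process: Poisson
  parents over the frame, Gaussian offspring around each parent.  Parents
  (and the per-parent offspring noise, keyed by a persistent per-parent
  seed) are shared across a sample's sections, so sections of one sample are
  correlated.  Moving away axially, parents are displaced by Gaussian noise
  with sigma proportional to the axial offset and are thinned/replaced at a
  per-micron turnover rate — agreement between sections therefore decays
  smoothly with inter-slide distance, and vanishes entirely only in the
  zero-rate limit where all sections of a sample are identical.
* **Embeddings.**  Each sample owns a Gaussian mixture in R^d whose
  component means are separated between samples; each section draws its
  tiles from a slightly drifted copy of the sample's mixture (drift
  proportional to axial offset), so within-sample slide pairs are closer in
  distribution than cross-sample pairs.

All randomness derives from a single spec seed through documented
``SeedSequence`` substreams keyed by (purpose, sample, section), so adding
samples does not reshuffle existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .schemes import BASE_TYPES

# substream purpose codes (documented counter scheme)
_PARENTS = 1
_PERTURB = 2
_EMB_SAMPLE = 4
_EMB_SECTION = 5

DEFAULT_SECTIONS: tuple[tuple[str, float], ...] = (
    ("C1", 0.0),
    ("C2", 55.0),
    ("C3", 105.0),
)


@dataclass(frozen=True)
class TypePointParams:
    """Thomas-process parameters of one cell type.

    ``expected_count`` is the expected number of nuclei of the type per
    slide; ``expected_parents`` the expected number of cluster parents over
    the frame (parent intensity x frame area); ``offspring_sigma`` the
    Gaussian dispersion of offspring around their parent, in pixels.
    """

    expected_count: float
    expected_parents: float
    offspring_sigma: float
    sparse: bool = False

    def __post_init__(self) -> None:
        if self.expected_count < 0 or self.expected_parents < 0:
            raise ValueError("intensities must be >= 0")
        if self.offspring_sigma <= 0:
            raise ValueError("offspring_sigma must be > 0")


#: Default per-type abundances for a benign prostate-like slide: epithelial
#: and connective nuclei dominate; dead cells and neutrophils are sparse
#: (< 1% of nuclei), as is the non-neoplastic epithelial subtype.
DEFAULT_TYPE_PARAMS: Mapping[str, TypePointParams] = {
    "neoplastic_epithelial": TypePointParams(2500, 60, 120.0),
    "non_neoplastic_epithelial": TypePointParams(120, 12, 100.0, sparse=True),
    "uncategorized_epithelial": TypePointParams(700, 40, 110.0),
    "inflammatory": TypePointParams(500, 35, 150.0),
    "lymphocyte": TypePointParams(900, 30, 90.0),
    "neutrophil": TypePointParams(30, 15, 80.0, sparse=True),
    "connective": TypePointParams(1800, 50, 200.0),
    "dead": TypePointParams(25, 20, 100.0, sparse=True),
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic serial-section cohort.

    ``displacement_sigma_per_um`` (pixels of parent displacement per micron
    of axial offset), ``turnover_rate_per_um`` (per-micron whole-cluster
    death/birth rate) and ``offspring_turnover_rate_per_um`` (per-micron
    single-nucleus death/birth rate within surviving clusters) control how
    fast sections decorrelate with inter-slide distance; all zero makes all
    sections of a sample identical.
    """

    n_samples: int = 50
    sections: tuple[tuple[str, float], ...] = DEFAULT_SECTIONS
    frame: tuple[float, float] = (10_000.0, 10_000.0)
    type_params: Mapping[str, TypePointParams] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PARAMS)
    )
    displacement_sigma_per_um: float = 1.5
    turnover_rate_per_um: float = 0.003
    offspring_turnover_rate_per_um: float = 0.008
    between_sample_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if len(self.sections) < 2:
            raise ValueError("need >= 2 sections")
        if self.frame[0] <= 0 or self.frame[1] <= 0:
            raise ValueError("frame must have positive area")
        offs = [o for _, o in self.sections]
        if any(o < 0 for o in offs):
            raise ValueError("axial offsets must be >= 0")
        if min(self.displacement_sigma_per_um, self.turnover_rate_per_um,
               self.offspring_turnover_rate_per_um) < 0:
            raise ValueError("decorrelation rates must be >= 0")
        if self.between_sample_cv < 0:
            raise ValueError("between_sample_cv must be >= 0")
        if not any(p.sparse for p in self.type_params.values()):
            raise ValueError("at least one cell type must be flagged sparse")

    @property
    def area(self) -> float:
        return self.frame[0] * self.frame[1]

    def scaled(self, factor: float) -> "CohortSpec":
        """Spec with all per-type abundances scaled (for small test cohorts)."""
        tp = {
            name: replace(
                p,
                expected_count=p.expected_count * factor,
                expected_parents=max(p.expected_parents * factor, 1.0),
            )
            for name, p in self.type_params.items()
        }
        return replace(self, type_params=tp)


@dataclass(frozen=True)
class EmbeddingSpec:
    """Specification of synthetic per-slide tile-embedding matrices."""

    d: int = 64
    m_range: tuple[int, int] = (80, 120)
    k_components: int = 5
    between_sample_spread: float = 2.0
    within_sample_spread: float = 0.5
    section_drift_per_um: float = 0.005
    dirichlet_alpha: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("d must be >= 2")
        if self.m_range[0] < self.k_components:
            raise ValueError("m_range min must be >= k_components")
        if min(self.between_sample_spread, self.within_sample_spread,
               self.section_drift_per_um) < 0:
            raise ValueError("spreads must be >= 0")


@dataclass
class ParentSet:
    """Latent point-pattern state of one sample, shared across its sections.

    Per type: parent locations, the per-parent expected offspring count
    ``mu``, and the realized offspring (stored as offsets relative to their
    parent plus a parent index) so that a surviving parent carries its
    offspring cloud rigidly through every section.
    """

    locations: dict[str, np.ndarray]
    mu: dict[str, float]
    offsets: dict[str, np.ndarray]
    parent_index: dict[str, np.ndarray]
    frame: tuple[float, float]


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Documented substream scheme: Generator keyed by (purpose, indices)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def sample_parent_pattern(
    spec: CohortSpec, sample_index: int, rng: np.random.Generator | None = None
) -> ParentSet:
    """Draw the persistent parent layer of one sample.

    Parent counts are Poisson with the stated parent intensity over the
    frame, modulated by a per-(sample, type) lognormal abundance multiplier
    with coefficient of variation ``between_sample_cv`` (mean 1), which
    emulates biological composition differences between patients.
    Reproducible from (spec.seed, sample_index) when ``rng`` is not supplied.
    """
    if sample_index >= spec.n_samples:
        raise ValueError("sample_index out of range")
    if spec.area <= 0:
        raise ValueError("zero-area frame")
    if rng is None:
        rng = _substream(spec.seed, _PARENTS, sample_index)
    w, h = spec.frame
    locations, mu, offsets, parent_index = {}, {}, {}, {}
    for name, p in spec.type_params.items():
        # per-(sample, type) biological abundance multiplier (mean 1)
        cv = spec.between_sample_cv
        mult = float(np.exp(rng.normal(-0.5 * cv**2, cv))) if cv > 0 else 1.0
        n_par = int(rng.poisson(p.expected_parents * mult)) if p.expected_parents > 0 else 0
        locs = np.column_stack([rng.uniform(0, w, n_par), rng.uniform(0, h, n_par)])
        locations[name] = locs
        mu[name] = p.expected_count / p.expected_parents if p.expected_parents > 0 else 0.0
        counts = rng.poisson(mu[name], size=n_par)
        total = int(counts.sum())
        offsets[name] = rng.normal(0.0, p.offspring_sigma, size=(total, 2))
        parent_index[name] = np.repeat(np.arange(n_par), counts)
    return ParentSet(locations=locations, mu=mu, offsets=offsets,
                     parent_index=parent_index, frame=spec.frame)


def perturb_parents(
    parents: ParentSet,
    axial_offset_um: float,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> ParentSet:
    """The point-pattern state ``axial_offset_um`` microns away from this one.

    Three mechanisms, each proportional to the offset: parents are displaced
    by Gaussian noise with sigma ``displacement_sigma_per_um * offset``
    (carrying their offspring rigidly); whole clusters die with probability
    ``1 - exp(-turnover_rate_per_um * offset)`` and fresh uniform clusters
    are born at the matching rate; and individual offspring within surviving
    clusters die and are reborn at ``offspring_turnover_rate_per_um``.  The
    offspring-level turnover injects per-section count noise whose relative
    size scales as 1/sqrt(abundance), so sparse cell types reproduce less
    faithfully across sections than common ones.
    """
    if axial_offset_um < 0:
        raise ValueError("axial_offset_um must be >= 0")
    w, h = parents.frame
    sigma_d = spec.displacement_sigma_per_um * axial_offset_um
    survive_par = math.exp(-spec.turnover_rate_per_um * axial_offset_um)
    survive_off = math.exp(-spec.offspring_turnover_rate_per_um * axial_offset_um)
    locations, offsets, parent_index = {}, {}, {}
    for name, p in spec.type_params.items():
        locs = parents.locations[name]
        n_par = len(locs)
        mu = parents.mu[name]
        disp = rng.normal(0.0, sigma_d, size=(n_par, 2)) if sigma_d > 0 else np.zeros((n_par, 2))
        keep = rng.random(n_par) < survive_par
        # surviving parents: renumber and keep (possibly thinned) offspring
        new_idx = np.full(n_par, -1, dtype=int)
        new_idx[keep] = np.arange(int(keep.sum()))
        pidx = parents.parent_index[name]
        off_keep = keep[pidx] if n_par else np.zeros(0, dtype=bool)
        off_keep &= rng.random(len(pidx)) < survive_off
        kept_offsets = parents.offsets[name][off_keep]
        kept_pidx = new_idx[pidx[off_keep]]
        # offspring births within surviving parents
        n_kept_par = int(keep.sum())
        birth_counts = rng.poisson(mu * (1.0 - survive_off), size=n_kept_par)
        off_births = rng.normal(0.0, p.offspring_sigma, size=(int(birth_counts.sum()), 2))
        birth_pidx = np.repeat(np.arange(n_kept_par), birth_counts)
        # parent births: fresh clusters with full offspring complements
        n_birth = int(rng.poisson(p.expected_parents * (1.0 - survive_par)))
        birth_locs = np.column_stack([rng.uniform(0, w, n_birth), rng.uniform(0, h, n_birth)])
        new_counts = rng.poisson(mu, size=n_birth)
        new_offsets = rng.normal(0.0, p.offspring_sigma, size=(int(new_counts.sum()), 2))
        new_pidx = n_kept_par + np.repeat(np.arange(n_birth), new_counts)
        locations[name] = np.vstack([(locs + disp)[keep], birth_locs])
        offsets[name] = np.vstack([kept_offsets, off_births, new_offsets])
        parent_index[name] = np.concatenate([kept_pidx, birth_pidx, new_pidx]).astype(int)
    return ParentSet(locations=locations, mu=dict(parents.mu), offsets=offsets,
                     parent_index=parent_index, frame=parents.frame)


def emit_nuclei(parents: ParentSet, spec: CohortSpec) -> pd.DataFrame:
    """Render a nuclei table from the point-pattern state (pure function:
    offspring sit at their stored offsets from their parent's current
    location; points falling outside the frame are dropped)."""
    w, h = parents.frame
    frames = []
    counter = 0
    for name in spec.type_params:
        locs = parents.locations[name]
        pidx = parents.parent_index[name]
        xy = (locs[pidx] + parents.offsets[name]) if len(pidx) else np.empty((0, 2))
        if len(xy):
            inside = (xy[:, 0] >= 0) & (xy[:, 0] <= w) & (xy[:, 1] >= 0) & (xy[:, 1] <= h)
            xy = xy[inside]
        if len(xy):
            frames.append(
                pd.DataFrame(
                    dict(
                        nucleus_id=np.arange(counter, counter + len(xy)),
                        x=xy[:, 0],
                        y=xy[:, 1],
                        cell_type=name,
                    )
                )
            )
            counter += len(xy)
    if frames:
        return pd.concat(frames, ignore_index=True)
    return pd.DataFrame(columns=["nucleus_id", "x", "y", "cell_type"])


def generate_section(
    parents: ParentSet,
    axial_offset_um: float,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Nuclei table of one section at a given axial offset from the parents.

    Equivalent to perturbing the parent layer by the offset and rendering
    its offspring.  With both decorrelation rates zero the output is
    independent of the offset and of ``rng`` consumption, so sections
    coincide exactly.
    """
    return emit_nuclei(perturb_parents(parents, axial_offset_um, spec, rng), spec)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, dict[tuple[str, str], pd.DataFrame]]:
    """Full cohort: manifest plus one nuclei table per (sample, section).

    Sections are generated sequentially along the axial axis: each section's
    parent layer derives from the previous section's by a perturbation
    proportional to the offset increment (a random walk through the tissue
    block), so the decorrelation between any two sections grows with their
    axial gap.  The manifest records sample id, section label, axial offset
    and the cohort seed; outputs are a pure function of the spec.
    """
    width = len(str(spec.n_samples))
    manifest_rows = []
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    sections = sorted(enumerate(spec.sections), key=lambda t: t[1][1])
    for si in range(spec.n_samples):
        sample_id = f"S{si + 1:0{width}d}"
        current = sample_parent_pattern(spec, si)
        prev_offset = sections[0][1][1]
        for sj, (label, offset) in sections:
            rng = _substream(spec.seed, _PERTURB, si, sj)
            current = perturb_parents(current, offset - prev_offset, spec, rng)
            prev_offset = offset
            tables[(sample_id, label)] = emit_nuclei(current, spec)
            manifest_rows.append(
                dict(
                    sample_id=sample_id,
                    section=label,
                    axial_offset_um=offset,
                    seed=spec.seed,
                )
            )
    manifest = pd.DataFrame(manifest_rows)
    manifest = manifest.sort_values(
        ["sample_id", "axial_offset_um"], kind="stable"
    ).reset_index(drop=True)
    return manifest, tables


def generate_embedding_set(espec: EmbeddingSpec, manifest: pd.DataFrame):
    """Synthetic tile-embedding matrices for every slide in the manifest.

    Per sample: a Gaussian mixture with ``k_components`` means drawn with
    standard deviation ``between_sample_spread`` and Dirichlet weights.
    Moving through the sample's sections in axial order, mixture means and
    weight logits drift by Gaussian increments of scale
    ``section_drift_per_um`` times the offset increment (a random walk along
    the block), before each slide's tiles are drawn with within-component
    spread ``within_sample_spread``.
    """
    from .embeddings import EmbeddingSet

    if len(manifest) == 0:
        raise ValueError("empty manifest")
    sample_ids = list(pd.unique(manifest["sample_id"]))
    sample_index = {s: t for t, s in enumerate(sample_ids)}
    section_index = {s: t for t, s in enumerate(pd.unique(manifest["section"]))}
    out: dict[str, tuple[str, str, np.ndarray]] = {}
    for samp, rows in manifest.groupby("sample_id", sort=False):
        rng_s = _substream(espec.seed, _EMB_SAMPLE, sample_index[samp])
        means = rng_s.standard_normal((espec.k_components, espec.d)) * espec.between_sample_spread
        weights = rng_s.dirichlet(np.full(espec.k_components, espec.dirichlet_alpha))
        logits = np.log(weights)
        prev_offset = float(rows["axial_offset_um"].min())
        for _, row in rows.sort_values("axial_offset_um").iterrows():
            sec, offset = row["section"], float(row["axial_offset_um"])
            rng = _substream(espec.seed, _EMB_SECTION, sample_index[samp], section_index[sec])
            drift = espec.section_drift_per_um * (offset - prev_offset)
            prev_offset = offset
            if drift > 0:
                means = means + rng.normal(0.0, drift, size=means.shape)
                logits = logits + rng.normal(0.0, drift, size=len(logits))
            weights_s = np.exp(logits - logits.max())
            weights_s /= weights_s.sum()
            m = int(rng.integers(espec.m_range[0], espec.m_range[1] + 1))
            comps = rng.choice(espec.k_components, size=m, p=weights_s)
            tiles = means[comps] + rng.normal(0.0, espec.within_sample_spread, size=(m, espec.d))
            out[f"{samp}_{sec}"] = (samp, sec, tiles)
    slide_ids = [f"{r['sample_id']}_{r['section']}" for _, r in manifest.iterrows()]
    return EmbeddingSet(
        slide_ids=slide_ids,
        sample_ids=[out[s][0] for s in slide_ids],
        sections=[out[s][1] for s in slide_ids],
        matrices=[out[s][2] for s in slide_ids],
    )
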