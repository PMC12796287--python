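# Methods

This note documents the models, estimators and numerical conventions behind
`sliderep`, the choices made where several readings were defensible, and
what the synthetic cohort does and does not emulate.

## Synthetic serial-section cohort

**Nuclei.** Each cell type in a sample follows a Thomas cluster process:
parents are Poisson over the frame (default 10,000 × 10,000 px) with a
per-type expected parent count, and offspring are Gaussian around their
parent (per-type dispersion, 80–200 px). A per-(sample, type) lognormal
abundance multiplier (mean 1, CV `between_sample_cv`, default 0.3)
modulates parent intensity, emulating biological composition differences
between patients; without it, Poisson between- and within-sample variances
both scale as 1/N and agreement would be independent of abundance, which is
not what low-abundance cell types show in practice.

Default abundances describe a benign prostate-like slide: ~6,400 nuclei
with epithelial and connective nuclei dominant and dead cells, neutrophils
and the non-neoplastic epithelial subtype sparse (≲1% each).

**Axial decorrelation.** The realized point pattern — parents plus their
offspring, stored as offsets so clusters move rigidly — is the state of a
random walk along the block axis. Moving `δ` µm deeper applies three
mechanisms, each proportional to `δ`:

* parent displacement: Gaussian with σ = `displacement_sigma_per_um`·δ
  (default 1.5 px/µm);
* cluster turnover: whole clusters die with probability 1 − exp(−rδ)
  (default r = 0.003/µm) and fresh uniform clusters are born at the
  matching rate, keeping intensity stationary;
* offspring turnover: individual nuclei within surviving clusters die and
  are reborn at `offspring_turnover_rate_per_um` (default 0.008/µm). This
  term injects per-section count noise with relative size ∝ 1/√N, which is
  what makes sparse types less reproducible than common ones.

Because sections are generated sequentially (C1 → C2 → C3), the
decorrelation between two sections grows with their axial gap, so the
distant pair (105 µm) always agrees least — the ordering the analysis is
designed to detect. With all three rates zero the walk is the identity and
every section of a sample is identical, giving downstream ICC = 1 exactly;
this limit is used as a calibration test.

**Embeddings.** Each sample owns a Gaussian mixture in R^d (default d = 64;
the production dimension of vision encoders, 1024, is configurable but
unnecessary for correctness): `k` = 5 component means drawn with standard
deviation `between_sample_spread` (default 2.0), Dirichlet weights, and
within-component spread `within_sample_spread` (default 0.5) — a 4×
between/within ratio, giving clear related-vs-unrelated separation. Means
and weight logits drift along the section walk with per-µm scale
`section_drift_per_um` (default 0.005, chosen when the generator was
designed so that section drift is resolvable against the tile-sampling
noise of ~100-tile slides). Tiles per slide are uniform on `m_range`
(default 80–120).

**Determinism.** All randomness derives from the spec seed through
`SeedSequence(entropy=seed, spawn_key=(purpose, sample[, section]))`
substreams, so adding samples or sections never reshuffles existing ones.

**What the generator does not emulate:** nuclear morphology and polygon
shape, segmentation/classification errors, stain variation, tissue-scale
anatomy (glands, stroma gradients), or the heavy-tailed tile counts of real
WSIs. Passing tests therefore demonstrate correctness of the statistical
machinery and the qualitative distance-dependence, not calibrated agreement
with any real cohort's printed values.

## Per-slide features

Feature names follow a fixed grammar: `count.<type>`, `prop.<type>`,
`vor_cv.<group>`, `del_mean.<group>`, `del_sd.<group>`,
`nn.<center>.<neighbor>`, `shannon.<group>` — 61 in total for the default
8-type / 5-group scheme. The default grouping (3 epithelial subtypes →
epithelial; neutrophil → inflammatory; lymphocyte, connective, dead alone)
is a package default and fully configurable.

Conventions and edge cases:

* **Voronoi.** Default scope tessellates each group's points separately
  (`voronoi_scope="per_type"`); a pooled tessellation with attribution by
  seed group is available because the two readings give different values.
  Unbounded peripheral regions are dropped before the Tukey fence (they
  have no finite area); the fence (1.5·IQR beyond linear-interpolation
  quartiles) then operates on finite areas only. Fewer than `min_points`
  (4) surviving areas, or qhull degeneracy, yields a missing value.
* **Delaunay.** Unique undirected edges of the triangulation; sample SD
  (n−1). Collinear groups are missing, not errors.
* **Nearest neighbors.** Exact KD-tree search; distance ties broken by the
  smallest nucleus id. Exactness (vs the approximate indexing common in
  production pipelines) costs nothing at desk scale and makes equivalence
  to O(n²) brute force a test rather than an assumption.
* **Shannon diversity.** Neighborhood = intersection of the radius rule
  (100 coordinate units) and the count cap (15); natural log by default
  (configurable base); nuclei with empty neighborhoods are excluded from
  the group mean rather than contributing H = 0. With 5 groups the index
  lies in [0, log 5].
* **Missing values** propagate as NaN and are never zero-filled; the
  distance threshold for k neighbors is summarized by the mean (median
  selectable) of per-nucleus k-th neighbor distances.

All spatial features are invariant under rigid motion; Delaunay statistics
scale linearly under uniform scaling while CV, diversity and counts are
scale-free (with the radius scaled accordingly).

## ICC and cluster bootstrap

The ICC is assembled from the two-way crossed ANOVA mean squares; the
default form is ICC(2,1) — two-way random effects, absolute agreement,
single measures — because section-to-section reproducibility should
penalize systematic shifts between sections; ICC(1,1) and ICC(3,1) are
selectable and the form identifier is stamped into every result. 95% CIs
use the standard F-pivots (Satterthwaite degrees of freedom for the
absolute-agreement form). Estimates can be negative and are reported as
computed (truncation would bias bootstrap means); the Cicchetti bands map
them to "poor", with band boundaries (0.40/0.60/0.75) belonging to the
upper band. A relative tolerance of 1e-10 on the sums of squares snaps
pure floating-point residue (e.g. identical columns) to exact zero so the
perfect-agreement limit returns exactly 1. Pairwise-complete deletion is
used per (feature, comparison); combinations with < 3 complete pairs are
omitted with a logged reason.

Two bootstrap modes, both with a 1/B p-value floor and two-tailed p =
2·min(frac(D ≤ 0), frac(D ≥ 0)):

* **Group level** (`cluster_bootstrap_groups`): observations are the
  feature-level ICC values within each comparison group, resampled with
  replacement independently per group (B = 10,000 default). Group
  resampling streams are keyed by the group label, so results are
  invariant to mapping order. The reported group value is the mean over
  resample means, and reported differences equal differences of reported
  means by construction.
* **Per feature** (`cluster_bootstrap_per_feature`): the clusters are the
  samples. One subject resample is drawn per iteration and every
  comparison's ICC is recomputed on it, preserving the between-group
  correlation induced by shared subjects (independent per-group resampling
  would roughly √2-inflate the null spread of differences and lose most
  power at realistic effect sizes). Resamples with < 3 distinct subjects
  are redrawn (bounded retries, logged). The headline summary is the
  fraction of features whose distant comparison is significantly lower
  (p < α and negative difference) than *both* neighboring comparisons —
  the conservative reading of "significantly lower than the neighboring
  comparisons" — with per-pair fractions and the denominator reported
  alongside.

## Embedding metrics

* **MMD:** unbiased (diagonal-excluded) squared MMD with a Gaussian
  kernel, bandwidth = median pairwise distance of the pooled pair (the
  median heuristic), recomputed per pair. Both MMD² and √max(MMD², 0) are
  emitted; matrices store the square-root scale by default.
* **Wasserstein:** default is the sliced distance — the mean over seeded
  random unit projections (default 128) of the 1-D order-2 Wasserstein
  distance, computed from the shared quantile segmentation of the two
  sorted projected samples (exact for the empirical measures, any sizes).
  An exact variant solves the assignment problem on equal-size
  (subsampled, ≤2,000-point) clouds. No installed library provides
  multivariate OT, so both variants are implemented here and validated
  against closed forms (translated point masses; 1-D Gaussians).
* **Distance matrix:** every unordered slide pair once; per-slide tile
  caps (default 2,000, seeded) bound the O(m²) kernel cost; a metric
  failure flags the entry NaN and the run continues.
* **Permutation test:** statistic T = median(related) − median(unrelated);
  null from shuffling the slide→sample labels with the matrix fixed;
  p = (1 + #{T_perm ≤ T_obs}) / (n_perm + 1). With few samples the null is
  discrete and lumpy (a shuffle can nearly preserve the partition), so the
  attainable minimum p is only reached for cohorts of ≳10 samples.
* **Reduction:** one reducer fitted on pooled cohort tiles (per-pair
  fitting would make matrix entries incomparable). PCA is the first-class
  deterministic reducer; UMAP is available behind the same interface as an
  optional extra. Candidate output dimensions are compared on
  trustworthiness, sampled-pair distance monotonicity (Spearman) and mean
  inter-slide MMD; the chosen dimension is the smallest within 0.02 of the
  best trustworthiness and monotonicity.

## Problem sizes

The test suite exercises the full default conditions — 50 samples × 3
sections, ~6,400 nuclei per slide, ~100 tiles × 64 dimensions per slide,
B = 10,000 group bootstrap and 10,000 permutations — once, via shared
fixtures; replicate-cohort properties (ICC ordering, sparse-type deficit,
bootstrap power and calibration) run on 12–20-sample cohorts with
abundances scaled to ~30%, sizes at which the asserted orderings were
verified to be stable across 20 independent replicates. The acceptance
script runs the full 150-slide embedding analysis end to end.

## Known limitations

* The per-feature bootstrap's power depends on the decorrelation regime;
  with very strong decorrelation all ICCs drop and their sampling variance
  grows, so the fraction-significant summary is not monotone in the
  decorrelation rates.
* Voronoi CV values depend on the tessellation scope choice; results
  produced under different scopes are not comparable.
* The related/unrelated permutation test assumes exchangeability of slides
  under the null; systematic section-order effects (e.g. C1 always first
  off the block) would violate it.
* Exact OT distances on subsampled clouds are biased upward relative to
  the full-cloud distance; the subsample cap is recorded in the matrix
  parameters.
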