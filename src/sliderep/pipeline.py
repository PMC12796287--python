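"""End-to-end orchestration: simulate -> features -> ICC -> bootstrap ->
embedding metrics -> report.

A :class:`RunConfig` (typically loaded from YAML with strict key checking)
names either a synthetic cohort spec or on-disk inputs, plus all statistical
settings and seeds; :func:`run_pipeline` executes the stages in order,
skipping stages whose inputs are absent, writes every artifact under the
output directory and returns a :class:`ReportBundle`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io
from .icc import (
    BootstrapResult,
    cluster_bootstrap_groups,
    cluster_bootstrap_per_feature,
    icc_table,
)
from .embeddings import (
    DistanceMatrix,
    PermutationResult,
    metric_group_bootstrap,
    pairwise_distance_matrix,
    permutation_test,
    reduce_embeddings,
    related_unrelated_summary,
)
from .features import extract_cohort_features
from .schemes import CellTypeScheme, SpatialConfig
from .synthetic import (
    CohortSpec,
    EmbeddingSpec,
    TypePointParams,
    generate_cohort,
    generate_embedding_set,
)

logger = logging.getLogger(__name__)


def _version() -> str:
    from . import __version__

    return __version__


def _build(cls, mapping: Mapping[str, Any], context: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"{context}: unknown key(s) {sorted(unknown)}")
    return cls(**mapping)


def _cohort_spec_from_dict(d: Mapping[str, Any]) -> CohortSpec:
    d = dict(d)
    if "sections" in d:
        d["sections"] = tuple((str(l), float(o)) for l, o in d["sections"])
    if "frame" in d:
        d["frame"] = tuple(float(v) for v in d["frame"])
    if "type_params" in d:
        d["type_params"] = {
            name: _build(TypePointParams, p, f"cohort.type_params.{name}")
            for name, p in d["type_params"].items()
        }
    return _build(CohortSpec, d, "cohort")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    output_dir: str = "sliderep_out"
    cohort: CohortSpec | None = None
    embeddings_spec: EmbeddingSpec | None = None
    manifest_path: str | None = None
    nuclei_dir: str | None = None
    embedding_index: str | None = None
    scheme: CellTypeScheme = field(default_factory=CellTypeScheme.default)
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    icc_form: str = "icc2"
    n_boot: int = 10_000
    bootstrap_seed: int = 0
    per_feature_boot: int = 2000
    metrics: tuple[str, ...] = ("mmd", "swd")
    n_proj: int = 128
    max_tiles: int = 2000
    metric_seed: int = 0
    mmd_value: str = "mmd"
    n_perm: int = 10_000
    perm_seed: int = 0
    reduce_dim: int | None = None
    reduce_method: str = "pca"
    reduce_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        if "cohort" in raw and raw["cohort"] is not None:
            raw["cohort"] = _cohort_spec_from_dict(raw["cohort"])
        if "embeddings_spec" in raw and raw["embeddings_spec"] is not None:
            d = dict(raw["embeddings_spec"])
            if "m_range" in d:
                d["m_range"] = tuple(int(v) for v in d["m_range"])
            raw["embeddings_spec"] = _build(EmbeddingSpec, d, "embeddings_spec")
        if "spatial" in raw and raw["spatial"] is not None:
            raw["spatial"] = _build(SpatialConfig, raw["spatial"], "spatial")
        if "scheme" in raw and raw["scheme"] is not None:
            s = dict(raw["scheme"])
            if "base_types" in s:
                s["base_types"] = tuple(s["base_types"])
            if "spatial_groups" in s:
                s["spatial_groups"] = tuple(s["spatial_groups"])
            raw["scheme"] = _build(CellTypeScheme, s, "scheme")
        if "metrics" in raw:
            raw["metrics"] = tuple(raw["metrics"])
        return _build(cls, raw, "run config")

    def echo(self) -> dict:
        def conv(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {f.name: conv(getattr(v, f.name)) for f in dataclasses.fields(v)}
            if isinstance(v, Mapping):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, tuple):
                return [conv(x) for x in v]
            return v

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


@dataclass
class ReportBundle:
    """Everything one run computed, with provenance in ``run_record``."""

    features: pd.DataFrame | None = None
    icc_table: pd.DataFrame | None = None
    group_bootstrap: BootstrapResult | None = None
    per_feature_bootstrap: pd.DataFrame | None = None
    per_feature_summary: dict | None = None
    distance_matrices: dict[str, DistanceMatrix] = field(default_factory=dict)
    related_unrelated: dict[str, dict] = field(default_factory=dict)
    permutation: dict[str, PermutationResult] = field(default_factory=dict)
    metric_bootstrap: dict[str, BootstrapResult] = field(default_factory=dict)
    run_record: dict = field(default_factory=dict)


ALL_STAGES = ("simulate", "features", "icc", "bootstrap", "embed")


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ALL_STAGES) -> ReportBundle:
    """Execute the pipeline stages in order and write all outputs.

    Stages whose inputs are absent are skipped (e.g. an embeddings-only run
    needs no nuclei tables); the returned bundle holds every in-memory
    result and the run record is written as JSON.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle()
    record: dict = dict(
        package_version=_version(),
        numpy_version=np.__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        config=config.echo(),
        stages_run=[],
    )

    manifest = None
    tables = None
    if "simulate" in stages and config.cohort is not None:
        manifest, tables = generate_cohort(config.cohort)
        manifest = io.write_cohort(manifest, tables, out)
        record["stages_run"].append("simulate")
    elif config.manifest_path is not None:
        manifest = io.validate_manifest(
            io.read_manifest(config.manifest_path),
            base_dir=config.nuclei_dir or Path(config.manifest_path).parent,
        )
        tables = io.load_cohort_tables(
            manifest, config.nuclei_dir or Path(config.manifest_path).parent, config.scheme
        )

    if "features" in stages and tables is not None:
        bundle.features = extract_cohort_features(tables, config.scheme, config.spatial)
        io.write_feature_table(bundle.features, out / "features_long.csv")
        io.write_feature_table(bundle.features, out / "features_wide.csv", wide=True)
        record["stages_run"].append("features")

    if "icc" in stages and bundle.features is not None:
        bundle.icc_table = icc_table(bundle.features, manifest, form=config.icc_form)
        bundle.icc_table.to_csv(out / "icc_results.csv", index=False)
        record["stages_run"].append("icc")

    if "bootstrap" in stages and bundle.icc_table is not None and len(bundle.icc_table):
        by_group = {
            label: grp["estimate"].to_numpy()
            for label, grp in bundle.icc_table.groupby("comparison")
        }
        bundle.group_bootstrap = cluster_bootstrap_groups(
            by_group, n_boot=config.n_boot, seed=config.bootstrap_seed
        )
        bundle.group_bootstrap.table().to_csv(out / "bootstrap_groups.csv", index=False)
        if config.per_feature_boot > 0:
            bundle.per_feature_bootstrap, bundle.per_feature_summary = (
                cluster_bootstrap_per_feature(
                    bundle.features,
                    manifest,
                    n_boot=config.per_feature_boot,
                    seed=config.bootstrap_seed,
                    form=config.icc_form,
                )
            )
            bundle.per_feature_bootstrap.to_csv(out / "bootstrap_per_feature.csv", index=False)
            with open(out / "bootstrap_per_feature_summary.json", "w") as fh:
                json.dump(bundle.per_feature_summary, fh, indent=1)
        record["stages_run"].append("bootstrap")

    eset = None
    if "embed" in stages:
        if config.embeddings_spec is not None and manifest is not None:
            eset = generate_embedding_set(config.embeddings_spec, manifest)
            io.write_embedding_set(eset, out)
        elif config.embedding_index is not None:
            eset = io.read_embedding_set(config.embedding_index)
    if eset is not None:
        if config.reduce_dim is not None:
            eset = reduce_embeddings(
                eset, d_out=config.reduce_dim, method=config.reduce_method,
                seed=config.reduce_seed,
            )
        for metric in config.metrics:
            dm = pairwise_distance_matrix(
                eset, metric=metric, n_proj=config.n_proj,
                seed=config.metric_seed, max_tiles=config.max_tiles,
                mmd_value=config.mmd_value,
            )
            bundle.distance_matrices[metric] = dm
            io.write_distance_matrix(dm, out, f"distance_{metric}")
            bundle.related_unrelated[metric] = related_unrelated_summary(dm)
            bundle.permutation[metric] = permutation_test(
                dm, n_perm=config.n_perm, seed=config.perm_seed
            )
            try:
                bundle.metric_bootstrap[metric] = metric_group_bootstrap(
                    dm, n_boot=config.n_boot, seed=config.bootstrap_seed
                )
            except ValueError as exc:
                logger.warning("metric bootstrap skipped for %s: %s", metric, exc)
        summary_rows = []
        for metric, ru in bundle.related_unrelated.items():
            for cls_name, s in ru.items():
                summary_rows.append(dict(metric=metric, pair_class=cls_name, **s))
        pd.DataFrame(summary_rows).to_csv(out / "related_unrelated.csv", index=False)
        with open(out / "permutation.json", "w") as fh:
            json.dump(
                {m: dataclasses.asdict(r) for m, r in bundle.permutation.items()},
                fh, indent=1,
            )
        for metric, br in bundle.metric_bootstrap.items():
            br.table().to_csv(out / f"metric_bootstrap_{metric}.csv", index=False)
        record["stages_run"].append("embed")

    record["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    bundle.run_record = record
    with open(out / "run_record.json", "w") as fh:
        json.dump(record, fh, indent=1)
    return bundle
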