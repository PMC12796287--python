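"""Readers and writers for the pipeline's text formats.

Nuclei tables travel as CSV (``nucleus_id,x,y,cell_type``) or GeoJSON
FeatureCollections (Point geometries, or Polygon geometries reduced to the
mean of their exterior-ring vertices); cohort manifests as CSV; feature
tables as long or wide CSV; embedding sets as one TSV matrix per slide plus
a JSON index.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .embeddings import EmbeddingSet
from .features import NUCLEI_COLUMNS, validate_nuclei
from .schemes import CellTypeScheme

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("sample_id", "section", "axial_offset_um")


def _polygon_centroid(coords: list) -> tuple[float, float]:
    """Vertex mean of a polygon's exterior ring (closing vertex dropped)."""
    ring = np.asarray(coords[0], dtype=float)
    if len(ring) > 1 and np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    return float(ring[:, 0].mean()), float(ring[:, 1].mean())


def _geojson_label(props: Mapping, class_key: str):
    value = props.get(class_key)
    if isinstance(value, Mapping):  # e.g. {"name": "...", "color": ...}
        value = value.get("name")
    return value


def read_nuclei(
    path: str | Path,
    dialect: str | None = None,
    scheme: CellTypeScheme | None = None,
    class_key: str = "classification",
) -> pd.DataFrame:
    """Read a nuclei table from CSV or GeoJSON.

    ``dialect`` is inferred from the extension when omitted.  Unknown labels
    (when a scheme is given), missing columns, malformed geometries and
    non-finite coordinates raise descriptive errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "geojson" if path.suffix.lower() in (".geojson", ".json") else "csv"
    if dialect == "csv":
        table = pd.read_csv(path)
        missing = [c for c in NUCLEI_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        table = table[list(NUCLEI_COLUMNS)]
    elif dialect == "geojson":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("type") != "FeatureCollection":
            raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
        rows = []
        for i, feat in enumerate(doc.get("features", [])):
            geom = feat.get("geometry") or {}
            gtype = geom.get("type")
            if gtype == "Point":
                x, y = geom["coordinates"][:2]
            elif gtype == "Polygon":
                try:
                    x, y = _polygon_centroid(geom["coordinates"])
                except (IndexError, KeyError, TypeError) as exc:
                    raise ValueError(f"{path}: malformed Polygon in feature {i}") from exc
            else:
                raise ValueError(f"{path}: unsupported geometry {gtype!r} in feature {i}")
            label = _geojson_label(feat.get("properties") or {}, class_key)
            if label is None:
                raise ValueError(f"{path}: feature {i} lacks property {class_key!r}")
            rows.append(dict(nucleus_id=feat.get("id", i), x=float(x), y=float(y), cell_type=label))
        table = pd.DataFrame(rows, columns=list(NUCLEI_COLUMNS))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if scheme is not None:
        unknown = set(table["cell_type"]) - set(scheme.base_types)
        if unknown:
            rows_bad = table.index[table["cell_type"].isin(unknown)][:5].tolist()
            raise ValueError(f"{path}: unknown label(s) {sorted(unknown)} at rows {rows_bad}")
    return validate_nuclei(table)


def write_nuclei(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table[list(NUCLEI_COLUMNS)].to_csv(path, index=False)


def write_cohort(
    manifest: pd.DataFrame,
    tables: Mapping[tuple[str, str], pd.DataFrame],
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write per-slide nuclei CSVs plus a manifest CSV with relative paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    paths = []
    for _, row in manifest.iterrows():
        rel = f"nuclei/{row['sample_id']}_{row['section']}.csv"
        write_nuclei(tables[(row["sample_id"], row["section"])], out_dir / rel)
        paths.append(rel)
    manifest["path"] = paths
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    return manifest


def validate_manifest(
    manifest: pd.DataFrame, base_dir: str | Path | None = None
) -> pd.DataFrame:
    """Check manifest consistency (and file existence when paths present).

    Duplicate (sample, section) rows raise; samples missing some section are
    only warned about — they drop out of the affected comparisons later.
    """
    dup = manifest.duplicated(subset=["sample_id", "section"])
    if dup.any():
        pair = manifest.loc[dup, ["sample_id", "section"]].iloc[0].tolist()
        raise ValueError(f"duplicate (sample, section) in manifest: {pair}")
    n_sections = manifest.groupby("sample_id")["section"].nunique()
    full = n_sections.max()
    incomplete = n_sections[n_sections < full]
    for samp, n in incomplete.items():
        logger.warning("sample %s has only %d/%d sections", samp, n, full)
    if "path" in manifest.columns and base_dir is not None:
        base = Path(base_dir)
        for _, row in manifest.iterrows():
            p = base / row["path"]
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing table: {p}")
    return manifest


def load_cohort_tables(
    manifest: pd.DataFrame, base_dir: str | Path, scheme: CellTypeScheme | None = None
) -> dict[tuple[str, str], pd.DataFrame]:
    tables = {}
    for _, row in manifest.iterrows():
        tables[(row["sample_id"], row["section"])] = read_nuclei(
            Path(base_dir) / row["path"], scheme=scheme
        )
    return tables


def write_feature_table(features: pd.DataFrame, path: str | Path, wide: bool = False) -> None:
    """Write the cohort feature table as long (default) or wide CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if wide:
        features.to_csv(path)
    else:
        long = features.stack().rename("value").reset_index()
        long.columns = ["sample_id", "section", "feature", "value"]
        long.to_csv(path, index=False)


def read_feature_table(path: str | Path, wide: bool = False) -> pd.DataFrame:
    if wide:
        return pd.read_csv(path, index_col=[0, 1])
    long = pd.read_csv(path)
    out = long.pivot_table(
        index=["sample_id", "section"], columns="feature", values="value", dropna=False
    )
    out.columns.name = None
    return out


def write_embedding_set(eset: EmbeddingSet, out_dir: str | Path) -> Path:
    """One TSV matrix per slide plus a JSON index; returns the index path."""
    out_dir = Path(out_dir)
    (out_dir / "embeddings").mkdir(parents=True, exist_ok=True)
    entries = []
    for sid, samp, sec, mat in zip(
        eset.slide_ids, eset.sample_ids, eset.sections, eset.matrices
    ):
        rel = f"embeddings/{sid}.tsv"
        np.savetxt(out_dir / rel, mat, delimiter="\t", fmt="%.8g")
        entries.append(dict(slide_id=sid, sample_id=samp, section=sec, path=rel))
    index = dict(d=eset.d, slides=entries)
    index_path = out_dir / "embedding_index.json"
    with open(index_path, "w") as fh:
        json.dump(index, fh, indent=1)
    return index_path


def read_embedding_set(index_path: str | Path) -> EmbeddingSet:
    index_path = Path(index_path)
    with open(index_path) as fh:
        index = json.load(fh)
    base = index_path.parent
    slide_ids, samples, sections, mats = [], [], [], []
    for entry in index["slides"]:
        mat = np.loadtxt(base / entry["path"], delimiter="\t", ndmin=2)
        slide_ids.append(entry["slide_id"])
        samples.append(entry["sample_id"])
        sections.append(entry["section"])
        mats.append(mat)
    return EmbeddingSet(
        slide_ids=slide_ids, sample_ids=samples, sections=sections, matrices=mats
    )


def write_distance_matrix(dm, out_dir: str | Path, stem: str) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dm.to_frame().to_csv(out_dir / f"{stem}.csv")
    sidecar = dict(
        metric=dm.metric, params=dm.params, n_failed=dm.n_failed,
        sample_ids=dm.sample_ids, sections=dm.sections,
    )
    with open(out_dir / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
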