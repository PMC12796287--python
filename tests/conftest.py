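"""Shared fixtures: small deterministic slides and the full desk-scale cohort.

The full 50-sample x 3-section cohort (and its features/embeddings) is
expensive, so it is built once per session and shared by the end-to-end
tests; unit tests use small scaled-down cohorts or hand-built tables.
"""

import numpy as np
import pandas as pd
import pytest

import sliderep as sr


def make_slide(rng: np.random.Generator, counts: dict[str, int],
               extent: float = 1000.0) -> pd.DataFrame:
    """Uniform-random nuclei table with the given per-type counts."""
    rows = []
    nid = 0
    for cell_type, n in counts.items():
        for _ in range(n):
            rows.append(dict(nucleus_id=nid, x=rng.uniform(0, extent),
                             y=rng.uniform(0, extent), cell_type=cell_type))
            nid += 1
    return pd.DataFrame(rows)


RICH_COUNTS = {
    "neoplastic_epithelial": 60,
    "non_neoplastic_epithelial": 25,
    "uncategorized_epithelial": 25,
    "inflammatory": 40,
    "lymphocyte": 50,
    "neutrophil": 20,
    "connective": 50,
    "dead": 30,
}


@pytest.fixture
def rich_slide():
    """Slide containing all 8 base types with plenty of nuclei per group."""
    return make_slide(np.random.default_rng(7), RICH_COUNTS)


@pytest.fixture(scope="session")
def scheme():
    return sr.CellTypeScheme.default()


@pytest.fixture(scope="session")
def spatial_config():
    return sr.SpatialConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap 6-sample cohort for pipeline-level unit tests."""
    spec = sr.CohortSpec(n_samples=6, seed=3).scaled(0.15)
    manifest, tables = sr.generate_cohort(spec)
    return spec, manifest, tables


@pytest.fixture(scope="session")
def full_cohort():
    """The default desk-scale study conditions: 50 samples x 3 sections."""
    spec = sr.CohortSpec(seed=11)
    manifest, tables = sr.generate_cohort(spec)
    return spec, manifest, tables


@pytest.fixture(scope="session")
def full_features(full_cohort):
    _, _, tables = full_cohort
    return sr.extract_cohort_features(tables)


@pytest.fixture(scope="session")
def full_icc_table(full_cohort, full_features):
    _, manifest, _ = full_cohort
    return sr.icc_table(full_features, manifest)


@pytest.fixture(scope="session")
def full_embeddings(full_cohort):
    _, manifest, _ = full_cohort
    return sr.generate_embedding_set(sr.EmbeddingSpec(seed=5), manifest)
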