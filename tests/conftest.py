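from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from batjsdm.core_data import (CaptureTable, ModelData, PhyloCorrelation,
                               SiteCovariateTable, TraitTable)


@pytest.fixture
def toy_captures() -> CaptureTable:
    """Three records over two sessions at two sites, plus one all-zero
    session kept in the register."""
    records = pd.DataFrame({
        "site_id": ["CF01", "CF01", "FR01"],
        "session_id": ["CF01-P1-01", "CF01-P1-01", "FR01-P1-01"],
        "period": [1, 1, 1],
        "date": ["", "", ""],
        "species_id": ["spA", "spB", "spA"],
        "individuals": [2, 1, 5],
        "effort_mnh": [100.0, 100.0, 80.0],
    })
    sessions = pd.DataFrame({
        "session_id": ["CF01-P1-01", "FR01-P1-01", "SF01-P2-01"],
        "site_id": ["CF01", "FR01", "SF01"],
        "period": [1, 1, 2],
        "effort_mnh": [100.0, 80.0, 40.0],
    })
    return CaptureTable(records=records, sessions=sessions)


@pytest.fixture
def toy_covariates() -> SiteCovariateTable:
    rows = []
    for site, hab, c1, c2 in (("CF01", "continuous", 2.0, 8.0),
                              ("FR01", "fragment", 40.0, 55.0),
                              ("SF01", "secondary", 70.0, 85.0)):
        rows.append((site, 1, hab, c1))
        rows.append((site, 2, hab, c2))
    return SiteCovariateTable(pd.DataFrame(
        rows, columns=["site_id", "period", "habitat", "sec_cover_500m"]))


@pytest.fixture
def toy_traits() -> TraitTable:
    return TraitTable(pd.DataFrame({
        "species_id": ["spA", "spB"],
        "affinity": ["specialist", "generalist"],
    }))


@pytest.fixture
def toy_phylo() -> PhyloCorrelation:
    return PhyloCorrelation(["spA", "spB"], np.eye(2))


def make_probit_model_data(rng: np.random.Generator, n: int = 30,
                           beta=(0.3, -0.8)) -> tuple[ModelData, np.ndarray]:
    """Single-species, two-covariate occurrence-only dataset with known
    generating coefficients (for oracle comparisons)."""
    X = np.column_stack([np.ones(n), rng.normal(0.0, 1.0, n)])
    beta = np.asarray(beta, float)
    y = (X @ beta + rng.standard_normal(n) > 0).astype(np.int8)
    data = ModelData(
        Y_occ=y[:, None], Y_cond=np.where(y[:, None] > 0, 0.0, np.nan),
        cond_mask=y[:, None] > 0, X=X, T=np.ones((1, 1)),
        C=PhyloCorrelation(["sp1"], np.eye(1)),
        site_index=np.zeros(n, dtype=int), site_ids=["s1"],
        session_ids=[f"v{i}" for i in range(n)], species_ids=["sp1"],
        design_columns=("b0", "b1"))
    return data, y


def make_tiny_joint_data(rng: np.random.Generator) -> ModelData:
    """S=3, n=20, p=2 hurdle dataset scaffold (observations get replaced
    during joint-distribution testing)."""
    n, S = 20, 3
    X = np.column_stack([np.ones(n), rng.normal(0.0, 0.5, n)])
    C = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.2], [0.2, 0.2, 1.0]])
    T = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 0.0]])
    y = np.zeros((n, S), dtype=np.int8)
    y[::2] = 1
    return ModelData(
        Y_occ=y, Y_cond=np.where(y > 0, 0.0, np.nan), cond_mask=y > 0,
        X=X, T=T, C=PhyloCorrelation(["a", "b", "c"], C),
        site_index=np.repeat(np.arange(4), 5), site_ids=list("PQRS"),
        session_ids=[f"v{i}" for i in range(n)],
        species_ids=["a", "b", "c"], design_columns=("b0", "b1"))
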