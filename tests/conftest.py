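import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from atlasq import (
    ExpressionDataset,
    SimSpec,
    fit_reference,
    normalize_log1p,
    select_hvg,
    simulate_reference,
)


def make_dataset(counts, cell_ids=None, gene_ids=None, biotypes=None, **cell_cols):
    """Small helper to build a dataset from a dense array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    cell_ids = cell_ids or [f"c{i}" for i in range(n)]
    gene_ids = gene_ids or [f"g{j}" for j in range(g)]
    cell_meta = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    for k, v in cell_cols.items():
        cell_meta[k] = v
    gene_meta = pd.DataFrame(
        {
            "symbol": gene_ids,
            "biotype": biotypes if biotypes is not None else "protein_coding",
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return ExpressionDataset(
        counts=sparse.csr_matrix(counts), cell_meta=cell_meta, gene_meta=gene_meta
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_spec():
    return SimSpec(seed=1, cells_per_type=80, n_genes=1200, markers_per_type=30,
                   n_maturation_genes=60)


@pytest.fixture(scope="session")
def sim_reference(small_spec):
    """Normalized simulated reference + ground truth (session-scoped)."""
    ds, truth = simulate_reference(small_spec)
    return normalize_log1p(ds), truth


@pytest.fixture(scope="session")
def sim_model(sim_reference):
    ds, _ = sim_reference
    hvg = select_hvg(ds, n=800)
    return fit_reference(ds, hvg, d=20)
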