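import warnings

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

import clonodyn as cd


@pytest.fixture(scope="session")
def model():
    return cd.TrajectoryModel()


@pytest.fixture(scope="session")
def uniform_cells(model):
    """2,500 cells of one stage spread uniformly along the trajectory."""
    cells, truth = cd.simulate_cells(
        model,
        2500,
        [cd.CohortSpec("cohort1", "stage1", loc=0.0, scale=1.0, distribution="uniform")],
        seed=11,
    )
    return cells, truth


@pytest.fixture(scope="session")
def small_adata(model, uniform_cells):
    """Normalized + scaled expression for the uniform cells (300-gene panel)."""
    cells, _ = uniform_cells
    panel = cd.archetype_panel(300, model, stages=("stage1",), n_dynamic=6, seed=12)
    adata, truth = cd.simulate_expression(cells, panel, seed=13)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adata = cd.normalize_counts(adata)
        adata = cd.scale_genes(adata)
    return adata, truth


def make_adata(counts, normalize=True):
    """Small hand-built AnnData with counts (cells x genes) and derived layers."""
    counts = np.asarray(counts, dtype=np.int32)
    n, g = counts.shape
    adata = AnnData(
        X=counts.copy(),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(n)]),
        var=pd.DataFrame(index=[f"g{j}" for j in range(g)]),
    )
    adata.layers["counts"] = counts
    if normalize:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adata = cd.normalize_counts(adata)
            adata = cd.scale_genes(adata)
    return adata
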