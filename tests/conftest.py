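import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

import empflow as ef


@pytest.fixture(scope="session")
def cohort():
    """Small default cohort with programs, CNVs, batch effects and doublets."""
    config = ef.SyntheticConfig(cells_per_patient=300, seed=11)
    adata, truth = ef.generate_cohort(config)
    return config, adata, truth


@pytest.fixture(scope="session")
def cohort_norm(cohort):
    _, adata, _ = cohort
    return ef.log_normalize(adata)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with all effects at 1 and no copy-number blocks."""
    config = ef.SyntheticConfig(
        n_patients=1, cells_per_patient=600, doublet_rate=0.0,
        program_gene_sets={}, cnv_blocks=[], patient_batch_sd=0.0, seed=21,
    )
    adata, truth = ef.generate_cohort(config)
    return config, adata, truth


@pytest.fixture()
def tiny_adata():
    """3 cells x 4 genes with known counts, one mito and one housekeeper gene."""
    X = sp.csr_matrix(np.array([
        [1, 9, 0, 0],
        [0, 0, 0, 0],
        [5, 5, 5, 5],
    ], dtype=np.int64))
    var = pd.DataFrame(
        {
            "chromosome": ["MT", "chr1", "chr1", "chr2"],
            "position": [1, 1, 2, 1],
            "mito": [True, False, False, False],
            "housekeeper": [False, False, True, False],
        },
        index=pd.Index(["mt1", "g1", "hk1", "g2"], name="gene_id"),
    )
    obs = pd.DataFrame(index=pd.Index(["c1", "c2", "c3"], name="barcode"))
    return AnnData(X=X, obs=obs, var=var)


def make_norm(values, gene_ids=None, cell_ids=None, counts=None):
    """Build a normalized-matrix AnnData directly from a dense array of
    log-normalized values (counts layer defaults to expm1-rounded values)."""
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    gene_ids = gene_ids or [f"g{j}" for j in range(g)]
    cell_ids = cell_ids or [f"c{i}" for i in range(n)]
    adata = AnnData(
        X=sp.csr_matrix(values),
        obs=pd.DataFrame(index=pd.Index(cell_ids, name="barcode")),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )
    if counts is None:
        counts = np.round(np.expm1(values)).astype(np.int64)
    adata.layers["counts"] = sp.csr_matrix(np.asarray(counts))
    return adata


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
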