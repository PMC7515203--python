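import numpy as np
import pandas as pd
import pytest

from adipomr import deconvolution as dc
from adipomr import synthetic


@pytest.fixture(scope="session")
def small_reference():
    """A small QC'd single-nucleus reference with its truth record."""
    cfg = synthetic.CellSimConfig(
        n_subjects=6, n_celltypes=4, n_genes=600, cells_per_subject=300,
        libsize_mean=4000, seed=42,
    )
    adata, truth = synthetic.simulate_sc_reference(cfg)
    qcd, _ = dc.qc_reference(adata)
    return cfg, adata, qcd, truth


@pytest.fixture(scope="session")
def small_bulk(small_reference):
    cfg, adata, qcd, truth = small_reference
    return synthetic.simulate_bulk_mixtures(
        truth, truth.true_proportions, seed=11, gene_lengths=adata.var["length"]
    )


@pytest.fixture(scope="session")
def cohort_with_truth():
    cfg = synthetic.PhenoSimConfig(n_individuals=1000, seed=9)
    return synthetic.simulate_cohort(cfg)


@pytest.fixture()
def hand_ivs():
    """Five hand-written instruments for oracle comparisons."""
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(1, 6)],
            "beta_exp": [0.10, -0.07, 0.22, 0.05, -0.14],
            "se_exp": [0.01, 0.012, 0.02, 0.015, 0.011],
            "p_exp": [1e-20, 1e-9, 1e-25, 1e-8, 1e-30],
            "beta_out": [0.06, -0.02, 0.10, 0.04, -0.08],
            "se_out": [0.02, 0.03, 0.025, 0.04, 0.015],
        }
    )


def wls_oracle(x, y, w, intercept: bool):
    """Independent weighted-least-squares solve via normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    return np.linalg.solve(A, b)
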