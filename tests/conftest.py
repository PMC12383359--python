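import anndata as ad
import numpy as np
import pandas as pd
import pytest

from embryotrans.qc import compute_qc_metrics, normalize
from embryotrans.simulate import RIBO_GENES, SimDesign, generate_counts


def make_adata(counts, genes, cells=None, obs=None):
    """Small AnnData from a dense cells x genes count array."""
    counts = np.asarray(counts)
    if cells is None:
        cells = [f"cell{i}" for i in range(counts.shape[0])]
    if obs is None:
        obs = pd.DataFrame(index=pd.Index(cells, name="cell"))
    else:
        obs = obs.copy()
        obs.index = pd.Index(cells, name="cell")
    return ad.AnnData(
        X=counts,
        obs=obs,
        var=pd.DataFrame(index=pd.Index(list(genes), name="gene")),
    )


@pytest.fixture(scope="session")
def small_simulated():
    """A modest simulated dataset, QC'd and normalized, shared read-only."""
    adata, truth = generate_counts(
        SimDesign(n_cells_per_group=60, n_genes=300, seed=42)
    )
    compute_qc_metrics(adata, ribo_genes=RIBO_GENES)
    normalize(adata)
    return adata, truth
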