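import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pimth17 import BulkExperiment, BulkSimConfig, SCExperiment, generate_bulk


@pytest.fixture(scope="session")
def small_bulk():
    """A 200-gene paired bulk simulation shared across read-only tests."""
    return generate_bulk(BulkSimConfig(n_genes=200, seed=7))


def make_bulk_experiment(counts: np.ndarray, n_pairs: int, timepoint: str = "6h"):
    """Wrap a raw genes × (2·n_pairs) array as a paired Scr/TKD experiment."""
    names, meta = [], []
    for cond in ("Scr", "TKD"):
        for p in range(n_pairs):
            names.append(f"{cond}_p{p + 1}")
            meta.append({"condition": cond, "pair": f"p{p + 1}", "timepoint": timepoint})
    genes = [f"g{i}" for i in range(counts.shape[0])]
    return BulkExperiment(
        counts=pd.DataFrame(counts, index=genes, columns=names),
        samples=pd.DataFrame(meta, index=names),
    )


def make_sc_experiment(counts: np.ndarray, gene_names, sample_of=None):
    """Wrap a dense genes × cells array as an SCExperiment."""
    n_cells = counts.shape[1]
    if sample_of is None:
        sample_of = ["S1"] * n_cells
    return SCExperiment(
        counts=sp.csr_matrix(counts),
        features=pd.DataFrame(
            {"gene_id": [f"id{i}" for i in range(len(gene_names))],
             "gene_name": list(gene_names)}
        ),
        barcodes=np.array([f"bc{i}" for i in range(n_cells)], dtype=object),
        sample_of=np.array(sample_of, dtype=object),
    )
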