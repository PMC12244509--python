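import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tgctsc import AtlasConfig, CellMatrix, NormalizedMatrix, generate_cell_atlas, normalize_log


@pytest.fixture(scope="session")
def default_atlas():
    """Default synthetic atlas with one whole-chromosome +1 log2 gain."""
    cfg = AtlasConfig(seed=11)
    matrix, positions, truth = generate_cell_atlas(cfg)
    return cfg, matrix, positions, truth


@pytest.fixture(scope="session")
def default_normalized(default_atlas):
    _, matrix, _, _ = default_atlas
    return normalize_log(matrix)


def make_cell_matrix(values: np.ndarray, mito: np.ndarray | None = None,
                     cell_types=None, samples=None) -> CellMatrix:
    """Small dense-count helper: values is genes x cells."""
    values = np.asarray(values)
    n_genes, n_cells = values.shape
    genes = pd.Index([f"g{j}" for j in range(n_genes)])
    cells = pd.Index([f"c{j}" for j in range(n_cells)])
    meta = pd.DataFrame(
        {
            "cell_type": cell_types if cell_types is not None else ["t"] * n_cells,
            "sample": samples if samples is not None else ["s1"] * n_cells,
            "condition": ["x"] * n_cells,
        },
        index=cells,
    )
    return CellMatrix(
        counts=sp.csr_matrix(values),
        gene_ids=genes,
        cell_ids=cells,
        cell_meta=meta,
        mito_genes=mito,
    )


def make_normalized(values: np.ndarray, cell_types=None, samples=None,
                    gene_ids=None) -> NormalizedMatrix:
    """Wrap a dense genes x cells value matrix as a NormalizedMatrix."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    genes = pd.Index(gene_ids) if gene_ids is not None else pd.Index(
        [f"g{j}" for j in range(n_genes)]
    )
    cells = pd.Index([f"c{j}" for j in range(n_cells)])
    meta = pd.DataFrame(
        {
            "cell_type": cell_types if cell_types is not None else ["t"] * n_cells,
            "sample": samples if samples is not None else ["s1"] * n_cells,
            "condition": ["x"] * n_cells,
        },
        index=cells,
    )
    return NormalizedMatrix(
        values=sp.csr_matrix(values),
        gene_ids=genes,
        cell_ids=cells,
        cell_meta=meta,
    )
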