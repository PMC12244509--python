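"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`CellMatrix`, a gene x cell sparse count matrix
with per-cell metadata (cell-type label, sample, condition) and a per-gene
mitochondrial flag. Downstream stages consume its log-normalized counterpart
:class:`NormalizedMatrix` and the genomic coordinates in
:class:`GenePositionTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ValidationError",
    "CellMatrix",
    "NormalizedMatrix",
    "GenePositionTable",
]

META_COLUMNS = ("cell_type", "sample", "condition")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class CellMatrix:
    """Sparse gene x cell raw counts plus per-cell metadata.

    Parameters
    ----------
    counts
        Nonnegative integer counts, genes on rows, cells on columns.
    gene_ids
        Unique, ordered gene identifiers (length = n_genes).
    cell_ids
        Unique, ordered cell identifiers (length = n_cells).
    cell_meta
        Per-cell frame indexed by ``cell_ids`` with at least the columns
        ``cell_type``, ``sample`` and ``condition``.
    mito_genes
        Boolean mask over genes marking mitochondrial genes.
    """

    counts: sp.csr_matrix
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame
    mito_genes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.mito_genes is None:
            self.mito_genes = np.zeros(self.counts.shape[0], dtype=bool)
        self.mito_genes = np.asarray(self.mito_genes, dtype=bool)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"gene_ids length {len(self.gene_ids)} != {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"cell_ids length {len(self.cell_ids)} != {n_cells} matrix columns"
            )
        if not self.gene_ids.is_unique:
            dup = self.gene_ids[self.gene_ids.duplicated()][:3].tolist()
            raise ValidationError(f"duplicate gene identifiers: {dup}")
        if not self.cell_ids.is_unique:
            raise ValidationError("duplicate cell identifiers")
        if self.mito_genes.shape != (n_genes,):
            raise ValidationError("mito_genes mask length mismatch")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be nonnegative")
        missing = [c for c in META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise ValidationError(f"cell_meta missing columns: {missing}")
        if not self.cell_meta.index.equals(self.cell_ids):
            self.cell_meta = self.cell_meta.reindex(self.cell_ids)
            if self.cell_meta[list(META_COLUMNS)].isna().any().any():
                raise ValidationError("cell_meta does not cover all cell_ids")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, keep: np.ndarray) -> "CellMatrix":
        """Return a copy restricted to the boolean/index cell selection.

        Preserves the original ordering of surviving cells.
        """
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CellMatrix(
            counts=self.counts[:, keep].tocsr(),
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[keep],
            cell_meta=self.cell_meta.iloc[keep],
            mito_genes=self.mito_genes,
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells x genes) view."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame({"mito": self.mito_genes}, index=self.gene_ids),
        )


@dataclass
class NormalizedMatrix:
    """Library-size-normalized, log-transformed expression (genes x cells).

    ``values[g, c] = log(1 + scale_factor * count[g, c] / total[c])`` with
    natural log; de-logged per-cell sums therefore equal ``scale_factor``.
    """

    values: sp.csr_matrix
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_meta: pd.DataFrame
    scale_factor: float = 1e4
    source: CellMatrix | None = None

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("values shape inconsistent with identifiers")
        if self.values.nnz and not np.all(np.isfinite(self.values.data)):
            raise ValidationError("normalized values must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def labels(self, column: str = "cell_type") -> pd.Series:
        return self.cell_meta[column]

    def subset_cells(self, keep: np.ndarray) -> "NormalizedMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return NormalizedMatrix(
            values=self.values[:, keep].tocsr(),
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[keep],
            cell_meta=self.cell_meta.iloc[keep],
            scale_factor=self.scale_factor,
            source=self.source,
        )

    def subset_genes(self, genes) -> "NormalizedMatrix":
        idx = self.gene_ids.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            missing = list(pd.Index(genes)[idx < 0][:5])
            raise ValidationError(f"genes absent from matrix: {missing}")
        return NormalizedMatrix(
            values=self.values[idx, :].tocsr(),
            gene_ids=self.gene_ids[idx],
            cell_ids=self.cell_ids,
            cell_meta=self.cell_meta,
            scale_factor=self.scale_factor,
            source=self.source,
        )


class GenePositionTable:
    """Genomic coordinates per gene (0-based, half-open intervals).

    Stored sorted by (chromosome, start); provides the genomic gene order the
    copy-number stage smooths along.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"chrom", "start", "end", "gene"}
        if not required.issubset(frame.columns):
            raise ValidationError(f"position table needs columns {sorted(required)}")
        if frame["gene"].duplicated().any():
            dup = frame.loc[frame["gene"].duplicated(), "gene"].iloc[0]
            raise ValidationError(f"duplicate gene in position table: {dup!r}")
        if (frame["start"] >= frame["end"]).any():
            raise ValidationError("intervals must satisfy start < end")
        self.frame = (
            frame.sort_values(["chrom", "start"], kind="stable")
            .reset_index(drop=True)
            .copy()
        )

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.frame["gene"])

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.frame["gene"])

    @property
    def chromosomes(self) -> pd.Series:
        return self.frame["chrom"]

    def ordered_genes_present(self, gene_ids: pd.Index) -> pd.DataFrame:
        """Rows of the table whose gene is in ``gene_ids``, genomic order."""
        mask = self.frame["gene"].isin(set(gene_ids))
        return self.frame.loc[mask].reset_index(drop=True)
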