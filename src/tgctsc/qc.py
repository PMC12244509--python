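"""Cell-level quality control and log normalization.

QC keeps cells with a detected-feature count strictly between the configured
bounds and a mitochondrial count fraction strictly below the cap, then removes
lineage doublets: cells with nonzero counts for both genes of any configured
mutually-exclusive marker pair (e.g. a T-cell marker together with a B-cell
marker). All three inequalities are strict, read literally from the
"more than / less than" retention rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .containers import CellMatrix, NormalizedMatrix, ValidationError

__all__ = ["QcParams", "QcReport", "qc_filter", "normalize_log"]


@dataclass
class QcParams:
    min_features: int = 200  # exclusive lower bound
    max_features: int = 6000  # exclusive upper bound
    max_mito_frac: float = 0.10  # exclusive upper bound, fraction of counts
    doublet_pairs: tuple = ()

    def validate(self) -> None:
        if self.min_features >= self.max_features:
            raise ValidationError("min_features must be < max_features")
        if not 0.0 < self.max_mito_frac <= 1.0:
            raise ValidationError("max_mito_frac must be in (0, 1]")


@dataclass
class QcReport:
    n_input: int
    n_low_features: int
    n_high_features: int
    n_high_mito: int
    n_doublet: int
    n_retained: int


def qc_filter(m: CellMatrix, p: QcParams) -> tuple[CellMatrix, QcReport]:
    """Apply the retention rules in order; cells are never reordered.

    A cell removed by an earlier rule is not counted again by a later one.
    """
    p.validate()
    counts = m.counts.tocsc()
    n_features = np.asarray((counts > 0).sum(axis=0)).ravel()
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)

    keep = np.ones(m.n_cells, dtype=bool)
    low = n_features <= p.min_features
    keep &= ~low
    high = keep & (n_features >= p.max_features)
    keep &= ~high

    n_mito_fail = 0
    if p.max_mito_frac < 1.0:
        if not m.mito_genes.any():
            raise ValidationError(
                "max_mito_frac < 1 requires mitochondrial gene flags"
            )
        mito_counts = np.asarray(counts[m.mito_genes, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
        mito_fail = keep & (frac >= p.max_mito_frac)
        n_mito_fail = int(mito_fail.sum())
        keep &= ~mito_fail

    n_doublet = 0
    if p.doublet_pairs:
        gene_pos = {g: j for j, g in enumerate(m.gene_ids)}
        doublet = np.zeros(m.n_cells, dtype=bool)
        for ga, gb in p.doublet_pairs:
            for g in (ga, gb):
                if g not in gene_pos:
                    raise ValidationError(f"doublet-pair gene {g!r} absent from matrix")
            a = np.asarray((counts[gene_pos[ga], :] > 0).todense()).ravel()
            b = np.asarray((counts[gene_pos[gb], :] > 0).todense()).ravel()
            doublet |= a & b
        doublet &= keep
        n_doublet = int(doublet.sum())
        keep &= ~doublet

    report = QcReport(
        n_input=m.n_cells,
        n_low_features=int(low.sum()),
        n_high_features=int(high.sum()),
        n_high_mito=n_mito_fail,
        n_doublet=n_doublet,
        n_retained=int(keep.sum()),
    )
    return m.subset_cells(keep), report


def normalize_log(m: CellMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """``value = log(1 + scale_factor * count / cell_total)``, natural log."""
    if scale_factor <= 0:
        raise ValidationError("scale_factor must be > 0")
    totals = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    zero = totals == 0
    if zero.any():
        ids = list(m.cell_ids[zero][:10])
        raise ValidationError(f"cells with zero total count: {ids}")
    values = m.counts.tocsc().astype(float)
    # scale columns, then log1p; zeros stay zero so sparsity is preserved
    scaler = sp.diags(scale_factor / totals)
    values = values @ scaler
    values.data = np.log1p(values.data)
    return NormalizedMatrix(
        values=values.tocsr(),
        gene_ids=m.gene_ids,
        cell_ids=m.cell_ids,
        cell_meta=m.cell_meta,
        scale_factor=scale_factor,
        source=m,
    )
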