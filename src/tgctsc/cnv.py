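"""Reference-based copy-number inference from expression, and the CNV score.

Putative tumor lineages are compared with copy-number-normal reference
lineages (e.g. endothelial cells and lymphocytes): per gene the mean
reference expression is subtracted, each cell is re-centered, residuals are
clipped and smoothed with a centered moving average along the genomic gene
order within each chromosome. The whole residual matrix is then normalized to
[-1, 1] by its global maximum absolute value and the per-cell sum of squares
of the normalized values is the CNV score; query clusters whose score
distribution sits clearly above the reference distribution are annotated as
tumor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .containers import GenePositionTable, NormalizedMatrix, ValidationError

__all__ = [
    "CnvProfile",
    "CnvScoreResult",
    "infer_cnv_profile",
    "cnv_score",
    "call_tumor_clusters",
]


@dataclass
class CnvProfile:
    """Smoothed expression residuals, cells x genes in genomic order."""

    residuals: np.ndarray
    cell_ids: pd.Index
    cell_labels: pd.Series
    genes: pd.Index
    chromosomes: pd.Series
    window: int
    clip: float
    reference_labels: frozenset
    query_labels: frozenset
    dropped_genes: list = field(default_factory=list)


@dataclass
class CnvScoreResult:
    scores: pd.Series  # per cell, >= 0
    normalized: np.ndarray  # cells x genes in [-1, 1]
    cell_labels: pd.Series
    max_abs_residual: float
    tumor_flags: dict = field(default_factory=dict)
    margins: dict = field(default_factory=dict)


def _moving_average_shrink(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the last axis with symmetric shrinking
    windows at the edges: position j averages over [j-k, j+k] with
    k = min(half, j, L-1-j)."""
    L = x.shape[-1]
    h = window // 2
    if h == 0 or L < 3:
        return x.copy()
    cs = np.cumsum(x, axis=-1)
    cs = np.concatenate([np.zeros(x.shape[:-1] + (1,)), cs], axis=-1)
    j = np.arange(L)
    k = np.minimum(h, np.minimum(j, L - 1 - j))
    lo = j - k
    hi = j + k + 1
    return (cs[..., hi] - cs[..., lo]) / (hi - lo)


def infer_cnv_profile(
    nm: NormalizedMatrix,
    positions: GenePositionTable,
    query_labels,
    reference_labels,
    window: int = 51,
    clip: float = 1.5,
    label_column: str = "cell_type",
) -> CnvProfile:
    """Residual profiles for query *and* reference cells against the
    reference mean, smoothed along each chromosome.

    Genes without a genomic position are dropped (and reported on the
    returned profile); chromosomes with fewer than 3 positioned genes are
    passed through unsmoothed with a warning.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError("window must be a positive odd integer")
    if clip <= 0:
        raise ValidationError("clip must be > 0")
    query_labels = frozenset(query_labels)
    reference_labels = frozenset(reference_labels)
    if not query_labels or not reference_labels:
        raise ValidationError("query and reference label sets must be nonempty")
    if query_labels & reference_labels:
        raise ValidationError("query and reference label sets must be disjoint")

    labels = nm.labels(label_column)
    ref_mask = labels.isin(reference_labels).to_numpy()
    qry_mask = labels.isin(query_labels).to_numpy()
    if not ref_mask.any():
        raise ValidationError("no cells match the reference labels")
    if not qry_mask.any():
        raise ValidationError("no cells match the query labels")

    placed = positions.ordered_genes_present(nm.gene_ids)
    dropped = sorted(set(nm.gene_ids) - set(placed["gene"]))
    if len(placed) == 0:
        raise ValidationError("no genes have genomic positions")

    sub = nm.subset_genes(placed["gene"])
    keep_cells = ref_mask | qry_mask
    dense = np.asarray(sub.values[:, keep_cells].todense()).T  # cells x genes
    cell_ids = nm.cell_ids[keep_cells]
    cell_labels = labels[keep_cells]
    ref_rows = cell_labels.isin(reference_labels).to_numpy()

    ref_mean = dense[ref_rows].mean(axis=0)
    resid = dense - ref_mean[None, :]
    resid -= resid.mean(axis=1, keepdims=True)  # per-cell re-centering
    np.clip(resid, -clip, clip, out=resid)

    smoothed = np.empty_like(resid)
    chroms = placed["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        if cols.size < 3:
            warnings.warn(
                f"chromosome {chrom!r} has {cols.size} genes; left unsmoothed"
            )
            smoothed[:, cols] = resid[:, cols]
        else:
            smoothed[:, cols] = _moving_average_shrink(resid[:, cols], window)

    return CnvProfile(
        residuals=smoothed,
        cell_ids=cell_ids,
        cell_labels=cell_labels,
        genes=pd.Index(placed["gene"]),
        chromosomes=placed["chrom"],
        window=window,
        clip=clip,
        reference_labels=reference_labels,
        query_labels=query_labels,
        dropped_genes=dropped,
    )


def cnv_score(profile: CnvProfile) -> CnvScoreResult:
    """Normalize residuals to [-1, 1] by the global max-abs value; the CNV
    score of a cell is the sum of squares of its normalized values."""
    if profile.residuals.size == 0:
        raise ValidationError("empty CNV profile")
    m = float(np.abs(profile.residuals).max())
    if m == 0:
        normalized = np.zeros_like(profile.residuals)
    else:
        normalized = profile.residuals / m
    scores = pd.Series(
        (normalized**2).sum(axis=1), index=profile.cell_ids, name="cnv_score"
    )
    return CnvScoreResult(
        scores=scores,
        normalized=normalized,
        cell_labels=profile.cell_labels,
        max_abs_residual=m,
    )


def call_tumor_clusters(
    result: CnvScoreResult,
    query_labels,
    reference_labels,
    z_cut: float = 3.0,
) -> CnvScoreResult:
    """Flag query clusters whose median CNV score exceeds
    ``median(ref) + z_cut * MAD(ref)``.

    Falls back to a one-sided rank-sum test at alpha = 0.01 when the
    reference MAD is zero (degenerate reference spread); the fallback is
    noted in ``margins`` as +/- inf.
    """
    labels = result.cell_labels
    ref_scores = result.scores[labels.isin(set(reference_labels)).to_numpy()]
    if len(ref_scores) < 20:
        raise ValidationError("need at least 20 reference cells")
    ref_med = float(np.median(ref_scores))
    mad = float(np.median(np.abs(ref_scores - ref_med)))

    flags: dict[str, bool] = {}
    margins: dict[str, float] = {}
    for label in sorted(set(query_labels)):
        cluster = result.scores[(labels == label).to_numpy()]
        if len(cluster) == 0:
            continue
        med = float(np.median(cluster))
        if mad > 0:
            z = (med - ref_med) / mad
            flags[label] = bool(z > z_cut)
            margins[label] = z
        else:
            p = mannwhitneyu(cluster, ref_scores, alternative="greater").pvalue
            flags[label] = bool(p < 0.01 and med > ref_med)
            margins[label] = float("inf") if flags[label] else float("-inf")
    result.tumor_flags = flags
    result.margins = margins
    return result
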