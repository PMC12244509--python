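"""Group-wise expression statistics, one-vs-rest DEGs, and the strict
marker-specificity filter.

``pct.1`` / ``pct.2`` are the fractions of cells with nonzero expression
inside / outside the target population. ``log2fc`` is the log2 ratio of
de-logged group means with a pseudocount, matching the avg_log2FC convention
of the standard single-cell toolchain. The specificity filter applies the
strict criteria that single out tumor-exclusive surface markers: expressed in
more than half the target cells, in fewer than 3% of the rest, and with
|log2FC| above 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, ranksum_p
from .containers import NormalizedMatrix, ValidationError

__all__ = [
    "MarkerCriteria",
    "group_stats",
    "find_deg",
    "find_specific_markers",
]


@dataclass
class MarkerCriteria:
    """Strict specificity thresholds (all inequalities strict)."""

    min_pct1: float = 0.50
    max_pct2: float = 0.03
    min_abs_log2fc: float = 2.0

    def validate(self) -> None:
        if self.min_pct1 <= self.max_pct2:
            raise ValidationError("min_pct1 must exceed max_pct2")


def _group_blocks(nm: NormalizedMatrix, cells) -> np.ndarray:
    idx = nm.cell_ids.get_indexer(pd.Index(cells))
    if (idx < 0).any():
        raise ValidationError("group contains unknown cell ids")
    return np.asarray(nm.values[:, idx].todense())


def group_stats(
    nm: NormalizedMatrix,
    group1,
    group2,
    pseudocount: float = 1.0,
    *,
    test_p: bool = True,
) -> pd.DataFrame:
    """Per-gene pct1/pct2, log2 fold change and Wilcoxon p for two cell sets.

    ``log2fc = log2((mean(expm1(v1)) + pc) / (mean(expm1(v2)) + pc))``.
    p-values are two-sided rank-sum on the normalized values, BH-adjusted
    across the tested genes.
    """
    g1 = set(group1)
    g2 = set(group2)
    if g1 & g2:
        raise ValidationError("groups must be disjoint")
    if len(g1) < 3 or len(g2) < 3:
        raise ValidationError("each group needs at least 3 cells")
    v1 = _group_blocks(nm, sorted(g1))
    v2 = _group_blocks(nm, sorted(g2))

    pct1 = (v1 > 0).mean(axis=1)
    pct2 = (v2 > 0).mean(axis=1)
    m1 = np.expm1(v1).mean(axis=1)
    m2 = np.expm1(v2).mean(axis=1)
    log2fc = np.log2((m1 + pseudocount) / (m2 + pseudocount))

    if test_p:
        p = ranksum_p(v1, v2)
        adj = bh_adjust(p)
    else:
        p = np.full(nm.n_genes, np.nan)
        adj = p
    return pd.DataFrame(
        {
            "gene": nm.gene_ids,
            "pct1": pct1,
            "pct2": pct2,
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": adj,
        }
    ).set_index("gene")


def find_deg(
    nm: NormalizedMatrix,
    labels: pd.Series | None = None,
    min_pct: float = 0.1,
    min_log2fc: float = 0.5,
    only_pos: bool = True,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """One-vs-rest DEG tables per label, ranked by log2fc descending.

    Genes enter the test only if expressed in at least ``min_pct`` of either
    group and their fold change clears ``min_log2fc``; BH adjustment runs over
    the tested genes of each label, and genes with adjusted p >= ``alpha``
    are dropped.
    """
    if labels is None:
        labels = nm.labels()
    labels = pd.Series(labels, index=nm.cell_ids)
    uniq = [l for l in pd.unique(labels)]
    if len(uniq) < 2:
        raise ValidationError("find_deg needs at least 2 labels")

    dense = nm.dense()
    out: dict[str, pd.DataFrame] = {}
    for label in uniq:
        mask = (labels == label).to_numpy()
        if mask.sum() < 3:
            warnings.warn(f"label {label!r} has < 3 cells; skipped")
            continue
        v1 = dense[:, mask]
        v2 = dense[:, ~mask]
        pct1 = (v1 > 0).mean(axis=1)
        pct2 = (v2 > 0).mean(axis=1)
        m1 = np.expm1(v1).mean(axis=1)
        m2 = np.expm1(v2).mean(axis=1)
        log2fc = np.log2((m1 + pseudocount) / (m2 + pseudocount))

        keep = np.maximum(pct1, pct2) >= min_pct
        if only_pos:
            keep &= log2fc >= min_log2fc
        else:
            keep &= np.abs(log2fc) >= min_log2fc
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            warnings.warn(f"label {label!r}: no genes pass the DEG prefilter")
            out[str(label)] = pd.DataFrame(
                columns=["pct1", "pct2", "log2fc", "p_value", "adj_p"]
            )
            continue
        p = ranksum_p(v1[idx], v2[idx])
        adj = bh_adjust(p)
        table = pd.DataFrame(
            {
                "gene": nm.gene_ids[idx],
                "pct1": pct1[idx],
                "pct2": pct2[idx],
                "log2fc": log2fc[idx],
                "p_value": p,
                "adj_p": adj,
            }
        ).set_index("gene")
        table = table[table["adj_p"] < alpha]
        table = table.sort_values("log2fc", ascending=False, kind="stable")
        out[str(label)] = table
    return out


def find_specific_markers(stats: pd.DataFrame, c: MarkerCriteria | None = None) -> list[str]:
    """Genes passing all three strict specificity criteria, best fold first."""
    c = c or MarkerCriteria()
    c.validate()
    passes = (
        (stats["pct1"] > c.min_pct1)
        & (stats["pct2"] < c.max_pct2)
        & (stats["log2fc"].abs() > c.min_abs_log2fc)
    )
    hits = stats.loc[passes].sort_values("log2fc", ascending=False, kind="stable")
    return list(hits.index)
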