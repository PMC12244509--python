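"""Correlative cell-cell interaction network through a bulk cohort.

The procedure links single-cell populations via a bulk expression cohort:
(1) per-type signatures = top-N positive one-vs-rest DEGs; (2) "self-expressed
genes" per type (broadly expressed by the type itself); (3) per-sample type
abundance = mean z-scored bulk expression of the signature genes; (4) Pearson
correlation of every bulk gene with every type's abundance, with each type's
self-expressed genes masked to 0 (a type must not trivially "regulate" its own
abundance); (5) per target type, the top-N correlated genes form a gene set
whose module score in source-type cells is the directed edge weight
source -> target. Gene symbols are matched between the single-cell and bulk
universes case-insensitively (upper-cased), the single deliberate exception to
opaque identifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._stats import pearson_matrix, zscore_rows
from .containers import NormalizedMatrix, ValidationError
from .markers import find_deg
from .scoring import GeneSet, module_score

__all__ = [
    "SignatureSet",
    "cell_type_signatures",
    "self_expressed_genes",
    "estimate_bulk_abundance",
    "correlate_genes_abundance",
    "build_correlative_network",
]


@dataclass
class SignatureSet:
    """Top-ranked marker genes per cell type, with their DEG stats."""

    genes_of_type: dict  # type -> ordered gene list
    stats_of_type: dict = field(default_factory=dict)
    top_n: int = 30

    def __iter__(self):
        return iter(self.genes_of_type.items())


def cell_type_signatures(
    nm: NormalizedMatrix,
    labels: pd.Series | None = None,
    top_n: int = 30,
    min_pct: float = 0.1,
    min_log2fc: float = 0.5,
    alpha: float = 0.05,
) -> SignatureSet:
    """Per type, the ``top_n`` positive one-vs-rest DEGs by log2 fold change.

    Types with fewer passing genes keep all of them (the count is visible via
    the stored stats tables).
    """
    tables = find_deg(
        nm,
        labels,
        min_pct=min_pct,
        min_log2fc=min_log2fc,
        only_pos=True,
        alpha=alpha,
    )
    genes = {}
    stats = {}
    for label, table in tables.items():
        top = table.head(top_n)
        genes[label] = list(top.index)
        stats[label] = top
        if len(top) == 0:
            warnings.warn(f"type {label!r} has an empty signature")
    return SignatureSet(genes_of_type=genes, stats_of_type=stats, top_n=top_n)


def self_expressed_genes(
    nm: NormalizedMatrix,
    labels: pd.Series | None = None,
    min_avg: float = 1.0,
    min_freq: float = 0.20,
) -> dict[str, list]:
    """Genes each type broadly expresses: mean normalized expression strictly
    above ``min_avg`` and nonzero fraction strictly above ``min_freq``."""
    if labels is None:
        labels = nm.labels()
    labels = pd.Series(labels, index=nm.cell_ids)
    dense = nm.dense()
    out: dict[str, list] = {}
    for label in pd.unique(labels):
        mask = (labels == label).to_numpy()
        block = dense[:, mask]
        keep = (block.mean(axis=1) > min_avg) & ((block > 0).mean(axis=1) > min_freq)
        out[str(label)] = list(nm.gene_ids[keep])
    return out


def estimate_bulk_abundance(
    bulk: pd.DataFrame,
    sigs: SignatureSet,
    min_present_frac: float = 0.5,
) -> pd.DataFrame:
    """Sample x type abundance: mean z-scored bulk expression of each type's
    signature genes (then re-standardized per type so columns have mean 0 and
    SD 1 across samples).

    Bulk rows are genes, columns samples. Constant genes are dropped with a
    warning; a type with under ``min_present_frac`` of its signature present
    in the bulk raises.
    """
    if bulk.shape[1] < 2:
        raise ValidationError("bulk matrix needs >= 2 samples")
    upper_index = pd.Index([str(g).upper() for g in bulk.index])
    z, valid = zscore_rows(bulk.values)
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} constant bulk genes dropped from z-scoring"
        )
    zframe = pd.DataFrame(z[valid], index=upper_index[valid], columns=bulk.columns)

    abundance = {}
    for label, genes in sigs:
        wanted = pd.Index([str(g).upper() for g in genes])
        present = wanted[wanted.isin(zframe.index)]
        if len(genes) and len(present) / len(genes) < min_present_frac:
            raise ValidationError(
                f"type {label!r}: only {len(present)}/{len(genes)} signature genes "
                "present in bulk"
            )
        if len(present) == 0:
            warnings.warn(f"type {label!r}: no signature genes in bulk; skipped")
            continue
        mean_z = zframe.loc[present].values.mean(axis=0)
        sd = mean_z.std(ddof=0)
        abundance[label] = (mean_z - mean_z.mean()) / sd if sd > 0 else mean_z * 0.0
    if not abundance:
        raise ValidationError("no type has signature genes in the bulk matrix")
    return pd.DataFrame(abundance, index=bulk.columns)


def correlate_genes_abundance(
    bulk: pd.DataFrame,
    abundance: pd.DataFrame,
    self_sets: dict[str, list] | None = None,
) -> pd.DataFrame:
    """Adjusted gene x type Pearson correlation matrix.

    PCC of each bulk gene (across samples) with each type's abundance;
    entries for a type's self-expressed genes are set to 0 before any
    ranking, per the adjusted-correlation rule.
    """
    if bulk.shape[1] < 8:
        raise ValidationError("need >= 8 samples for correlation")
    if not bulk.columns.equals(abundance.index):
        abundance = abundance.reindex(bulk.columns)
        if abundance.isna().any().any():
            raise ValidationError("abundance samples do not match bulk samples")
    r = pearson_matrix(bulk.values, abundance.values.T)
    corr = pd.DataFrame(
        r,
        index=pd.Index([str(g).upper() for g in bulk.index]),
        columns=abundance.columns,
    )
    if self_sets:
        for label, genes in self_sets.items():
            if label not in corr.columns:
                continue
            mask = corr.index.isin({str(g).upper() for g in genes})
            corr.loc[mask, label] = 0.0
    return corr


def build_correlative_network(
    corr: pd.DataFrame,
    nm: NormalizedMatrix,
    labels: pd.Series | None = None,
    top_n: int = 30,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> nx.DiGraph:
    """Directed network: for each target type take its ``top_n`` most
    positively adjusted-correlated bulk genes, module-score that set over all
    cells, and weight the edge source -> target by the mean score of
    source-type cells.

    Edge attributes: ``weight`` and the correlated ``gene_set`` (mapped back
    into the single-cell universe). Targets whose correlated set is empty (or
    absent from the single-cell matrix) are skipped with a warning.
    """
    if labels is None:
        labels = nm.labels()
    labels = pd.Series(labels, index=nm.cell_ids)
    types = [str(t) for t in pd.unique(labels)]

    upper_to_sc = {}
    for g in nm.gene_ids:
        upper_to_sc.setdefault(str(g).upper(), g)

    graph = nx.DiGraph()
    graph.add_nodes_from(sorted(set(types) | set(map(str, corr.columns))))
    for target in corr.columns:
        col = corr[target]
        col = col[col > 0]
        # rank by correlation, ties broken by gene identifier
        ranked = col.sort_index(kind="stable").sort_values(
            ascending=False, kind="stable"
        )
        top_genes = [upper_to_sc[g] for g in ranked.index[:top_n] if g in upper_to_sc]
        if not top_genes:
            warnings.warn(f"target {target!r}: empty correlated gene set; skipped")
            continue
        scores = module_score(
            nm,
            GeneSet(name=f"corr_{target}", genes=top_genes),
            n_bins=n_bins,
            n_ctrl=n_ctrl,
            seed=seed,
        )
        for source in types:
            weight = float(scores[(labels == source).to_numpy()].mean())
            graph.add_edge(
                source,
                str(target),
                weight=weight,
                gene_set=list(map(str, top_genes)),
            )
    return graph
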