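"""Gene-set module scores with expression-matched control bins.

The score of a cell for a gene set is the mean normalized expression of the
set genes minus the mean over a pooled control set: for every set gene,
``n_ctrl`` control genes are drawn from the same average-expression bin
(genes ranked by mean expression over all cells and cut into ``n_bins``
equal-frequency bins, set genes excluded from the control pool). Control
draws are seeded, so scores are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .containers import NormalizedMatrix, ValidationError

__all__ = ["GeneSet", "module_score", "select_control_genes", "score_groups"]


@dataclass
class GeneSet:
    name: str
    genes: list

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        seen = set()
        uniq = []
        for g in self.genes:
            if g not in seen:
                uniq.append(g)
                seen.add(g)
        self.genes = uniq


def _expression_bins(nm: NormalizedMatrix, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per gene from mean expression over cells;
    ties broken by gene order (stable argsort)."""
    mean_expr = np.asarray(nm.values.mean(axis=1)).ravel()
    order = np.argsort(mean_expr, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    return (ranks * n_bins) // len(order)


def select_control_genes(
    nm: NormalizedMatrix,
    gs: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Seeded control-gene draws per present set gene.

    Draws are without replacement when the bin has at least ``n_ctrl``
    eligible genes, with replacement otherwise. Returns a mapping set gene ->
    array of control gene indices (into ``nm.gene_ids``).
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    present = [g for g in gs.genes if g in set(nm.gene_ids)]
    if not present:
        missing = [g for g in gs.genes if g not in set(nm.gene_ids)]
        raise ValidationError(f"no set gene present in matrix; missing: {missing[:10]}")
    bins = _expression_bins(nm, n_bins)
    set_idx = nm.gene_ids.get_indexer(pd.Index(present))
    set_mask = np.zeros(nm.n_genes, dtype=bool)
    set_mask[set_idx] = True

    rng = np.random.default_rng(seed)
    controls: dict[str, np.ndarray] = {}
    for g, j in zip(present, set_idx):
        eligible = np.flatnonzero((bins == bins[j]) & ~set_mask)
        if eligible.size == 0:
            continue
        replace = eligible.size < n_ctrl
        controls[g] = rng.choice(eligible, size=n_ctrl, replace=replace)
    return controls


def module_score(
    nm: NormalizedMatrix,
    gs: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell module score: mean set expression minus pooled control mean."""
    controls = select_control_genes(nm, gs, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    present = [g for g in gs.genes if g in set(nm.gene_ids)]
    if not controls:
        warnings.warn(
            f"gene set {gs.name!r} leaves no eligible control genes; scores are 0"
        )
        return pd.Series(0.0, index=nm.cell_ids, name=gs.name)
    dense = nm.dense()
    set_idx = nm.gene_ids.get_indexer(pd.Index(present))
    set_mean = dense[set_idx].mean(axis=0)
    pooled = np.concatenate(list(controls.values()))
    ctrl_mean = dense[pooled].mean(axis=0)
    return pd.Series(set_mean - ctrl_mean, index=nm.cell_ids, name=gs.name)


def score_groups(
    nm: NormalizedMatrix,
    gs: GeneSet,
    labels: pd.Series | None = None,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    test_pair: tuple | None = None,
) -> dict:
    """Aggregate module scores by label: per-label mean and rank, plus a
    two-sided rank-sum p for one requested label pair."""
    if labels is None:
        labels = nm.labels()
    labels = pd.Series(labels, index=nm.cell_ids)
    scores = module_score(nm, gs, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    means = scores.groupby(labels).mean().sort_values(ascending=False)
    if means.isna().any():
        raise ValidationError("a label has no cells")
    result = {
        "scores": scores,
        "group_means": means,
        "ranking": list(means.index),
    }
    if test_pair is not None:
        a, b = test_pair
        for lab in (a, b):
            if (labels == lab).sum() == 0:
                raise ValidationError(f"empty label {lab!r}")
        xa = scores[(labels == a).to_numpy()]
        xb = scores[(labels == b).to_numpy()]
        if np.array_equal(np.sort(xa), np.sort(xb)):
            result["pair_p"] = 1.0
        else:
            result["pair_p"] = float(
                mannwhitneyu(xa, xb, alternative="two-sided").pvalue
            )
    return result
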