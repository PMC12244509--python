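"""Shared statistical kernels: rank-sum tests, BH adjustment, z-scores, PCC.

The rank-sum test is vectorized across genes (tie-corrected normal
approximation with continuity correction) and switches to exact enumeration
over group assignments when both groups have at most ``EXACT_MAX`` samples,
so small-sample p-values are exact even under ties.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

EXACT_MAX = 8


def ranksum_p(values1: np.ndarray, values2: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values, one per row (gene).

    ``values1``/``values2`` are gene x cell blocks for the two groups.
    """
    values1 = np.atleast_2d(values1)
    values2 = np.atleast_2d(values2)
    n1, n2 = values1.shape[1], values2.shape[1]
    if n1 <= EXACT_MAX and n2 <= EXACT_MAX:
        return np.array(
            [_ranksum_exact(values1[g], values2[g]) for g in range(values1.shape[0])]
        )
    pooled = np.concatenate([values1, values2], axis=1)
    ranks = rankdata(pooled, axis=1)
    w = ranks[:, :n1].sum(axis=1)
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    tie_term = _tie_correction(pooled)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    dev = np.abs(w - mu)
    # continuity correction, as in the classical normal approximation
    z = np.where(sd > 0, np.maximum(dev - 0.5, 0.0) / np.where(sd > 0, sd, 1.0), 0.0)
    from scipy.stats import norm

    p = np.where(sd > 0, 2.0 * norm.sf(z), 1.0)
    return np.minimum(p, 1.0)


def _tie_correction(pooled: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tie groups, per row."""
    s = np.sort(pooled, axis=1)
    n_rows, n = s.shape
    out = np.zeros(n_rows)
    # run-length encode each sorted row
    changes = np.ones((n_rows, n), dtype=bool)
    changes[:, 1:] = s[:, 1:] != s[:, :-1]
    for r in range(n_rows):
        idx = np.flatnonzero(changes[r])
        lengths = np.diff(np.append(idx, n))
        out[r] = float(np.sum(lengths.astype(float) ** 3 - lengths))
    return out


def _ranksum_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating group assignments.

    Two-sided via the deviation of the group-1 rank sum from its null mean;
    valid under ties because the observed (mid-)ranks are permuted as-is.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    observed = abs(ranks[:n1].sum() - mu)
    hits = 0
    for idx in combinations(range(n), n1):
        if abs(ranks[list(idx)].sum() - mu) >= observed - 1e-9:
            hits += 1
    return hits / comb(n, n1)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def zscore_rows(x: np.ndarray, ddof: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each row; returns (z, valid_mask) where constant rows are
    flagged invalid instead of producing NaN."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    valid = sd.ravel() > 0
    z = np.zeros_like(x)
    np.divide(x - mu, sd, out=z, where=sd > 0)
    return z, valid


def pearson_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """PCC between each row of ``x`` and each row of ``y`` (shared columns).

    Rows with zero variance yield 0 rather than NaN.
    """
    zx, vx = zscore_rows(x)
    zy, vy = zscore_rows(y)
    n = x.shape[1]
    r = zx @ zy.T / n
    r[~vx, :] = 0.0
    r[:, ~vy] = 0.0
    return np.clip(r, -1.0, 1.0)
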