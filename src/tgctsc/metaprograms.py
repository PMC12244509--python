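"""Consensus NMF expression programs per sample, and meta-programs across
samples.

Each sample's tumor cells are factorized (cells x genes into usage x spectra)
by multiplicative-update NMF over a range of component numbers K; restarts
are matched by correlation, consensus spectra are component-wise medians, and
K is chosen from a stability/error trade-off. Programs pooled across samples
are then clustered into meta-programs by the Pearson correlation of their
top-gene spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.metrics import silhouette_score

from .containers import NormalizedMatrix, ValidationError
from .markers import find_deg

__all__ = [
    "SampleSpectra",
    "MetaProgramAssignment",
    "nmf_mu",
    "nmf_decompose",
    "select_k",
    "decompose_sample",
    "cluster_programs_to_mps",
    "assign_cells_to_mps",
    "mp_degs",
]

_EPS = 1e-10


@dataclass
class SampleSpectra:
    """One sample's consensus factorization at a single K."""

    spectra: pd.DataFrame  # programs x genes, >= 0
    usage: pd.DataFrame  # cells x programs, rows sum to 1
    k: int
    stability: float
    error: float  # relative Frobenius reconstruction error (best restart)


@dataclass
class MetaProgramAssignment:
    mp_of_program: dict  # program id -> MP label
    consensus_genes: dict  # MP label -> gene list
    pcc: pd.DataFrame  # program x program PCC
    top_genes: dict = field(default_factory=dict)


def nmf_mu(
    X: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 200,
    track_errors: bool = False,
):
    """Multiplicative-update NMF minimizing the Frobenius error ||X - WH||.

    Returns ``(W, H, errors)`` where ``errors`` has one entry per iteration
    when ``track_errors`` (the update is monotone: the objective never
    increases).
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValidationError("NMF input must be nonnegative")
    n, m = X.shape
    if k >= min(n, m):
        raise ValidationError(f"k={k} must be < min(cells, genes)={min(n, m)}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / k)
    W = rng.uniform(_EPS, 1.0, size=(n, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, m)) * scale
    errors = []
    norm_x = np.linalg.norm(X)
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        if track_errors:
            errors.append(np.linalg.norm(X - W @ H) / norm_x)
    return W, H, errors


def _match_components(H_ref: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Greedy max-correlation matching of rows of H to rows of H_ref.

    Returns for each row of ``H`` the index of its reference component.
    """
    k = H_ref.shape[0]
    c = np.corrcoef(np.vstack([H_ref, H]))[:k, k:]
    c = np.nan_to_num(c, nan=-1.0)
    assign = np.full(H.shape[0], -1)
    used_ref: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(-c, axis=None), c.shape))[0]
    used_h: set[int] = set()
    for ref_i, h_j in order:
        if ref_i in used_ref or h_j in used_h:
            continue
        assign[h_j] = ref_i
        used_ref.add(ref_i)
        used_h.add(h_j)
        if len(used_h) == H.shape[0]:
            break
    return assign


def nmf_decompose(
    nm: NormalizedMatrix,
    k: int,
    n_restarts: int = 20,
    max_iter: int = 200,
    seed: int = 0,
    sample: str | None = None,
) -> SampleSpectra:
    """Consensus NMF of one sample's cells at a fixed K.

    Runs ``n_restarts`` factorizations of the de-logged normalized matrix,
    matches components across restarts to the best restart by greedy maximum
    correlation, and keeps component-wise median spectra. Usage is re-fitted
    against the consensus spectra and row-normalized. Stability is the mean
    silhouette of the pooled restart components under the matching
    (correlation distance).
    """
    X = np.expm1(np.asarray(nm.values.todense())).T  # cells x genes
    best = None
    all_H = []
    for r in range(n_restarts):
        W, H, errs = nmf_mu(X, k, seed=seed * 100003 + r, max_iter=max_iter)
        err = np.linalg.norm(X - W @ H) / np.linalg.norm(X)
        # scale-normalize components so matching/medians compare shapes
        norms = np.linalg.norm(H, axis=1, keepdims=True)
        all_H.append(H / np.maximum(norms, _EPS))
        if best is None or err < best[0]:
            best = (err, W, H)
    best_err, _, H_best = best
    H_ref = H_best / np.maximum(np.linalg.norm(H_best, axis=1, keepdims=True), _EPS)

    pooled = []
    labels = []
    for H in all_H:
        assign = _match_components(H_ref, H)
        pooled.append(H)
        labels.extend(assign.tolist())
    pooled_arr = np.vstack(pooled)
    labels_arr = np.asarray(labels)
    if k > 1 and n_restarts > 1:
        corr = np.corrcoef(pooled_arr)
        dist = np.clip(1.0 - np.nan_to_num(corr, nan=0.0), 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        stability = float(silhouette_score(dist, labels_arr, metric="precomputed"))
    else:
        stability = 1.0

    H_cons = np.vstack(
        [np.median(pooled_arr[labels_arr == j], axis=0) for j in range(k)]
    )
    H_cons = np.maximum(H_cons, 0.0)

    # re-fit usage against consensus spectra (W-only multiplicative updates)
    rng = np.random.default_rng(seed)
    W = rng.uniform(_EPS, 1.0, size=(X.shape[0], k))
    HHt = H_cons @ H_cons.T
    XHt = X @ H_cons.T
    for _ in range(100):
        W *= XHt / (W @ HHt + _EPS)
    usage = W / np.maximum(W.sum(axis=1, keepdims=True), _EPS)

    name = sample or (nm.cell_meta["sample"].iloc[0] if nm.n_cells else "S")
    prog_ids = [f"{name}|p{j}" for j in range(k)]
    return SampleSpectra(
        spectra=pd.DataFrame(H_cons, index=prog_ids, columns=nm.gene_ids),
        usage=pd.DataFrame(usage, index=nm.cell_ids, columns=prog_ids),
        k=k,
        stability=stability,
        error=float(best_err),
    )


def select_k(results: dict[int, SampleSpectra], lam: float = 1.0) -> tuple[int, pd.DataFrame]:
    """Pick K maximizing ``stability - lam * error``.

    The error is the relative Frobenius reconstruction error, already a
    scale-free quantity in [0, 1], so it enters the criterion directly.
    Candidates whose criterion is within 1% of the maximum are tied and the
    smallest K among them wins. The full diagnostics table is returned for
    manual override.
    """
    if not results:
        raise ValidationError("no candidate K results")
    ks = sorted(results)
    if len(ks) == 1:
        k = ks[0]
        r = results[k]
        diag = pd.DataFrame(
            {"k": [k], "stability": [r.stability], "error": [r.error], "criterion": [r.stability]}
        )
        return k, diag
    errors = np.array([results[k].error for k in ks])
    stab = np.array([results[k].stability for k in ks])
    crit = stab - lam * errors
    best = crit.max()
    tol = 0.01 * max(abs(best), 1.0)
    chosen = min(k for k, c in zip(ks, crit) if c >= best - tol)
    diag = pd.DataFrame(
        {"k": ks, "stability": stab, "error": errors, "criterion": crit}
    )
    return chosen, diag


def decompose_sample(
    nm: NormalizedMatrix,
    sample: str,
    k_range=range(3, 11),
    n_restarts: int = 20,
    max_iter: int = 200,
    seed: int = 0,
    lam: float = 1.0,
) -> tuple[SampleSpectra, pd.DataFrame]:
    """Factorize one sample over a K range and keep the selected K."""
    mask = (nm.cell_meta["sample"] == sample).to_numpy()
    sub = nm.subset_cells(mask)
    results = {
        k: nmf_decompose(
            sub, k, n_restarts=n_restarts, max_iter=max_iter, seed=seed, sample=sample
        )
        for k in k_range
        if k < min(sub.n_cells, sub.n_genes)
    }
    k, diag = select_k(results, lam=lam)
    return results[k], diag


def cluster_programs_to_mps(
    spectra_by_sample: dict[str, SampleSpectra],
    top_n: int = 50,
    n_mps: int = 3,
) -> MetaProgramAssignment:
    """Cluster pooled programs into meta-programs.

    Per program the ``top_n`` genes by spectra score are taken; programs are
    compared by Pearson correlation of their z-scored spectra restricted to
    the union of top-gene sets, clustered hierarchically (average linkage on
    1 - PCC) and cut into ``n_mps`` groups. Per-MP consensus genes are those
    in the top list of at least half the member programs.
    """
    spectra_frames = [s.spectra for s in spectra_by_sample.values()]
    if not spectra_frames:
        raise ValidationError("no program spectra supplied")
    all_spectra = pd.concat(spectra_frames, axis=0).fillna(0.0)
    all_spectra = all_spectra.sort_index(kind="stable")
    if len(all_spectra) < n_mps:
        raise ValidationError("fewer pooled programs than requested meta-programs")

    top_genes = {
        prog: list(row.sort_values(ascending=False, kind="stable").index[:top_n])
        for prog, row in all_spectra.iterrows()
    }
    union = sorted(set(g for gs in top_genes.values() for g in gs))
    sub = all_spectra[union].values
    # z-score genes across programs so dominant programs do not swamp the PCC
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0)
    z = (sub - mu) / np.where(sd > 0, sd, 1.0)
    pcc = np.corrcoef(z)
    pcc = np.nan_to_num(pcc, nan=0.0)
    np.fill_diagonal(pcc, 1.0)
    pcc_frame = pd.DataFrame(pcc, index=all_spectra.index, columns=all_spectra.index)

    dist = np.clip(1.0 - pcc, 0.0, 2.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    link = sch.linkage(condensed, method="average")
    raw = sch.fcluster(link, t=n_mps, criterion="maxclust")

    # deterministic MP labels: order clusters by their lexicographically
    # smallest member program
    programs = list(all_spectra.index)
    members: dict[int, list[str]] = {}
    for prog, c in zip(programs, raw):
        members.setdefault(int(c), []).append(prog)
    ordered = sorted(members.values(), key=lambda m: min(m))
    mp_of_program = {}
    consensus = {}
    for i, progs in enumerate(ordered, start=1):
        label = f"MP{i}"
        for p in progs:
            mp_of_program[p] = label
        counts: dict[str, int] = {}
        for p in progs:
            for g in top_genes[p]:
                counts[g] = counts.get(g, 0) + 1
        consensus[label] = sorted(
            g for g, c in counts.items() if c >= 0.5 * len(progs)
        )
    return MetaProgramAssignment(
        mp_of_program=mp_of_program,
        consensus_genes=consensus,
        pcc=pcc_frame,
        top_genes=top_genes,
    )


def assign_cells_to_mps(
    spectra_by_sample: dict[str, SampleSpectra],
    assignment: MetaProgramAssignment,
) -> pd.Series:
    """Cell -> MP label via the cell's argmax-usage program."""
    out = {}
    for s in spectra_by_sample.values():
        dominant = s.usage.idxmax(axis=1)
        for cell, prog in dominant.items():
            out[cell] = assignment.mp_of_program[prog]
    return pd.Series(out, name="mp")


def mp_degs(
    nm: NormalizedMatrix,
    mp_labels: pd.Series,
    min_pct: float = 0.1,
    min_log2fc: float = 1.0,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per-MP one-vs-rest DEGs (positive only, log2FC threshold 1)."""
    aligned = mp_labels.reindex(nm.cell_ids)
    if aligned.isna().any():
        raise ValidationError("mp_labels do not cover all cells")
    return find_deg(
        nm, aligned, min_pct=min_pct, min_log2fc=min_log2fc, only_pos=True, alpha=alpha
    )
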