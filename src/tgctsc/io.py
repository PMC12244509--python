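"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as Matrix Market (.mtx, optionally gzipped) with ``genes.tsv``
and ``cells.tsv`` sidecars; gene positions as BED-like TSV (0-based,
half-open); bulk matrices and biomarker tables as TSV; gene sets as GMT or
two-column TSV; networks as edge-list TSV plus GraphML. Every ``write_*``
that produces a directory stamps a ``provenance.json`` with the package
version, a config hash and the seed.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from . import __version__
from .containers import CellMatrix, GenePositionTable, ValidationError
from .scoring import GeneSet

__all__ = [
    "read_counts",
    "write_counts",
    "read_bed",
    "write_bed",
    "read_bulk",
    "write_bulk",
    "read_biomarker_table",
    "write_biomarker_table",
    "read_gene_sets",
    "write_network",
    "write_provenance",
    "config_hash",
]


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_provenance(outdir: Path, config: dict, seed: int | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {
        "tool": "tgctsc",
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "config": config,
    }
    (outdir / "provenance.json").write_text(json.dumps(stamp, indent=2, default=str))


def write_counts(m: CellMatrix, outdir: Path, gzip_mtx: bool = False) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = "matrix.mtx.gz" if gzip_mtx else "matrix.mtx"
    if gzip_mtx:
        with gzip.open(outdir / name, "wb") as fh:
            sio.mmwrite(fh, m.counts.tocoo())
    else:
        sio.mmwrite(outdir / name, m.counts.tocoo())
    pd.DataFrame({"gene": m.gene_ids, "mito": m.mito_genes.astype(int)}).to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    cells = m.cell_meta.copy()
    cells.insert(0, "cell", m.cell_ids)
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)


def _find_matrix_file(indir: Path) -> Path:
    for name in ("matrix.mtx", "matrix.mtx.gz"):
        if (indir / name).exists():
            return indir / name
    raise ValidationError(f"no matrix.mtx[.gz] under {indir}")


def read_counts(indir: Path) -> CellMatrix:
    indir = Path(indir)
    path = _find_matrix_file(indir)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rb") as fh:
        first = fh.readline()
        if not first.startswith(b"%%MatrixMarket"):
            raise ValidationError(
                f"{path.name}: line 1: missing MatrixMarket header banner"
            )
    try:
        counts = sp.csr_matrix(sio.mmread(path))
    except ValueError as exc:
        raise ValidationError(f"{path.name}: malformed matrix body: {exc}") from exc
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    meta = cells.set_index("cell")
    return CellMatrix(
        counts=counts,
        gene_ids=pd.Index(genes["gene"]),
        cell_ids=pd.Index(meta.index),
        cell_meta=meta,
        mito_genes=genes["mito"].to_numpy(dtype=bool)
        if "mito" in genes
        else np.zeros(counts.shape[0], dtype=bool),
    )


def write_bed(positions: GenePositionTable, path: Path) -> None:
    positions.frame[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: Path) -> GenePositionTable:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(
                    f"{Path(path).name}: line {lineno}: expected 4 tab-separated "
                    f"fields (chrom, start, end, gene), got {len(parts)}"
                )
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
            except ValueError as exc:
                raise ValidationError(
                    f"{Path(path).name}: line {lineno}: {exc}"
                ) from exc
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    return GenePositionTable(frame)


def write_bulk(bulk: pd.DataFrame, path: Path) -> None:
    bulk.to_csv(path, sep="\t", index_label="gene")


def read_bulk(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_biomarker_table(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_biomarker_table(path: Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    rename = {"ror1_rate": "marker1_rate", "prkd1_rate": "marker2_rate",
              "recurrence": "outcome"}
    return table.rename(columns=rename)


def read_gene_sets(path: Path) -> list[GeneSet]:
    """GMT (name, description, genes...) or two-column TSV (set, gene)."""
    path = Path(path)
    sets: list[GeneSet] = []
    if path.suffix.lower() == ".gmt":
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets.append(GeneSet(name=parts[0], genes=parts[2:]))
    else:
        frame = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"])
        for name, group in frame.groupby("set", sort=False):
            sets.append(GeneSet(name=str(name), genes=list(group["gene"])))
    return sets


def write_network(graph: nx.DiGraph, outdir: Path, stem: str = "network") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        (u, v, d.get("weight", np.nan), len(d.get("gene_set", [])))
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "n_genes"]).to_csv(
        outdir / f"{stem}_edges.tsv", sep="\t", index=False
    )
    plain = nx.DiGraph()
    plain.add_nodes_from(graph.nodes)
    for u, v, d in graph.edges(data=True):
        plain.add_edge(u, v, weight=float(d.get("weight", 0.0)))
    nx.write_graphml(plain, outdir / f"{stem}.graphml")
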