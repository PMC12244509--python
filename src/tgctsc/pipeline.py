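"""Umbrella pipeline: simulate -> qc -> cnv -> markers -> score -> network ->
meta-programs -> roc, with provenance-stamped artifacts per stage."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .containers import ValidationError
from .cnv import call_tumor_clusters, cnv_score, infer_cnv_profile
from .io import write_biomarker_table, write_bulk, write_counts, write_network, write_provenance
from .markers import MarkerCriteria, find_specific_markers, group_stats
from .metaprograms import (
    assign_cells_to_mps,
    cluster_programs_to_mps,
    decompose_sample,
)
from .network import (
    build_correlative_network,
    cell_type_signatures,
    correlate_genes_abundance,
    estimate_bulk_abundance,
    self_expressed_genes,
)
from .qc import QcParams, normalize_log, qc_filter
from .roc import grid_roc
from .synthetic import (
    AtlasConfig,
    generate_bulk_cohort,
    generate_cell_atlas,
    generate_program_cells,
    generate_recurrence_cohort,
)

log = logging.getLogger("tgctsc")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline-wide configuration; unknown keys are rejected on load."""

    seed: int = 0
    log_level: str = "INFO"
    atlas: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    cnv: dict = field(default_factory=lambda: {"window": 51, "clip": 1.5, "z_cut": 3.0})
    markers: dict = field(default_factory=dict)
    network: dict = field(
        default_factory=lambda: {"n_samples": 50, "noise_sd": 0.1, "top_n": 30}
    )
    metaprograms: dict = field(
        default_factory=lambda: {
            "n_programs": 3,
            "genes_per_program": 25,
            "n_cells": 300,
            "n_genes": 150,
            "n_samples": 3,
            "k_min": 2,
            "k_max": 5,
            "n_restarts": 5,
        }
    )
    roc: dict = field(
        default_factory=lambda: {"n_pos": 16, "n_neg": 17, "mean_shift": 0.25, "rule": "and"}
    )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_json(cls, path: Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig, outdir: Path) -> dict:
    """Execute the full synthetic-data pipeline; returns a result summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    cfg_dict = config.to_dict()
    summary: dict = {"version": __version__}

    # --- simulate + QC + normalize
    atlas_cfg = AtlasConfig(**{"seed": config.seed, **config.atlas})
    matrix, positions, truth = generate_cell_atlas(atlas_cfg)
    write_counts(matrix, outdir / "atlas")
    write_provenance(outdir / "atlas", cfg_dict, config.seed)
    pairs = [
        (truth.marker_genes_of_type[a][0], truth.marker_genes_of_type[b][0])
        for i, a in enumerate(sorted(truth.marker_genes_of_type))
        for b in sorted(truth.marker_genes_of_type)[i + 1 :]
    ]
    qc_params = QcParams(**{"doublet_pairs": tuple(pairs), **config.qc})
    filtered, report = qc_filter(matrix, qc_params)
    log.info("qc: retained %d/%d cells", report.n_retained, report.n_input)
    nm = normalize_log(filtered)
    summary["qc"] = dataclasses.asdict(report)

    # --- CNV scoring and tumor calling
    types = sorted(set(truth.cell_type_of_cell.values()))
    ref_labels = set(config.cnv.get("reference_labels", types[-3:]))
    qry_labels = set(config.cnv.get("query_labels", [t for t in types if t not in ref_labels]))
    profile = infer_cnv_profile(
        nm,
        positions,
        qry_labels,
        ref_labels,
        window=config.cnv.get("window", 51),
        clip=config.cnv.get("clip", 1.5),
    )
    result = cnv_score(profile)
    result = call_tumor_clusters(
        result, qry_labels, ref_labels, z_cut=config.cnv.get("z_cut", 3.0)
    )
    result.scores.to_frame().assign(
        cluster=result.cell_labels.values,
        tumor_flag=[result.tumor_flags.get(l, False) for l in result.cell_labels],
    ).to_csv(outdir / "cnv_scores.csv")
    summary["cnv"] = {"tumor_flags": result.tumor_flags, "margins": result.margins}

    tumor_types = [t for t, flag in result.tumor_flags.items() if flag]
    tumor_cells = nm.cell_ids[nm.labels().isin(tumor_types).to_numpy()]
    other_cells = nm.cell_ids[~nm.labels().isin(tumor_types).to_numpy()]

    # --- strict tumor markers
    stats = group_stats(nm, tumor_cells, other_cells)
    criteria = MarkerCriteria(**config.markers) if config.markers else MarkerCriteria()
    specific = find_specific_markers(stats, criteria)
    stats.assign(passes_criteria=stats.index.isin(specific)).to_csv(
        outdir / "marker_stats.csv"
    )
    summary["markers"] = {"specific": specific}

    # --- correlative network over a synthetic bulk cohort
    sigs = cell_type_signatures(nm, top_n=config.network.get("top_n", 30))
    self_sets = self_expressed_genes(nm)
    bulk, truth = generate_bulk_cohort(
        truth,
        truth.mean_profiles,
        n_samples=config.network.get("n_samples", 50),
        noise_sd=config.network.get("noise_sd", 0.1),
        couplings=config.network.get("couplings", []),
        seed=config.seed + 1,
    )
    write_bulk(bulk, outdir / "bulk.tsv")
    abundance = estimate_bulk_abundance(bulk, sigs)
    corr = correlate_genes_abundance(bulk, abundance, self_sets)
    graph = build_correlative_network(
        corr, nm, top_n=config.network.get("top_n", 30), seed=config.seed
    )
    write_network(graph, outdir, stem="network")
    summary["network"] = {"n_edges": graph.number_of_edges()}

    # --- meta-programs on a program-structured cohort
    mp_cfg = config.metaprograms
    cells, mp_truth = generate_program_cells(
        mp_cfg.get("n_programs", 3),
        mp_cfg.get("genes_per_program", 25),
        mp_cfg.get("n_cells", 300),
        mp_cfg.get("n_genes", 150),
        seed=config.seed + 2,
        n_samples=mp_cfg.get("n_samples", 3),
    )
    nm_prog = normalize_log(cells)
    spectra = {}
    for sample in sorted(nm_prog.cell_meta["sample"].unique()):
        spec, diag = decompose_sample(
            nm_prog,
            sample,
            k_range=range(mp_cfg.get("k_min", 2), mp_cfg.get("k_max", 5) + 1),
            n_restarts=mp_cfg.get("n_restarts", 5),
            seed=config.seed + 3,
        )
        spectra[sample] = spec
        diag.to_csv(outdir / f"nmf_diagnostics_{sample}.csv", index=False)
    assignment = cluster_programs_to_mps(
        spectra, n_mps=mp_cfg.get("n_programs", 3)
    )
    mp_cells = assign_cells_to_mps(spectra, assignment)
    pd.DataFrame(
        {
            "program": list(assignment.mp_of_program),
            "mp": list(assignment.mp_of_program.values()),
        }
    ).to_csv(outdir / "metaprograms.csv", index=False)
    summary["metaprograms"] = {
        "chosen_k": {s: spec.k for s, spec in spectra.items()},
        "n_mps": len(assignment.consensus_genes),
        "mp_cell_counts": mp_cells.value_counts().to_dict(),
    }

    # --- recurrence ROC
    roc_cfg = config.roc
    cohort = generate_recurrence_cohort(
        roc_cfg.get("n_pos", 16),
        roc_cfg.get("n_neg", 17),
        roc_cfg.get("mean_shift", 0.25),
        seed=config.seed + 4,
    )
    write_biomarker_table(cohort, outdir / "biomarker_cohort.tsv")
    roc = grid_roc(cohort, rule=roc_cfg.get("rule", "and"))
    roc.grid.to_csv(outdir / "roc_grid.csv", index=False)
    roc.envelope.to_csv(outdir / "roc_envelope.csv", index=False)
    summary["roc"] = {
        "auc": roc.auc,
        "best_c1": roc.best[0],
        "best_c2": roc.best[1],
        "youden_j": roc.best[2],
    }

    write_provenance(outdir, cfg_dict, config.seed)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
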