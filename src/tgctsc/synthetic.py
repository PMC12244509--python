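"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the structure of a synovial tumor single-cell atlas at
desk scale: a handful of cell types with exclusive marker genes, one "tumor"
type carrying contiguous copy-number gain/loss blocks, mitochondrial genes,
lineage doublets, a bulk cohort mixed from type mean profiles with planted
abundance-driver couplings, per-sample gene expression programs, and a
two-marker biomarker/outcome cohort. Everything is a pure function of its
configuration and seed.

Count model
-----------
Counts are negative binomial around ``mu[g, c] = lib_c * rate_g * modifiers``
with variance ``mu + dispersion * mu**2``. Marker genes of a type are
near-exclusive: their rate is ``marker_strength`` times the mean gene rate in
the owning type and ``marker_leak`` times the mean gene rate elsewhere, so
planted markers clear the strict specificity criteria (expressed in >50% of
owner cells, <3% of others) with high probability. Copy-number blocks
multiply the expected counts of a contiguous run of genes by ``2**shift`` in
the tumor type only, which makes the induced log-ratio shift analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CellMatrix, GenePositionTable, ValidationError

__all__ = [
    "AtlasConfig",
    "GroundTruth",
    "generate_cell_atlas",
    "generate_bulk_cohort",
    "generate_recurrence_cohort",
    "generate_program_cells",
]


@dataclass
class AtlasConfig:
    """Configuration of the synthetic cell atlas.

    ``cnv_blocks`` is a list of ``(chromosome_index, (start, end), log2_shift)``
    tuples; the gene span is local to the chromosome, 0-based half-open, and
    spans must not overlap within a chromosome.
    """

    n_cell_types: int = 5
    cells_per_type: int = 300
    n_genes: int = 500
    n_markers_per_type: int = 3
    n_mito_genes: int = 10
    cnv_blocks: list = field(default_factory=lambda: [(0, (0, 100), 1.0)])
    tumor_type_index: int = 0
    doublet_fraction: float = 0.0
    nb_dispersion: float = 0.1
    library_size_mean: float = 2000.0
    seed: int = 0
    # secondary knobs (see module docstring)
    n_chromosomes: int = 5
    marker_strength: float = 8.0
    marker_leak: float = 5e-4
    n_aux_exclusive_per_type: int = 0
    aux_strength: float = 3.0
    library_size_cv: float = 0.25
    n_samples: int = 2

    def validate(self) -> None:
        for name in (
            "n_cell_types",
            "cells_per_type",
            "n_genes",
            "n_markers_per_type",
            "n_chromosomes",
            "n_samples",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0 (got {getattr(self, name)})")
        if self.n_mito_genes < 0:
            raise ValidationError("n_mito_genes must be >= 0")
        if not 0.0 <= self.doublet_fraction <= 0.2:
            raise ValidationError(
                f"doublet_fraction must be in [0, 0.2] (got {self.doublet_fraction})"
            )
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")
        if self.library_size_mean <= 0:
            raise ValidationError("library_size_mean must be > 0")
        if not 0 <= self.tumor_type_index < self.n_cell_types:
            raise ValidationError(
                f"tumor_type_index must be < n_cell_types (got {self.tumor_type_index})"
            )
        per_chrom = self.n_genes // self.n_chromosomes
        seen: dict[int, list[tuple[int, int]]] = {}
        for chrom, (a, b), _shift in self.cnv_blocks:
            if not 0 <= chrom < self.n_chromosomes:
                raise ValidationError(f"cnv_blocks chromosome {chrom} out of range")
            if not 0 <= a < b <= per_chrom:
                raise ValidationError(
                    f"cnv_blocks span ({a},{b}) outside chromosome of {per_chrom} genes"
                )
            for a2, b2 in seen.get(chrom, []):
                if a < b2 and a2 < b:
                    raise ValidationError(
                        f"cnv_blocks spans overlap on chromosome {chrom}"
                    )
            seen.setdefault(chrom, []).append((a, b))
        n_exclusive = self.n_cell_types * (
            self.n_markers_per_type + self.n_aux_exclusive_per_type
        )
        if n_exclusive + self.n_mito_genes > self.n_genes // 2:
            raise ValidationError(
                "n_genes too small for the requested marker/mito gene counts"
            )


@dataclass
class GroundTruth:
    """Planted truth recorded alongside each generated dataset."""

    cell_type_of_cell: dict = field(default_factory=dict)
    marker_genes_of_type: dict = field(default_factory=dict)
    aux_genes_of_type: dict = field(default_factory=dict)
    cnv_gene_mask: np.ndarray | None = None
    doublet_flags: np.ndarray | None = None
    program_loadings: pd.DataFrame | None = None
    program_of_cell: dict = field(default_factory=dict)
    bulk_abundances: pd.DataFrame | None = None
    driver_couplings: list = field(default_factory=list)
    driver_genes: dict = field(default_factory=dict)
    mean_profiles: pd.DataFrame | None = None
    tumor_type: str | None = None

    def to_jsonable(self) -> dict:
        out: dict = {
            "cell_type_of_cell": self.cell_type_of_cell,
            "marker_genes_of_type": self.marker_genes_of_type,
            "aux_genes_of_type": self.aux_genes_of_type,
            "tumor_type": self.tumor_type,
            "driver_couplings": [list(c) for c in self.driver_couplings],
            "driver_genes": {k: list(v) for k, v in self.driver_genes.items()},
            "program_of_cell": self.program_of_cell,
        }
        if self.cnv_gene_mask is not None:
            out["cnv_gene_mask"] = np.asarray(self.cnv_gene_mask).astype(int).tolist()
        if self.doublet_flags is not None:
            out["doublet_flags"] = np.asarray(self.doublet_flags).astype(int).tolist()
        if self.bulk_abundances is not None:
            out["bulk_abundances"] = self.bulk_abundances.to_dict()
        if self.program_loadings is not None:
            out["program_loadings"] = self.program_loadings.to_dict()
        return out


def _sample_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, var = mu + dispersion*mu^2); Poisson when dispersion == 0."""
    if dispersion == 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    # gamma-Poisson mixture keeps vectorization simple and exact
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam)


def generate_cell_atlas(
    config: AtlasConfig,
) -> tuple[CellMatrix, GenePositionTable, GroundTruth]:
    """Simulate a multi-type cell atlas with planted markers, CNV and doublets.

    Returns the raw count matrix, the genomic position table of its genes and
    the planted :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_types = config.n_cell_types
    n_genes = config.n_genes
    per_chrom = n_genes // config.n_chromosomes
    n_placed = per_chrom * config.n_chromosomes
    type_names = [f"type{t}" for t in range(n_types)]
    tumor_type = type_names[config.tumor_type_index]

    # --- gene universe and genomic layout (genes consecutive per chromosome)
    gene_ids = np.array([f"G{j:05d}" for j in range(n_genes)], dtype=object)
    chroms = np.array(
        [f"chr{1 + j // per_chrom}" if j < n_placed else "chrU" for j in range(n_genes)],
        dtype=object,
    )
    local = np.array([j % per_chrom for j in range(n_genes)])
    positions = pd.DataFrame(
        {
            "chrom": chroms,
            "start": local * 1000,
            "end": local * 1000 + 500,
            "gene": gene_ids,
        }
    )

    # --- CNV gain/loss mask (global gene indices)
    cnv_mask = np.zeros(n_genes, dtype=bool)
    cnv_mult = np.ones(n_genes)
    for chrom, (a, b), shift in config.cnv_blocks:
        g0 = chrom * per_chrom
        cnv_mask[g0 + a : g0 + b] = True
        cnv_mult[g0 + a : g0 + b] = 2.0 ** shift

    # --- assign marker / auxiliary-exclusive / mito genes outside CNV blocks
    free = np.flatnonzero(~cnv_mask)
    free = rng.permutation(free)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = free[cursor : cursor + k]
        cursor += k
        return np.sort(out)

    markers = {t: take(config.n_markers_per_type) for t in type_names}
    aux = {t: take(config.n_aux_exclusive_per_type) for t in type_names}
    mito_idx = take(config.n_mito_genes)
    mito_mask = np.zeros(n_genes, dtype=bool)
    mito_mask[mito_idx] = True
    for k, j in enumerate(mito_idx):
        gene_ids[j] = f"MT-{k}"
    positions["gene"] = gene_ids

    # --- per-gene base rates; mean gene rate anchors marker effect sizes
    rel = rng.lognormal(mean=0.0, sigma=0.4, size=n_genes)
    rel /= rel.mean()
    mean_rate = config.library_size_mean / n_genes
    base_rate = rel * mean_rate

    # type x gene rate profiles
    profiles = np.tile(base_rate, (n_types, 1))
    for t_idx, t in enumerate(type_names):
        for other in type_names:
            for j in markers[other]:
                profiles[t_idx, j] = mean_rate * (
                    config.marker_strength if other == t else config.marker_leak
                )
            for j in aux[other]:
                profiles[t_idx, j] = mean_rate * (
                    config.aux_strength if other == t else config.marker_leak
                )
    profiles[config.tumor_type_index] *= cnv_mult

    # --- cells
    n_cells = n_types * config.cells_per_type
    type_of = np.repeat(np.arange(n_types), config.cells_per_type)
    cell_ids = np.array([f"C{j:05d}" for j in range(n_cells)], dtype=object)
    sigma = np.sqrt(np.log1p(config.library_size_cv**2))
    lib = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_cells)

    rates = profiles[type_of] * lib[:, None]  # cells x genes

    # doublets: replace a random subset with the sum of two rate vectors from
    # distinct types (lineage doublets, detectable via marker co-expression)
    n_doub = int(round(config.doublet_fraction * n_cells))
    doublet_flags = np.zeros(n_cells, dtype=bool)
    if n_doub:
        picks = rng.choice(n_cells, size=n_doub, replace=False)
        for c in picks:
            other_pool = np.flatnonzero(type_of != type_of[c])
            partner = int(rng.choice(other_pool))
            rates[c] = rates[c] + profiles[type_of[partner]] * lib[partner]
        doublet_flags[picks] = True

    counts = _sample_counts(rng, rates, config.nb_dispersion)

    samples = np.array(
        [f"S{1 + (j % config.n_samples)}" for j in range(n_cells)], dtype=object
    )
    meta = pd.DataFrame(
        {
            "cell_type": [type_names[t] for t in type_of],
            "sample": samples,
            "condition": "D",
        },
        index=pd.Index(cell_ids),
    )

    matrix = CellMatrix(
        counts=sp.csr_matrix(counts.T),  # genes x cells
        gene_ids=pd.Index(gene_ids),
        cell_ids=pd.Index(cell_ids),
        cell_meta=meta,
        mito_genes=mito_mask,
    )
    truth = GroundTruth(
        cell_type_of_cell={c: type_names[t] for c, t in zip(cell_ids, type_of)},
        marker_genes_of_type={t: [gene_ids[j] for j in markers[t]] for t in type_names},
        aux_genes_of_type={t: [gene_ids[j] for j in aux[t]] for t in type_names},
        cnv_gene_mask=cnv_mask,
        doublet_flags=doublet_flags,
        mean_profiles=pd.DataFrame(profiles, index=type_names, columns=gene_ids),
        tumor_type=tumor_type,
    )
    return matrix, GenePositionTable(positions), truth


def generate_bulk_cohort(
    truth: GroundTruth,
    mean_profiles: pd.DataFrame,
    n_samples: int,
    noise_sd: float,
    couplings: list,
    seed: int,
    *,
    coupling_shift: float = 1.0,
    n_driver_genes: int = 20,
    dirichlet_concentration: float = 100.0,
    abundances: np.ndarray | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Mix type mean profiles into a noisy bulk log-expression cohort.

    Each sample's log-expression is ``log(sum_t a[t] * profile[t]) + noise``
    with per-sample abundances ``a`` drawn from a symmetric Dirichlet. For a
    coupling ``(A, B)``, ``n_driver_genes`` of B's auxiliary exclusive genes
    receive an additive shift ``coupling_shift * standardized(a[A])``, planting
    a gene-abundance correlation the network stage should recover.
    """
    if n_samples < 8:
        raise ValidationError(f"n_samples must be >= 8 (got {n_samples})")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if (mean_profiles.values < 0).any():
        raise ValidationError("mean_profiles must be nonnegative")
    types = list(mean_profiles.index)
    for c in couplings:
        a, b = c[0], c[1]
        for t in (a, b):
            if t not in types:
                raise ValidationError(f"coupling references unknown type {t!r}")
        if len(truth.aux_genes_of_type.get(b, [])) < n_driver_genes:
            raise ValidationError(
                f"type {b!r} has fewer than {n_driver_genes} auxiliary exclusive "
                "genes to use as coupling drivers"
            )

    rng = np.random.default_rng(seed)
    n_types = len(types)
    if abundances is not None:
        A = np.asarray(abundances, dtype=float)
        if A.shape != (n_samples, n_types):
            raise ValidationError("abundances must be n_samples x n_types")
        if not np.allclose(A.sum(axis=1), 1.0):
            raise ValidationError("abundances rows must sum to 1")
    else:
        alpha = np.full(n_types, dirichlet_concentration / n_types)
        A = rng.dirichlet(alpha, size=n_samples)  # samples x types
    P = mean_profiles.values  # types x genes
    mixture = A @ P
    log_expr = np.log(mixture + 1e-9)
    if noise_sd > 0:
        log_expr = log_expr + rng.normal(0.0, noise_sd, size=log_expr.shape)

    sample_ids = [f"B{j:03d}" for j in range(n_samples)]
    bulk = pd.DataFrame(log_expr.T, index=mean_profiles.columns, columns=sample_ids)

    driver_genes: dict[str, list[str]] = {}
    for c in couplings:
        src, tgt = c[0], c[1]
        drivers = list(truth.aux_genes_of_type[tgt][:n_driver_genes])
        a_src = A[:, types.index(src)]
        z = (a_src - a_src.mean()) / a_src.std(ddof=0)
        bulk.loc[drivers] = bulk.loc[drivers].values + coupling_shift * z[None, :]
        driver_genes[f"{src}->{tgt}"] = drivers

    truth.bulk_abundances = pd.DataFrame(A, index=sample_ids, columns=types)
    truth.driver_couplings = [(c[0], c[1]) for c in couplings]
    truth.driver_genes = driver_genes
    return bulk, truth


def generate_recurrence_cohort(
    n_pos: int,
    n_neg: int,
    mean_shift: float,
    seed: int,
    *,
    base_means: tuple[float, float] = (0.40, 0.30),
    concentration: float = 12.0,
) -> pd.DataFrame:
    """Two per-patient marker positivity rates plus a binary recurrence outcome.

    Rates are Beta-distributed; within the recurrent group the mean of each
    marker is shifted up by ``mean_shift``. Returns a frame with columns
    ``patient_id, marker1_rate, marker2_rate, outcome`` (1 = recurrent).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValidationError("n_pos and n_neg must both be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for outcome, n, shift in ((1, n_pos, mean_shift), (0, n_neg, 0.0)):
        rates = []
        for base in base_means:
            m = base + shift
            a, b = m * concentration, (1.0 - m) * concentration
            if a <= 0 or b <= 0:
                raise ValidationError(
                    f"mean_shift {mean_shift} drives Beta parameters <= 0 "
                    f"(mean {m} outside (0, 1))"
                )
            rates.append(rng.beta(a, b, size=n))
        for j in range(n):
            rows.append((outcome, rates[0][j], rates[1][j]))
    frame = pd.DataFrame(rows, columns=["outcome", "marker1_rate", "marker2_rate"])
    frame.insert(0, "patient_id", [f"P{j:03d}" for j in range(len(frame))])
    return frame[["patient_id", "marker1_rate", "marker2_rate", "outcome"]]


def generate_program_cells(
    n_programs: int,
    genes_per_program: int,
    n_cells: int,
    n_genes: int,
    seed: int,
    *,
    program_genes: list | None = None,
    n_samples: int = 1,
    sample_conditions: list | None = None,
    condition_of_program: dict | None = None,
    baseline_rate: float = 1.0,
    program_rate: float = 8.0,
    second_program_prob: float = 0.35,
    dispersion: float = 0.05,
) -> tuple[CellMatrix, GroundTruth]:
    """Cells whose rate vectors mix a baseline with 1-2 planted gene programs.

    Used as the fixture for the consensus NMF stage: each cell draws a primary
    program (restricted to its sample's condition when ``condition_of_program``
    is given) and, with some probability, a weaker secondary program.
    """
    if n_programs < 1:
        raise ValidationError("n_programs must be >= 1")
    if program_genes is None:
        if n_programs * genes_per_program > n_genes:
            raise ValidationError("program gene sets do not fit in n_genes")
        program_genes = [
            list(range(p * genes_per_program, (p + 1) * genes_per_program))
            for p in range(n_programs)
        ]
    flat = [g for gs in program_genes for g in gs]
    if len(set(flat)) != len(flat):
        raise ValidationError("program gene sets must be disjoint")

    rng = np.random.default_rng(seed)
    loadings = np.zeros((n_programs, n_genes))
    for p, gs in enumerate(program_genes):
        loadings[p, gs] = program_rate * rng.gamma(shape=4.0, scale=0.25, size=len(gs))

    if sample_conditions is None:
        sample_conditions = ["A"] * n_samples
    if len(sample_conditions) != n_samples:
        raise ValidationError("sample_conditions length must equal n_samples")
    condition_of_program = condition_of_program or {}

    sample_of = np.array([j % n_samples for j in range(n_cells)])
    allowed_by_cond = {
        c: [
            p
            for p in range(n_programs)
            if condition_of_program.get(p) in (None, c)
        ]
        for c in set(sample_conditions)
    }

    # the baseline rides on each program's loading (weights scale both), so a
    # single-program cohort is exactly rank one in expectation
    rates = np.zeros((n_cells, n_genes))
    program_of_cell = {}
    cell_ids = [f"PC{j:05d}" for j in range(n_cells)]
    for j in range(n_cells):
        cond = sample_conditions[sample_of[j]]
        allowed = allowed_by_cond[cond]
        if not allowed:
            raise ValidationError(f"no program allowed in condition {cond!r}")
        p1 = int(rng.choice(allowed))
        w1 = rng.uniform(0.7, 1.3)
        rates[j] += w1 * (baseline_rate + loadings[p1])
        if len(allowed) > 1 and rng.uniform() < second_program_prob:
            p2 = int(rng.choice([p for p in allowed if p != p1]))
            rates[j] += rng.uniform(0.1, 0.4) * (baseline_rate + loadings[p2])
        program_of_cell[cell_ids[j]] = p1

    counts = _sample_counts(rng, rates, dispersion)
    gene_ids = pd.Index([f"PG{j:04d}" for j in range(n_genes)])
    meta = pd.DataFrame(
        {
            "cell_type": "tumor",
            "sample": [f"S{s + 1}" for s in sample_of],
            "condition": [sample_conditions[s] for s in sample_of],
        },
        index=pd.Index(cell_ids),
    )
    matrix = CellMatrix(
        counts=sp.csr_matrix(counts.T),
        gene_ids=gene_ids,
        cell_ids=pd.Index(cell_ids),
        cell_meta=meta,
    )
    truth = GroundTruth(
        program_loadings=pd.DataFrame(
            loadings,
            index=[f"MP_truth{p}" for p in range(n_programs)],
            columns=gene_ids,
        ),
        program_of_cell=program_of_cell,
    )
    return matrix, truth
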