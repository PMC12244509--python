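"""Generators: planted structure, determinism, validation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import NMF
from sklearn.metrics import roc_auc_score

from tgctsc import (
    AtlasConfig,
    ValidationError,
    generate_bulk_cohort,
    generate_cell_atlas,
    generate_program_cells,
    generate_recurrence_cohort,
    normalize_log,
)


class TestCellAtlas:
    def test_no_doublets_when_fraction_zero(self, default_atlas):
        _, _, _, truth = default_atlas
        assert not truth.doublet_flags.any()

    def test_same_seed_gives_identical_counts(self):
        m1, _, _ = generate_cell_atlas(AtlasConfig(seed=42))
        m2, _, _ = generate_cell_atlas(AtlasConfig(seed=42))
        assert (m1.counts != m2.counts).nnz == 0
        assert list(m1.gene_ids) == list(m2.gene_ids)

    def test_gain_block_doubles_mean_counts(self, default_atlas):
        # +1 log2 shift acts multiplicatively on expected counts: the ratio of
        # mean raw counts (tumor block genes vs other types) should be ~2
        _, matrix, _, truth = default_atlas
        dense = np.asarray(matrix.counts.todense())
        tumor = (matrix.cell_meta["cell_type"] == truth.tumor_type).to_numpy()
        blk = truth.cnv_gene_mask
        ratio = dense[blk][:, tumor].mean() / dense[blk][:, ~tumor].mean()
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_gene_positions_consecutive_per_chromosome(self, default_atlas):
        _, _, positions, _ = default_atlas
        frame = positions.frame
        for _, chrom_frame in frame.groupby("chrom"):
            starts = chrom_frame["start"].to_numpy()
            assert (np.diff(starts) > 0).all()
            assert (chrom_frame["start"] < chrom_frame["end"]).all()

    @pytest.mark.parametrize(
        "field, value",
        [
            ("doublet_fraction", 0.5),
            ("tumor_type_index", 9),
            ("n_genes", -5),
            ("cnv_blocks", [(0, (0, 50), 1.0), (0, (40, 80), -1.0)]),
            ("cnv_blocks", [(7, (0, 10), 1.0)]),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = AtlasConfig(seed=0)
        setattr(cfg, field, value)
        with pytest.raises(ValidationError):
            generate_cell_atlas(cfg)

    def test_planted_doublets_coexpress_lineage_markers(self):
        cfg = AtlasConfig(seed=9, doublet_fraction=0.05)
        matrix, _, truth = generate_cell_atlas(cfg)
        assert truth.doublet_flags.sum() == round(0.05 * matrix.n_cells)


class TestBulkCohort:
    def _atlas(self, seed=0):
        cfg = AtlasConfig(
            seed=seed, cells_per_type=200, n_genes=700,
            n_markers_per_type=30, n_aux_exclusive_per_type=20,
        )
        return generate_cell_atlas(cfg)

    def test_pure_sample_equals_log_profile(self):
        _, _, truth = self._atlas()
        profiles = truth.mean_profiles
        ab = np.full((10, 5), 0.0)
        ab[:, :] = 0.25
        ab[:, 1] = 0.0
        ab[0] = [0.0, 1.0, 0.0, 0.0, 0.0]  # sample 0 is pure type1
        ab[1:, 1] = 0.25
        ab[1:] /= ab[1:].sum(axis=1, keepdims=True)
        bulk, _ = generate_bulk_cohort(
            truth, profiles, n_samples=10, noise_sd=0.0, couplings=[], seed=3,
            abundances=ab,
        )
        expected = np.log(profiles.loc["type1"].values + 1e-9)
        np.testing.assert_allclose(bulk.iloc[:, 0].values, expected, atol=1e-9)

    def test_coupled_driver_tracks_source_abundance(self):
        _, _, truth = self._atlas(seed=4)
        bulk, truth = generate_bulk_cohort(
            truth, truth.mean_profiles, n_samples=50, noise_sd=0.1,
            couplings=[("type2", "type1")], seed=5, coupling_shift=1.0,
        )
        a = truth.bulk_abundances["type2"].values
        for g in truth.driver_genes["type2->type1"]:
            assert np.corrcoef(bulk.loc[g].values, a)[0, 1] > 0.8

    def test_no_coupling_keeps_drivers_within_permutation_null(self):
        # couplings plant *positive* gene-abundance correlations (and the
        # network ranks by largest positive PCC); without a coupling the
        # positive tail must stay inside the permutation null. (Sum-to-one
        # abundances make exclusive genes intrinsically anti-correlated with
        # other types, so the negative tail is not a coupling signature.)
        _, _, truth = self._atlas(seed=6)
        bulk, truth = generate_bulk_cohort(
            truth, truth.mean_profiles, n_samples=200, noise_sd=0.1,
            couplings=[], seed=7,
        )
        rng = np.random.default_rng(0)
        drivers = truth.aux_genes_of_type["type1"]
        other_ab = truth.bulk_abundances.drop(columns=["type1"]).values

        def max_pos_corr(ab):
            return max(
                np.corrcoef(bulk.loc[g].values, ab[:, j])[0, 1]
                for g in drivers
                for j in range(ab.shape[1])
            )

        observed = max_pos_corr(other_ab)
        null = [
            max_pos_corr(other_ab[rng.permutation(other_ab.shape[0])])
            for _ in range(200)
        ]
        assert observed <= np.quantile(null, 0.99)

    def test_unknown_coupling_type_rejected(self):
        _, _, truth = self._atlas()
        with pytest.raises(ValidationError, match="unknown type"):
            generate_bulk_cohort(
                truth, truth.mean_profiles, n_samples=10, noise_sd=0.0,
                couplings=[("type0", "nope")], seed=0,
            )

    def test_abundances_sum_to_one(self):
        _, _, truth = self._atlas()
        _, truth = generate_bulk_cohort(
            truth, truth.mean_profiles, n_samples=20, noise_sd=0.1,
            couplings=[], seed=1,
        )
        np.testing.assert_allclose(truth.bulk_abundances.sum(axis=1), 1.0)


class TestRecurrenceCohort:
    def test_null_shift_gives_chance_auc(self):
        tab = generate_recurrence_cohort(500, 500, 0.0, seed=3)
        for col in ("marker1_rate", "marker2_rate"):
            auc = roc_auc_score(tab["outcome"], tab[col])
            assert abs(auc - 0.5) < 0.1

    def test_zero_patients_rejected(self):
        with pytest.raises(ValidationError):
            generate_recurrence_cohort(0, 10, 0.1, seed=0)

    def test_nonoverlapping_supports_give_perfect_auc(self):
        from tgctsc import grid_roc

        tab = generate_recurrence_cohort(
            8, 8, 0.85, seed=1, base_means=(0.05, 0.05), concentration=400
        )
        assert grid_roc(tab).auc == pytest.approx(1.0)

    def test_invalid_beta_parameters_rejected(self):
        with pytest.raises(ValidationError, match="Beta"):
            generate_recurrence_cohort(5, 5, 0.9, seed=0, base_means=(0.4, 0.3))


class TestProgramCells:
    def test_rank_one_structure(self):
        # with one planted program the matrix is near rank-1: the independent
        # factorization oracle reaches the same error at K=1 and K=3
        cells, _ = generate_program_cells(
            1, 80, 500, 300, seed=2, baseline_rate=2.0, program_rate=10.0
        )
        X = np.expm1(np.asarray(normalize_log(cells).values.todense())).T
        errs = {}
        for k in (1, 3):
            model = NMF(n_components=k, init="random", random_state=0, max_iter=300)
            W = model.fit_transform(X)
            errs[k] = np.linalg.norm(X - W @ model.components_) / np.linalg.norm(X)
        assert errs[1] <= errs[3] * 1.05

    def test_disjointness_enforced(self):
        with pytest.raises(ValidationError, match="disjoint"):
            generate_program_cells(
                2, 5, 50, 100, seed=0, program_genes=[[0, 1, 2], [2, 3, 4]]
            )

    def test_same_seed_identical(self):
        a, _ = generate_program_cells(3, 10, 100, 80, seed=5)
        b, _ = generate_program_cells(3, 10, 100, 80, seed=5)
        assert (a.counts != b.counts).nnz == 0

    def test_condition_restriction_honoured(self):
        cells, truth = generate_program_cells(
            3, 10, 200, 80, seed=1, n_samples=4,
            sample_conditions=["D", "D", "L", "L"],
            condition_of_program={2: "D"},
        )
        prog = pd.Series(truth.program_of_cell)
        cond = cells.cell_meta["condition"]
        assert set(cond[prog.reindex(cells.cell_ids).values == 2]) == {"D"}
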