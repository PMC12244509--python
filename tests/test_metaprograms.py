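"""Consensus NMF, K selection, and meta-program clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import NMF as SkNMF
from sklearn.metrics import adjusted_rand_score

from tgctsc import (
    ValidationError,
    assign_cells_to_mps,
    cluster_programs_to_mps,
    decompose_sample,
    generate_program_cells,
    mp_degs,
    nmf_decompose,
    normalize_log,
    select_k,
)
from tgctsc.metaprograms import SampleSpectra, nmf_mu

from conftest import make_normalized


def truth_family(top_genes, loadings):
    """Best-matching planted program per discovered program (by overlap)."""
    planted = [
        set(loadings.columns[loadings.iloc[p].values > 0]) for p in range(len(loadings))
    ]
    return {
        prog: max(range(len(planted)), key=lambda p: len(set(genes) & planted[p]))
        for prog, genes in top_genes.items()
    }


@pytest.fixture(scope="module")
def program_cohort():
    cells, truth = generate_program_cells(3, 50, 600, 200, seed=3, n_samples=5)
    return normalize_log(cells), truth


class TestNmf:
    def test_objective_nonincreasing(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 5, (40, 30))
        _, _, errors = nmf_mu(X, 3, seed=1, max_iter=80, track_errors=True)
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))

    def test_exact_low_rank_recovery(self):
        rng = np.random.default_rng(1)
        W = rng.uniform(0, 2, (60, 1))
        H = rng.uniform(0, 2, (1, 40))
        X = W @ H
        _, _, errors = nmf_mu(X, 1, seed=2, max_iter=400, track_errors=True)
        assert errors[-1] < 1e-3

    def test_matches_sklearn_error_scale(self):
        # independent implementation cross-check on a program fixture
        cells, _ = generate_program_cells(2, 20, 120, 80, seed=4)
        X = np.expm1(np.asarray(normalize_log(cells).values.todense())).T
        _, _, errors = nmf_mu(X, 2, seed=0, max_iter=300, track_errors=True)
        sk = SkNMF(n_components=2, init="random", random_state=0, max_iter=500)
        W = sk.fit_transform(X)
        sk_err = np.linalg.norm(X - W @ sk.components_) / np.linalg.norm(X)
        assert errors[-1] == pytest.approx(sk_err, rel=0.02)

    def test_k_too_large_rejected(self):
        nm = make_normalized(np.ones((5, 4)) + np.arange(5)[:, None])
        with pytest.raises(ValidationError, match="k="):
            nmf_decompose(nm, 4, n_restarts=2, seed=0)

    def test_same_seed_identical_spectra(self, program_cohort):
        nm, _ = program_cohort
        sub = nm.subset_cells((nm.cell_meta["sample"] == "S1").to_numpy())
        a = nmf_decompose(sub, 3, n_restarts=3, max_iter=60, seed=7)
        b = nmf_decompose(sub, 3, n_restarts=3, max_iter=60, seed=7)
        pd.testing.assert_frame_equal(a.spectra, b.spectra)

    def test_recovers_planted_programs(self, program_cohort):
        nm, truth = program_cohort
        sub = nm.subset_cells((nm.cell_meta["sample"] == "S1").to_numpy())
        spec = nmf_decompose(sub, 3, n_restarts=5, max_iter=150, seed=0)
        planted = [
            set(truth.program_loadings.columns[truth.program_loadings.iloc[p].values > 0])
            for p in range(3)
        ]
        for _, row in spec.spectra.iterrows():
            top50 = set(row.sort_values(ascending=False).index[:50])
            jaccard = max(
                len(top50 & ps) / len(top50 | ps) for ps in planted
            )
            assert jaccard >= 0.6

    def test_usage_rows_sum_to_one(self, program_cohort):
        nm, _ = program_cohort
        sub = nm.subset_cells((nm.cell_meta["sample"] == "S2").to_numpy())
        spec = nmf_decompose(sub, 3, n_restarts=3, max_iter=100, seed=1)
        np.testing.assert_allclose(spec.usage.sum(axis=1), 1.0, atol=1e-9)


class TestSelectK:
    def _fake(self, stability, error):
        return SampleSpectra(
            spectra=pd.DataFrame(), usage=pd.DataFrame(), k=0,
            stability=stability, error=error,
        )

    def test_single_candidate_returned(self):
        k, diag = select_k({4: self._fake(0.5, 0.3)})
        assert k == 4 and len(diag) == 1

    def test_tie_rule_prefers_smallest_k(self):
        # flat stability, error differences within the 1% tie band
        results = {k: self._fake(0.8, 0.300 - 0.001 * k) for k in (3, 4, 5)}
        k, _ = select_k(results)
        assert k == 3

    def test_chooses_planted_k(self, program_cohort):
        nm, _ = program_cohort
        spec, diag = decompose_sample(
            nm, "S3", k_range=range(3, 11), n_restarts=5, max_iter=120, seed=0
        )
        assert spec.k == 3
        assert set(diag["k"]) == set(range(3, 11))


class TestMetaPrograms:
    def test_duplicate_programs_share_mp(self):
        rng = np.random.default_rng(2)
        H = pd.DataFrame(
            rng.uniform(0, 1, (3, 60)),
            index=["A|p0", "A|p1", "A|p2"],
            columns=[f"g{j}" for j in range(60)],
        )
        sa = SampleSpectra(H, pd.DataFrame(), 3, 1.0, 0.1)
        dup = H.copy()
        dup.index = ["B|p0", "B|p1", "B|p2"]
        sb = SampleSpectra(dup, pd.DataFrame(), 3, 1.0, 0.1)
        out = cluster_programs_to_mps({"A": sa, "B": sb}, top_n=20, n_mps=3)
        for j in range(3):
            assert out.mp_of_program[f"A|p{j}"] == out.mp_of_program[f"B|p{j}"]
        # PCC matrix symmetric with unit diagonal
        np.testing.assert_allclose(out.pcc.values, out.pcc.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(out.pcc.values), 1.0, atol=1e-12)

    def test_recovers_planted_families(self, program_cohort):
        nm, truth = program_cohort
        spectra = {}
        for s in sorted(nm.cell_meta["sample"].unique()):
            spec, _ = decompose_sample(
                nm, s, k_range=[3], n_restarts=5, max_iter=120, seed=0
            )
            spectra[s] = spec
        out = cluster_programs_to_mps(spectra, top_n=50, n_mps=3)
        fam = truth_family(out.top_genes, truth.program_loadings)
        progs = list(out.mp_of_program)
        ari = adjusted_rand_score(
            [fam[p] for p in progs], [out.mp_of_program[p] for p in progs]
        )
        assert ari >= 0.9

    def test_assignment_invariant_to_sample_order(self, program_cohort):
        nm, _ = program_cohort
        spectra = {}
        for s in ("S1", "S2", "S3"):
            spec, _ = decompose_sample(
                nm, s, k_range=[3], n_restarts=3, max_iter=80, seed=0
            )
            spectra[s] = spec
        fwd = cluster_programs_to_mps(spectra, n_mps=3)
        rev = cluster_programs_to_mps(
            dict(reversed(list(spectra.items()))), n_mps=3
        )
        assert fwd.mp_of_program == rev.mp_of_program

    def test_condition_exclusive_family_yields_pure_mp(self):
        # one program family planted only in condition "D": the MP holding it
        # must contain cells from condition "D" only
        cells, truth = generate_program_cells(
            3, 25, 500, 150, seed=9, n_samples=4,
            sample_conditions=["D", "D", "L", "L"],
            condition_of_program={2: "D"},
        )
        nm = normalize_log(cells)
        spectra = {}
        for s in sorted(nm.cell_meta["sample"].unique()):
            spec, _ = decompose_sample(
                nm, s, k_range=range(2, 5), n_restarts=5, max_iter=120, seed=0
            )
            spectra[s] = spec
        out = cluster_programs_to_mps(spectra, n_mps=3)
        mp_cells = assign_cells_to_mps(spectra, out)
        fam = truth_family(out.top_genes, truth.program_loadings)
        # the MP dominated by family 2 programs
        mp_label = pd.Series(
            {p: out.mp_of_program[p] for p in fam if fam[p] == 2}
        ).mode()[0]
        cond = nm.cell_meta["condition"].reindex(mp_cells.index)
        assert set(cond[mp_cells == mp_label]) == {"D"}

    def test_mp_deg_threshold_excludes_moderate_fold(self, program_cohort):
        nm, truth = program_cohort
        labels = pd.Series(truth.program_of_cell).reindex(nm.cell_ids).map(
            lambda p: f"MP{p + 1}"
        )
        tables = mp_degs(nm, labels)
        for table in tables.values():
            assert (table["log2fc"] >= 1.0).all()
        # planted program genes dominate their MP's DEG table
        for p in range(3):
            planted = set(
                truth.program_loadings.columns[truth.program_loadings.iloc[p].values > 0]
            )
            recovered = set(tables[f"MP{p + 1}"].index)
            assert len(planted & recovered) >= 0.8 * len(planted)
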