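"""Group statistics, DEG discovery, and the strict specificity filter."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgctsc import (
    MarkerCriteria,
    ValidationError,
    find_deg,
    find_specific_markers,
    group_stats,
    generate_cell_atlas,
    normalize_log,
)
from tgctsc._stats import bh_adjust
from tgctsc.synthetic import AtlasConfig

from conftest import make_normalized


def bh_oracle(p):
    """Textbook Benjamini-Hochberg step-up, coded independently."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj


def exact_ranksum_oracle(x, y):
    """Exact two-sided rank-sum p by full enumeration (independent code)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    mu = n1 * (n + 1) / 2
    obs = abs(sum(ranks[:n1]) - mu)
    count = sum(
        1
        for idx in combinations(range(n), n1)
        if abs(sum(ranks[i] for i in idx) - mu) >= obs - 1e-9
    )
    return count / comb(n, n1)


class TestGroupStats:
    def test_all_zero_gene(self):
        vals = np.zeros((3, 8))
        vals[1:] = 1.0  # keep other genes nonzero
        nm = make_normalized(vals)
        stats = group_stats(nm, [f"c{j}" for j in range(4)], [f"c{j}" for j in range(4, 8)])
        row = stats.loc["g0"]
        assert row["pct1"] == 0 and row["pct2"] == 0
        assert row["log2fc"] == 0
        assert row["p_value"] == pytest.approx(1.0)

    def test_log2fc_hand_example(self):
        # group1 de-logs to mean 3, group2 to mean 1, pseudocount 1 -> log2(4/2)=1
        g1 = np.log1p(np.full(4, 3.0))
        g2 = np.log1p(np.full(4, 1.0))
        vals = np.vstack([np.concatenate([g1, g2])])
        nm = make_normalized(vals)
        stats = group_stats(nm, [f"c{j}" for j in range(4)], [f"c{j}" for j in range(4, 8)])
        assert stats["log2fc"].iloc[0] == pytest.approx(1.0)

    def test_matches_dense_oracle_and_exact_wilcoxon(self):
        rng = np.random.default_rng(3)
        vals = rng.poisson(1.0, size=(50, 14)).astype(float)
        vals[:, 0] += 1
        nm = make_normalized(vals)
        g1 = [f"c{j}" for j in range(7)]
        g2 = [f"c{j}" for j in range(7, 14)]
        stats = group_stats(nm, g1, g2)
        v1, v2 = vals[:, :7], vals[:, 7:]
        np.testing.assert_allclose(stats["pct1"], (v1 > 0).mean(axis=1), atol=1e-12)
        np.testing.assert_allclose(stats["pct2"], (v2 > 0).mean(axis=1), atol=1e-12)
        fc = np.log2((np.expm1(v1).mean(axis=1) + 1) / (np.expm1(v2).mean(axis=1) + 1))
        np.testing.assert_allclose(stats["log2fc"], fc, atol=1e-12)
        for g in range(0, 50, 10):
            assert stats["p_value"].iloc[g] == pytest.approx(
                exact_ranksum_oracle(v1[g], v2[g]), abs=1e-12
            )

    def test_invariant_to_cell_and_gene_order(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 2, size=(12, 10))
        nm = make_normalized(vals)
        g1 = [f"c{j}" for j in range(5)]
        g2 = [f"c{j}" for j in range(5, 10)]
        base = group_stats(nm, g1, g2)
        shuffled = nm.subset_cells(rng.permutation(10)).subset_genes(
            nm.gene_ids[rng.permutation(12)]
        )
        again = group_stats(shuffled, g1, g2).reindex(base.index)
        pd.testing.assert_frame_equal(base, again)

    def test_overlapping_groups_rejected(self):
        nm = make_normalized(np.ones((3, 6)))
        with pytest.raises(ValidationError, match="disjoint"):
            group_stats(nm, ["c0", "c1", "c2"], ["c2", "c3", "c4"])


class TestFindDeg:
    def test_planted_markers_recalled(self):
        for seed in (0, 1):
            matrix, _, truth = generate_cell_atlas(AtlasConfig(seed=seed))
            nm = normalize_log(matrix)
            tables = find_deg(nm)
            for label, markers in truth.marker_genes_of_type.items():
                assert set(markers) <= set(tables[label].index)

    def test_only_pos_contract(self, default_normalized):
        tables = find_deg(default_normalized, min_log2fc=0.5, only_pos=True)
        for table in tables.values():
            assert (table["log2fc"] >= 0.5).all()

    def test_permuted_labels_yield_few_discoveries(self, default_normalized):
        rng = np.random.default_rng(0)
        labels = default_normalized.labels().to_numpy()
        counts = []
        for _ in range(5):
            perm = pd.Series(
                rng.permutation(labels), index=default_normalized.cell_ids
            )
            tables = find_deg(default_normalized, perm)
            counts.append(sum(len(t) for t in tables.values()))
        # BH at alpha=0.05 over ~no true signal: discoveries stay rare
        assert np.mean(counts) <= 0.05 * default_normalized.n_genes

    def test_tiny_label_skipped_with_warning(self, default_normalized):
        labels = default_normalized.labels().copy()
        labels.iloc[:2] = "rare"
        with pytest.warns(UserWarning, match="rare"):
            tables = find_deg(default_normalized, labels)
        assert "rare" not in tables


class TestSpecificMarkers:
    def _stats(self, rows):
        return pd.DataFrame(
            rows, columns=["pct1", "pct2", "log2fc"],
            index=[f"g{j}" for j in range(len(rows))],
        )

    def test_passing_gene(self):
        stats = self._stats([[0.60, 0.02, 2.5]])
        assert find_specific_markers(stats) == ["g0"]

    def test_boundaries_are_strict(self):
        stats = self._stats(
            [[0.60, 0.03, 2.5], [0.50, 0.02, 2.5], [0.60, 0.02, 2.0]]
        )
        assert find_specific_markers(stats) == []

    def test_exact_recovery_on_atlas(self):
        for seed in (5, 6):
            matrix, _, truth = generate_cell_atlas(AtlasConfig(seed=seed))
            nm = normalize_log(matrix)
            labels = nm.labels()
            tumor = nm.cell_ids[(labels == truth.tumor_type).to_numpy()]
            rest = nm.cell_ids[(labels != truth.tumor_type).to_numpy()]
            stats = group_stats(nm, tumor, rest, test_p=False)
            assert sorted(find_specific_markers(stats)) == sorted(
                truth.marker_genes_of_type[truth.tumor_type]
            )

    def test_tightening_never_adds_genes(self):
        rng = np.random.default_rng(2)
        stats = self._stats(
            np.column_stack(
                [rng.uniform(0, 1, 50), rng.uniform(0, 0.1, 50), rng.uniform(0, 4, 50)]
            )
        )
        loose = set(find_specific_markers(stats, MarkerCriteria(0.4, 0.05, 1.5)))
        for crit in (
            MarkerCriteria(0.5, 0.05, 1.5),
            MarkerCriteria(0.4, 0.03, 1.5),
            MarkerCriteria(0.4, 0.05, 2.5),
        ):
            assert set(find_specific_markers(stats, crit)) <= loose


class TestBhAdjustment:
    def test_ten_value_oracle(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 10)
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_matches_oracle_on_arbitrary_vectors(self, p):
        np.testing.assert_allclose(bh_adjust(np.array(p)), bh_oracle(p), atol=1e-12)
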