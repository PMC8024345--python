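"""Rank-sum enrichment test, marker filter rules, conserved markers, k-means modules."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crossatlas import (
    NormalizedMatrix,
    ValidationError,
    cluster_enriched_genes,
    cluster_specific_markers,
    conserved_gene_profiles,
    conserved_markers,
    kmeans_modules,
    ranksum_pvalue,
)

from conftest import make_annotation


def oracle_ranksum_p(x, y):
    """Independent exact oracle: enumerate all group assignments, compare |U - n1*n2/2|.

    Uses the Mann-Whitney U statistic (pair counting with half credit for
    ties) instead of the rank-sum W; the two deviations are identical, so the
    two-sided tail fraction must agree with the implementation.
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = x + y

    def u_stat(group1):
        group2 = list(pooled)
        for v in group1:
            group2.remove(v)
        u = 0.0
        for a in group1:
            for b in group2:
                u += (a > b) + 0.5 * (a == b)
        return u

    center = n1 * n2 / 2.0
    dev = abs(u_stat(x) - center)
    count = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        g1 = [pooled[i] for i in idx]
        total += 1
        if abs(u_stat(g1) - center) >= dev - 1e-9:
            count += 1
    return count / total


class TestRanksum:
    def test_example_enumeration_over_35_assignments(self):
        # in-cluster (5,6,7) vs rest (1,2,3,4): C(7,3) = 35 assignments
        p = ranksum_pvalue([5, 6, 7], [1, 2, 3, 4])
        assert p == pytest.approx(oracle_ranksum_p([5, 6, 7], [1, 2, 3, 4]), abs=1e-12)
        assert p == pytest.approx(2 / 35, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 4), (5, 5), (4, 8), (8, 8)])
    def test_exact_matches_oracle_with_ties(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(5):
            x = rng.integers(0, 4, size=n1).astype(float)  # heavy ties
            y = rng.integers(0, 4, size=n2).astype(float)
            assert ranksum_pvalue(x, y) == pytest.approx(oracle_ranksum_p(x, y), abs=1e-12)

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=6),
        st.lists(st.integers(0, 5), min_size=2, max_size=6),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_exact_p_symmetric_and_in_unit_interval(self, x, y):
        p = ranksum_pvalue(x, y)
        assert 0 < p <= 1
        assert p == pytest.approx(ranksum_pvalue(y, x), abs=1e-12)

    def test_large_groups_use_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = np.round(rng.normal(0.5, 1, 60), 1)
        y = np.round(rng.normal(0.0, 1, 80), 1)
        p = ranksum_pvalue(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            ranksum_pvalue([], [1.0])


def _norm(values):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        cell_ids=[f"c{i}" for i in range(values.shape[0])],
        gene_ids=[f"g{j}" for j in range(values.shape[1])],
        values=sp.csr_matrix(values),
    )


class TestClusterEnrichedGenes:
    def _two_cluster_matrix(self):
        """20 + 20 cells, three genes probing the pct and log2fc gates.

        g0: detected in 1 cell per group (5% < 10%) -> never tested.
        g1: detected everywhere but fold change ~2^0.5 -> below 0.58 gate.
        g2: strong marker of cluster 'm'.
        """
        n = 20
        X = np.zeros((2 * n, 3))
        X[0, 0] = X[n, 0] = 1.0
        X[:n, 1] = np.log1p(np.expm1(1.0) * 2**0.5)  # modest shift: |log2fc| ~ 0.34
        X[n:, 1] = 1.0
        X[:n, 2] = 3.0
        X[n:, 2] = 0.05
        labels = ["m"] * n + ["rest"] * n
        return _norm(X), make_annotation([f"c{i}" for i in range(2 * n)], labels)

    def test_low_detection_gene_not_tested(self):
        norm, ann = self._two_cluster_matrix()
        recs = cluster_enriched_genes(norm, ann)
        assert "g0" not in set(recs["gene_id"])

    def test_low_fold_change_gene_excluded(self):
        norm, ann = self._two_cluster_matrix()
        recs = cluster_enriched_genes(norm, ann)
        sub = recs[recs["gene_id"] == "g1"]
        assert len(sub) == 0  # |log2fc| ~ 0.5 < 0.58

    def test_strong_marker_reported_with_small_p(self):
        norm, ann = self._two_cluster_matrix()
        recs = cluster_enriched_genes(norm, ann)
        row = recs[(recs["gene_id"] == "g2") & (recs["cluster_label"] == "m")].iloc[0]
        assert row["log2fc"] > 0.58
        assert row["pct1"] == 1.0
        assert row["p_value"] < 1e-6
        assert row["p_adjusted"] >= row["p_value"]

    def test_fold_change_uses_delogged_means_with_pseudocount(self):
        # one cluster at log-value a, other at 0: log2fc = log2(mean(expm1(a)) + 1)
        a = np.log(9.0)  # expm1 = 8 -> log2fc = log2(9/1) = log2 9
        X = np.zeros((8, 1))
        X[:4, 0] = a
        norm = _norm(X)
        ann = make_annotation([f"c{i}" for i in range(8)], ["hi"] * 4 + ["lo"] * 4)
        recs = cluster_enriched_genes(norm, ann, logfc_threshold=0.5)
        row = recs[recs["cluster_label"] == "hi"].iloc[0]
        assert row["log2fc"] == pytest.approx(np.log2(9.0), abs=1e-12)

    def test_single_cluster_rejected(self):
        norm = _norm(np.ones((4, 2)))
        ann = make_annotation([f"c{i}" for i in range(4)], ["only"] * 4)
        with pytest.raises(ValidationError, match="two clusters"):
            cluster_enriched_genes(norm, ann)


class TestClusterSpecificMarkers:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["cluster_label", "gene_id", "log2fc", "pct1", "pct2", "p_value", "p_adjusted"]
        )

    def test_threshold_examples(self):
        recs = self._records(
            [
                ("c", "keep", 0.30, 0.9, 0.08, 0.01, 0.01),
                ("c", "drop_pct2", 0.30, 0.9, 0.12, 0.01, 0.01),
                ("c", "drop_lfc", 0.25, 0.9, 0.05, 0.01, 0.01),  # strict >
            ]
        )
        out = cluster_specific_markers(recs)
        assert out["gene_id"].tolist() == ["keep"]

    def test_empty_input_gives_empty_output(self):
        out = cluster_specific_markers(self._records([]))
        assert len(out) == 0

    def test_output_is_subset_and_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        recs = self._records(
            [("c", f"g{i}", rng.uniform(-1, 1), rng.uniform(), rng.uniform(), 0.01, 0.01) for i in range(50)]
        )
        loose = cluster_specific_markers(recs, min_log2fc=0.1, max_pct2=0.5)
        tight = cluster_specific_markers(recs, min_log2fc=0.3, max_pct2=0.2)
        assert set(tight["gene_id"]) <= set(loose["gene_id"]) <= set(recs["gene_id"])


class TestConservedMarkers:
    def _recs(self, cluster, genes):
        return pd.DataFrame(
            [
                {
                    "cluster_label": cluster,
                    "gene_id": g,
                    "log2fc": 1.0,
                    "pct1": 0.9,
                    "pct2": 0.05,
                    "p_value": p,
                    "p_adjusted": p,
                }
                for g, p in genes
            ]
        )

    def test_intersection_rule_and_max_p(self):
        ra = self._recs("A1", [("a1", 0.01), ("a2", 0.02)])
        rb = self._recs("B1", [("b1", 0.03)])
        omap = pd.DataFrame({"gene_a": ["a1", "a2"], "gene_b": ["b1", "b2"]})
        out = conserved_markers(ra, rb, omap, {"A1": "B1"})
        assert out["gene_a"].tolist() == ["a1"]  # a2's ortholog b2 not enriched in B1
        assert out["combined_p"].iloc[0] == pytest.approx(0.03)

    def test_empty_map_gives_empty_output(self):
        ra = self._recs("A1", [("a1", 0.01)])
        rb = self._recs("B1", [("b1", 0.01)])
        out = conserved_markers(ra, rb, pd.DataFrame({"gene_a": [], "gene_b": []}), {"A1": "B1"})
        assert len(out) == 0

    def test_unknown_cluster_in_pairing_is_error(self):
        ra = self._recs("A1", [("a1", 0.01)])
        rb = self._recs("B1", [("b1", 0.01)])
        omap = pd.DataFrame({"gene_a": ["a1"], "gene_b": ["b1"]})
        with pytest.raises(ValidationError, match="unknown cluster"):
            conserved_markers(ra, rb, omap, {"A9": "B1"})


class TestKmeansModules:
    def _planted(self, n_per=50, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        centroids = np.array(
            [[5, 0, 0, 0, 5, 0], [0, 5, 0, 5, 0, 0], [0, 0, 5, 0, 0, 5], [5, 5, 0, 0, 0, 5]],
            dtype=float,
        )
        X = np.vstack([c + rng.normal(0, noise, size=(n_per, 6)) for c in centroids])
        truth = np.repeat(np.arange(4), n_per)
        genes = [f"g{i:03d}" for i in range(len(X))]
        return pd.DataFrame(X, index=genes), truth

    def test_recovers_well_separated_planting(self):
        from sklearn.metrics import adjusted_rand_score

        profiles, truth = self._planted()
        assignment = kmeans_modules(profiles, k=4, seed=1)
        assert adjusted_rand_score(truth, assignment.modules.to_numpy()) == 1.0

    def test_identical_rows_collapse_to_one_module(self):
        profiles = pd.DataFrame(np.ones((10, 4)), index=[f"g{i}" for i in range(10)])
        a1 = kmeans_modules(profiles, k=4, seed=0)
        a2 = kmeans_modules(profiles, k=4, seed=0)
        assert a1.modules.nunique() == 1
        assert a1.modules.equals(a2.modules)

    def test_k_equal_one_puts_everything_in_one_module(self):
        profiles, _ = self._planted(n_per=5)
        assignment = kmeans_modules(profiles, k=1, seed=0)
        assert set(assignment.modules) == {1}

    def test_fewer_genes_than_k_is_error(self):
        profiles = pd.DataFrame(np.eye(3))
        with pytest.raises(ValidationError, match="at least k"):
            kmeans_modules(profiles, k=4)

    def test_invariant_to_gene_ordering_under_fixed_seed(self):
        profiles, _ = self._planted(seed=3)
        perm = np.random.default_rng(9).permutation(len(profiles))
        a1 = kmeans_modules(profiles, k=4, seed=2)
        a2 = kmeans_modules(profiles.iloc[perm], k=4, seed=2)
        assert a1.modules.sort_index().equals(a2.modules.sort_index())

    def test_conserved_gene_profiles_concatenates_species_columns(self):
        from crossatlas import ClusterProfile

        pa = ClusterProfile(
            values=pd.DataFrame([[1.0, 2.0]], index=["x"], columns=["a1", "a2"]),
            n_cells=pd.Series([3], index=["x"]),
        )
        pb = ClusterProfile(
            values=pd.DataFrame([[4.0, 5.0]], index=["u"], columns=["b1", "b2"]),
            n_cells=pd.Series([3], index=["u"]),
        )
        conserved = pd.DataFrame({"gene_a": ["a1"], "gene_b": ["b2"]})
        prof = conserved_gene_profiles(pa, pb, conserved)
        assert prof.shape == (1, 2)
        assert prof.columns.tolist() == ["A:x", "B:u"]
        assert prof.iloc[0].tolist() == [1.0, 5.0]
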