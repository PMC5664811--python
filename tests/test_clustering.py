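import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from panelclass.clustering import (
    cluster_cohort,
    comutation_counts,
    label_clusters,
    normalize_matrix,
    select_k,
    ward_cluster,
)

from .conftest import make_tumor
from .oracles import comutation_counts_naive


class TestComutationCounts:
    def test_shared_pair(self, small_panel):
        t1 = make_tumor("A", mutated=["TP53"], gained=["ERBB2"])
        t2 = make_tumor("B", mutated=["TP53", "KRAS"], gained=["ERBB2"])
        sim = comutation_counts([t1, t2], small_panel.genes)
        assert sim.counts[0, 1] == 2            # TP53 + ERBB2 shared
        assert sim.counts[0, 0] == 2            # diagonal: own altered count
        assert sim.counts[1, 1] == 3

    def test_disjoint_profiles(self, small_panel):
        t1 = make_tumor("A", mutated=["TP53"])
        t2 = make_tumor("B", mutated=["KRAS"])
        assert comutation_counts([t1, t2], small_panel.genes).counts[0, 1] == 0

    def test_empty_gene_set_rejected(self, small_panel):
        with pytest.raises(ValueError):
            comutation_counts([make_tumor("A")], set())

    def test_matches_nested_loop_oracle(self):
        """Random binary profiles agree with a naive pairwise intersection."""
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(30)]
        profiles = [set(np.array(genes)[rng.random(30) < 0.3]) for _ in range(15)]
        tumors = [make_tumor(f"T{i}", mutated=sorted(p)) for i, p in enumerate(profiles)]
        # panel-free: pass the full gene list as the clustering gene set
        sim = comutation_counts(tumors, genes)
        expected = comutation_counts_naive(profiles)
        assert np.array_equal(sim.counts, np.array(expected))


class TestNormalization:
    @pytest.mark.parametrize("c, expected", [(0, 1.0), (1, 0.5), (3, 0.25)])
    def test_formula(self, c, expected):
        assert normalize_matrix(np.array([[c]]))[0, 0] == expected

    @given(st.lists(st.integers(0, 10_000), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=100)
    def test_range_and_strict_monotonicity(self, counts):
        c = np.array(counts)
        out = normalize_matrix(c)
        assert ((out > 0) & (out <= 1)).all()
        assert ((out == 1) == (c == 0)).all()
        order = np.argsort(c)
        assert (np.diff(out[order]) <= 0).all()

    def test_preserves_symmetry(self):
        rng = np.random.default_rng(0)
        c = rng.integers(0, 5, (8, 8))
        c = c + c.T
        out = normalize_matrix(c)
        assert np.array_equal(out, out.T)


class TestWardClustering:
    def test_k_one_is_single_cluster(self):
        x = np.random.default_rng(1).random((6, 6))
        assert set(ward_cluster(x, 1)) == {1}

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(np.eye(3), 4)

    def test_identical_rows_always_cocluster(self):
        rng = np.random.default_rng(2)
        x = rng.random((7, 5))
        x[3] = x[5]
        for k in range(1, 7):
            a = ward_cluster(x, k)
            assert a[3] == a[5]

    def test_two_planted_blocks_recovered_exactly(self):
        """Two blocks of tumors sharing within-block genes -> ARI = 1 at k=2."""
        block1 = [make_tumor(f"A{i}", mutated=["TP53", "CDH1"]) for i in range(5)]
        block2 = [make_tumor(f"B{i}", mutated=["KRAS", "APC"]) for i in range(5)]
        genes = ["TP53", "CDH1", "KRAS", "APC"]
        sim = comutation_counts(block1 + block2, genes)
        a = ward_cluster(sim.normalized, 2)
        truth = [0] * 5 + [1] * 5
        assert adjusted_rand_score(truth, a) == 1.0

    def test_invariant_under_row_permutation(self):
        rng = np.random.default_rng(8)
        tumors = [
            make_tumor(f"T{i}", mutated=["TP53"] if i < 6 else ["KRAS", "APC"])
            for i in range(12)
        ]
        genes = ["TP53", "KRAS", "APC"]
        a1 = cluster_cohort(tumors, genes, k=2).assignments
        perm = [tumors[i] for i in rng.permutation(12)]
        a2 = cluster_cohort(perm, genes, k=2).assignments
        # same partition of tumor_ids up to label permutation
        pairs1 = {frozenset((s, t)) for s in a1 for t in a1 if s < t and a1[s] == a1[t]}
        pairs2 = {frozenset((s, t)) for s in a2 for t in a2 if s < t and a2[s] == a2[t]}
        assert pairs1 == pairs2


class TestSelectK:
    @staticmethod
    def _three_block_matrix():
        tumors = []
        for b, genes in enumerate([["TP53", "CDH1"], ["KRAS", "APC"], ["ERBB2", "ATM"]]):
            tumors += [make_tumor(f"B{b}_{i}", mutated=genes) for i in range(6)]
        all_genes = ["TP53", "CDH1", "KRAS", "APC", "ERBB2", "ATM"]
        return comutation_counts(tumors, all_genes).normalized

    def test_three_separated_blocks_select_three(self):
        best, table = select_k(self._three_block_matrix(), range(2, 7))
        assert best == 3

    def test_table_has_one_row_per_k(self):
        ks = range(2, 7)
        _, table = select_k(self._three_block_matrix(), ks)
        assert list(table["k"]) == list(ks)
        assert {"connectivity", "silhouette", "dunn"} <= set(table.columns)

    def test_identical_rows_degenerate(self):
        x = np.ones((10, 10)) * 0.5
        with pytest.raises(ValueError, match="identical|undefined"):
            select_k(x, range(2, 5))


class TestLabels:
    def test_dominant_gene_labels_cluster(self):
        cluster1 = [make_tumor(f"A{i}", gained=["ERBB2"]) for i in range(25)]
        rest = [make_tumor(f"B{i}", mutated=["TP53"]) for i in range(30)]
        tumors = cluster1 + rest
        assignments = {t.tumor_id: 1 if t.tumor_id.startswith("A") else 2 for t in tumors}
        labels = label_clusters(assignments, tumors, ["ERBB2", "TP53", "KRAS"])
        assert labels[1] == "ERBB2"

    def test_no_dominant_gene_is_unassigned(self):
        sparse = [make_tumor(f"A{i}", mutated=["KRAS"] if i == 0 else []) for i in range(10)]
        rest = [make_tumor(f"B{i}", mutated=["TP53"]) for i in range(10)]
        tumors = sparse + rest
        assignments = {t.tumor_id: 1 if t.tumor_id.startswith("A") else 2 for t in tumors}
        labels = label_clusters(assignments, tumors, ["ERBB2", "TP53", "KRAS"])
        assert labels[1] == "unassigned"

    def test_labels_invariant_to_tumor_order(self):
        rng = np.random.default_rng(6)
        tumors = [make_tumor(f"A{i}", gained=["ERBB2"]) for i in range(8)]
        tumors += [make_tumor(f"B{i}", mutated=["KRAS"]) for i in range(8)]
        assignments = {t.tumor_id: 1 if t.tumor_id.startswith("A") else 2 for t in tumors}
        l1 = label_clusters(assignments, tumors, ["ERBB2", "KRAS"])
        l2 = label_clusters(assignments, [tumors[i] for i in rng.permutation(16)], ["ERBB2", "KRAS"])
        assert l1 == l2
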