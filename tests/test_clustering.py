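import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ssrkit.clustering import (
    bootstrap_support,
    cut_clusters,
    to_newick,
    ward_cluster,
)
from ssrkit.genotype_io import BinaryMatrix, encode_binary
from ssrkit.simulate import SimulationConfig, simulate_collection


def binmat(rows, values):
    values = np.asarray(values, dtype=np.int8)
    cols = [("L1", 100 + 2 * j) for j in range(values.shape[1])]
    return BinaryMatrix(rows, cols, values,
                        np.zeros(values.shape, dtype=bool))


class TestWardCluster:
    def test_identical_rows_merge_first_at_zero(self):
        m = binmat(["a", "b", "c"], [[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        root = ward_cluster(m)
        (left, right) = sorted(root.children, key=lambda n: len(n.members))
        assert right.members == ("a", "b")
        assert right.height == 0.0
        assert root.height > 0.0

    def test_two_separated_pairs_recovered(self):
        m = binmat(
            ["a", "b", "c", "d"],
            [[1, 1, 0, 0], [1, 1, 0, 1], [0, 0, 1, 0], [0, 0, 1, 1]],
        )
        labels = cut_clusters(ward_cluster(m), k=2)
        assert labels["a"] == labels["b"]
        assert labels["c"] == labels["d"]
        assert labels["a"] != labels["c"]

    def test_heights_monotone(self):
        rng = np.random.default_rng(0)
        m = binmat([f"r{i}" for i in range(12)],
                   rng.integers(0, 2, size=(12, 20)))
        root = ward_cluster(m)
        for node in root.walk():
            if node.children:
                assert all(
                    c.height <= node.height + 1e-9 for c in node.children
                )

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.integers(0, 2, size=(10, 15))
        vals[3] = vals[7]  # tie: a clone pair
        vals[2] = vals[5]
        ids = [f"r{i}" for i in range(10)]
        ref = ward_cluster(binmat(ids, vals)).internal_member_sets()
        perm = rng.permutation(10)
        shuffled = ward_cluster(
            binmat([ids[i] for i in perm], vals[perm])
        ).internal_member_sets()
        assert ref == shuffled

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(9, 6))  # continuous: no exact ties
        ids = [f"r{i}" for i in range(9)]
        m = BinaryMatrix(ids, [("L", j) for j in range(6)], vals,
                         np.zeros(vals.shape, dtype=bool))
        root = ward_cluster(m)
        ours = sorted(
            round(n.height, 8) for n in root.walk() if not n.is_leaf
        )
        Z = hierarchy.linkage(pdist(vals), method="ward")
        assert ours == pytest.approx(sorted(Z[:, 2]), abs=1e-8)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(binmat(["a"], [[1, 0]]))

    def test_subpopulation_recovery(self):
        cfg = SimulationConfig(
            seed=31, n_loci=19, n_subpops=5, fst_target=0.3,
            n_founders=15, triploid_fraction=0.0,
        )
        table, _, manifest = simulate_collection(cfg)
        root = ward_cluster(encode_binary(table))
        labels = cut_clusters(root, k=5)
        # adjusted agreement with truth
        true = np.array([
            manifest.subpop_label[a] for a in table.accession_ids
        ])
        pred = np.array([labels[a] for a in table.accession_ids])
        # contingency-based adjusted Rand index
        from collections import Counter
        n = len(true)
        pairs = lambda x: x * (x - 1) / 2
        nij = Counter(zip(true, pred))
        a = sum(pairs(c) for c in nij.values())
        b1 = sum(pairs(c) for c in Counter(true).values())
        b2 = sum(pairs(c) for c in Counter(pred).values())
        expected = b1 * b2 / pairs(n)
        ari = (a - expected) / ((b1 + b2) / 2 - expected)
        assert ari >= 0.9


class TestCutClusters:
    @pytest.fixture()
    def tree(self):
        rng = np.random.default_rng(2)
        return ward_cluster(
            binmat([f"r{i}" for i in range(6)],
                   rng.integers(0, 2, size=(6, 12)))
        )

    def test_k_extremes(self, tree):
        assert len(set(cut_clusters(tree, k=6).values())) == 6
        assert len(set(cut_clusters(tree, k=1).values())) == 1

    def test_height_above_root(self, tree):
        labels = cut_clusters(tree, height=tree.height + 1)
        assert len(set(labels.values())) == 1

    def test_k_out_of_range(self, tree):
        with pytest.raises(ValueError):
            cut_clusters(tree, k=7)
        with pytest.raises(ValueError):
            cut_clusters(tree)


class TestBootstrapSupport:
    def test_clone_pair_full_support(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 2, size=(6, 30))
        vals[1] = vals[4]
        ids = [f"r{i}" for i in range(6)]
        root = bootstrap_support(binmat(ids, vals), n_boot=50, seed=0)
        clone_node = next(
            n for n in root.walk() if n.members == ("r1", "r4")
        )
        assert clone_node.support == 1.0

    def test_random_matrix_low_supports(self):
        rng = np.random.default_rng(9)
        vals = rng.integers(0, 2, size=(14, 25))
        root = bootstrap_support(
            binmat([f"r{i}" for i in range(14)], vals), n_boot=60, seed=1
        )
        supports = [
            n.support for n in root.walk()
            if not n.is_leaf and n.support is not None
            and len(n.members) < 14
        ]
        assert np.median(supports) < 0.7

    def test_zero_bootstrap_leaves_tree_unchanged(self):
        m = binmat(["a", "b", "c"], [[1, 0, 1], [1, 1, 1], [0, 1, 0]])
        root = bootstrap_support(m, n_boot=0)
        assert all(n.support is None for n in root.walk())
        assert root.internal_member_sets() == \
            ward_cluster(m).internal_member_sets()


class TestNewick:
    def test_round_trip_topology(self):
        import io
        from Bio import Phylo
        rng = np.random.default_rng(5)
        m = binmat([f"r{i}" for i in range(7)],
                   rng.integers(0, 2, size=(7, 14)))
        root = bootstrap_support(m, n_boot=20, seed=0)
        text = to_newick(root)
        tree = Phylo.read(io.StringIO(text), "newick")
        leaves = sorted(t.name for t in tree.get_terminals())
        assert leaves == sorted(root.members)
        # clades match our internal member sets
        our_sets = root.internal_member_sets()
        bio_sets = {
            tuple(sorted(l.name for l in c.get_terminals()))
            for c in tree.get_nonterminals()
            if 1 < len(c.get_terminals()) < 7
        }
        assert bio_sets == our_sets

    def test_two_leaf_shape(self):
        m = binmat(["A", "B"], [[1, 0], [0, 1]])
        text = to_newick(ward_cluster(m))
        assert text.startswith("(A:") and ",B:" in text
        assert text.endswith(";")
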