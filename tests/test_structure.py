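import io

import numpy as np
import pytest
from skbio import TreeNode

from genocurate import structure
from genocurate.geno_io import MISSING
from genocurate.simdata import SimConfig, simulate_collection

from conftest import make_matrix


def random_additive_tree(n_leaves, rng):
    """Random binary tree with positive lengths, returned with its
    tip-to-tip (additive) distance matrix."""
    nodes = [f"L{i}:{rng.uniform(0.1, 2.0):.6f}" for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.6f}")
    tree = TreeNode.read(io.StringIO(f"({nodes[0]},{nodes[1]},{nodes[2]});"))
    dm = tree.tip_tip_distances()
    return list(dm.ids), dm.data


class TestDistanceMatrix:
    def test_one_minus_ibs(self, rng):
        calls = rng.choice([0, 2], size=(1, 50))
        G = make_matrix(np.vstack([calls, calls, 2 - calls]))
        D = structure.distance_matrix(G, min_compared=1)
        assert D.d[0, 1] == 0.0
        assert D.d[0, 2] == 1.0

    def test_euclidean_arithmetic(self):
        G = make_matrix([[0, 2], [2, 0]])
        D = structure.distance_matrix(G, metric="euclidean")
        assert D.d[0, 1] == pytest.approx(np.sqrt(8))

    def test_euclidean_missing_rescaled(self):
        # one shared locus of two total: squared distance scaled by 2
        G = make_matrix([[0, MISSING], [2, 0]])
        D = structure.distance_matrix(G, metric="euclidean")
        assert D.d[0, 1] == pytest.approx(np.sqrt(4 * 2))

    def test_undefined_pair_named(self):
        G = make_matrix([[1, MISSING], [0, 0], [0, 0]])
        with pytest.raises(ValueError, match="ACC001"):
            structure.distance_matrix(G, min_compared=1)


class TestNJTree:
    def test_three_taxon_closed_form(self):
        D = structure.DistanceMatrix(
            ["a", "b", "c"], np.array([[0., 2., 4.], [2., 0., 4.], [4., 4., 0.]]),
            "test")
        T = structure.nj_tree(D)
        lengths = {t.name: t.length for t in T.tree.tips()}
        assert lengths == {"a": 1.0, "b": 1.0, "c": 3.0}

    @pytest.mark.parametrize("n_leaves", [4, 5, 6])
    def test_additive_distances_recovered_exactly(self, n_leaves, rng):
        for _ in range(10):
            ids, d = random_additive_tree(n_leaves, rng)
            T = structure.nj_tree(structure.DistanceMatrix(ids, d, "additive"))
            got = T.tip_distances().loc[ids, ids].to_numpy()
            assert np.allclose(got, d, atol=1e-9)

    def test_identical_accessions_zero_pendants(self, rng):
        calls = rng.choice([0, 2], size=(1, 100))
        other = rng.choice([0, 2], size=(2, 100))
        G = make_matrix(np.vstack([calls, calls, other]))
        D = structure.distance_matrix(G, min_compared=1)
        T = structure.nj_tree(D)
        tips = {t.name: t for t in T.tree.tips()}
        a, b = tips["ACC001"], tips["ACC002"]
        assert a.parent is b.parent
        assert a.length == 0.0 and b.length == 0.0

    def test_too_few_leaves_rejected(self):
        D = structure.DistanceMatrix(["a", "b"], np.array([[0., 1.], [1., 0.]]),
                                     "test")
        with pytest.raises(ValueError, match="at least 3"):
            structure.nj_tree(D)


class TestNewick:
    def test_three_taxon_newick(self, tmp_path):
        D = structure.DistanceMatrix(
            ["a", "b", "c"], np.array([[0., 2., 4.], [2., 0., 4.], [4., 4., 0.]]),
            "test")
        T = structure.nj_tree(D)
        path = tmp_path / "t.nwk"
        structure.to_newick(T, path)
        reread = TreeNode.read(str(path))
        lengths = {t.name: t.length for t in reread.tips()}
        assert lengths == {"a": 1.0, "b": 1.0, "c": 3.0}

    def test_labels_with_spaces_quoted(self, tmp_path, rng):
        ids = ["acc one", "acc two", "acc three", "acc four"]
        _, d = random_additive_tree(4, rng)
        T = structure.nj_tree(structure.DistanceMatrix(ids, d, "test"))
        path = tmp_path / "t.nwk"
        structure.to_newick(T, path)
        reread = TreeNode.read(str(path))
        assert sorted(t.name for t in reread.tips()) == sorted(ids)


class TestGrmPca:
    def test_two_blocks_separated_on_pc1(self):
        calls = np.vstack([np.zeros((5, 40)), np.full((5, 40), 2)]).astype(np.int8)
        G = make_matrix(calls)
        res = structure.grm_pca(G, k=3)
        pc1 = res.coordinates[:, 0]
        assert np.all(np.sign(pc1[:5]) == -np.sign(pc1[5:]))
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_sums_to_one_at_full_rank(self, rng):
        G = make_matrix(rng.choice([0, 1, 2], size=(8, 60)))
        res = structure.grm_pca(G, k=8)
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.variance_explained) <= 1e-12)

    def test_duplicates_get_identical_coordinates(self, rng):
        calls = rng.choice([0, 2], size=(5, 80))
        G = make_matrix(np.vstack([calls, calls[:1]]))
        res = structure.grm_pca(G, k=3)
        assert np.allclose(res.coordinates[0], res.coordinates[5], atol=1e-9)

    def test_order_invariant_up_to_sign(self, rng):
        calls = rng.choice([0, 1, 2], size=(10, 100))
        G = make_matrix(calls)
        res = structure.grm_pca(G, k=2)
        perm = rng.permutation(10)
        Gp = make_matrix(calls[perm], ids=[G.accession_ids[i] for i in perm])
        resp = structure.grm_pca(Gp, k=2)
        for k in range(2):
            r = np.corrcoef(res.coordinates[perm, k], resp.coordinates[:, k])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_monomorphic_matrix_rejected(self):
        G = make_matrix(np.zeros((4, 10), dtype=np.int8))
        with pytest.raises(ValueError, match="polymorphism"):
            structure.grm_pca(G)


class TestFlagMisclassified:
    def test_all_same_label_no_proposals(self, rng):
        calls = rng.choice([0, 2], size=(12, 60))
        G = make_matrix(calls)
        D = structure.distance_matrix(G, min_compared=1)
        labels = {a: "x" for a in G.accession_ids}
        assert structure.flag_misclassified(D, labels, k_neighbors=5) == []

    def test_agreement_gate(self):
        # 0.6 majority < 0.8 agreement: not flagged
        n = 11
        d = np.ones((n, n)) - np.eye(n)
        ids = [f"a{i}" for i in range(n)]
        D = structure.DistanceMatrix(ids, d, "test")
        labels = {ids[0]: "x"}
        for i in range(1, 7):
            labels[ids[i]] = "y"
        for i in range(7, n):
            labels[ids[i]] = "x"
        out = structure.flag_misclassified(D, labels, k_neighbors=10,
                                           agreement=0.8)
        assert out == []

    def test_k_validated(self, rng):
        G = make_matrix(rng.choice([0, 2], size=(5, 50)))
        D = structure.distance_matrix(G, min_compared=1)
        with pytest.raises(ValueError, match="k_neighbors"):
            structure.flag_misclassified(D, {a: "x" for a in D.ids},
                                         k_neighbors=5)

    def test_planted_mislabels_flagged_without_false_positives(self):
        """Every proposal names a planted mislabel with its true label; a
        mislabel may be skipped only when its own neighborhood is
        contaminated by other mislabels below the agreement gate."""
        cfg = SimConfig(seed=9, L=2000, pop_labels=("A", "B", "C"),
                        n_per_pop=(40, 40, 40), F_pop=(0.5, 0.5, 0.5),
                        duplicates=(), mislabel_fraction=0.05, sweep=None)
        G, passports, truth = simulate_collection(cfg)
        labels = {p.accession_id: p.taxon for p in passports}
        D = structure.distance_matrix(G, min_compared=1)
        props = structure.flag_misclassified(D, labels, k_neighbors=10,
                                             agreement=0.8)
        flagged = {p[0]: p[2] for p in props}
        assert set(flagged) <= set(truth.mislabeled)  # zero false proposals
        assert len(flagged) >= 0.8 * len(truth.mislabeled)
        assert all(flagged[a] == truth.mislabeled[a] for a in flagged)
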