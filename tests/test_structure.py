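import io

import dendropy
import numpy as np
import pytest

from cnvpopscan import (
    SimulationConfig,
    build_dosage,
    distance_matrix,
    nj_tree,
    pca,
    simulate_callset,
)
from cnvpopscan.structure import DosageMatrix

from conftest import make_callset, make_record


def _dm(values, mask=None):
    values = np.asarray(values, dtype=float)
    mask = np.zeros_like(values, dtype=bool) if mask is None else np.asarray(mask, bool)
    n, m = values.shape
    return DosageMatrix(values, mask, [f"s{i}" for i in range(n)], [f"v{j}" for j in range(m)])


class TestBuildDosage:
    def test_states_to_dosage(self):
        cs = make_callset([make_record(genotypes=[0, 1, 2])])
        dm = build_dosage(cs)
        assert dm.values[:, 0].tolist() == [0.0, 1.0, 2.0]
        assert not dm.mask.any()

    def test_missing_masked_not_zero(self):
        cs = make_callset([make_record(genotypes=[-1, -1, -1])])
        dm = build_dosage(cs)
        assert dm.mask[:, 0].all()

    def test_shape(self):
        cs = make_callset(
            [make_record("a", genotypes=[0, 1, 2]),
             make_record("b", pos=5000, genotypes=[1, 1, 1])]
        )
        assert build_dosage(cs).values.shape == (3, 2)


class TestPCA:
    def test_identical_samples_coincide(self):
        dm = _dm([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 1]])
        res = pca(dm)
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_two_cluster_separation_matches_eigh_oracle(self):
        rng = np.random.default_rng(10)
        a = rng.binomial(2, 0.9, (2, 60)).astype(float)
        b = rng.binomial(2, 0.1, (2, 60)).astype(float)
        X = np.vstack([a, b])
        dm = _dm(X)
        res = pca(dm, scale=False)
        # PC1 separates the clusters, PC1 variance > PC2 variance
        pc1 = res.coordinates[:, 0]
        assert set(np.sign(pc1[:2])).isdisjoint(set(np.sign(pc1[2:])))
        assert res.explained_fraction[0] > res.explained_fraction[1]
        # independent oracle: direct eigendecomposition of the same matrix
        poly = [j for j in range(X.shape[1]) if 0 < X[:, j].mean() / 2 < 1]
        Xc = X[:, poly] - X[:, poly].mean(axis=0)
        lam = np.linalg.eigvalsh(Xc @ Xc.T / Xc.shape[1])[::-1]
        assert res.explained_fraction[0] == pytest.approx(lam[0] / lam.sum(), abs=1e-10)

    def test_explained_fractions_normalized(self):
        rng = np.random.default_rng(11)
        dm = _dm(rng.integers(0, 3, (6, 40)).astype(float))
        res = pca(dm, n_components=6)
        frac = res.explained_fraction
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() == pytest.approx(1.0)

    def test_bitwise_reproducible(self):
        rng = np.random.default_rng(12)
        vals = rng.integers(0, 3, (8, 30)).astype(float)
        r1, r2 = pca(_dm(vals)), pca(_dm(vals))
        assert np.array_equal(r1.coordinates, r2.coordinates)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="no variance"):
            pca(_dm(np.ones((3, 5))))


class TestDistanceMatrix:
    def test_identical_and_opposite(self):
        dm = _dm([[0, 0, 0], [0, 0, 0], [2, 2, 2]])
        d = distance_matrix(dm)
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0

    def test_hand_computed_three_by_three(self):
        # s0 vs s1: |0-1|+|1-2|+|2-0|+|1-1| = 4 -> 4/8 = 0.5
        dm = _dm([[0, 1, 2, 1], [1, 2, 0, 1], [2, 2, 2, 2]])
        d = distance_matrix(dm)
        assert d[0, 1] == pytest.approx(0.5)
        assert d[0, 2] == pytest.approx((2 + 1 + 0 + 1) / 8)
        assert d[1, 2] == pytest.approx((1 + 0 + 2 + 1) / 8)
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)

    def test_missing_excluded_pairwise(self):
        mask = [[True, False], [False, False]]
        dm = _dm([[0, 2], [2, 0]], mask)
        assert distance_matrix(dm)[0, 1] == pytest.approx(1.0)

    def test_no_joint_variant_errors(self):
        mask = [[True, False], [False, True]]
        dm = _dm([[0, 2], [2, 0]], mask)
        with pytest.raises(ValueError, match="share no called variant"):
            distance_matrix(dm)


def _patristic(newick, labels):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return out


def _random_additive(rng, n):
    """Random binary tree with random edge lengths -> its leaf distance matrix."""
    import itertools

    taxa = [dendropy.Taxon(label=f"t{i}") for i in range(n)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=ns, pop_size=1.0, rng=__import__("random").Random(int(rng.integers(1 << 30)))
    )
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = float(rng.uniform(0.05, 1.0))
    labels = [f"t{i}" for i in range(n)]
    return _patristic(tree.as_string(schema="newick"), labels), labels


class TestNJTree:
    def test_two_taxa(self):
        nwk = nj_tree(np.array([[0, 0.4], [0.4, 0]]), ["a", "b"])
        d = _patristic(nwk, ["a", "b"])
        assert d[0, 1] == pytest.approx(0.4)

    def test_three_taxon_branch_lengths(self):
        # d(A,B)=2, d(A,C)=4, d(B,C)=4 -> a=1, b=1, c=3
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        nwk = nj_tree(d, ["A", "B", "C"])
        pat = _patristic(nwk, ["A", "B", "C"])
        assert np.allclose(pat, d, atol=1e-9)
        lengths = sorted(
            float(x.split(":")[1].rstrip(");")) for x in nwk.replace("(", "").split(",")
        )
        assert lengths == pytest.approx([1.0, 1.0, 3.0])

    def test_additive_four_taxon_recovery(self):
        # ((A:1,B:2):1,(C:3,D:1)); internal edge 1
        d = np.array(
            [
                [0, 3, 5, 3],
                [3, 0, 6, 4],
                [5, 6, 0, 4],
                [3, 4, 4, 0],
            ],
            dtype=float,
        )
        nwk = nj_tree(d, ["A", "B", "C", "D"])
        assert np.allclose(_patristic(nwk, ["A", "B", "C", "D"]), d, atol=1e-9)

    def test_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(13)
        for n in (4, 5, 6, 7, 8):
            for _ in range(5):
                d, labels = _random_additive(rng, n)
                nwk = nj_tree(d, labels)
                assert np.allclose(_patristic(nwk, labels), d, atol=1e-8)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(14)
        d, labels = _random_additive(rng, 6)
        perm = rng.permutation(6)
        d2 = d[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        p1 = _patristic(nj_tree(d, labels), labels)
        p2 = _patristic(nj_tree(d2, labels2), labels2)
        # distances between the same taxon pairs agree
        assert np.allclose(p2, p1[np.ix_(perm, perm)], atol=1e-9)

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(d, ["a", "b"])


class TestStructureRecovery:
    def test_pc1_sign_partitions_populations(self):
        for f in (0.2, 0.5):
            cs, _ = simulate_callset(
                SimulationConfig(n_variants=2000, fst_param=f, seed=0, dup_rate=0.0)
            )
            res = pca(build_dosage(cs))
            pc1 = res.coordinates[:, 0]
            labels = np.array([cs.pop_of[s] for s in cs.samples])
            sa = set(np.sign(pc1[labels == "WBP"]))
            sb = set(np.sign(pc1[labels == "AWB"]))
            assert sa.isdisjoint(sb)
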