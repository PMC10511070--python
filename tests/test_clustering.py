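"""Neighbor joining, orderings, PCA and SNP-group clustering."""

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare
from skbio import DistanceMatrix
from sklearn.metrics import adjusted_rand_score

from alignstat import clustering
from alignstat.clustering import (cluster_snps, correlation_ordering,
                                  leaf_order, nj_tree, pca_samples, pca_snps,
                                  tree_distance_matrix)
from alignstat.seqio import newick_string
from alignstat.simgen import simulate_alignment
from alignstat.variants import encode_genotypes, filter_biallelic, scan_sites


def random_tree(rng: np.random.Generator, n_taxa: int) -> dendropy.Tree:
    """Random unrooted binary topology with branch lengths in [0.1, 1]."""
    labels = [f"t{i:02d}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(labels)
    pool = [dendropy.Node(taxon=ns.get_taxon(l)) for l in labels]
    while len(pool) > 3:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        parent = dendropy.Node()
        for child in (pool[i], pool[j]):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(0.1, 1.0))
        pool = [p for k, p in enumerate(pool) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    for p in pool:
        tree.seed_node.add_child(p)
        p.edge.length = float(rng.uniform(0.1, 1.0))
    tree.is_rooted = False
    return tree


def same_splits(true_tree: dendropy.Tree, built: dendropy.Tree) -> bool:
    other = dendropy.Tree.get(
        data=newick_string(built), schema="newick",
        taxon_namespace=true_tree.taxon_namespace, preserve_underscores=True,
    )
    other.is_rooted = False
    true_tree.update_bipartitions()
    other.update_bipartitions()
    return treecompare.symmetric_difference(true_tree, other) == 0


class TestNjTree:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]],
                           ids=["a", "b", "c"])
        t = nj_tree(d)
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in t.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_four_taxa_additive_recovers_split_and_matrix(self):
        # tree: (a:1, b:2) -- 5 -- (c:3, d:4)
        m = np.array([
            [0, 3, 9, 10],
            [3, 0, 10, 11],
            [9, 10, 0, 7],
            [10, 11, 7, 0],
        ], dtype=float)
        d = DistanceMatrix(m, ids=list("abcd"))
        t = nj_tree(d)
        back = tree_distance_matrix(t)
        np.testing.assert_allclose(np.asarray(back.data), m, atol=1e-9)
        # split {a,b}|{c,d}: path a-b avoids the internal edge
        assert back["a", "b"] == pytest.approx(3.0, abs=1e-9)

    def test_consistency_on_random_additive_matrices(self, rng):
        """NJ recovers the generating topology and reproduces the matrix
        for 50 random 5-10 taxon trees with positive branches."""
        for _ in range(50):
            true = random_tree(rng, int(rng.integers(5, 11)))
            d = tree_distance_matrix(true)
            built = nj_tree(d)
            assert same_splits(true, built)
            back = tree_distance_matrix(built)
            np.testing.assert_allclose(np.asarray(back.data),
                                       np.asarray(d.data), atol=1e-9)

    def test_agrees_with_skbio_on_additive_input(self, rng):
        from skbio.tree import nj as skbio_nj

        true = random_tree(rng, 8)
        d = tree_distance_matrix(true)
        mine = tree_distance_matrix(nj_tree(d))
        other = skbio_nj(d).tip_tip_distances().filter(list(mine.ids))
        np.testing.assert_allclose(np.asarray(mine.data),
                                   np.asarray(other.data), atol=1e-8)

    def test_fewer_than_three_taxa_errors(self):
        d = DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(d)

    def test_negative_estimates_clamped_with_warning(self):
        # non-additive matrix that forces a negative branch estimate
        m = np.array([
            [0, 0.1, 0.4, 0.45],
            [0.1, 0, 0.45, 0.4],
            [0.4, 0.45, 0, 0.05],
            [0.45, 0.4, 0.05, 0],
        ])
        d = DistanceMatrix(m, ids=list("abcd"))
        t = nj_tree(d)
        assert all(e.length is None or e.length >= 0
                   for e in t.preorder_edge_iter())


class TestLeafOrder:
    def test_star_is_label_order(self):
        d = DistanceMatrix([[0, 2, 2], [2, 0, 2], [2, 2, 0]], ids=list("bac"))
        assert leaf_order(nj_tree(d)) == ["a", "b", "c"]

    def test_caterpillar_ladder_order(self, rng):
        # caterpillar: t00 and t01 split first, then t02 joins, etc.
        n = 6
        labels = [f"t{i:02d}" for i in range(n)]
        ns = dendropy.TaxonNamespace(labels)
        tree = dendropy.Tree(taxon_namespace=ns)
        node = tree.seed_node
        for i in range(n - 1):
            leaf = dendropy.Node(taxon=ns.get_taxon(labels[i]))
            leaf.edge.length = 1.0
            node.add_child(leaf)
            if i < n - 2:
                inner = dendropy.Node()
                inner.edge.length = 1.0
                node.add_child(inner)
                node = inner
            else:
                last = dendropy.Node(taxon=ns.get_taxon(labels[n - 1]))
                last.edge.length = 1.0
                node.add_child(last)
        assert leaf_order(tree) == labels

    def test_output_is_permutation_of_leaf_set(self, rng):
        for _ in range(20):
            t = random_tree(rng, int(rng.integers(4, 12)))
            order = leaf_order(t)
            assert sorted(order) == sorted(
                l.taxon.label for l in t.leaf_node_iter()
            )


class TestCorrelationOrdering:
    def test_identical_rows_adjacent(self, rng):
        base = rng.normal(size=20)
        rows = np.vstack([base, rng.normal(size=20), base,
                          rng.normal(size=20)])
        order = correlation_ordering(rows, ["a", "b", "c", "d"])
        assert abs(order.index("a") - order.index("c")) == 1

    def test_block_structure_stays_contiguous(self, rng):
        b1 = rng.normal(size=30)
        b2 = rng.normal(size=30)
        rows = np.vstack(
            [b1 + 0.05 * rng.normal(size=30) for _ in range(3)]
            + [b2 + 0.05 * rng.normal(size=30) for _ in range(3)]
        )
        labels = [f"x{i}" for i in range(6)]
        order = correlation_ordering(rows, labels)
        positions = [order.index(l) for l in labels[:3]]
        assert max(positions) - min(positions) == 2

    def test_singleton(self):
        assert correlation_ordering(np.array([[1.0, 2.0]]), ["only"]) == ["only"]

    def test_constant_row_warns(self, rng):
        rows = np.vstack([np.ones(10), rng.normal(size=10),
                          rng.normal(size=10)])
        with pytest.warns(UserWarning, match="constant"):
            order = correlation_ordering(rows, ["a", "b", "c"])
        assert sorted(order) == ["a", "b", "c"]


def _genotypes(seed=5, **kw):
    params = dict(n_seqs=15, width=400, n_blocks=2, snps_per_block=10,
                  seed=seed)
    params.update(kw)
    aln, truth = simulate_alignment(**params)
    sites = filter_biallelic(scan_sites(aln), max_missing=1.0)
    return encode_genotypes(sites, aln), truth


class TestPca:
    def test_scores_match_eigendecomposition_oracle(self, rng):
        g, _ = _genotypes(seed=21, missing_rate=0.05)
        res = pca_samples(g)
        # oracle: impute, center, eigh of covariance, project
        X = g.values.copy()
        for i in range(X.shape[0]):
            nan = np.isnan(X[i])
            X[i, nan] = X[i, ~nan].mean()
        X = X.T
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        scores = Xc @ v
        k = res.scores.shape[1]
        np.testing.assert_allclose(np.abs(res.scores),
                                   np.abs(scores[:, :k]), atol=1e-8)
        np.testing.assert_allclose(res.explained,
                                   (w / w.sum())[:k], atol=1e-8)

    def test_explained_sums_to_one_and_nonincreasing(self):
        g, _ = _genotypes(seed=6)
        for res in (pca_samples(g), pca_snps(g)):
            assert res.explained.sum() == pytest.approx(1.0, abs=1e-9)
            assert (np.diff(res.explained) <= 1e-12).all()

    def test_reconstruction_from_all_components(self):
        g, _ = _genotypes(seed=7)
        res = pca_samples(g)
        recon = res.scores @ res.loadings.T + res.mean
        np.testing.assert_allclose(recon, g.values.T, atol=1e-8)

    def test_rank_one_data_single_component(self):
        g, _ = _genotypes(seed=8, n_blocks=1, block_corr=1.0)
        res = pca_samples(g)
        assert res.explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_identical_observations_identical_scores(self):
        g, _ = _genotypes(seed=9, n_blocks=2, block_corr=1.0)
        res = pca_snps(g)
        # within a block (corr 1.0) all sites share a genotype vector
        rows = {tuple(v) for v in g.values}
        assert len(rows) == 2
        first_block = [i for i, v in enumerate(g.values)
                       if tuple(v) == tuple(g.values[0])]
        for i in first_block[1:]:
            np.testing.assert_allclose(res.scores[i], res.scores[first_block[0]],
                                       atol=1e-10)

    def test_transpose_duality_of_engine(self, rng):
        # on a double-centered matrix both PCA modes see the same
        # nonzero spectrum
        X = rng.normal(size=(8, 12))
        X -= X.mean(axis=0)
        X -= X.mean(axis=1, keepdims=True)
        X -= X.mean(axis=0)
        X -= X.mean(axis=1, keepdims=True)
        a = clustering._run_pca(X, list(range(8)), list(range(12)))
        b = clustering._run_pca(X.T, list(range(12)), list(range(8)))
        k = min(len(a.explained), len(b.explained))
        nz = a.explained[:k] > 1e-12
        np.testing.assert_allclose(a.explained[:k][nz], b.explained[:k][nz],
                                   atol=1e-8)

    def test_all_missing_site_dropped_with_warning(self):
        g, _ = _genotypes(seed=10)
        g.values[3, :] = np.nan
        with pytest.warns(UserWarning, match="entirely missing"):
            res = pca_samples(g)
        assert len(res.var_labels) == g.n_sites - 1

    def test_snp_mode_shape_contract(self):
        g, _ = _genotypes(seed=12)
        res = pca_snps(g)
        assert res.scores.shape == (g.n_sites,
                                    min(g.n_sites, len(g.sample_ids)))


class TestClusterSnps:
    def test_planted_blocks_recovered_exactly(self):
        g, truth = _genotypes(seed=13, block_corr=1.0)
        res = cluster_snps(pca_snps(g), seed=1337)
        assert res.k == 2
        truth_labels = [truth.snp_block_labels[s.column] for s in g.sites]
        got = [res.labels[s.column] for s in g.sites]
        assert adjusted_rand_score(truth_labels, got) == 1.0

    def test_labels_dense_and_size_ordered(self):
        g, _ = _genotypes(seed=14, n_blocks=3, snps_per_block=6)
        res = cluster_snps(pca_snps(g), seed=1)
        labels = list(res.labels.values())
        assert set(labels) == set(range(1, res.k + 1))
        sizes = [labels.count(c) for c in range(1, res.k + 1)]
        assert sizes == sorted(sizes, reverse=True)

    def test_duplicated_site_shares_label(self):
        g, _ = _genotypes(seed=15, block_corr=1.0)
        res = cluster_snps(pca_snps(g), seed=2)
        cols = [s.column for s in g.sites]
        for i, vi in enumerate(g.values):
            for j, vj in enumerate(g.values):
                if i < j and np.array_equal(vi, vj):
                    assert res.labels[cols[i]] == res.labels[cols[j]]

    def test_same_seed_is_deterministic(self):
        g, _ = _genotypes(seed=16, block_corr=0.8)
        r1 = cluster_snps(pca_snps(g), seed=99)
        r2 = cluster_snps(pca_snps(g), seed=99)
        assert r1.labels == r2.labels and r1.k == r2.k
        assert r1.silhouette == r2.silhouette

    def test_too_few_sites_errors(self):
        g, _ = _genotypes(seed=17)
        res = pca_snps(g)
        res.scores = res.scores[:2]
        res.obs_labels = res.obs_labels[:2]
        with pytest.raises(ValueError, match="too few"):
            cluster_snps(res)
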