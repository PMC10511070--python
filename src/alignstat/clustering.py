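"""Tree building, matrix orderings, PCA and SNP-group clustering.

The neighbor-joining implementation follows Saitou & Nei's agglomerative
scheme on the pairwise dissimilarity matrix and is exact on additive
inputs.  Two PCA modes share one engine: samples-as-observations (genetic
relationships between sequences) and SNPs-as-observations (groups of
co-varying sites, a linkage-disequilibrium-like view at the gene scale).
SNP groups are found by k-means on the leading PCA scores with the
cluster count chosen by mean silhouette.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .variants import GenotypeMatrix

__all__ = [
    "PcaResult",
    "SnpClusterAssignment",
    "nj_tree",
    "leaf_order",
    "tree_distance_matrix",
    "correlation_ordering",
    "pca_samples",
    "pca_snps",
    "cluster_snps",
]


def _clamp(length: float, context: str) -> float:
    if length < 0:
        warnings.warn(f"negative branch length {length:.3g} at {context} "
                      "clamped to 0")
        return 0.0
    return length


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    Iteratively joins the pair minimizing the Q-criterion
    Q(i,j) = (r-2) d(i,j) - R_i - R_j with the standard branch-length
    formulas; ties break on the smallest (i,j) pair in current label
    order, negative branch estimates are clamped to zero, and the final
    three lineages form the trifurcating root of the unrooted tree.
    """
    labels = list(d.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.asarray(d.data, dtype=float).copy()
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes.append(node)
    while len(nodes) > 3:
        r = len(nodes)
        rowsum = D.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * D[i, j] - rowsum[i] - rowsum[j]
                if q < best_q:
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = D[i, j]
        li = dij / 2 + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = _clamp(li, f"join({i},{j})")
        nodes[j].edge.length = _clamp(lj, f"join({i},{j})")
        # distances from the new node u to every other cluster k
        du = np.array([
            (D[i, k] + D[j, k] - dij) / 2 for k in range(r)
        ])
        keep = [k for k in range(r) if k not in (i, j)]
        D = D[np.ix_(keep, keep)]
        du = du[keep]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = du
        D[:-1, -1] = du
        nodes = [nodes[k] for k in keep] + [parent]
    # trifurcating root: three-point closed form
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    root = tree.seed_node
    for child, length in (
        (a, (dab + dac - dbc) / 2),
        (b, (dab + dbc - dac) / 2),
        (c, (dac + dbc - dab) / 2),
    ):
        root.add_child(child)
        child.edge.length = _clamp(length, "root")
    tree.is_rooted = False
    return tree


def _subtree_min_label(node: dendropy.Node) -> str:
    return min(t.label for t in
               (leaf.taxon for leaf in node.leaf_iter()))


def leaf_order(t: dendropy.Tree) -> list[str]:
    """Depth-first leaf ordering; at each node children are visited in
    ascending subtree-minimum-label order, so the order is a pure
    function of the (unordered) tree."""
    out: list[str] = []

    def visit(node: dendropy.Node) -> None:
        if node.is_leaf():
            out.append(node.taxon.label)
            return
        for child in sorted(node.child_nodes(), key=_subtree_min_label):
            visit(child)

    visit(t.seed_node)
    return out


def tree_distance_matrix(t: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree."""
    pdm = t.phylogenetic_distance_matrix()
    taxa = sorted(t.taxon_namespace, key=lambda x: x.label)
    labels = [x.label for x in taxa]
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(m, ids=labels)


def correlation_ordering(values: np.ndarray, labels: Sequence[str],
                         linkage: str = "average") -> list[str]:
    """Label ordering from agglomerative clustering on 1 - correlation.

    Rows of ``values`` are the profiles being correlated; a constant
    (zero-variance) row has its correlations set to 0 with a warning.
    Returns the dendrogram leaf order.
    """
    if linkage not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    values = np.asarray(values, dtype=float)
    labels = list(labels)
    if values.shape[0] != len(labels):
        raise ValueError("row count must match label count")
    if len(labels) == 1:
        return labels
    sd = values.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant row(s); correlations set to 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = (dist + dist.T) / 2
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    z = sch.linkage(squareform(dist, checks=False), method=linkage)
    return [labels[i] for i in sch.leaves_list(z)]


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance fractions of one PCA run."""

    scores: np.ndarray  # observations x components
    loadings: np.ndarray  # variables x components
    explained: np.ndarray  # fractions, non-increasing, summing to 1
    obs_labels: list
    var_labels: list
    mean: np.ndarray  # per-variable mean removed before projection

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.obs_labels, columns=cols)


def _impute_sites(g: GenotypeMatrix) -> tuple[np.ndarray, list, list[int]]:
    """Per-site mean imputation of NaN entries; drops all-NaN sites."""
    x = g.values.copy()
    keep = []
    for i in range(x.shape[0]):
        row = x[i]
        nan = np.isnan(row)
        if nan.all():
            warnings.warn(
                f"site at column {g.sites[i].column} is entirely missing; dropped"
            )
            continue
        if nan.any():
            row[nan] = row[~nan].mean()
        keep.append(i)
    return x[keep], [g.sites[i].column for i in keep], keep


def _run_pca(X: np.ndarray, obs_labels: list, var_labels: list) -> PcaResult:
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 observations")
    mean = X.mean(axis=0)
    if not np.any(X.var(axis=0) > 0):
        raise ValueError("PCA undefined: data has zero total variance")
    n_comp = min(X.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # variables x components
    # fix signs: largest-|.| loading entry of each component positive
    for k in range(n_comp):
        idx = np.argmax(np.abs(loadings[:, k]))
        if loadings[idx, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained=pca.explained_variance_ratio_,
        obs_labels=list(obs_labels),
        var_labels=list(var_labels),
        mean=mean,
    )


def pca_samples(g: GenotypeMatrix) -> PcaResult:
    """PCA with samples as observations and SNP sites as variables.

    Missing genotypes are mean-imputed per site; variables are centered
    but not scaled (the 0/1 coding is already bounded).
    """
    x, site_cols, _ = _impute_sites(g)
    if x.shape[0] == 0:
        raise ValueError("no usable sites for PCA")
    return _run_pca(x.T, obs_labels=g.sample_ids, var_labels=site_cols)


def pca_snps(g: GenotypeMatrix) -> PcaResult:
    """Transposed PCA: SNP sites as observations, samples as variables."""
    x, site_cols, _ = _impute_sites(g)
    if x.shape[0] == 0:
        raise ValueError("no usable sites for PCA")
    return _run_pca(x, obs_labels=site_cols, var_labels=g.sample_ids)


@dataclass
class SnpClusterAssignment:
    """Cluster labels (dense, 1..k, numbered by descending size) for the
    filtered biallelic sites, with the silhouette-selected k."""

    labels: dict  # site column -> label in 1..k
    k: int
    silhouette: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["column", "cluster"]
        )


def cluster_snps(p: PcaResult, k_range: tuple[int, int] = (2, 10),
                 n_components: Optional[int] = None,
                 seed: int = 1337) -> SnpClusterAssignment:
    """Group SNPs by k-means on their leading PCA scores.

    For each k in ``k_range`` (clipped to at most n_sites - 1) a k-means
    with 10 restarts is fit on the first ``n_components`` score columns;
    the k with the highest mean silhouette wins (ties to the smaller k).
    Labels are renumbered 1..k by descending cluster size.
    """
    n_sites = p.scores.shape[0]
    if n_sites < 3:
        raise ValueError("too few sites to cluster")
    if n_components is None:
        n_components = min(5, p.scores.shape[1])
    if n_components > p.scores.shape[1]:
        raise ValueError("n_components exceeds available components")
    X = p.scores[:, :n_components]
    lo = max(2, k_range[0])
    hi = min(k_range[1], n_sites - 1)
    if hi < lo:
        raise ValueError(f"empty k range [{lo}, {hi}]")
    best = None
    for k in range(lo, hi + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        with warnings.catch_warnings():
            # duplicate score points (identical genotype vectors) routinely
            # collapse clusters at large k; that k just scores poorly
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            labels = km.fit_predict(X)
        if len(set(labels)) < 2:
            continue
        score = float(silhouette_score(X, labels))
        if best is None or score > best[0]:
            best = (score, k, labels)
    if best is None:
        raise ValueError("k-means produced no valid clustering")
    score, k, labels = best
    # relabel by descending cluster size; ties by first appearance
    counts = pd.Series(labels).value_counts(sort=False)
    order = sorted(counts.index, key=lambda c: (-counts[c], c))
    remap = {old: new + 1 for new, old in enumerate(order)}
    site_labels = {
        site: remap[lab] for site, lab in zip(p.obs_labels, labels)
    }
    return SnpClusterAssignment(labels=site_labels, k=k,
                                silhouette=score, seed=seed)
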