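"""Hierarchical clustering with multiscale bootstrap support values.

The cluster-support machinery follows the multiscale bootstrap idea: the
feature columns (peptides for binding matrices, descriptor columns for
encoded motifs) are resampled with replacement at a range of sample-size
scales r (default 0.5..1.4), the tree is rebuilt per replicate, and for each
edge of the observed tree the per-scale clade frequencies BP_r are recorded.
Transforming to normal quantiles z_r = Phi^-1(1 - BP_r) and fitting

    z(r) = v * sqrt(r) + c / sqrt(r)

by weighted least squares (binomial weights via the delta method) yields a
signed distance v and curvature c per edge, from which

    AU = 1 - Phi(v - c)      (approximately unbiased p-value)
    BP = 1 - Phi(v + c)      (model bootstrap probability at scale 1)

and a delta-method standard error for AU. Clusters are then extracted by
scanning the annotated tree with an AU cutoff that is lowered stepwise.

Agglomeration is implemented here with Lance-Williams updates and a fixed,
documented tie-break (ties in the minimum distance are resolved toward the
lexicographically smallest pair of cluster representatives), so trees are
reproducible across platforms — a requirement for counting exact clade
matches over thousands of bootstrap replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))

LINKAGES = ("average", "complete", "single", "ward")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _as_item_matrix(matrix) -> pd.DataFrame:
    """Items-as-rows DataFrame from a BinaryBindingMatrix / FeatureMatrix /
    DataFrame / ndarray."""
    if hasattr(matrix, "bits"):
        return matrix.bits
    if hasattr(matrix, "features"):
        return matrix.features
    if isinstance(matrix, pd.DataFrame):
        return matrix
    arr = np.asarray(matrix)
    return pd.DataFrame(arr, index=[f"item{i}" for i in range(arr.shape[0])])


def pairwise_distance(matrix, metric: str = "jaccard") -> pd.DataFrame:
    """Symmetric item x item distance matrix.

    ``jaccard`` (1 - |intersection|/|union|, for binary rows; two all-zero
    rows are at distance 0) or ``euclidean``. Items are the rows.
    """
    df = _as_item_matrix(matrix)
    X = df.to_numpy()
    if metric == "jaccard":
        if not np.isin(X, (0, 1)).all():
            raise ValueError("jaccard distance requires binary rows")
        d = pdist(X.astype(bool), metric="jaccard")
    elif metric == "euclidean":
        d = pdist(X.astype(float), metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(squareform(d), index=df.index, columns=df.index)


# ---------------------------------------------------------------------------
# tree container
# ---------------------------------------------------------------------------

@dataclass
class Node:
    """One node of a merge tree; ``leaves`` is the sorted tuple of leaf ids."""

    leaves: tuple[str, ...]
    height: float = 0.0
    children: tuple = ()
    annotation: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def leaf_set(self) -> frozenset:
        return frozenset(self.leaves)


@dataclass
class AnnotatedDendrogram:
    """A binary merge tree whose internal edges carry bootstrap support.

    Each internal node's ``annotation`` holds ``bp_by_scale`` (scale r ->
    observed clade proportion) and, after fitting, ``au``, ``bp``, ``v``,
    ``c``, ``se_au`` and a ``degenerate`` flag.
    """

    root: Node
    leaf_ids: tuple[str, ...]
    scales: tuple[float, ...] = ()
    n_boot: int = 0

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        out: list[Node] = []

        def walk(n: Node) -> None:
            if not n.is_leaf:
                out.append(n)
                for c in n.children:
                    walk(c)
        walk(self.root)
        if not include_root:
            out = [n for n in out if n is not self.root]
        return out

    def node_by_clade(self) -> dict[frozenset, Node]:
        return {n.leaf_set: n for n in self.internal_nodes()}

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for n in self.internal_nodes(include_root=False):
            a = n.annotation
            rows.append({"clade": "|".join(n.leaves), "size": len(n.leaves),
                         "height": n.height, "bp": a.get("bp"), "au": a.get("au"),
                         "v": a.get("v"), "c": a.get("c"), "se_au": a.get("se_au")})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deterministic agglomeration (Lance-Williams)
# ---------------------------------------------------------------------------

def _agglomerate_indices(D: np.ndarray, linkage: str) -> list[tuple[int, int, float]]:
    """Merge order over item indices 0..n-1.

    Returns (i, j, height) triples where i < j are the representative indices
    (minimum member index) of the merged clusters; the merged cluster keeps
    representative i. Ties in the minimum distance break toward the smallest
    (i, j) pair.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    n = D.shape[0]
    work = D.astype(float).copy()
    if linkage == "ward":
        work = work ** 2
    np.fill_diagonal(work, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    merges = []
    for _ in range(n - 1):
        sub = np.where(active)[0]
        block = work[np.ix_(sub, sub)]
        m = block.min()
        cand = np.argwhere(block <= m)  # exact ties only
        cand = [(sub[a], sub[b]) for a, b in cand if sub[a] < sub[b]]
        i, j = min(cand)
        height = float(np.sqrt(m)) if linkage == "ward" else float(m)
        ni, nj = sizes[i], sizes[j]
        k = active.copy()
        k[[i, j]] = False
        di, dj = work[i, k], work[j, k]
        if linkage == "average":
            new = (ni * di + nj * dj) / (ni + nj)
        elif linkage == "complete":
            new = np.maximum(di, dj)
        elif linkage == "single":
            new = np.minimum(di, dj)
        else:  # ward, on squared distances
            nk = sizes[k]
            new = ((ni + nk) * di + (nj + nk) * dj - nk * work[i, j]) / (ni + nj + nk)
        work[i, k] = new
        work[k, i] = new
        sizes[i] = ni + nj
        active[j] = False
        merges.append((int(i), int(j), height))
    return merges


def hierarchical_cluster(dist, linkage: str = "average") -> AnnotatedDendrogram:
    """Agglomerative clustering of a symmetric distance matrix into a binary
    merge tree. Item ids are sorted lexicographically before merging so the
    tie-break is id-order independent."""
    if isinstance(dist, pd.DataFrame):
        ids = sorted(str(x) for x in dist.index)
        D = dist.loc[ids, ids].to_numpy(dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
        ids = [f"item{i}" for i in range(D.shape[0])]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")

    nodes: dict[int, Node] = {i: Node(leaves=(ids[i],)) for i in range(len(ids))}
    for i, j, h in _agglomerate_indices(D, linkage):
        merged = Node(leaves=tuple(sorted(nodes[i].leaves + nodes[j].leaves)),
                      height=h, children=(nodes[i], nodes[j]))
        nodes[i] = merged
        del nodes[j]
    (root,) = nodes.values()
    return AnnotatedDendrogram(root=root, leaf_ids=tuple(ids))


def _clades_of_merges(merges, n: int) -> list[frozenset]:
    """Clades (as frozensets of item indices) of a merge list, root included."""
    members: dict[int, frozenset] = {i: frozenset((i,)) for i in range(n)}
    clades = []
    for i, j, _ in merges:
        members[i] = members[i] | members[j]
        clades.append(members[i])
    return clades


# ---------------------------------------------------------------------------
# multiscale bootstrap
# ---------------------------------------------------------------------------

def multiscale_bootstrap(data, metric: str = "jaccard", linkage: str = "average",
                         scales: Sequence[float] = DEFAULT_SCALES, B: int = 1000,
                         seed: int = 0) -> AnnotatedDendrogram:
    """Build the observed tree and attach per-scale clade frequencies.

    At each scale r, ``round(r * n_features)`` feature columns are drawn with
    replacement B times; distances and the tree are recomputed per replicate
    and each observed-tree clade's frequency of exact recurrence is recorded
    in that node's ``bp_by_scale``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    scales = tuple(float(r) for r in scales)
    if not scales:
        raise ValueError("empty scale set")
    df = _as_item_matrix(data)
    ids = sorted(str(x) for x in df.index)
    X = df.loc[ids].to_numpy()
    n_items, n_feat = X.shape
    if n_feat < 2:
        raise ValueError("need at least 2 feature columns")

    tree = hierarchical_cluster(pairwise_distance(df, metric), linkage)
    clade_nodes = {frozenset(ids.index(l) for l in n.leaves): n
                   for n in tree.internal_nodes()}

    is_binary = metric == "jaccard"
    Xb = X.astype(bool) if is_binary else X.astype(float)
    rng = np.random.default_rng(seed)
    counts = {cl: {r: 0 for r in scales} for cl in clade_nodes}
    for r in scales:
        n_r = max(1, int(round(r * n_feat)))
        for _ in range(B):
            cols = rng.integers(0, n_feat, size=n_r)
            sub = Xb[:, cols]
            d = pdist(sub, metric="jaccard" if is_binary else "euclidean")
            merges = _agglomerate_indices(squareform(d), linkage)
            for cl in _clades_of_merges(merges, n_items):
                rec = counts.get(cl)
                if rec is not None:
                    rec[r] += 1

    for cl, node in clade_nodes.items():
        node.annotation["bp_by_scale"] = {r: counts[cl][r] / B for r in scales}
    tree.scales = scales
    tree.n_boot = B
    return tree


def estimate_au(bp_by_scale: Mapping[float, float], B: int
                ) -> tuple[float, float, float, float, float, bool]:
    """Fit (v, c) to per-scale bootstrap proportions and return
    ``(au, bp, v, c, se_au, degenerate)``.

    Scales whose proportion is exactly 0 or 1 carry no quantile information
    and are dropped; if fewer than two informative scales remain, AU is
    clamped to 0 or 1 (majority side) with ``degenerate=True`` and se_au NaN.
    """
    items = [(r, p) for r, p in bp_by_scale.items() if 0.0 < p < 1.0]
    if len(items) < 2:
        hi = np.mean(list(bp_by_scale.values())) >= 0.5
        au = 1.0 if hi else 0.0
        return au, au, np.nan, np.nan, np.nan, True
    r = np.array([it[0] for it in items])
    p = np.array([it[1] for it in items])
    z = norm.isf(p)  # Phi^-1(1 - p)
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    # delta method: var(z) = p(1-p) / (B * phi(z)^2)
    w = B * norm.pdf(z) ** 2 / (p * (1 - p))
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    v, c = cov @ (XtW @ z)
    au = float(1 - norm.cdf(v - c))
    bp = float(1 - norm.cdf(v + c))
    se_au = float(norm.pdf(v - c) * np.sqrt(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]))
    return au, bp, float(v), float(c), se_au, False


def annotate_tree(tree: AnnotatedDendrogram) -> AnnotatedDendrogram:
    """Fill au/bp/v/c/se_au on every internal node from its bp_by_scale."""
    for node in tree.internal_nodes():
        bps = node.annotation.get("bp_by_scale")
        if bps is None:
            raise ValueError("run multiscale_bootstrap first")
        au, bp, v, c, se, degen = estimate_au(bps, tree.n_boot)
        node.annotation.update(au=au, bp=bp, v=v, c=c, se_au=se, degenerate=degen)
    return tree


def msboot_cluster(data, metric: str = "jaccard", linkage: str = "average",
                   scales: Sequence[float] = DEFAULT_SCALES, B: int = 1000,
                   seed: int = 0) -> AnnotatedDendrogram:
    """Convenience: bootstrap + AU annotation in one call."""
    return annotate_tree(multiscale_bootstrap(data, metric, linkage, scales, B, seed))


# ---------------------------------------------------------------------------
# cluster extraction
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Significant clusters pulled from an annotated tree."""

    clusters: list[frozenset]
    au_of: dict[frozenset, float]
    alpha_trace: list[float]

    @property
    def universe(self) -> frozenset:
        return frozenset().union(*self.clusters) if self.clusters else frozenset()

    def partition_labels(self, all_items: Sequence[str]) -> list[int]:
        """Integer labels over ``all_items``; unclustered items become
        singletons (useful for adjusted-Rand comparisons)."""
        label = {}
        for k, cl in enumerate(self.clusters):
            for item in cl:
                label[item] = k
        nxt = len(self.clusters)
        out = []
        for item in all_items:
            if item not in label:
                label[item] = nxt
                nxt += 1
            out.append(label[item])
        return out


def cut_tree(tree: AnnotatedDendrogram, k: int) -> list[frozenset]:
    """The k-group partition obtained by cutting the dendrogram below its
    k-1 highest merges (the 'true cluster plot' view of the tree)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    groups = [tree.root]
    while len(groups) < k:
        internal = [n for n in groups if not n.is_leaf]
        if not internal:
            break
        tallest = max(internal, key=lambda n: n.height)
        groups.remove(tallest)
        groups.extend(tallest.children)
    return [n.leaf_set for n in groups]


def extract_clusters(tree: AnnotatedDendrogram, alpha_start: float = 0.95,
                     alpha_step: float = 0.1, min_size: int = 2,
                     max_iters: int = 5) -> ClusterSet:
    """Scan the tree with a stepwise-lowered AU cutoff and collect maximal
    significant clusters.

    Iteration k uses cutoff ``alpha_start - k * alpha_step``. At each
    iteration, edges with AU >= cutoff that do not touch an already accepted
    cluster are candidates; only maximal candidates (not nested inside
    another) are accepted, so accepted clusters are pairwise disjoint. The
    root edge (all leaves) is never a cluster.
    """
    if alpha_step <= 0:
        raise ValueError("alpha_step must be positive")
    candidates = [n for n in tree.internal_nodes(include_root=False)
                  if len(n.leaves) >= min_size and "au" in n.annotation]
    accepted: list[frozenset] = []
    au_of: dict[frozenset, float] = {}
    covered: set = set()
    trace = []
    for k in range(max_iters):
        alpha = alpha_start - k * alpha_step
        if alpha <= 0:
            break
        trace.append(round(alpha, 10))
        eligible = [n for n in candidates
                    if n.annotation["au"] >= alpha and not (n.leaf_set & covered)]
        for n in eligible:
            if any(n.leaf_set < m.leaf_set for m in eligible):
                continue  # nested inside a larger eligible edge
            accepted.append(n.leaf_set)
            au_of[n.leaf_set] = float(n.annotation["au"])
            covered |= n.leaf_set
    return ClusterSet(clusters=accepted, au_of=au_of, alpha_trace=trace)
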