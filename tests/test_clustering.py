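import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import hlasupertypes as h
from hlasupertypes.clustering import Node, _agglomerate_indices


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestPairwiseDistance:
    def test_identical_nonzero_rows_at_distance_zero(self):
        m = pd.DataFrame([[1, 1, 0], [1, 1, 0]], index=["a", "b"])
        d = h.pairwise_distance(m, "jaccard")
        assert d.at["a", "b"] == 0.0

    def test_jaccard_hand_enumeration(self):
        # u=(1,1,0), v=(1,0,1): intersection 1, union 3 -> 2/3
        m = pd.DataFrame([[1, 1, 0], [1, 0, 1]], index=["u", "v"])
        assert h.pairwise_distance(m, "jaccard").at["u", "v"] == pytest.approx(2 / 3)

    def test_euclidean_3_4_5(self):
        m = pd.DataFrame([[0, 0], [3, 4]], index=["u", "v"])
        assert h.pairwise_distance(m, "euclidean").at["u", "v"] == pytest.approx(5.0)

    def test_jaccard_rejects_non_binary(self):
        m = pd.DataFrame([[0.5, 1.0]], index=["u"])
        with pytest.raises(ValueError):
            h.pairwise_distance(m, "jaccard")

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(0, 2, (5, 12)))
        d = h.pairwise_distance(m, "jaccard").to_numpy()
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


# ---------------------------------------------------------------------------
# agglomeration vs brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_clades(D: np.ndarray, linkage: str) -> set:
    """Independent oracle: recompute linkage distances from scratch between
    leaf sets at every step, same tie-break (min distance, then smallest
    (min-member, min-member) pair)."""
    n = D.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    clades = set()

    def dist(a, b):
        pairs = [D[i, j] for i in a for j in b]
        if linkage == "average":
            return float(np.mean(pairs))
        if linkage == "complete":
            return float(np.max(pairs))
        if linkage == "single":
            return float(np.min(pairs))
        raise ValueError(linkage)

    while len(clusters) > 1:
        best = min(
            ((dist(a, b), min(a), min(b), a, b)
             for a, b in itertools.combinations(clusters, 2)),
            key=lambda t: (t[0], min(t[1], t[2]), max(t[1], t[2])))
        _, _, _, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        clades.add(a | b)
    return clades


def impl_clades(D: np.ndarray, linkage: str) -> set:
    members = {i: frozenset([i]) for i in range(D.shape[0])}
    out = set()
    for i, j, _ in _agglomerate_indices(D.copy(), linkage):
        members[i] = members[i] | members[j]
        out.add(members[i])
    return out


@pytest.mark.parametrize("linkage", ["average", "complete", "single"])
@pytest.mark.parametrize("seed", range(8))
def test_agglomeration_matches_brute_force_oracle(linkage, seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 7))
    D = rng.random((n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    assert impl_clades(D, linkage) == brute_force_clades(D, linkage)


def test_all_equal_distances_resolved_by_tie_break():
    D = np.ones((4, 4)) - np.eye(4)
    assert impl_clades(D, "average") == brute_force_clades(D, "average")
    # documented tie-break: items merge in index order
    merges = _agglomerate_indices(D, "average")
    assert [(i, j) for i, j, _ in merges] == [(0, 1), (0, 2), (0, 3)]


def test_agrees_with_scipy_on_tie_free_instances():
    from scipy.cluster.hierarchy import linkage as scipy_linkage
    from scipy.spatial.distance import squareform
    rng = np.random.default_rng(42)
    for _ in range(5):
        n = 7
        cond = rng.random(n * (n - 1) // 2) + 0.1  # generic -> no ties
        D = squareform(cond)
        Z = scipy_linkage(cond, method="average")
        members = {i: frozenset([i]) for i in range(n)}
        scipy_clades = set()
        for k, (a, b, _, _) in enumerate(Z):
            members[n + k] = members[int(a)] | members[int(b)]
            scipy_clades.add(members[n + k])
        assert impl_clades(D, "average") == scipy_clades


class TestHierarchicalCluster:
    def test_closest_pair_merges_first(self):
        d = pd.DataFrame([[0, 1, 9], [1, 0, 9], [9, 9, 0]],
                         index=list("abc"), columns=list("abc"))
        tree = h.hierarchical_cluster(d)
        clades = {n.leaf_set for n in tree.internal_nodes()}
        assert frozenset({"a", "b"}) in clades

    def test_n_items_give_n_minus_1_merges(self):
        data = h.simulate_null(9, 15, seed=0)
        tree = h.hierarchical_cluster(h.pairwise_distance(data, "euclidean"))
        assert len(tree.internal_nodes()) == 8

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            h.hierarchical_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))


# ---------------------------------------------------------------------------
# multiscale bootstrap + AU
# ---------------------------------------------------------------------------

def _two_block_data(seed=0, n_per=4, n_feat=40):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n_per, n_feat))
    b = rng.normal(8, 1, (n_per, n_feat))
    ids = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    return pd.DataFrame(np.vstack([a, b]), index=ids)


class TestMultiscaleBootstrap:
    def test_planted_block_edges_have_bp_near_one(self):
        data = _two_block_data()
        tree = h.multiscale_bootstrap(data, metric="euclidean", B=200, seed=1)
        blocks = [frozenset(f"a{i}" for i in range(4)),
                  frozenset(f"b{i}" for i in range(4))]
        by_clade = tree.node_by_clade()
        for blk in blocks:
            bps = by_clade[blk].annotation["bp_by_scale"]
            assert min(bps.values()) > 0.9

    def test_null_data_block_bp_not_near_one(self):
        data = h.simulate_null(8, 40, seed=3)
        tree = h.multiscale_bootstrap(data, metric="euclidean", B=200, seed=3)
        bps = [n.annotation["bp_by_scale"][1.0]
               for n in tree.internal_nodes(include_root=False)
               if 2 <= len(n.leaves) <= 6]
        assert np.mean(bps) < 0.8

    def test_seed_reproducibility(self):
        data = _two_block_data(seed=5)
        t1 = h.multiscale_bootstrap(data, metric="euclidean", B=50, seed=9)
        t2 = h.multiscale_bootstrap(data, metric="euclidean", B=50, seed=9)
        for n1, n2 in zip(t1.internal_nodes(), t2.internal_nodes()):
            assert n1.annotation["bp_by_scale"] == n2.annotation["bp_by_scale"]

    def test_invalid_arguments(self):
        data = _two_block_data()
        with pytest.raises(ValueError):
            h.multiscale_bootstrap(data, B=0)
        with pytest.raises(ValueError):
            h.multiscale_bootstrap(data, scales=())


class TestEstimateAU:
    def test_bp_half_everywhere_gives_au_half(self):
        au, bp, v, c, se, degen = h.estimate_au(
            {r: 0.5 for r in h.DEFAULT_SCALES}, B=1000)
        assert au == pytest.approx(0.5, abs=1e-12)
        assert v == pytest.approx(0.0, abs=1e-9) and c == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_generating_parameters_recovered(self):
        v0, c0 = 1.0, 0.2
        bp = {r: float(norm.sf(v0 * np.sqrt(r) + c0 / np.sqrt(r)))
              for r in h.DEFAULT_SCALES}
        au, _, v, c, se, degen = h.estimate_au(bp, B=1000)
        assert au == pytest.approx(float(norm.sf(v0 - c0)), abs=1e-3)
        assert not degen and se >= 0

    def test_zero_curvature_makes_au_equal_model_bp(self):
        bp = {r: float(norm.sf(0.7 * np.sqrt(r))) for r in h.DEFAULT_SCALES}
        au, bp1, *_ = h.estimate_au(bp, B=1000)
        assert au == pytest.approx(bp1, abs=1e-9)

    def test_degenerate_proportions_clamp_with_flag(self):
        au1, _, _, _, se1, deg1 = h.estimate_au({r: 1.0 for r in (0.5, 1.0)}, B=10)
        au0, _, _, _, se0, deg0 = h.estimate_au({r: 0.0 for r in (0.5, 1.0)}, B=10)
        assert (au1, au0) == (1.0, 0.0) and deg1 and deg0
        assert np.isnan(se1) and np.isnan(se0)

    def test_se_shrinks_with_more_replicates(self):
        data = _two_block_data(seed=11, n_per=3, n_feat=30)
        med = []
        for B in (100, 200):
            tree = h.msboot_cluster(data, metric="euclidean", B=B, seed=4)
            ses = [n.annotation["se_au"]
                   for n in tree.internal_nodes(include_root=False)
                   if not n.annotation["degenerate"]]
            med.append(np.median(ses))
        assert med[1] <= med[0] * 1.25  # ~1/sqrt(B) with slack


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def _leaf(name):
    return Node(leaves=(name,))


def _internal(children, au, height=1.0):
    node = Node(leaves=tuple(sorted(l for c in children for l in c.leaves)),
                height=height, children=tuple(children))
    node.annotation.update(au=au, bp=au, bp_by_scale={})
    return node


def _tree(root):
    return h.AnnotatedDendrogram(root=root, leaf_ids=root.leaves)


class TestCutTree:
    def test_three_group_cut_separates_planted_blocks(self):
        rng = np.random.default_rng(6)
        blocks = [rng.normal(c, 1, (3, 20)) for c in (0, 10, 20)]
        ids = [f"{g}{i}" for g in "abc" for i in range(3)]
        df = pd.DataFrame(np.vstack(blocks), index=ids)
        tree = h.hierarchical_cluster(h.pairwise_distance(df, "euclidean"))
        cut = set(h.cut_tree(tree, 3))
        assert cut == {frozenset(f"{g}{i}" for i in range(3)) for g in "abc"}

    def test_cut_sizes_and_partition(self):
        data = h.simulate_null(7, 20, seed=1)
        tree = h.hierarchical_cluster(h.pairwise_distance(data, "euclidean"))
        for k in (1, 3, 7):
            cut = h.cut_tree(tree, k)
            assert len(cut) == k
            assert sorted(l for s in cut for l in s) == sorted(tree.leaf_ids)

    def test_invalid_k(self):
        data = h.simulate_null(4, 10, seed=0)
        tree = h.hierarchical_cluster(h.pairwise_distance(data, "euclidean"))
        with pytest.raises(ValueError):
            h.cut_tree(tree, 0)


class TestExtractClusters:
    def test_single_significant_edge_found_at_first_cutoff(self):
        ab = _internal([_leaf("a"), _leaf("b")], au=0.99)
        root = _internal([ab, _leaf("c")], au=0.5, height=2)
        cs = h.extract_clusters(_tree(root))
        assert cs.clusters == [frozenset({"a", "b"})]
        assert cs.alpha_trace[0] == 0.95

    def test_nested_significant_edges_keep_only_maximal(self):
        ab = _internal([_leaf("a"), _leaf("b")], au=0.99)
        abc = _internal([ab, _leaf("c")], au=0.98, height=2)
        root = _internal([abc, _leaf("d")], au=0.1, height=3)
        cs = h.extract_clusters(_tree(root))
        assert cs.clusters == [frozenset({"a", "b", "c"})]

    def test_brute_force_maximal_selection(self):
        # oracle: among AU>=alpha edges, keep those not contained in another
        rng = np.random.default_rng(2)
        data = _two_block_data(seed=2)
        tree = h.msboot_cluster(data, metric="euclidean", B=100, seed=2)
        cs = h.extract_clusters(tree, alpha_start=0.9, max_iters=1)
        sig = [n.leaf_set for n in tree.internal_nodes(include_root=False)
               if n.annotation["au"] >= 0.9]
        maximal = {s for s in sig if not any(s < t for t in sig)}
        assert set(cs.clusters) == maximal

    def test_all_zero_au_gives_empty_set(self):
        ab = _internal([_leaf("a"), _leaf("b")], au=0.0)
        root = _internal([ab, _leaf("c")], au=0.0, height=2)
        cs = h.extract_clusters(_tree(root), max_iters=3)
        assert cs.clusters == [] and cs.alpha_trace == [0.95, 0.85, 0.75]

    def test_root_never_extracted(self):
        root = _internal([_leaf("a"), _leaf("b")], au=1.0)
        assert h.extract_clusters(_tree(root)).clusters == []

    def test_alpha_step_must_be_positive(self):
        root = _internal([_leaf("a"), _leaf("b")], au=1.0)
        with pytest.raises(ValueError):
            h.extract_clusters(_tree(root), alpha_step=0.0)
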