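"""Distances, UPGMA/NJ trees (with library cross-checks), bootstrap,
K-medoids clustering, PCA fractions and LD decay."""

import numpy as np
import pytest

from coresnp import (
    PanelSpec,
    bootstrap_support,
    cluster_varieties,
    genotype_distance,
    ld_decay,
    neighbor_joining,
    pca_variance,
    simulate_panel,
    upgma,
)
from coresnp.diversity import DistanceMatrix, upgma_builder

from conftest import make_panel


# ---------------------------------------------------------------------------
# distance
# ---------------------------------------------------------------------------

def test_distance_scoring_rules():
    calls = np.array(
        [
            [0, 0, 0, 0],
            [0, 0, 0, 0],   # identical -> 0
            [2, 2, 2, 2],   # opposite homozygotes -> 1
            [1, 1, 1, 1],   # het vs hom -> 0.5
        ],
        dtype=np.int8,
    )
    dm = genotype_distance(make_panel(calls))
    assert dm.values[0, 1] == 0.0
    assert dm.values[0, 2] == 1.0
    assert dm.values[0, 3] == 0.5
    assert np.allclose(dm.values, dm.values.T)
    assert np.all(np.diag(dm.values) == 0)


def test_distance_single_compared_locus():
    calls = np.array([[1, -1], [0, 2]], dtype=np.int8)
    dm = genotype_distance(make_panel(calls))
    assert dm.values[0, 1] == 0.5
    assert dm.n_compared[0, 1] == 1


def test_distance_no_cocalled_loci_errors():
    calls = np.array([[0, -1], [-1, 0]], dtype=np.int8)
    with pytest.raises(ValueError, match="no co-called"):
        genotype_distance(make_panel(calls))


def test_strict_mismatch_metric():
    calls = np.array([[0, 0], [1, 2]], dtype=np.int8)
    dm = genotype_distance(make_panel(calls), metric="mismatch")
    assert dm.values[0, 1] == 1.0


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def _dm(ids, values):
    v = np.asarray(values, dtype=float)
    return DistanceMatrix(ids=list(ids), values=v, n_compared=np.ones_like(v, int))


def test_upgma_three_taxon_hand_example():
    """d(A,B)=2, d(A,C)=d(B,C)=4: A,B join at height 1; total branch
    length 1+1+1+2 = 5."""
    tree, stats = upgma(_dm("ABC", [[0, 2, 4], [2, 0, 4], [4, 4, 0]]))
    assert stats["sum_branch_length"] == pytest.approx(5.0)
    assert stats["min_leaf_pair_path"] == pytest.approx(2.0)


def test_upgma_two_taxa():
    tree, stats = upgma(_dm("AB", [[0, 0.4], [0.4, 0]]))
    assert stats["sum_branch_length"] == pytest.approx(0.4)
    (c1, b1), (c2, b2) = tree.children
    assert b1 == pytest.approx(0.2) and b2 == pytest.approx(0.2)


def _leaf_depths(node, depth=0.0, out=None):
    out = {} if out is None else out
    if node.is_leaf:
        out[node.label] = depth
    for child, bl in node.children:
        _leaf_depths(child, depth + bl, out)
    return out


@pytest.mark.parametrize("seed", range(5))
def test_upgma_ultrametric(seed):
    rng = np.random.default_rng(seed)
    n = 8
    x = rng.random((n, 4))
    d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
    tree, _ = upgma(_dm([f"t{i}" for i in range(n)], d))
    depths = np.array(list(_leaf_depths(tree).values()))
    assert np.ptp(depths) < 1e-9


def test_upgma_matches_scipy_average_linkage():
    """Sum of branch lengths agrees with scipy's average-linkage merge
    heights on a tie-free matrix."""
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(3)
    x = rng.random((7, 5))
    d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
    tree, stats = upgma(_dm([f"t{i}" for i in range(7)], d))
    z = average(squareform(d))
    # scipy: each merge at height h contributes the two child stems
    total = 0.0
    heights = {i: 0.0 for i in range(7)}
    for k, (a, b, h, _) in enumerate(z):
        total += (h / 2 - heights[int(a)]) + (h / 2 - heights[int(b)])
        heights[7 + k] = h / 2
    assert stats["sum_branch_length"] == pytest.approx(total, abs=1e-9)


def test_upgma_equal_distances_any_order_same_sum():
    tree, stats = upgma(_dm("ABCD", np.ones((4, 4)) - np.eye(4)))
    depths = np.array(list(_leaf_depths(tree).values()))
    assert np.ptp(depths) < 1e-9
    assert stats["sum_branch_length"] == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# NJ
# ---------------------------------------------------------------------------

from conftest import random_additive_tree as _random_additive_tree
from conftest import tree_path_matrix as _tree_path_matrix


@pytest.mark.parametrize("seed", range(10))
def test_nj_recovers_additive_metric(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    ids, d = _random_additive_tree(rng, n)
    tree = neighbor_joining(_dm(ids, d))
    # total branch length of the generating tree = recovered total
    # and leaf path distances match the input metric exactly
    depths = _tree_path_matrix(tree, ids)
    assert np.allclose(depths, d, atol=1e-9)


def test_nj_matches_skbio_topology():
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(7)
    ids, d = _random_additive_tree(rng, 7)
    ours = neighbor_joining(_dm(ids, d))
    theirs = skbio_nj(SkbioDM(d, ids))
    our_bips = ours.bipartitions()
    their_bips = set()
    for node in theirs.non_tips():
        below = frozenset(t.name for t in node.tips())
        side = frozenset(ids) - below if min(ids) in below else below
        if 1 < len(side) < len(ids) - 1:
            their_bips.add(side)
    assert our_bips == their_bips


def test_nj_star_topology_zero_internal_edges():
    d = np.ones((4, 4)) - np.eye(4)
    tree = neighbor_joining(_dm("ABCD", d))
    # internal edge of the resolved quartet has length ~0
    internal = [bl for child, bl in tree.children if not child.is_leaf]
    assert all(abs(bl) < 1e-12 for bl in internal)


def test_nj_taxon_order_invariance():
    rng = np.random.default_rng(5)
    ids, d = _random_additive_tree(rng, 6)
    t1 = neighbor_joining(_dm(ids, d))
    perm = rng.permutation(6)
    t2 = neighbor_joining(
        _dm([ids[i] for i in perm], d[np.ix_(perm, perm)])
    )
    assert t1.bipartitions() == t2.bipartitions()


def test_newick_round_trip_branch_length_sum():
    """Tree serialized to Newick re-parses (dendropy) to the same total."""
    import dendropy

    rng = np.random.default_rng(2)
    ids, d = _random_additive_tree(rng, 6)
    tree = neighbor_joining(_dm(ids, d))
    parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
    assert parsed.length() == pytest.approx(tree.total_branch_length(), abs=1e-9)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _cherry_panel():
    rng = np.random.default_rng(0)
    base = rng.choice([0, 2], size=(1, 40))
    calls = np.vstack(
        [
            base, base,                       # identical pair
            rng.choice([0, 1, 2], size=(3, 40)),
        ]
    ).astype(np.int8)
    return make_panel(calls, variety_ids=["a1", "a2", "x", "y", "z"])


def test_identical_pair_cherry_full_support():
    panel = _cherry_panel()
    tree = bootstrap_support(panel, neighbor_joining, n_reps=25, seed=1)

    def find_support(node):
        out = []
        if node.support is not None:
            out.append((frozenset(node.leaves()), node.support))
        for child, _ in node.children:
            out += find_support(child)
        return out

    supports = dict(find_support(tree))
    for leaves, sup in supports.items():
        if leaves == frozenset({"a1", "a2"}) or leaves == frozenset({"x", "y", "z"}):
            assert sup == 1.0


def test_bootstrap_single_rep_supports_binary():
    panel = _cherry_panel()
    tree = bootstrap_support(panel, neighbor_joining, n_reps=1, seed=3)

    def all_supports(node):
        out = [] if node.support is None else [node.support]
        for child, _ in node.children:
            out += all_supports(child)
        return out

    assert set(all_supports(tree)) <= {0.0, 1.0}


def test_bootstrap_seed_determinism():
    panel = _cherry_panel()
    t1 = bootstrap_support(panel, upgma_builder, n_reps=10, seed=9)
    t2 = bootstrap_support(panel, upgma_builder, n_reps=10, seed=9)
    assert t1.newick(with_support=True) == t2.newick(with_support=True)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_kmedoids_k_equals_n():
    panel = make_panel(np.diag([2, 2, 2, 2]).astype(np.int8))
    model = cluster_varieties(panel, 4, seed=0)
    assert sorted(model.labels) == [1, 2, 3, 4]


def test_kmedoids_k_one():
    panel = make_panel(np.diag([2, 2, 2]).astype(np.int8))
    model = cluster_varieties(panel, 1, seed=0)
    assert set(model.labels) == {1}
    assert np.allclose(model.proportions.sum(axis=1), 1.0)


def test_kmedoids_recovery_on_synthetic_truth():
    from sklearn.metrics import rand_score

    spec = PanelSpec(n_varieties=90, n_markers=400, n_clusters=4, fst=0.25, seed=3)
    panel, _, truth = simulate_panel(spec)
    model = cluster_varieties(panel, 4, seed=3)
    lab_true = np.array([truth.cluster_labels[v] for v in panel.variety_ids])
    assert rand_score(lab_true, model.labels) > 0.9


def test_kmedoids_permutation_equivariance():
    rng = np.random.default_rng(1)
    calls = rng.choice([0, 2], size=(12, 50)).astype(np.int8)
    ids = [f"v{i}" for i in range(12)]
    panel = make_panel(calls, variety_ids=ids)
    m1 = cluster_varieties(panel, 3, seed=5)
    perm = list(rng.permutation(12))
    panel2 = panel.subset_varieties([ids[i] for i in perm])
    m2 = cluster_varieties(panel2, 3, seed=5)
    # same partition of variety ids, whatever the label names
    def partition(model):
        groups = {}
        for v, lab in zip(model.variety_ids, model.labels):
            groups.setdefault(lab, set()).add(v)
        return frozenset(frozenset(g) for g in groups.values())

    assert partition(m1) == partition(m2)


def test_outgroup_sentinel_label():
    spec = PanelSpec(n_varieties=40, n_markers=300, n_clusters=3, fst=0.3, seed=8)
    panel, _, _ = simulate_panel(spec)
    model = cluster_varieties(panel, 3, seed=1, outgroup=True)
    assert 99 in set(model.labels)
    assert model.outgroup_label == 99


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_rank_one_matrix():
    base = np.array([0, 0, 2, 2, 2], dtype=np.int8)
    calls = np.column_stack([base] * 6)
    frac = pca_variance(make_panel(calls), 2)
    assert frac[0] == pytest.approx(1.0)


def test_pca_fractions_non_increasing(small_panel):
    frac = pca_variance(small_panel[0], 5)
    assert np.all(np.diff(frac) <= 1e-12)
    assert frac.sum() <= 1.0 + 1e-9


def test_pca_duplicated_columns_same_fractions():
    rng = np.random.default_rng(4)
    calls = rng.choice([0, 1, 2], size=(20, 15)).astype(np.int8)
    panel = make_panel(calls)
    dup = make_panel(np.hstack([calls, calls]))
    f1 = pca_variance(panel, 4)
    f2 = pca_variance(dup, 4)
    assert np.allclose(f1, f2, atol=1e-9)


def test_pca_empty_panel_errors():
    with pytest.raises(ValueError):
        pca_variance(make_panel(np.empty((3, 0), dtype=np.int8)), 1)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def test_ld_duplicated_marker_r2_one():
    rng = np.random.default_rng(0)
    col = rng.choice([0, 1, 2], size=30).astype(np.int8)
    calls = np.column_stack([col, col])
    panel = make_panel(calls)  # positions 100, 200
    table, _ = ld_decay(panel, max_dist_bp=1000, bin_bp=500)
    assert table["mean_r2"].iloc[0] == pytest.approx(1.0)


def test_ld_unlinked_null_expectation():
    """For independent markers E[r^2] ~ 1/(n-1), checked over ~1000 pairs."""
    spec = PanelSpec(n_varieties=100, n_markers=46, n_chromosomes=1,
                     n_clusters=1, fst=0.0, missing_rate=0.0,
                     f1_fraction=0.99, seed=12)
    panel, _, _ = simulate_panel(spec)
    table, _ = ld_decay(panel, max_dist_bp=10**9, bin_bp=10**9)
    n = 100
    n_pairs = table["n_pairs"].sum()
    assert n_pairs >= 1000
    mean_r2 = (table["mean_r2"] * table["n_pairs"]).sum() / n_pairs
    se = np.sqrt(2.0) / (n - 1) / np.sqrt(n_pairs)
    assert abs(mean_r2 - 1 / (n - 1)) < 3 * se


def test_ld_monomorphic_pairs_excluded():
    col = np.array([0, 1, 2, 0, 1, 2], dtype=np.int8)
    mono = np.zeros(6, dtype=np.int8)
    panel = make_panel(np.column_stack([col, mono, col]))
    table, _ = ld_decay(panel, max_dist_bp=1000, bin_bp=1000)
    # only the col-col pair contributes
    assert table["n_pairs"].sum() == 1
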