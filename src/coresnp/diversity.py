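"""Genotype distances, UPGMA/NJ trees with bootstrap, K-medoids cluster
assignment, PCA variance fractions and LD-decay estimation.

The default dissimilarity is the allele-sharing distance: per co-called
locus, 0 for identical genotypes, 0.5 for het vs hom (one shared allele),
1 for opposite homozygotes, averaged over compared loci. A strict-mismatch
metric (any difference scores 1) is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .panel import GenotypePanel, MISSING


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray        # symmetric, zero diagonal
    n_compared: np.ndarray    # per-pair compared-locus counts

    @property
    def n(self) -> int:
        return len(self.ids)


def genotype_distance(panel: GenotypePanel, metric: str = "allele-sharing") -> DistanceMatrix:
    """Pairwise variety dissimilarity over co-called loci."""
    if panel.n_varieties < 2:
        raise ValueError("need at least 2 varieties")
    calls = panel.calls
    n = panel.n_varieties
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        gi = calls[i]
        both = (gi != MISSING) & (calls[i + 1:] != MISSING)
        if metric == "allele-sharing":
            score = np.abs(gi - calls[i + 1:]) / 2.0
        elif metric == "mismatch":
            score = (gi != calls[i + 1:]).astype(float)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        score = np.where(both, score, 0.0)
        cmp_counts = both.sum(axis=1)
        if np.any(cmp_counts == 0):
            j = int(np.flatnonzero(cmp_counts == 0)[0]) + i + 1
            raise ValueError(
                f"varieties {panel.variety_ids[i]} and {panel.variety_ids[j]} "
                "share no co-called loci"
            )
        d = score.sum(axis=1) / cmp_counts
        values[i, i + 1:] = d
        values[i + 1:, i] = d
        counts[i, i + 1:] = cmp_counts
        counts[i + 1:, i] = cmp_counts
    return DistanceMatrix(ids=list(panel.variety_ids), values=values, n_compared=counts)


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for i, name in enumerate(dm.ids):
            row = " ".join(f"{x:.6f}" for x in dm.values[i])
            fh.write(f"{name[:10]:<10s} {row}\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Tree node; ``children`` holds (child, branch_length) pairs."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label or ""]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def total_branch_length(self) -> float:
        tot = 0.0
        for child, bl in self.children:
            tot += bl + child.total_branch_length()
        return tot

    def newick(self, with_support: bool = False) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf:
            return self.label or ""
        inner = ",".join(
            f"{child._newick(with_support)}:{bl:.10g}" for child, bl in self.children
        )
        lab = ""
        if with_support and self.support is not None:
            lab = f"{self.support:.10g}"
        return f"({inner}){lab}"

    def bipartitions(self, all_leaves: frozenset[str] | None = None) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions, normalized to the side not
        containing the alphabetically first leaf."""
        if all_leaves is None:
            all_leaves = frozenset(self.leaves())
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label or ""])
            below: frozenset[str] = frozenset()
            for child, _ in node.children:
                below = below | walk(child)
            side = all_leaves - below if ref in below else below
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
            return below

        walk(self)
        return out


def upgma(dm: DistanceMatrix) -> tuple[TreeNode, dict[str, float]]:
    """Average-linkage agglomeration (UPGMA); node height = distance / 2.

    Ties in the minimum distance break by lexicographic cluster label
    (smallest member id). Returns the rooted ultrametric tree and a stats
    dict with the sum of branch lengths and the minimum leaf-pair path.
    """
    n = dm.n
    if n < 2:
        raise ValueError("need at least 2 taxa")
    # active clusters: key -> (node, height, size, min_label)
    nodes = {i: (TreeNode(label=dm.ids[i]), 0.0, 1, dm.ids[i]) for i in range(n)}
    dist = {(i, j): dm.values[i, j] for i in range(n) for j in range(i + 1, n)}
    min_pair_path = float(min(dist.values())) if dist else 0.0
    next_key = n
    while len(nodes) > 1:
        keys = sorted(nodes)
        best = None
        for a_i, a in enumerate(keys):
            for b in keys[a_i + 1:]:
                d = dist[(min(a, b), max(a, b))]
                lab = tuple(sorted((nodes[a][3], nodes[b][3])))
                cand = (d, lab, a, b)
                if best is None or cand < best:
                    best = cand
        d, _, a, b = best
        node_a, _, size_a, lab_a = nodes[a]
        node_b, _, size_b, lab_b = nodes[b]
        height = d / 2.0
        merged = TreeNode(
            children=[
                (node_a, height - nodes[a][1]),
                (node_b, height - nodes[b][1]),
            ]
        )
        for other in keys:
            if other in (a, b):
                continue
            da = dist[(min(a, other), max(a, other))]
            db = dist[(min(b, other), max(b, other))]
            dnew = (size_a * da + size_b * db) / (size_a + size_b)
            dist[(min(other, next_key), max(other, next_key))] = dnew
        del nodes[a], nodes[b]
        nodes[next_key] = (merged, height, size_a + size_b, min(lab_a, lab_b))
        next_key += 1
    root = next(iter(nodes.values()))[0]
    stats = {
        "sum_branch_length": root.total_branch_length(),
        "min_leaf_pair_path": min_pair_path,
    }
    return root, stats


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; unrooted (trifurcating root).

    Negative branch lengths are clamped to zero with the remainder shifted
    to the sister edge so the joined pair's distance is preserved.
    """
    n = dm.n
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=name) for name in dm.ids]
    D = dm.values.astype(float).copy()
    active = list(range(n))
    # grow matrix as we add internal nodes
    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (
            D[i, [a for a in active if a not in (i, j)]]
            + D[j, [a for a in active if a not in (i, j)]]
            - dij
        )
        idx_new = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        rest = [a for a in active if a not in (i, j)]
        D[idx_new, rest] = dnew
        D[rest, idx_new] = dnew
        nodes.append(new)
        active = rest + [idx_new]
    # final trifurcation
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    return TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])


def upgma_builder(dm: DistanceMatrix) -> TreeNode:
    return upgma(dm)[0]


def bootstrap_support(
    panel: GenotypePanel,
    tree_builder: Callable[[DistanceMatrix], TreeNode] = neighbor_joining,
    n_reps: int = 1000,
    seed: int = 0,
    metric: str = "allele-sharing",
) -> TreeNode:
    """Resample markers with replacement; support of an internal edge =
    fraction of replicate trees containing its bipartition. Seeded."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = tree_builder(genotype_distance(panel, metric=metric))
    all_leaves = frozenset(base.leaves())
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    m = panel.n_markers
    for _ in range(n_reps):
        idx = rng.integers(0, m, size=m)
        calls = panel.calls[:, idx]
        rep_dm = _distance_from_calls(calls, panel.variety_ids, metric)
        rep = tree_builder(rep_dm)
        for bip in rep.bipartitions(all_leaves):
            counts[bip] = counts.get(bip, 0) + 1

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.label or ""])
        below: frozenset[str] = frozenset()
        for child, _ in node.children:
            below = below | annotate(child)
        ref = min(all_leaves)
        side = all_leaves - below if ref in below else below
        if 1 < len(side) < len(all_leaves) - 1:
            node.support = counts.get(side, 0) / n_reps
        return below

    annotate(base)
    return base


def _distance_from_calls(calls: np.ndarray, ids, metric: str) -> DistanceMatrix:
    tmp = GenotypePanel.__new__(GenotypePanel)  # bypass marker-table checks
    tmp.variety_ids = list(ids)
    tmp.calls = calls
    tmp.markers = pd.DataFrame(
        {"id": range(calls.shape[1]), "chrom": "*", "pos": range(calls.shape[1]),
         "ref": "A", "alt": "T"}
    )
    return genotype_distance(tmp, metric=metric)


# ---------------------------------------------------------------------------
# clustering (structure surrogate)
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """Hard labels plus Q-like soft proportions per variety."""

    variety_ids: list[str]
    labels: np.ndarray              # in 1..K, or 99 for a flagged outgroup
    proportions: np.ndarray         # n x K, rows sum to 1
    medoids: list[str]
    k: int
    outgroup_label: int | None = None

    def label_of(self, variety: str) -> int:
        return int(self.labels[self.variety_ids.index(variety)])


def cluster_varieties(
    panel: GenotypePanel,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    metric: str = "allele-sharing",
    outgroup: bool = False,
) -> ClusterModel:
    """K-medoids on the genotype distance matrix (best of ``restarts``
    seeded inits by total within-cluster distance).

    Soft proportions are normalized inverse distances to the medoids and
    the hard label is their argmax, mimicking assignment by highest
    ancestry proportion. Cluster ids are relabeled by decreasing size;
    with ``outgroup=True`` the cluster most distant from the panel-wide
    allele frequencies takes the sentinel label 99.
    """
    n = panel.n_varieties
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}]")
    dm = genotype_distance(panel, metric=metric)
    # canonical internal ordering by variety id: shuffling the input rows
    # then permutes the output labels only (permutation equivariance)
    canon = sorted(range(n), key=lambda i: panel.variety_ids[i])
    D = dm.values[np.ix_(canon, canon)]
    rng = np.random.default_rng(seed)

    best_cost, best_medoids = np.inf, None
    for _ in range(max(restarts, 1)):
        medoids = list(rng.choice(n, size=k, replace=False))
        for _ in range(100):
            assign = np.argmin(D[:, medoids], axis=1)
            new_medoids = []
            for c in range(k):
                members = np.flatnonzero(assign == c)
                if members.size == 0:
                    # re-seed an empty cluster at the worst-served point
                    far = int(np.argmax(np.min(D[:, medoids], axis=1)))
                    new_medoids.append(far)
                    continue
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids.append(int(members[np.argmin(within)]))
            if set(new_medoids) == set(medoids):
                medoids = new_medoids
                break
            medoids = new_medoids
        assign = np.argmin(D[:, medoids], axis=1)
        cost = D[np.arange(n), [medoids[c] for c in assign]].sum()
        if cost < best_cost:
            best_cost, best_medoids = cost, list(medoids)

    medoids = best_medoids
    dist_to_medoids = D[:, medoids]
    with np.errstate(divide="ignore"):
        inv = 1.0 / np.maximum(dist_to_medoids, 1e-12)
    exact = dist_to_medoids <= 1e-12
    props = np.where(
        exact.any(axis=1)[:, None], exact / np.maximum(exact.sum(axis=1), 1)[:, None],
        inv / inv.sum(axis=1)[:, None],
    )
    hard0 = np.argmax(props, axis=1)

    # relabel by decreasing size (stable: ties by medoid order)
    sizes = np.array([(hard0 == c).sum() for c in range(k)])
    order = sorted(range(k), key=lambda c: (-sizes[c], c))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[c] for c in hard0])
    props = props[:, order]
    medoid_ids = [panel.variety_ids[canon[medoids[c]]] for c in order]

    # back from canonical ordering to the panel's variety order
    inv = np.empty(n, dtype=int)
    inv[np.asarray(canon)] = np.arange(n)
    labels = labels[inv]
    props = props[inv]

    outgroup_label = None
    if outgroup and k > 1:
        d = panel.dosage()
        with np.errstate(invalid="ignore"):
            global_freq = np.nanmean(d, axis=0) / 2.0
        div = []
        for lab in range(1, k + 1):
            sub = d[labels == lab]
            with np.errstate(invalid="ignore"):
                f = np.nanmean(sub, axis=0) / 2.0
            div.append(np.nanmean(np.abs(f - global_freq)))
        outgroup_label = int(np.argmax(div)) + 1
        labels = np.where(labels == outgroup_label, 99, labels)

    return ClusterModel(
        variety_ids=list(panel.variety_ids),
        labels=labels,
        proportions=props,
        medoids=medoid_ids,
        k=k,
        outgroup_label=99 if outgroup_label is not None else None,
    )


# ---------------------------------------------------------------------------
# PCA and LD decay
# ---------------------------------------------------------------------------

def pca_variance(panel: GenotypePanel, n_components: int) -> np.ndarray:
    """Variance fractions of the leading principal components of the
    mean-imputed, centered 0/1/2 genotype matrix."""
    if panel.n_markers == 0 or panel.n_varieties == 0:
        raise ValueError("empty panel")
    if n_components > min(panel.n_varieties, panel.n_markers):
        raise ValueError("n_components too large")
    d = panel.dosage()
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    filled = np.where(np.isnan(d), col_mean, d)
    pca = PCA(n_components=n_components)
    pca.fit(filled)
    return pca.explained_variance_ratio_


def ld_decay(
    panel: GenotypePanel,
    max_dist_bp: int,
    bin_bp: int,
    r2_threshold: float | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """Binned mean r^2 versus physical distance, plus the decay distance.

    r^2 is the squared Pearson correlation of 0/1/2 dosages over
    pairwise-complete varieties, for same-chromosome marker pairs within
    ``max_dist_bp``. Pairs involving a monomorphic marker are excluded.
    The decay distance is the start of the first bin whose mean drops
    below ``r2_threshold`` (default: half the maximum bin mean).
    """
    d = panel.dosage()
    chroms = panel.markers["chrom"].to_numpy()
    pos = panel.markers["pos"].to_numpy()
    dists: list[int] = []
    r2s: list[float] = []
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for a_i, i in enumerate(idx):
            for j in idx[a_i + 1:]:
                gap = int(pos[j] - pos[i])
                if gap > max_dist_bp:
                    break
                xi, xj = d[:, i], d[:, j]
                mask = ~np.isnan(xi) & ~np.isnan(xj)
                if mask.sum() < 3:
                    continue
                a, b = xi[mask], xj[mask]
                if a.std() == 0 or b.std() == 0:
                    continue
                r = np.corrcoef(a, b)[0, 1]
                dists.append(gap)
                r2s.append(float(r * r))
    if not dists:
        raise ValueError("no intra-chromosome marker pairs within range")
    bins = np.asarray(dists) // bin_bp
    df = pd.DataFrame({"dist_bp": dists, "r2": r2s, "bin": bins})
    table = (
        df.groupby("bin")
        .agg(n_pairs=("r2", "size"), mean_r2=("r2", "mean"))
        .reset_index()
    )
    table["bin_start_bp"] = table["bin"] * bin_bp
    table["bin_mid_bp"] = table["bin_start_bp"] + bin_bp / 2
    if r2_threshold is None:
        r2_threshold = table["mean_r2"].max() / 2.0
    below = table[table["mean_r2"] < r2_threshold]
    decay = float(below["bin_start_bp"].iloc[0]) if len(below) else None
    return table.drop(columns="bin"), decay
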