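import numpy as np
import pandas as pd
import pytest

from coresnp import GenotypePanel, PanelSpec, simulate_panel, worked_toy_panel


@pytest.fixture
def toy():
    """The fixed 6-variety x 8-marker worked example panel."""
    return worked_toy_panel()


@pytest.fixture
def toy_panel(toy):
    return toy[0]


@pytest.fixture
def toy_traits(toy):
    return toy[1]


@pytest.fixture(scope="session")
def small_panel():
    """A small simulated panel shared by read-only tests."""
    spec = PanelSpec(
        n_varieties=40, n_markers=300, n_clusters=3, fst=0.2, seed=42,
        trait_types=("QN", "QN", "QL"),
    )
    return simulate_panel(spec)


def random_additive_tree(rng, n_taxa):
    """Random unrooted binary tree with branch lengths in [0.1, 1];
    returns (taxon ids, exact path-distance matrix)."""
    import itertools

    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_taxa)}
    nxt = n_taxa
    active = list(range(n_taxa))
    while len(active) > 3:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        for x in (a, b):
            bl = float(rng.uniform(0.1, 1.0))
            adj.setdefault(nxt, []).append((x, bl))
            adj[x].append((nxt, bl))
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    hub = nxt
    for x in active:
        bl = float(rng.uniform(0.1, 1.0))
        adj.setdefault(hub, []).append((x, bl))
        adj[x].append((hub, bl))

    def dist(a, b):
        seen = {a: 0.0}
        stack = [a]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        return seen[b]

    d = np.zeros((n_taxa, n_taxa))
    for a, b in itertools.combinations(range(n_taxa), 2):
        d[a, b] = d[b, a] = dist(a, b)
    return [f"t{i}" for i in range(n_taxa)], d


def tree_path_matrix(tree, ids):
    """Leaf-to-leaf path-length matrix of a TreeNode tree."""
    adj: dict[int, list] = {}

    def build(node):
        adj.setdefault(id(node), [])
        for child, bl in node.children:
            adj[id(node)].append((id(child), bl))
            adj.setdefault(id(child), []).append((id(node), bl))
            build(child)

    build(tree)
    label_to_id = {}

    def collect(node):
        if node.is_leaf:
            label_to_id[node.label] = id(node)
        for child, _ in node.children:
            collect(child)

    collect(tree)
    n = len(ids)
    mat = np.zeros((n, n))
    for a_i, a in enumerate(ids):
        seen = {label_to_id[a]: 0.0}
        stack = [label_to_id[a]]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        for b_i, b in enumerate(ids):
            mat[a_i, b_i] = seen[label_to_id[b]]
    return mat


def make_panel(calls, variety_ids=None, chrom="C1"):
    """Panel from a raw call matrix with synthetic marker metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if variety_ids is None:
        variety_ids = [f"v{i}" for i in range(n)]
    markers = pd.DataFrame(
        {
            "id": [f"m{j}" for j in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * 100,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypePanel(variety_ids=list(variety_ids), markers=markers, calls=calls)
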