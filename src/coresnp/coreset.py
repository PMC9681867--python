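"""Minimal distinguishing (nested) marker-set selection.

A marker *separates* an unordered variety pair when both calls are
non-missing and differ (het vs hom counts as different; missing never
discriminates). Identifying every variety uniquely is a set-cover problem
over the C(n, 2) pairs; the selector is the classic greedy cover with
deterministic tie-breaking (higher PIC, then panel order), optionally with
seeded randomized restarts. Larger nested sets grow from the smallest by a
weighted score of coverage redundancy, per-trait representation evenness
and per-cluster allele-frequency contrast, guaranteeing the subset chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .panel import GenotypePanel, MISSING


@dataclass
class DiscriminationMatrix:
    """Pair-separation structure: one bitmask over variety pairs per marker."""

    variety_ids: list[str]
    marker_ids: list[str]
    masks: list[int]            # per marker, bit p set iff pair p separated
    pair_index: list[tuple[int, int]]  # bit position -> (i, j), i < j

    @property
    def n_pairs(self) -> int:
        return len(self.pair_index)

    @property
    def coverable_mask(self) -> int:
        out = 0
        for m in self.masks:
            out |= m
        return out

    def pair_labels(self, mask: int) -> list[tuple[str, str]]:
        """Variety-id pairs for the set bits of ``mask``."""
        out = []
        p = 0
        while mask:
            if mask & 1:
                i, j = self.pair_index[p]
                out.append((self.variety_ids[i], self.variety_ids[j]))
            mask >>= 1
            p += 1
        return out


@dataclass
class CoreSet:
    """Ordered marker set with its discrimination certificate."""

    marker_ids: list[str]
    certificate: dict[tuple[str, str], str]  # pair -> first separating marker
    unresolved: list[tuple[str, str]]
    covered_mask: int = 0

    @property
    def size(self) -> int:
        return len(self.marker_ids)

    @property
    def complete(self) -> bool:
        return not self.unresolved


@dataclass
class IdentificationReport:
    """Outcome of restricting a panel to a marker set."""

    set_size: int
    n_varieties: int
    n_distinct: int
    colliding_groups: list[list[str]]
    min_pairwise_dissimilarity: float


def build_discrimination(panel: GenotypePanel) -> DiscriminationMatrix:
    """Exact pair-separation sets for every marker (bitmask encoded)."""
    n = panel.n_varieties
    if n < 2:
        return DiscriminationMatrix(
            variety_ids=list(panel.variety_ids),
            marker_ids=panel.marker_ids,
            masks=[0] * panel.n_markers,
            pair_index=[],
        )
    iu, ju = np.triu_indices(n, k=1)
    pair_index = list(zip(iu.tolist(), ju.tolist()))
    calls = panel.calls
    masks = []
    for j in range(panel.n_markers):
        g = calls[:, j]
        sep = (g[iu] != g[ju]) & (g[iu] != MISSING) & (g[ju] != MISSING)
        mask = int.from_bytes(
            np.packbits(sep, bitorder="little").tobytes(), "little"
        )
        masks.append(mask)
    return DiscriminationMatrix(
        variety_ids=list(panel.variety_ids),
        marker_ids=panel.marker_ids,
        masks=masks,
        pair_index=pair_index,
    )


def greedy_min_set(
    dm: DiscriminationMatrix,
    weights: np.ndarray | None = None,
    required: list[str] | None = None,
    size_cap: int | None = None,
    rng: np.random.Generator | None = None,
) -> CoreSet:
    """Greedy set cover over unseparated pairs.

    Repeatedly adds the marker covering the most uncovered pairs, breaking
    ties toward higher weight (PIC) then earlier panel order — or at random
    when ``rng`` is given (randomized-restart mode). ``required`` markers
    are seeded first. Stops when all coverable pairs are covered or the cap
    is reached; unseparable pairs are reported, never silently dropped.
    """
    m = len(dm.marker_ids)
    weights = np.zeros(m) if weights is None else np.asarray(weights, dtype=float)
    id_to_idx = {mid: k for k, mid in enumerate(dm.marker_ids)}

    all_pairs = (1 << dm.n_pairs) - 1
    coverable = dm.coverable_mask
    covered = 0
    chosen: list[int] = []
    certificate: dict[tuple[str, str], str] = {}

    def record(marker_idx: int) -> None:
        nonlocal covered
        new = dm.masks[marker_idx] & ~covered
        for v1, v2 in dm.pair_labels(new):
            certificate[(v1, v2)] = dm.marker_ids[marker_idx]
        covered |= dm.masks[marker_idx]
        chosen.append(marker_idx)

    for mid in required or []:
        record(id_to_idx[mid])

    while covered & coverable != coverable:
        if size_cap is not None and len(chosen) >= size_cap:
            break
        best_gain = -1
        candidates: list[int] = []
        for k in range(m):
            if k in chosen:
                continue
            gain = (dm.masks[k] & ~covered).bit_count()
            if gain > best_gain:
                best_gain, candidates = gain, [k]
            elif gain == best_gain:
                candidates.append(k)
        if best_gain <= 0:
            break
        if rng is not None:
            pick = int(rng.choice(candidates))
        else:
            pick = max(candidates, key=lambda k: (weights[k], -k))
        record(pick)

    unresolved = dm.pair_labels(all_pairs & ~covered)
    return CoreSet(
        marker_ids=[dm.marker_ids[k] for k in chosen],
        certificate=certificate,
        unresolved=unresolved,
        covered_mask=covered,
    )


def greedy_with_restarts(
    dm: DiscriminationMatrix,
    weights: np.ndarray | None = None,
    restarts: int = 10,
    seed: int = 0,
    size_cap: int | None = None,
) -> CoreSet:
    """Best of ``restarts`` randomized greedy runs (smallest complete set),
    emulating a random-then-refine manual search reproducibly."""
    best = greedy_min_set(dm, weights=weights, size_cap=size_cap)
    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        cand = greedy_min_set(
            dm, weights=weights, size_cap=size_cap,
            rng=np.random.default_rng(int(rng.integers(0, 2**31))),
        )
        if (cand.complete, -cand.size) > (best.complete, -best.size):
            best = cand
    return best


def nested_sets(
    panel: GenotypePanel,
    dm: DiscriminationMatrix,
    sizes: list[int],
    structure_hint: np.ndarray | None = None,
    best_trait: dict[str, str] | None = None,
    weights: np.ndarray | None = None,
    score_weights: dict[str, float] | None = None,
) -> list[CoreSet]:
    """Nested core sets for descending ``sizes`` (S_small ⊆ ... ⊆ S_large).

    The smallest set comes from the greedy cover (capped at its size);
    each larger set grows by adding the marker maximizing a weighted sum of
    (a) normalized pair-coverage redundancy, (b) gain in entropy of the
    per-trait counts of included trait-linked markers and (c) per-cluster
    allele-frequency contrast from ``structure_hint`` (hard cluster
    labels). A smallest size below the greedy minimum is returned with its
    unresolved pairs flagged rather than raised.
    """
    if sorted(sizes, reverse=True) != list(sizes):
        raise ValueError("sizes must be strictly descending")
    sw = {"redundancy": 1.0, "trait": 0.5, "structure": 0.5}
    sw.update(score_weights or {})
    id_to_idx = {mid: k for k, mid in enumerate(dm.marker_ids)}
    m = len(dm.marker_ids)

    contrast = np.zeros(m)
    if structure_hint is not None:
        contrast = _cluster_contrast(panel, np.asarray(structure_hint))
        if contrast.max() > 0:
            contrast = contrast / contrast.max()

    smallest = sizes[-1]
    base = greedy_min_set(dm, weights=weights, size_cap=smallest)
    current = list(base.marker_ids)
    n_pairs = max(dm.n_pairs, 1)
    sets_small_to_large = []

    for target in reversed(sizes):
        # grow (greedy may cover everything below the requested size)
        while len(current) < target:
            trait_counts: dict[str, int] = {}
            if best_trait:
                for mid in current:
                    t = best_trait.get(mid)
                    if t:
                        trait_counts[t] = trait_counts.get(t, 0) + 1
            best_score, best_k = -math.inf, None
            for k in range(m):
                mid = dm.marker_ids[k]
                if mid in current:
                    continue
                score = sw["redundancy"] * dm.masks[k].bit_count() / n_pairs
                if best_trait:
                    t = best_trait.get(mid)
                    score += sw["trait"] * _entropy_gain(trait_counts, t)
                score += sw["structure"] * contrast[k]
                if score > best_score or (
                    score == best_score and k < (best_k if best_k is not None else m)
                ):
                    best_score, best_k = score, k
            if best_k is None:
                break
            current.append(dm.marker_ids[best_k])
        sets_small_to_large.append(_materialize(dm, current, id_to_idx))

    return list(reversed(sets_small_to_large))


def _materialize(
    dm: DiscriminationMatrix, marker_ids: list[str], id_to_idx: dict[str, int]
) -> CoreSet:
    covered = 0
    certificate: dict[tuple[str, str], str] = {}
    for mid in marker_ids:
        new = dm.masks[id_to_idx[mid]] & ~covered
        for pair in dm.pair_labels(new):
            certificate[pair] = mid
        covered |= new
    all_pairs = (1 << dm.n_pairs) - 1
    return CoreSet(
        marker_ids=list(marker_ids),
        certificate=certificate,
        unresolved=dm.pair_labels(all_pairs & ~covered),
        covered_mask=covered,
    )


def _entropy_gain(counts: dict[str, int], trait: str | None) -> float:
    """Entropy increase of the per-trait representation counts if one more
    marker of ``trait`` joins the set."""
    if trait is None:
        return 0.0
    after = dict(counts)
    after[trait] = after.get(trait, 0) + 1
    return _entropy(after) - _entropy(counts)


def _entropy(counts: dict[str, int]) -> float:
    tot = sum(counts.values())
    if tot == 0:
        return 0.0
    return -sum((c / tot) * math.log(c / tot) for c in counts.values() if c)


def _cluster_contrast(panel: GenotypePanel, labels: np.ndarray) -> np.ndarray:
    """Per-marker variance of cluster alt-allele frequencies."""
    d = panel.dosage()
    out = np.zeros(panel.n_markers)
    freqs = []
    for lab in np.unique(labels):
        sub = d[labels == lab]
        with np.errstate(invalid="ignore"):
            freqs.append(np.nanmean(sub, axis=0) / 2.0)
    f = np.vstack(freqs)
    out = np.nanvar(f, axis=0)
    return np.nan_to_num(out)


def verify_identification(panel: GenotypePanel, marker_ids: list[str]) -> IdentificationReport:
    """Check how many varieties the marker set tells apart.

    Two varieties collide when no set marker separates them under the
    missing-aware rule; colliding groups are connected components of the
    collision graph, and ``n_distinct`` counts the components (equal to the
    number of unique restricted genotype vectors when data are complete).
    """
    from .diversity import genotype_distance  # local import to avoid a cycle

    sub = panel.subset_markers_by_id(marker_ids) if marker_ids else None
    n = panel.n_varieties
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    if sub is None or sub.n_markers == 0:
        for i in range(1, n):
            parent[i] = 0
        min_diss = 0.0
    else:
        calls = sub.calls
        for i in range(n):
            for j in range(i + 1, n):
                gi, gj = calls[i], calls[j]
                sep = np.any((gi != gj) & (gi != MISSING) & (gj != MISSING))
                if not sep:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        try:
            dmat = genotype_distance(sub)
            iu, ju = np.triu_indices(n, k=1)
            min_diss = float(dmat.values[iu, ju].min()) if n > 1 else 0.0
        except ValueError:
            min_diss = float("nan")

    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(panel.variety_ids[i])
    colliding = [sorted(g) for g in groups.values() if len(g) > 1]
    return IdentificationReport(
        set_size=len(marker_ids),
        n_varieties=n,
        n_distinct=len(groups),
        colliding_groups=sorted(colliding),
        min_pairwise_dissimilarity=min_diss,
    )
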