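"""Synthetic variety-panel generator.

Emulates the statistical structure of a commercial crop variety panel as it
reaches a genotyping pipeline: subpopulation divergence under the
Balding-Nichols model, inbred lines and F1 hybrids (heterozygous wherever
the two inbred parents differ), uniform missingness, and DUS-style traits
(quantitative measurements plus graded qualitative / pseudo-qualitative
scores) linked to causal markers.

Defaults mirror a cabbage-style study panel: 96 varieties over 8
chromosomes, 7 subpopulation clusters, a predominance of F1 hybrids, an
ancestral minor-allele-frequency floor of 0.05 and 10% missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel, HET, HOM_ALT, HOM_REF, MISSING, TraitTable

#: Trait type layout used by default: 2 QL, 11 QN, 6 PQ (19 total).
DEFAULT_TRAIT_TYPES: tuple[str, ...] = ("QL",) * 2 + ("QN",) * 11 + ("PQ",) * 6

#: Integer grade sets for simulated graded traits.
QL_GRADES: tuple[int, ...] = (1, 9)
PQ_GRADES: tuple[int, ...] = (1, 2, 5)
QN_GRADES: tuple[int, ...] = (3, 5, 7)


@dataclass
class PanelSpec:
    """Parameters of a simulated variety panel.

    ``fst`` is the Balding-Nichols divergence of cluster allele frequencies
    around the ancestral frequency; ``f1_fraction`` is the fraction of
    varieties generated as inbred x inbred crosses; ``effect_size`` is the
    per-alt-allele shift of a causal marker in units of ``noise_sd``.
    """

    n_varieties: int = 96
    n_markers: int = 3000
    n_chromosomes: int = 8
    chrom_length_bp: int = 50_000_000
    n_clusters: int = 7
    fst: float = 0.2
    f1_fraction: float = 0.8
    missing_rate: float = 0.10
    maf_floor: float = 0.05
    trait_types: tuple[str, ...] = field(default=DEFAULT_TRAIT_TYPES)
    causal_per_trait: int = 5
    effect_size: float = 1.0
    noise_sd: float = 1.0
    cross_between_clusters: bool = False
    outgroup_cluster: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_varieties", "n_markers", "n_chromosomes",
                     "chrom_length_bp", "n_clusters", "causal_per_trait"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        for name in ("f1_fraction", "missing_rate"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (0.0 < self.maf_floor <= 0.5):
            raise ValueError("maf_floor must lie in (0, 0.5]")
        bad = set(self.trait_types) - {"QL", "QN", "PQ"}
        if bad:
            raise ValueError(f"unknown trait types {sorted(bad)}")
        if self.causal_per_trait > self.n_markers:
            raise ValueError("causal_per_trait exceeds n_markers")
        if self.n_clusters > self.n_varieties:
            raise ValueError("n_clusters exceeds n_varieties")


@dataclass
class TruthRecord:
    """Ground truth of a simulated panel, for recovery tests."""

    cluster_labels: dict[str, int]
    causal_markers: dict[str, list[str]]
    causal_effects: dict[str, list[float]]
    f1_parents: dict[str, tuple[np.ndarray, np.ndarray]]
    outgroup_label: int | None = None


def _marker_positions(spec: PanelSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Sorted unique marker positions spread over the chromosomes."""
    per_chrom = np.full(spec.n_chromosomes, spec.n_markers // spec.n_chromosomes)
    per_chrom[: spec.n_markers % spec.n_chromosomes] += 1
    rows = []
    for c, n in enumerate(per_chrom, start=1):
        if n == 0:
            continue
        pos = np.sort(
            rng.choice(np.arange(1, spec.chrom_length_bp + 1), size=n, replace=False)
        )
        for p in pos:
            rows.append((f"C{c}_{p}", f"C{c}", int(p)))
    df = pd.DataFrame(rows, columns=["id", "chrom", "pos"])
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=len(df))
    alt = (ref + rng.integers(1, 4, size=len(df))) % 4
    df["ref"] = bases[ref]
    df["alt"] = bases[alt]
    return df


def simulate_panel(spec: PanelSpec) -> tuple[GenotypePanel, TraitTable, TruthRecord]:
    """Simulate a genotype panel, a trait table and the generating truth.

    Inbred varieties are fully homozygous (one allele drawn per locus from
    their cluster's frequency); F1 varieties take one allele from each of
    two simulated inbred parents and are heterozygous exactly where the
    parents differ. QN traits are additive in causal dosage plus Gaussian
    noise; QL/PQ traits threshold a causal score into printed grade levels.
    The same spec (same seed) reproduces the output bitwise.
    """
    rng = np.random.default_rng(spec.seed)
    K = spec.n_clusters
    n, m = spec.n_varieties, spec.n_markers

    markers = _marker_positions(spec, rng)

    # ancestral frequencies with a MAF floor, then per-cluster Balding-Nichols
    p_anc = rng.uniform(spec.maf_floor, 1.0 - spec.maf_floor, size=m)
    if spec.fst > 0:
        F = spec.fst
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        p_clust = rng.beta(a, b, size=(K, m))
        p_clust = np.clip(p_clust, 1e-6, 1.0 - 1e-6)
    else:
        p_clust = np.tile(p_anc, (K, 1))

    # every cluster non-empty: tile labels then shuffle
    labels = np.resize(np.arange(1, K + 1), n)
    rng.shuffle(labels)

    variety_ids = [f"V{i + 1:03d}" for i in range(n)]
    n_f1 = int(round(spec.f1_fraction * n))
    is_f1 = np.zeros(n, dtype=bool)
    if n_f1 > 0:
        is_f1[rng.choice(n, size=n_f1, replace=False)] = True

    calls = np.empty((n, m), dtype=np.int8)
    f1_parents: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def draw_inbred(cluster: int) -> np.ndarray:
        """Fully homozygous gamete-doubled line: allele per locus."""
        allele = (rng.random(m) < p_clust[cluster - 1]).astype(np.int8)
        return allele  # 1 = alt allele

    for i in range(n):
        k = int(labels[i])
        if is_f1[i]:
            k2 = k
            if spec.cross_between_clusters and K > 1:
                others = [c for c in range(1, K + 1) if c != k]
                k2 = int(rng.choice(others))
            a1 = draw_inbred(k)
            a2 = draw_inbred(k2)
            calls[i] = a1 + a2  # 0 hom-ref, 1 het, 2 hom-alt
            f1_parents[variety_ids[i]] = (2 * a1, 2 * a2)
        else:
            a = draw_inbred(k)
            calls[i] = 2 * a

    # traits: causal markers drawn without replacement per trait
    trait_ids = _trait_ids(spec.trait_types)
    dosage = calls.astype(float)
    causal_markers: dict[str, list[str]] = {}
    causal_effects: dict[str, list[float]] = {}
    values: dict[str, np.ndarray] = {}
    grade_sets: dict[str, tuple[int, ...] | None] = {}
    types: dict[str, str] = {}
    marker_id_arr = markers["id"].to_numpy()

    for trait, ttype in zip(trait_ids, spec.trait_types):
        idx = rng.choice(m, size=spec.causal_per_trait, replace=False)
        effects = np.full(spec.causal_per_trait, spec.effect_size * spec.noise_sd)
        score = dosage[:, idx] @ effects
        noise = rng.normal(0.0, spec.noise_sd, size=n)
        types[trait] = ttype
        causal_markers[trait] = [str(x) for x in marker_id_arr[idx]]
        causal_effects[trait] = [float(e) for e in effects]
        if ttype == "QN":
            values[trait] = score + noise
            grade_sets[trait] = None
        else:
            grades = QL_GRADES if ttype == "QL" else PQ_GRADES
            values[trait] = _grade_by_quantile(score + noise, grades)
            grade_sets[trait] = grades

    # missingness: uniform mask over all calls
    if spec.missing_rate > 0:
        mask = rng.random((n, m)) < spec.missing_rate
        calls[mask] = MISSING

    panel = GenotypePanel(variety_ids=variety_ids, markers=markers, calls=calls)
    traits = TraitTable(
        values=pd.DataFrame(values, index=variety_ids),
        types=types,
        grade_sets=grade_sets,
    )
    outgroup = None
    if spec.outgroup_cluster and K > 1:
        # most divergent cluster = largest mean |cluster freq - ancestral freq|
        div = np.abs(p_clust - p_anc).mean(axis=1)
        outgroup = int(np.argmax(div)) + 1
    truth = TruthRecord(
        cluster_labels=dict(zip(variety_ids, (int(x) for x in labels))),
        causal_markers=causal_markers,
        causal_effects=causal_effects,
        f1_parents=f1_parents,
        outgroup_label=outgroup,
    )
    return panel, traits, truth


def _trait_ids(trait_types: tuple[str, ...]) -> list[str]:
    return [f"{t}{i + 1:02d}" for i, t in enumerate(trait_types)]


def _grade_by_quantile(score: np.ndarray, grades: tuple[int, ...]) -> np.ndarray:
    """Threshold a continuous score into equal-quantile grade levels."""
    qs = np.quantile(score, np.linspace(0, 1, len(grades) + 1)[1:-1])
    return np.asarray(grades, dtype=float)[np.searchsorted(qs, score, side="left")]


def simulate_annotation(
    n_chromosomes: int = 8,
    chrom_length_bp: int = 50_000_000,
    genes_per_chrom: int = 800,
    seed: int = 0,
) -> list[tuple[str, int, int, str]]:
    """Synthetic gene-model intervals for annotation-aware selection.

    Each gene body alternates CDS (synonymous / non-synonymous halves) and
    intron segments and carries 1 kb upstream/downstream flanks; genes are
    spaced so roughly a third of the genome is genic. Returns BED-like
    (chrom, start, end, class) tuples, 1-based inclusive.
    """
    rng = np.random.default_rng(seed)
    intervals: list[tuple[str, int, int, str]] = []
    for c in range(1, n_chromosomes + 1):
        chrom = f"C{c}"
        starts = np.sort(
            rng.choice(
                np.arange(2_000, chrom_length_bp - 30_000, 5_000),
                size=genes_per_chrom, replace=False,
            )
        )
        prev_end = 0
        for s in starts:
            if s <= prev_end + 2_000:
                continue
            length = int(rng.integers(8_000, 25_000))
            end = min(int(s) + length, chrom_length_bp - 1_000)
            intervals.append((chrom, int(s) - 1_000, int(s) - 1, "upstream"))
            # alternate exon/intron blocks through the gene body
            pos = int(s)
            exon = True
            while pos < end:
                block = min(int(rng.integers(1_000, 4_000)), end - pos)
                if exon:
                    half = block // 2
                    intervals.append((chrom, pos, pos + half, "CDS-synonymous"))
                    if pos + half + 1 <= pos + block:
                        intervals.append(
                            (chrom, pos + half + 1, pos + block, "CDS-non-synonymous")
                        )
                else:
                    intervals.append((chrom, pos, pos + block, "intron"))
                pos += block + 1
                exon = not exon
            intervals.append((chrom, end + 1, end + 1_000, "downstream"))
            prev_end = end + 1_000
    return intervals


# ---------------------------------------------------------------------------
# fixed worked example
# ---------------------------------------------------------------------------

_TOY_VARIETIES = ["T01", "T02", "T03", "T04", "T05", "T06"]

_TOY_MARKERS = pd.DataFrame(
    {
        "id": ["m1", "m2", "m3", "m4", "m5", "m6", "m7", "m8"],
        "chrom": ["C1", "C1", "C1", "C2", "C2", "C2", "C3", "C3"],
        "pos": [100, 2500, 8000, 150, 5000, 9000, 300, 7000],
        "ref": ["A", "C", "G", "T", "A", "C", "G", "T"],
        "alt": ["T", "G", "A", "C", "G", "T", "A", "A"],
    }
)

# m1 carries 3 alt alleles over 12 called alleles -> MAF 0.25
_TOY_CALLS = np.array(
    [
        # m1 m2 m3 m4 m5 m6 m7 m8
        [0, 0, 1, 0, 2, 0, 0, 1],  # T01
        [0, 1, 1, 0, 2, 0, 0, 0],  # T02
        [1, 0, 0, 1, 0, 2, 0, 0],  # T03
        [0, 2, 0, 1, 0, 2, 1, 0],  # T04
        [2, 0, 2, 2, 1, 0, 2, 2],  # T05
        [0, 0, 2, 2, 1, 0, 2, -1],  # T06
    ],
    dtype=np.int8,
)


def worked_toy_panel() -> tuple[GenotypePanel, TraitTable]:
    """A fixed 6-variety x 8-marker panel with one QN and one QL trait.

    Used across module examples and tests; all six genotype rows are
    pairwise distinct and marker ``m1`` has MAF 0.25 by direct allele count.
    """
    panel = GenotypePanel(
        variety_ids=list(_TOY_VARIETIES),
        markers=_TOY_MARKERS.copy(),
        calls=_TOY_CALLS.copy(),
    )
    values = pd.DataFrame(
        {
            "QN01": [12.1, 11.8, 17.5, 18.2, 24.9, 25.3],
            "QL02": [1.0, 1.0, 1.0, 9.0, 9.0, 9.0],
        },
        index=_TOY_VARIETIES,
    )
    traits = TraitTable(
        values=values,
        types={"QN01": "QN", "QL02": "QL"},
        grade_sets={"QN01": None, "QL02": (1, 9)},
    )
    return panel, traits
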