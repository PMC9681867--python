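"""The association funnel: per-trait marker scans, top-K pooling across
traits, positional deduplication and annotation/spacing-aware candidate
selection.

The scan regresses trait value on additively coded genotype (0/1/2) by
ordinary least squares and reports the F-test p-value, following the plain
generalised-linear-model association usage in DUS marker screening. No
multiple-testing correction is applied: downstream stages consume rank
order, not significance calls. Graded (QL/PQ) traits are regressed on their
integer grade codes by default; a one-way ANOVA mode is available for
unordered pseudo-qualitative traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GENIC_CLASSES, GenotypePanel, MISSING, TraitTable


@dataclass
class CandidateSet:
    """Ordered candidate markers with selection bookkeeping."""

    table: pd.DataFrame  # marker, chrom, pos, class, best_trait, p_value, reason
    min_spacing_bp: int  # final (possibly relaxed) spacing actually enforced
    relaxations: list[int] = field(default_factory=list)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table["marker"])


def scan_trait(
    panel: GenotypePanel,
    traits: TraitTable,
    trait_id: str,
    mode: str = "linear",
) -> pd.DataFrame:
    """Per-marker association of one trait.

    Varieties with missing genotype or phenotype are dropped pairwise.
    Markers monomorphic after dropping (or with fewer than 3 informative
    varieties) are reported with p = 1 and ``flag`` set. Returns a frame
    with columns marker, chrom, pos, trait_id, p_value, neg_log10_p,
    effect, n_used, flag.
    """
    y_full = traits.trait_vector(trait_id, panel.variety_ids)
    y_obs = y_full[~np.isnan(y_full)]
    if y_obs.size == 0 or np.all(y_obs == y_obs[0]):
        raise ValueError(f"trait {trait_id!r} is constant or empty")
    if np.unique(y_obs).size < 2:
        raise ValueError(f"trait {trait_id!r} has fewer than 2 levels")

    d = panel.dosage()
    valid = ~np.isnan(d) & ~np.isnan(y_full)[:, None]
    n = valid.sum(axis=0).astype(float)

    if mode == "linear":
        x = np.where(valid, d, 0.0)
        yv = np.where(valid, y_full[:, None], 0.0)
        sx = x.sum(axis=0)
        sy = yv.sum(axis=0)
        sxx = (x * x).sum(axis=0)
        syy = (yv * yv).sum(axis=0)
        sxy = (x * yv).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ssx = sxx - sx * sx / n
            ssy = syy - sy * sy / n
            sxy_c = sxy - sx * sy / n
            r2 = np.where(ssx * ssy > 0, sxy_c**2 / (ssx * ssy), np.nan)
            slope = np.where(ssx > 0, sxy_c / ssx, 0.0)
            df2 = n - 2
            fstat = r2 * df2 / np.maximum(1.0 - r2, 1e-300)
        usable = (n >= 3) & (ssx > 0) & (ssy > 0)
        p = np.ones(panel.n_markers)
        p[usable] = stats.f.sf(fstat[usable], 1, df2[usable])
        # numerically exact fits give r2 == 1; keep p at the floor, not NaN
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        effect = np.sign(slope)
        flag = ~usable
    elif mode == "anova":
        p = np.ones(panel.n_markers)
        effect = np.zeros(panel.n_markers)
        flag = np.zeros(panel.n_markers, dtype=bool)
        for j in range(panel.n_markers):
            mask = valid[:, j]
            groups = [
                y_full[mask & (panel.calls[:, j] == g)]
                for g in (0, 1, 2)
            ]
            groups = [g for g in groups if g.size > 0]
            if mask.sum() < 3 or len(groups) < 2:
                flag[j] = True
                continue
            fval, pval = stats.f_oneway(*groups)
            p[j] = pval if np.isfinite(pval) else 1.0
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return pd.DataFrame(
        {
            "marker": panel.markers["id"],
            "chrom": panel.markers["chrom"],
            "pos": panel.markers["pos"],
            "trait_id": trait_id,
            "p_value": p,
            "neg_log10_p": -np.log10(p),
            "effect": effect,
            "n_used": n.astype(int),
            "flag": flag,
        }
    )


def scan_all_traits(
    panel: GenotypePanel, traits: TraitTable, mode: str = "linear"
) -> dict[str, pd.DataFrame]:
    """Run :func:`scan_trait` for every trait in the table."""
    return {t: scan_trait(panel, traits, t, mode=mode) for t in traits.trait_ids}


def top_k_pool(
    results_by_trait: dict[str, pd.DataFrame],
    k: int,
    maf: pd.Series | None = None,
) -> pd.DataFrame:
    """Per trait, the k smallest p-values; pooled with cross-trait
    duplicates retained.

    Ties on p break toward the larger MAF (when supplied), then toward
    chromosome/position order. Pool size is the sum over traits of
    ``min(k, markers tested)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    parts = []
    for trait in sorted(results_by_trait):
        res = results_by_trait[trait].copy()
        if maf is not None:
            res["_maf"] = res["marker"].map(maf).fillna(0.0)
        else:
            res["_maf"] = 0.0
        res = res.sort_values(
            ["p_value", "_maf", "chrom", "pos"],
            ascending=[True, False, True, True],
            kind="mergesort",
        ).head(k)
        res["rank"] = np.arange(1, len(res) + 1)
        parts.append(res.drop(columns="_maf"))
    return pd.concat(parts, ignore_index=True)


def dedup_positions(pool: pd.DataFrame) -> pd.DataFrame:
    """One entry per (chrom, pos), keeping the smallest-p trait for each;
    output sorted by chromosome then position. Idempotent."""
    if pool.empty:
        return pool.copy()
    best = (
        pool.sort_values(["p_value", "trait_id"], kind="mergesort")
        .drop_duplicates(subset=["chrom", "pos"], keep="first")
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return best.rename(columns={"trait_id": "best_trait"})


_CLASS_TIER = {
    "CDS-non-synonymous": 0,
    "CDS-synonymous": 0,
    "splice": 1,
    "intron": 1,
    "up/downstream": 2,
    "upstream": 2,
    "downstream": 2,
    "intergenic": 2,
}


def select_candidates(
    unique: pd.DataFrame,
    classes: dict[str, str],
    n_target: int,
    min_spacing_bp: int = 0,
) -> CandidateSet:
    """Greedy annotation- and spacing-aware candidate pick.

    Markers are ranked by genic-class priority (CDS > other genic >
    intergenic group) then by association strength, and accepted subject to
    a minimum physical spacing from already-picked markers on the same
    chromosome. If the target is unreachable the spacing is halved
    (repeatedly, logged) until it is.
    """
    if n_target > len(unique):
        raise ValueError(f"n_target {n_target} exceeds list size {len(unique)}")
    df = unique.copy()
    df["class"] = df["marker"].map(classes).fillna("intergenic")
    df["_tier"] = df["class"].map(_CLASS_TIER)
    df = df.sort_values(
        ["_tier", "p_value", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)

    spacing = int(min_spacing_bp)
    relaxations: list[int] = []
    while True:
        picked_idx: list[int] = []
        picked_pos: dict[str, list[int]] = {}
        for i, row in df.iterrows():
            if len(picked_idx) == n_target:
                break
            chrom, pos = str(row["chrom"]), int(row["pos"])
            near = picked_pos.get(chrom, ())
            if spacing > 0 and any(abs(pos - q) < spacing for q in near):
                continue
            picked_idx.append(i)
            picked_pos.setdefault(chrom, []).append(pos)
        if len(picked_idx) == n_target or spacing == 0:
            break
        spacing //= 2
        relaxations.append(spacing)

    out = df.loc[picked_idx].drop(columns="_tier").reset_index(drop=True)
    out["reason"] = np.where(
        out["class"].isin(sorted(GENIC_CLASSES)), "annotation", "spacing"
    )
    return CandidateSet(table=out, min_spacing_bp=spacing, relaxations=relaxations)
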