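"""Trait determination across genotype clusters: one-way ANOVA, Duncan's
new multiple range test (DMRT) with compact letter display, and the
"trait explained by g cluster groups" summary.

DMRT compares the p ordered means spanning a gap with the critical range

    R_p = q(1 - (1 - alpha)^(p-1); p, df_error) * sqrt(MSE / n_h)

where q is the studentized-range quantile at Duncan's protection level and
n_h the harmonic mean of the span's group sizes (unbalanced clusters).
Two means differ when their gap exceeds R_p; a non-significant wider span
protects all inner pairs. Letters come from the standard insert-and-absorb
algorithm scanning from the largest mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .panel import TraitTable


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    mse: float
    df_between: int
    df_error: int
    group_stats: pd.DataFrame  # cluster, n, mean
    dropped_clusters: list = field(default_factory=list)


@dataclass
class DmrtResult:
    trait_id: str
    alpha: float
    anova: AnovaResult
    letters: dict  # cluster -> letter string, e.g. "a", "ab"

    @property
    def p_value(self) -> float:
        return self.anova.p_value


@dataclass
class TraitExplanation:
    trait_id: str
    marker_set: str | None
    explained: bool
    n_groups: int | None      # number of distinct letter blocks, or None
    grouping: str             # e.g. "1,2 / 3,99"
    overlap: bool             # some cluster carries several letters
    unclear_clusters: list
    p_value: float


def anova_by_cluster(values: Sequence[float], labels: Sequence[int]) -> AnovaResult:
    """One-way fixed-effects ANOVA of a trait across cluster labels.

    Unbalanced groups are supported; clusters with no phenotyped member
    are dropped; identical values everywhere give F = 0, p = 1.
    """
    y = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    keep = ~np.isnan(y)
    y, lab = y[keep], lab[keep]
    uniq = [u for u in pd.unique(lab)]
    groups = {u: y[lab == u] for u in uniq}
    dropped = [u for u, g in groups.items() if g.size == 0]
    groups = {u: g for u, g in groups.items() if g.size > 0}
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 clusters with phenotyped members")
    n_tot = sum(g.size for g in groups.values())
    if not any(g.size >= 2 for g in groups.values()):
        raise ValueError("need at least one cluster with >= 2 values")
    grand = y.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups.values())
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    dfb, dfe = k - 1, n_tot - k
    if ssw <= 0 and ssb <= 0:
        f, p, mse = 0.0, 1.0, 0.0
    elif ssw <= 0:
        f, p, mse = np.inf, 0.0, 0.0
    else:
        mse = ssw / dfe
        f = (ssb / dfb) / mse
        from scipy.stats import f as fdist

        p = float(fdist.sf(f, dfb, dfe))
    stats = pd.DataFrame(
        {
            "cluster": list(groups),
            "n": [g.size for g in groups.values()],
            "mean": [g.mean() for g in groups.values()],
        }
    )
    return AnovaResult(
        f_statistic=float(f),
        p_value=float(p),
        mse=float(mse),
        df_between=dfb,
        df_error=dfe,
        group_stats=stats,
        dropped_clusters=dropped,
    )


@lru_cache(maxsize=4096)
def _q_upper(protection: float, span: int, df_error: int) -> float:
    """Upper-tail studentized-range quantile (cached: its numeric inversion
    is expensive and spans/df repeat heavily across traits)."""
    return float(studentized_range.isf(protection, span, df_error))


def duncan_critical_range(
    span: int, df_error: int, mse: float, n_harmonic: float, alpha: float = 0.05
) -> float:
    """Duncan's least significant range for a span of ``span`` ordered means."""
    protection = 1.0 - (1.0 - alpha) ** (span - 1)
    q = _q_upper(round(protection, 12), span, df_error)
    return float(q * np.sqrt(mse / n_harmonic))


def duncan_mrt(
    values: Sequence[float],
    labels: Sequence[int],
    alpha: float = 0.05,
    trait_id: str = "",
) -> DmrtResult:
    """Duncan's new multiple range test with letter groups."""
    anova = anova_by_cluster(values, labels)
    stats = anova.group_stats.sort_values(
        "mean", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    g = len(stats)
    if g < 2:
        raise ValueError("DMRT needs at least 2 clusters")
    means = stats["mean"].to_numpy()
    ns = stats["n"].to_numpy()

    # pairwise significance with Duncan protection: a non-significant wider
    # span forces all inner pairs non-significant
    sig = np.zeros((g, g), dtype=bool)
    if anova.mse > 0:
        for i in range(g):
            for j in range(i + 1, g):
                span = j - i + 1
                n_h = span / np.sum(1.0 / ns[i: j + 1])
                r_p = duncan_critical_range(span, anova.df_error, anova.mse, n_h, alpha)
                sig[i, j] = sig[j, i] = (means[i] - means[j]) > r_p
        for width in range(g - 1, 1, -1):
            for i in range(g - width):
                j = i + width
                if not sig[i, j]:
                    sig[i: j + 1, i: j + 1] = False
    else:
        # zero error variance: any mean difference is significant
        for i in range(g):
            for j in range(i + 1, g):
                sig[i, j] = sig[j, i] = means[i] > means[j]

    # insert-and-absorb compact letter display on the sorted means
    intervals: list[tuple[int, int]] = []
    for i in range(g):
        j = i
        while j + 1 < g and not sig[i, j + 1]:
            j += 1
        intervals.append((i, j))
    # drop intervals contained in another
    kept = [
        (a, b)
        for a, b in dict.fromkeys(intervals)
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in intervals)
    ]
    kept.sort()
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    cluster_order = list(stats["cluster"])
    letter_map: dict = {c: "" for c in cluster_order}
    for li, (a, b) in enumerate(kept):
        for i in range(a, b + 1):
            letter_map[cluster_order[i]] += alphabet[li % len(alphabet)]
    return DmrtResult(
        trait_id=trait_id, alpha=alpha, anova=anova, letters=letter_map
    )


def dmrt_report(results: Sequence[DmrtResult]) -> pd.DataFrame:
    """Flat per-(trait, cluster) report table."""
    rows = []
    for res in results:
        for _, r in res.anova.group_stats.iterrows():
            rows.append(
                (
                    res.trait_id,
                    r["cluster"],
                    int(r["n"]),
                    r["mean"],
                    res.letters[r["cluster"]],
                    res.p_value,
                )
            )
    return pd.DataFrame(
        rows, columns=["trait", "cluster", "n", "mean", "letters", "p_value"]
    )


def explain_trait(res: DmrtResult, marker_set: str | None = None) -> TraitExplanation:
    """Read a DMRT letter display into an "explained by g groups" verdict.

    A trait is unexplained when the global ANOVA p >= alpha or every
    cluster shares a single letter. Otherwise the distinct letters define
    the cluster groups; clusters carrying several letters (e.g. "ab"
    between "a" and "b") set the overlap flag and are listed as unclear.
    """
    letters = res.letters
    distinct = sorted(set("".join(letters.values())))
    all_one = len(distinct) <= 1
    if res.p_value >= res.alpha or all_one:
        return TraitExplanation(
            trait_id=res.trait_id,
            marker_set=marker_set,
            explained=False,
            n_groups=None,
            grouping="",
            overlap=False,
            unclear_clusters=[],
            p_value=res.p_value,
        )
    unclear = sorted((c for c, l in letters.items() if len(l) > 1), key=str)
    blocks = []
    for letter in distinct:
        members = sorted(
            (c for c, l in letters.items() if l == letter), key=str
        )
        if members:
            blocks.append(members)
    grouping = " / ".join(",".join(str(c) for c in blk) for blk in blocks if blk)
    return TraitExplanation(
        trait_id=res.trait_id,
        marker_set=marker_set,
        explained=True,
        n_groups=len(distinct),
        grouping=grouping,
        overlap=bool(unclear),
        unclear_clusters=unclear,
        p_value=res.p_value,
    )


def explain_traits(
    dmrt_by_set: Mapping[str, Mapping[str, DmrtResult]]
) -> list[TraitExplanation]:
    """Best-marker-set explanation per trait (smallest global p wins)."""
    traits: set[str] = set()
    for per_trait in dmrt_by_set.values():
        traits.update(per_trait)
    out = []
    for trait in sorted(traits):
        candidates = [
            (per_trait[trait].p_value, set_name, per_trait[trait])
            for set_name, per_trait in dmrt_by_set.items()
            if trait in per_trait
        ]
        candidates.sort(key=lambda t: (t[0], t[1]))
        p, set_name, res = candidates[0]
        out.append(explain_trait(res, marker_set=set_name))
    return out


def correlate_traits(traits: TraitTable) -> pd.DataFrame:
    """Pairwise Pearson correlation over varieties (pairwise-complete).

    Entries involving a constant trait are NaN (flagged undefined).
    """
    if len(traits.trait_ids) < 2:
        raise ValueError("need at least 2 traits")
    return traits.values.corr(method="pearson", min_periods=2)
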