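"""Core in-memory containers: genotype panel, trait table, annotation map.

Genotype calls are stored as a dense ``int8`` matrix (varieties x markers)
with codes ``0`` hom-ref, ``1`` het, ``2`` hom-alt and ``-1`` missing.
Coordinates are 1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

VALID_CODES = frozenset({HOM_REF, HET, HOM_ALT, MISSING})

#: Annotation classes, ordered by precedence when intervals overlap.
ANNOTATION_CLASSES = (
    "CDS-non-synonymous",
    "CDS-synonymous",
    "splice",
    "intron",
    "up/downstream",
    "upstream",
    "downstream",
    "intergenic",
)

GENIC_CLASSES = frozenset(
    {"CDS-non-synonymous", "CDS-synonymous", "splice", "intron"}
)
INTERGENIC_CLASSES = frozenset(
    {"intergenic", "upstream", "downstream", "up/downstream"}
)

MARKER_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]

TRAIT_TYPES = ("QL", "QN", "PQ")


class PanelError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class GenotypePanel:
    """Varieties x markers matrix of diploid biallelic calls.

    Parameters
    ----------
    variety_ids :
        Ordered, unique variety names.
    markers :
        DataFrame with columns ``id, chrom, pos, ref, alt``; ``pos`` is
        1-based and strictly increasing within each chromosome.
    calls :
        ``int8`` array of shape ``(n_varieties, n_markers)`` with codes
        0/1/2/-1.
    """

    variety_ids: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.variety_ids = list(self.variety_ids)
        if len(set(self.variety_ids)) != len(self.variety_ids):
            raise PanelError("variety ids must be unique")
        self.markers = self.markers.reset_index(drop=True)
        missing_cols = set(MARKER_COLUMNS) - set(self.markers.columns)
        if missing_cols:
            raise PanelError(f"marker table lacks columns {sorted(missing_cols)}")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variety_ids), len(self.markers)):
            raise PanelError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.variety_ids)} varieties x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise PanelError("calls contain codes outside {-1, 0, 1, 2}")
        key = list(zip(self.markers["chrom"], self.markers["pos"]))
        if len(set(key)) != len(key):
            raise PanelError("duplicate (chrom, pos) in marker table")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise PanelError(f"positions not sorted within chromosome {chrom}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_varieties(self) -> int:
        return len(self.variety_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers["id"])

    def variety_index(self, variety: str) -> int:
        try:
            return self.variety_ids.index(variety)
        except ValueError:
            raise KeyError(f"unknown variety {variety!r}") from None

    def marker_index(self, marker_id: str) -> int:
        ids = self.markers["id"]
        hits = ids[ids == marker_id].index
        if len(hits) == 0:
            raise KeyError(f"unknown marker {marker_id!r}")
        return int(hits[0])

    # -- views ----------------------------------------------------------
    def dosage(self) -> np.ndarray:
        """Alt-allele dosage (0/1/2) as float with NaN for missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def subset_markers(self, index: Sequence[int]) -> "GenotypePanel":
        """New panel restricted to the given marker positions (panel order kept)."""
        idx = sorted(int(i) for i in index)
        return GenotypePanel(
            variety_ids=list(self.variety_ids),
            markers=self.markers.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx].copy(),
        )

    def subset_markers_by_id(self, marker_ids: Iterable[str]) -> "GenotypePanel":
        return self.subset_markers([self.marker_index(m) for m in marker_ids])

    def subset_varieties(self, varieties: Sequence[str]) -> "GenotypePanel":
        idx = [self.variety_index(v) for v in varieties]
        return GenotypePanel(
            variety_ids=[self.variety_ids[i] for i in idx],
            markers=self.markers.copy(),
            calls=self.calls[idx, :].copy(),
        )

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            self.variety_ids == other.variety_ids
            and self.markers[MARKER_COLUMNS].equals(other.markers[MARKER_COLUMNS])
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class TraitTable:
    """Per-variety phenotypes typed QL (qualitative), QN (quantitative) or
    PQ (pseudo-qualitative), with the declared grade set for graded traits.

    ``values`` is wide: index = variety ids, one column per trait id. Grades
    are stored as their printed integer codes; QN traits are measurements.
    Missing phenotypes are NaN.
    """

    values: pd.DataFrame
    types: dict[str, str]
    grade_sets: dict[str, tuple[int, ...] | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for trait in self.values.columns:
            ttype = self.types.get(trait)
            if ttype not in TRAIT_TYPES:
                raise PanelError(f"trait {trait!r} has invalid type {ttype!r}")
            if not str(trait).startswith(ttype):
                raise PanelError(
                    f"trait id {trait!r} does not start with its type {ttype!r}"
                )
            col = self.values[trait]
            if ttype in ("QL", "PQ"):
                grades = self.grade_sets.get(trait)
                if grades:
                    ok = col.dropna().isin(grades)
                    if not ok.all():
                        raise PanelError(
                            f"trait {trait!r} has values outside grade set {grades}"
                        )
            else:
                if np.isinf(col.dropna().to_numpy(dtype=float)).any():
                    raise PanelError(f"QN trait {trait!r} has non-finite values")

    @property
    def trait_ids(self) -> list[str]:
        return list(self.values.columns)

    def trait_vector(self, trait_id: str, variety_ids: Sequence[str]) -> np.ndarray:
        """Trait values aligned to the given variety order (NaN when absent)."""
        return (
            self.values[trait_id].reindex(list(variety_ids)).to_numpy(dtype=float)
        )

    def equals(self, other: "TraitTable") -> bool:
        """Content equality; trait column order is not significant."""
        cols = sorted(self.values.columns)
        return (
            sorted(other.values.columns) == cols
            and self.values[cols].equals(other.values[cols])
            and self.types == other.types
            and {k: v for k, v in self.grade_sets.items() if v}
            == {k: v for k, v in other.grade_sets.items() if v}
        )


class AnnotationMap:
    """Genomic intervals with a functional class, 1-based inclusive.

    Overlaps resolve by the fixed precedence in :data:`ANNOTATION_CLASSES`
    (most specific / most functional first); positions covered by no
    interval are intergenic.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end, cls in intervals:
            self.add(chrom, start, end, cls)

    def add(self, chrom: str, start: int, end: int, cls: str) -> None:
        if cls not in ANNOTATION_CLASSES:
            raise PanelError(f"unknown annotation class {cls!r}")
        if end < start or start < 1:
            raise PanelError(f"bad interval [{start}, {end}] on {chrom}")
        # interval tree is half-open; store [start, end] as [start, end+1)
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, cls)

    def lookup(self, chrom: str, pos: int) -> str:
        tree = self._trees.get(chrom)
        if tree is None:
            return "intergenic"
        hits = [iv.data for iv in tree.at(pos)]
        if not hits:
            return "intergenic"
        return min(hits, key=ANNOTATION_CLASSES.index)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def genic_fraction(classes: Sequence[str]) -> float:
    """Fraction of markers whose class is genic (CDS/splice/intron)."""
    if len(classes) == 0:
        return float("nan")
    return sum(c in GENIC_CLASSES for c in classes) / len(classes)
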