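"""Readers and writers for the formats the pipeline touches.

VCFv4.2 (via cyvcf2 for reading), IUPAC-coded genotype FASTA, the wide
reference-variety database TSV (two-letter genotypes, ``NN`` missing), long
trait-table TSV, BED-like annotation TSV (1-based inclusive) and a JSON
truth file for simulated panels.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import (
    ANNOTATION_CLASSES,
    GenotypePanel,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AnnotationMap,
    PanelError,
    TraitTable,
)
from .simulate import TruthRecord

log = logging.getLogger(__name__)

IUPAC_AMBIGUITY = {
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
}

_DB_META_COLS = ["marker", "chrom", "pos", "ref", "alt"]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypePanel:
    """Load biallelic SNP records from a VCFv4.2 file.

    Multiallelic and indel records are skipped (count logged); phased and
    unphased genotypes are treated identically. Duplicate (chrom, pos)
    records are a hard error.
    """
    vcf = VCF(str(path), gts012=True)
    variety_ids = list(vcf.samples)
    if not variety_ids:
        raise PanelError(f"{path}: VCF has no samples / no GT field")
    rows = []
    calls_cols = []
    skipped = 0
    seen: set[tuple[str, int]] = set()
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        key = (var.CHROM, var.POS)
        if key in seen:
            raise PanelError(f"duplicate site {var.CHROM}:{var.POS}")
        seen.add(key)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        rows.append((vid, var.CHROM, var.POS, var.REF, var.ALT[0]))
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        calls_cols.append(gt)
    if skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    markers = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    calls = (
        np.column_stack(calls_cols)
        if calls_cols
        else np.empty((len(variety_ids), 0), dtype=np.int8)
    )
    panel = GenotypePanel(variety_ids=variety_ids, markers=markers, calls=calls)
    panel.n_skipped_records = skipped  # type: ignore[attr-defined]
    return panel


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as a minimal VCFv4.2 with diploid GT calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(panel.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.variety_ids)
            + "\n"
        )
        for j, row in panel.markers.iterrows():
            gts = "\t".join(_GT_STR[int(c)] for c in panel.calls[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# IUPAC genotype strings / FASTA
# ---------------------------------------------------------------------------

def encode_iupac(panel: GenotypePanel, variety: str) -> str:
    """One character per marker: allele letter for homozygotes, IUPAC
    ambiguity code for heterozygotes, ``N`` for missing."""
    i = panel.variety_index(variety)
    ref = panel.markers["ref"].to_numpy()
    alt = panel.markers["alt"].to_numpy()
    out = []
    for j, call in enumerate(panel.calls[i]):
        if call == MISSING:
            out.append("N")
        elif call == HOM_REF:
            out.append(str(ref[j]))
        elif call == HOM_ALT:
            out.append(str(alt[j]))
        else:
            pair = frozenset((str(ref[j]), str(alt[j])))
            try:
                out.append(IUPAC_AMBIGUITY[pair])
            except KeyError:
                raise PanelError(
                    f"no IUPAC code for allele pair {sorted(pair)} at marker "
                    f"{panel.markers['id'][j]}"
                ) from None
    return "".join(out)


def write_iupac_fasta(panel: GenotypePanel, path: str | Path) -> None:
    """One FASTA record per variety, sequence = concatenated IUPAC calls."""
    with open(path, "w") as fh:
        for v in panel.variety_ids:
            fh.write(f">{v}\n{encode_iupac(panel, v)}\n")


# ---------------------------------------------------------------------------
# reference-variety database (wide TSV, two-letter genotypes)
# ---------------------------------------------------------------------------

def write_reference_db(panel: GenotypePanel, path: str | Path) -> None:
    """Wide TSV: marker metadata columns then one genotype column per
    variety, genotypes as two-letter codes (missing = ``NN``)."""
    ref = panel.markers["ref"].to_numpy()
    alt = panel.markers["alt"].to_numpy()
    data = {
        "marker": panel.markers["id"],
        "chrom": panel.markers["chrom"],
        "pos": panel.markers["pos"],
        "ref": ref,
        "alt": alt,
    }
    for i, v in enumerate(panel.variety_ids):
        col = []
        for j, call in enumerate(panel.calls[:, :][i]):
            if call == MISSING:
                col.append("NN")
            elif call == HOM_REF:
                col.append(ref[j] + ref[j])
            elif call == HOM_ALT:
                col.append(alt[j] + alt[j])
            else:
                col.append(ref[j] + alt[j])
        data[v] = col
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_reference_db(path: str | Path) -> GenotypePanel:
    """Inverse of :func:`write_reference_db` (round-trip identity)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[: len(_DB_META_COLS)]) != _DB_META_COLS:
        raise PanelError(
            f"{path}: malformed header, expected leading columns {_DB_META_COLS}"
        )
    variety_ids = list(df.columns[len(_DB_META_COLS):])
    markers = pd.DataFrame(
        {
            "id": df["marker"],
            "chrom": df["chrom"],
            "pos": df["pos"].astype(int) if len(df) else df["pos"],
            "ref": df["ref"],
            "alt": df["alt"],
        }
    )
    n, m = len(variety_ids), len(df)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    ref = df["ref"].to_numpy() if m else np.array([])
    alt = df["alt"].to_numpy() if m else np.array([])
    for i, v in enumerate(variety_ids):
        col = df[v].to_numpy()
        for j in range(m):
            g = col[j]
            if g == "NN":
                calls[i, j] = MISSING
            elif g == ref[j] + ref[j]:
                calls[i, j] = HOM_REF
            elif g == alt[j] + alt[j]:
                calls[i, j] = HOM_ALT
            elif g in (ref[j] + alt[j], alt[j] + ref[j]):
                calls[i, j] = HET
            else:
                raise PanelError(
                    f"{path}: genotype {g!r} at marker {df['marker'][j]} does "
                    f"not match alleles {ref[j]}/{alt[j]}"
                )
    return GenotypePanel(variety_ids=variety_ids, markers=markers, calls=calls)


# ---------------------------------------------------------------------------
# trait table (long TSV)
# ---------------------------------------------------------------------------

def write_trait_table(traits: TraitTable, path: str | Path) -> None:
    """Long TSV: variety_id, trait_id, type, value."""
    rows = []
    for trait in traits.trait_ids:
        for variety, value in traits.values[trait].items():
            if pd.isna(value):
                continue
            rows.append((variety, trait, traits.types[trait], value))
    pd.DataFrame(
        rows, columns=["variety_id", "trait_id", "type", "value"]
    ).to_csv(path, sep="\t", index=False)


def read_trait_table(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", dtype={"variety_id": str, "trait_id": str})
    wide = df.pivot(index="variety_id", columns="trait_id", values="value")
    wide = wide.rename_axis(index=None, columns=None)
    types = dict(df.drop_duplicates("trait_id")[["trait_id", "type"]].values)
    grade_sets: dict[str, tuple[int, ...] | None] = {}
    for trait, ttype in types.items():
        if ttype in ("QL", "PQ"):
            grade_sets[trait] = tuple(
                sorted(int(v) for v in df.loc[df["trait_id"] == trait, "value"].unique())
            )
        else:
            grade_sets[trait] = None
    return TraitTable(values=wide, types=types, grade_sets=grade_sets)


# ---------------------------------------------------------------------------
# annotation (BED-like TSV, 1-based inclusive) and per-marker classes
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> AnnotationMap:
    """BED-like TSV with columns chrom, start, end, class (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "class": str})
    return AnnotationMap(
        (r["chrom"], int(r["start"]), int(r["end"]), r["class"])
        for _, r in df.iterrows()
    )


def write_annotation(intervals, path: str | Path) -> None:
    pd.DataFrame(
        list(intervals), columns=["chrom", "start", "end", "class"]
    ).to_csv(path, sep="\t", index=False)


def annotate_markers(panel: GenotypePanel, ann: AnnotationMap) -> list[str]:
    """Exactly one class per marker; positions in no interval are intergenic;
    overlapping classes resolve by the fixed precedence order."""
    return [
        ann.lookup(str(row["chrom"]), int(row["pos"]))
        for _, row in panel.markers.iterrows()
    ]


# ---------------------------------------------------------------------------
# simulation truth JSON
# ---------------------------------------------------------------------------

def write_truth(truth: TruthRecord, path: str | Path) -> None:
    payload = {
        "cluster_labels": truth.cluster_labels,
        "causal_markers": truth.causal_markers,
        "causal_effects": truth.causal_effects,
        "f1_parents": {
            v: [a.tolist(), b.tolist()] for v, (a, b) in truth.f1_parents.items()
        },
        "outgroup_label": truth.outgroup_label,
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path: str | Path) -> TruthRecord:
    payload = json.loads(Path(path).read_text())
    return TruthRecord(
        cluster_labels={k: int(v) for k, v in payload["cluster_labels"].items()},
        causal_markers=payload["causal_markers"],
        causal_effects=payload["causal_effects"],
        f1_parents={
            v: (np.asarray(a, dtype=np.int8), np.asarray(b, dtype=np.int8))
            for v, (a, b) in payload["f1_parents"].items()
        },
        outgroup_label=payload.get("outgroup_label"),
    )
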