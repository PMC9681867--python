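"""End-to-end orchestration: filter -> associate -> candidates -> core sets
-> trees/clusters -> DUS evaluation -> reference DB, with a run manifest.

One global seed fans out to per-stage seeds by stable hashing of the stage
name, so stages are reproducible independently of each other. Every output
file is declared in the manifest; rerunning the same config and seed in a
clean directory reproduces the manifest counts exactly.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .association import dedup_positions, scan_all_traits, select_candidates, top_k_pool
from .coreset import build_discrimination, nested_sets, verify_identification
from .diversity import (
    bootstrap_support,
    cluster_varieties,
    genotype_distance,
    neighbor_joining,
    upgma,
)
from .dus import dmrt_report, duncan_mrt, explain_trait, explain_traits
from .markerstats import filter_markers, marker_metrics
from .panel import AnnotationMap, GENIC_CLASSES, GenotypePanel, TraitTable

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and knobs of the full funnel (defaults follow the usual
    GBS screening cascade: MAF > 0.05, missing < 30% for association,
    < 10% for structure, top-200 ranking, nested core sizes 87/24/10)."""

    maf_min: float = 0.05
    missing_assoc: float = 0.30
    missing_struct: float = 0.10
    top_k: int = 200
    n_candidates: int | None = None
    min_spacing_bp: int = 100_000
    core_sizes: tuple[int, ...] = (87, 24, 10)
    k_clusters: int = 7
    alpha: float = 0.05
    bootstrap: int = 1000
    seed: int = 0
    exclusions: tuple[str, ...] = ()
    outdir: str = "coresnp_run"

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 1 and 0 <= self.missing_assoc <= 1
                and 0 <= self.missing_struct <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
        if list(self.core_sizes) != sorted(set(self.core_sizes), reverse=True):
            raise ValueError("core_sizes must be strictly descending")
        if self.top_k < 1 or self.bootstrap < 0:
            raise ValueError("top_k must be >= 1 and bootstrap >= 0")


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed from the global seed by stable hashing (< 2**31)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def run_pipeline(
    config: RunConfig,
    panel: GenotypePanel,
    traits: TraitTable,
    annotation: AnnotationMap | None = None,
) -> dict:
    """Execute the funnel and write every intermediate artifact.

    Returns the manifest (also written as ``manifest.json``): per-stage
    counts, output paths, seeds and the identification verdicts.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "counts": {},
        "outputs": {},
        "warnings": [],
    }

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path)

    if config.exclusions:
        keep = [v for v in panel.variety_ids if v not in set(config.exclusions)]
        panel = panel.subset_varieties(keep)
    manifest["counts"]["varieties"] = panel.n_varieties
    manifest["counts"]["input_markers"] = panel.n_markers

    # --- stage: filters ------------------------------------------------
    assoc_panel, flog = filter_markers(panel, config.maf_min, config.missing_assoc)
    struct_panel, _ = filter_markers(panel, config.maf_min, config.missing_struct)
    manifest["counts"]["markers_association"] = assoc_panel.n_markers
    manifest["counts"]["markers_structure"] = struct_panel.n_markers
    log.info("filter: %d -> %d (assoc), %d (struct)",
             panel.n_markers, assoc_panel.n_markers, struct_panel.n_markers)
    p = out / "filtered_markers.tsv"
    flog.to_csv(p, sep="\t", index=False)
    emit("filter_log", p)

    # --- stage: association -------------------------------------------
    results = scan_all_traits(assoc_panel, traits)
    assoc = pd.concat(results.values(), ignore_index=True)
    p = out / "association.tsv"
    assoc.to_csv(p, sep="\t", index=False)
    emit("association", p)

    metrics = marker_metrics(assoc_panel).set_index("marker")
    pool = top_k_pool(results, config.top_k, maf=metrics["maf"])
    unique = dedup_positions(pool)
    manifest["counts"]["top_k_pool"] = len(pool)
    manifest["counts"]["unique_positions"] = len(unique)

    # --- stage: candidates ---------------------------------------------
    classes_list = (
        gio.annotate_markers(assoc_panel, annotation)
        if annotation is not None
        else ["intergenic"] * assoc_panel.n_markers
    )
    classes = dict(zip(assoc_panel.marker_ids, classes_list))
    n_cand = config.n_candidates or min(len(unique), 348)
    n_cand = min(n_cand, len(unique))
    cand = select_candidates(unique, classes, n_cand, config.min_spacing_bp)
    manifest["counts"]["candidates"] = len(cand.table)
    manifest["counts"]["candidate_genic"] = int(
        cand.table["class"].isin(sorted(GENIC_CLASSES)).sum()
    )
    if cand.relaxations:
        manifest["warnings"].append(
            f"candidate spacing relaxed to {cand.min_spacing_bp} bp"
        )
    p = out / "candidates.tsv"
    cand.table.to_csv(p, sep="\t", index=False)
    emit("candidates", p)

    # --- stage: core sets ----------------------------------------------
    cand_panel = panel.subset_markers_by_id(cand.marker_ids)
    dm = build_discrimination(cand_panel)
    cand_metrics = marker_metrics(cand_panel)
    weights = cand_metrics["pic"].to_numpy()
    struct_hint = cluster_varieties(
        struct_panel if struct_panel.n_markers else panel,
        config.k_clusters,
        seed=stage_seed(config.seed, "structure_hint"),
    ).labels
    best_trait = dict(zip(cand.table["marker"], cand.table["best_trait"]))
    sizes = [s for s in config.core_sizes if s <= cand_panel.n_markers]
    if not sizes:
        sizes = [cand_panel.n_markers]
    cores = nested_sets(
        cand_panel, dm, sizes,
        structure_hint=struct_hint, best_trait=best_trait, weights=weights,
    )
    core_reports = {}
    for size, core in zip(sizes, cores):
        name = f"F{size}"
        report = verify_identification(cand_panel, core.marker_ids)
        core_reports[name] = report
        if core.unresolved:
            manifest["warnings"].append(
                f"{name}: {len(core.unresolved)} unresolved variety pairs"
            )
        rows = cand_metrics[cand_metrics["marker"].isin(core.marker_ids)].copy()
        rows["core_rank"] = rows["marker"].map(
            {m: r for r, m in enumerate(core.marker_ids, 1)}
        )
        p = out / f"core_{name}.tsv"
        rows.sort_values("core_rank").to_csv(p, sep="\t", index=False)
        emit(f"core_{name}", p)
        cert_path = out / f"core_{name}_certificate.json"
        cert_path.write_text(json.dumps(
            {
                "pairs": {f"{a}|{b}": m for (a, b), m in core.certificate.items()},
                "unresolved": [f"{a}|{b}" for a, b in core.unresolved],
            }
        ))
        emit(f"core_{name}_certificate", cert_path)
        manifest["counts"][f"core_{name}"] = core.size
        manifest["counts"][f"core_{name}_distinct"] = report.n_distinct
    largest = cores[0]

    # --- stage: trees ---------------------------------------------------
    core_panel = cand_panel.subset_markers_by_id(largest.marker_ids)
    dmat = genotype_distance(core_panel)
    tree_u, ustats = upgma(dmat)
    p = out / "upgma.nwk"
    p.write_text(tree_u.newick())
    emit("upgma_tree", p)
    manifest["counts"]["upgma_sum_branch_length"] = ustats["sum_branch_length"]
    if core_panel.n_varieties >= 3 and config.bootstrap > 0:
        nj = bootstrap_support(
            core_panel, neighbor_joining, n_reps=config.bootstrap,
            seed=stage_seed(config.seed, "bootstrap"),
        )
        p = out / "nj.nwk"
        p.write_text(nj.newick(with_support=True))
        emit("nj_tree", p)

    # --- stage: clustering + DUS ----------------------------------------
    dmrt_by_set: dict[str, dict] = {}
    for size, core in zip(sizes, cores):
        name = f"F{size}"
        sub = cand_panel.subset_markers_by_id(core.marker_ids)
        model = cluster_varieties(
            sub, config.k_clusters, seed=stage_seed(config.seed, f"cluster_{name}")
        )
        per_trait = {}
        for trait in traits.trait_ids:
            y = traits.trait_vector(trait, sub.variety_ids)
            try:
                per_trait[trait] = duncan_mrt(
                    y, model.labels, alpha=config.alpha, trait_id=trait
                )
            except ValueError as exc:
                manifest["warnings"].append(f"{name}/{trait}: {exc}")
        dmrt_by_set[name] = per_trait
        p = out / f"dmrt_{name}.tsv"
        dmrt_report(list(per_trait.values())).to_csv(p, sep="\t", index=False)
        emit(f"dmrt_{name}", p)

    explanations = explain_traits(dmrt_by_set)
    p = out / "trait_explanations.tsv"
    pd.DataFrame(
        [
            (e.trait_id, e.marker_set, e.p_value, e.explained, e.n_groups,
             e.grouping, e.overlap)
            for e in explanations
        ],
        columns=["trait", "marker_set", "p_value", "explained", "n_groups",
                 "group", "overlap"],
    ).to_csv(p, sep="\t", index=False)
    emit("trait_explanations", p)
    manifest["counts"]["traits_explained"] = sum(e.explained for e in explanations)
    manifest["counts"]["traits_total"] = len(explanations)

    # --- stage: reference DB --------------------------------------------
    p = out / "reference_db.tsv"
    gio.write_reference_db(core_panel, p)
    emit("reference_db", p)
    manifest["counts"]["reference_db_cells"] = (
        core_panel.n_varieties * core_panel.n_markers
    )
    p = out / "reference_db.fasta"
    gio.write_iupac_fasta(core_panel, p)
    emit("reference_fasta", p)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    emit("manifest", manifest_path)
    return manifest


def summarize_cascade(manifest: dict) -> str:
    """Render the stage-count cascade with one-decimal percentages.

    Any ``*_genic`` count is shown as genic / intergenic percentages of
    its stage total; genic% + intergenic% always prints to 100.0 +- 0.1.
    """
    counts = manifest["counts"]
    lines = ["stage\tcount"]
    for key in (
        "varieties", "input_markers", "markers_association",
        "markers_structure", "top_k_pool", "unique_positions", "candidates",
    ):
        if key in counts:
            lines.append(f"{key}\t{counts[key]}")
    for key in counts:
        if key.startswith("core_F") and not key.endswith("_distinct"):
            lines.append(f"{key}\t{counts[key]}")
    if "candidate_genic" in counts and counts.get("candidates"):
        tot = counts["candidates"]
        genic = counts["candidate_genic"]
        lines.append(f"candidate_genic_pct\t{percentage(genic, tot)}%")
        lines.append(f"candidate_intergenic_pct\t{percentage(tot - genic, tot)}%")
    if "mean_reads_per_sample" in counts:
        lines.append(f"mean_reads_per_sample\t{counts['mean_reads_per_sample']}")
    return "\n".join(lines)


def percentage(part: int | float, total: int | float) -> float:
    """One-decimal percentage as printed in screening cascade tables."""
    if total == 0:
        return 0.0
    return round(100.0 * part / total, 1)


def mean_per_sample(total: int, n_samples: int) -> int:
    """Whole-number mean of a cascade total over samples (e.g. reads per
    variety in a sequencing summary)."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return round(total / n_samples)
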