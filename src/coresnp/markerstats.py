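"""Per-marker summary metrics and the threshold filter cascade.

MAF and call rate are computed over called genotypes only; PIC uses
Botstein's biallelic closed form ``1 - (p^2 + q^2) - 2 p^2 q^2``, which for
a biallelic locus is bounded by 0.375 (attained at MAF 0.5). Filters use
strict inequalities: a marker is kept when ``maf > maf_min`` and
``missing_rate < missing_max``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import GenotypePanel, HET, HOM_ALT, HOM_REF, MISSING


def compute_maf(calls: np.ndarray) -> float:
    """Minor allele frequency over called diploid genotypes.

    Heterozygotes contribute one copy of each allele. Raises on an
    all-missing marker.
    """
    calls = np.asarray(calls)
    called = calls[calls != MISSING]
    if called.size == 0:
        raise ValueError("all genotypes missing; MAF undefined")
    alt = int(np.sum(called))  # codes 0/1/2 are alt-allele dosages
    p_alt = alt / (2 * called.size)
    return min(p_alt, 1.0 - p_alt)


def compute_pic(maf: float) -> float:
    """Polymorphism information content for a biallelic locus."""
    if not (0.0 <= maf <= 0.5):
        raise ValueError(f"maf {maf} outside [0, 0.5]")
    p, q = 1.0 - maf, maf
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def marker_metrics(panel: GenotypePanel) -> pd.DataFrame:
    """Per-marker MAF, call rate, missing rate, PIC and called count."""
    calls = panel.calls
    n = panel.n_varieties
    called = calls != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_called > 0, alt / np.maximum(2 * n_called, 1), np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    maf = np.where(n_called > 0, maf, np.nan)
    p = 1.0 - maf
    pic = 1.0 - (p**2 + maf**2) - 2.0 * p**2 * maf**2
    call_rate = n_called / n
    return pd.DataFrame(
        {
            "marker": panel.markers["id"],
            "chrom": panel.markers["chrom"],
            "pos": panel.markers["pos"],
            "maf": maf,
            "call_rate": call_rate,
            "missing_rate": 1.0 - call_rate,
            "pic": pic,
            "n_called": n_called,
        }
    )


def filter_markers(
    panel: GenotypePanel, maf_min: float = 0.05, missing_max: float = 0.30
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Keep markers with ``maf > maf_min`` and ``missing_rate < missing_max``
    (both strict); order preserved. Returns the filtered panel and a
    per-marker keep/drop log."""
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= missing_max <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    metrics = marker_metrics(panel)
    maf_ok = metrics["maf"].to_numpy() > maf_min
    miss_ok = metrics["missing_rate"].to_numpy() < missing_max
    keep = np.nan_to_num(maf_ok) & miss_ok
    log = metrics.assign(kept=keep)
    kept_panel = panel.subset_markers(np.flatnonzero(keep))
    return kept_panel, log
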