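"""Cell-level quality-control filters for multiome and scRNA data.

Cells are removed when ANY rule fires (disjunctive filtering). The multiome
rules remove cells with extreme ATAC depth in either direction, very high
RNA depth, poor nucleosome signal (mononucleosomal/nucleosome-free ratio),
low TSS enrichment, or high mitochondrial fraction; the scRNA rules remove
cells with too few detected genes or high mitochondrial fraction. All
metrics are taken as input columns — the package does not compute TSS
enrichment or fragment-size ratios from reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class CellQCThresholds:
    """Removal thresholds. Each rule states the condition under which a cell is REMOVED."""

    atac_max: float = 100_000   # atac_reads >= atac_max
    atac_min: float = 1_000     # atac_reads <= atac_min
    rna_max: float = 50_000     # rna_reads >= rna_max
    mono_nfr_ratio_max: float = 2.0  # mono_nfr_ratio >= this
    tss_min: float = 1.0        # tss_enrichment <= tss_min
    mito_frac_max: float = 0.25  # mito_frac >= this (multiome)
    min_genes: int = 200        # n_genes < min_genes (scRNA)
    mito_frac_max_scrna: float = 0.15  # mito_frac > this (scRNA)


MULTIOME_METRICS = ["atac_reads", "rna_reads", "mono_nfr_ratio",
                    "tss_enrichment", "mito_frac"]
SCRNA_METRICS = ["n_genes", "mito_frac"]


def qc_filter_cells(metrics: pd.DataFrame,
                    thresholds: CellQCThresholds | None = None,
                    mode: str = "multiome"):
    """Apply disjunctive cell-removal rules.

    Parameters
    ----------
    metrics
        Per-cell metric table indexed by cell barcode.
    mode
        ``"multiome"`` or ``"scrna"``; selects which rule set applies.

    Returns
    -------
    retained : pandas.Index
        Barcodes of cells passing every rule, in input order.
    removal_counts : dict[str, int]
        Number of cells violating each rule (a cell may violate several),
        plus ``"total_removed"``.
    """
    t = thresholds or CellQCThresholds()
    if mode == "multiome":
        required = MULTIOME_METRICS
    elif mode == "scrna":
        required = SCRNA_METRICS
    else:
        raise ValueError(f"unknown QC mode {mode!r}")
    missing = [c for c in required if c not in metrics.columns]
    if missing:
        raise ValueError(f"missing QC metric column(s): {missing}")

    if mode == "multiome":
        rules = {
            "atac_reads_high": metrics["atac_reads"] >= t.atac_max,
            "atac_reads_low": metrics["atac_reads"] <= t.atac_min,
            "rna_reads_high": metrics["rna_reads"] >= t.rna_max,
            "mono_nfr_ratio_high": metrics["mono_nfr_ratio"] >= t.mono_nfr_ratio_max,
            "tss_enrichment_low": metrics["tss_enrichment"] <= t.tss_min,
            "mito_frac_high": metrics["mito_frac"] >= t.mito_frac_max,
        }
    else:
        rules = {
            "n_genes_low": metrics["n_genes"] < t.min_genes,
            "mito_frac_high": metrics["mito_frac"] > t.mito_frac_max_scrna,
        }

    removed = pd.Series(False, index=metrics.index)
    counts: dict[str, int] = {}
    for rule, mask in rules.items():
        counts[rule] = int(mask.sum())
        removed |= mask
    counts["total_removed"] = int(removed.sum())
    return metrics.index[~removed], counts
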