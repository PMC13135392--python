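"""Bias-corrected per-cell motif accessibility deviations and group ranking.

Implements the deviation z-score of Schep et al.'s chromVAR method: for each
cell and motif, the observed count in motif-bearing peaks is compared with
the expectation under the cell's depth and the peaks' overall popularity;
the raw deviation is standardized against deviations of background peak
sets matched on GC content and mean accessibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DeviationResult:
    z: pd.DataFrame                      # cells x motifs
    raw: pd.DataFrame                    # cells x motifs raw deviations
    comparison: pd.DataFrame | None = None  # per-motif group test, ranked


def _match_bins(gc: np.ndarray, mean_acc: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin index per peak on a quantile grid of GC x mean accessibility."""
    def qbin(v):
        ranks = stats.rankdata(v, method="average") / len(v)
        return np.minimum((ranks * n_bins).astype(int), n_bins - 1)
    return qbin(gc) * n_bins + qbin(mean_acc)


def sample_matched_backgrounds(gc: np.ndarray, mean_acc: np.ndarray,
                               n_background: int, n_bins: int,
                               rng: np.random.Generator) -> np.ndarray:
    """(n_background x n_peaks) indices of replacement peaks from matched bins."""
    bins = _match_bins(gc, mean_acc, n_bins)
    members = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
    out = np.empty((n_background, len(gc)), dtype=int)
    for p in range(len(gc)):
        pool = members[bins[p]]
        out[:, p] = pool[rng.integers(0, len(pool), size=n_background)]
    return out


def compute_deviation_zscores(counts, annotations, gc, mean_accessibility=None,
                              n_background: int = 50, n_bins: int = 10,
                              seed: int = 0,
                              background_samples: np.ndarray | None = None,
                              cell_names=None) -> DeviationResult:
    """Per-cell, per-motif deviation z-scores against matched backgrounds.

    Parameters
    ----------
    counts
        Cells x peaks count matrix (dense array or anything np.asarray-able).
    annotations
        Peaks x motifs binary membership (DataFrame, columns = motif names).
    gc, mean_accessibility
        Per-peak covariates for background matching; mean accessibility
        defaults to the column means of ``counts``.
    background_samples
        Optional explicit (n x n_peaks) matrix of background peak indices,
        overriding random sampling (used by exhaustive-enumeration checks).

    Notes
    -----
    Expected count for cell i and motif m is ``total_i * sum_{p in m} f_p``
    with f_p the peak's fraction of all counts; raw deviation is
    (observed - expected) / expected, and z standardizes the raw deviation
    by the mean and SD of the same statistic over background peak sets.
    """
    X = np.asarray(counts, dtype=float)
    if isinstance(annotations, pd.DataFrame):
        motif_names = list(annotations.columns)
        M = annotations.to_numpy(dtype=float)
    else:
        M = np.asarray(annotations, dtype=float)
        motif_names = [f"motif_{j}" for j in range(M.shape[1])]
    if M.shape[0] != X.shape[1]:
        raise ValueError("annotation rows must equal number of peaks")
    empty = np.flatnonzero(M.sum(axis=0) == 0)
    if empty.size:
        raise ValueError(
            f"motif(s) with zero member peaks: {[motif_names[j] for j in empty]}")
    gc = np.asarray(gc, dtype=float)
    mean_acc = (X.mean(axis=0) if mean_accessibility is None
                else np.asarray(mean_accessibility, dtype=float))

    totals = X.sum(axis=1)                      # per-cell depth
    f = X.sum(axis=0) / X.sum()                 # per-peak fraction of all counts
    observed = X @ M
    expected = np.outer(totals, f @ M)
    raw = (observed - expected) / expected

    if background_samples is None:
        rng = np.random.default_rng(seed)
        background_samples = sample_matched_backgrounds(
            gc, mean_acc, n_background, n_bins, rng)
    n_bg = background_samples.shape[0]
    bg_dev = np.empty((n_bg, X.shape[0], M.shape[1]))
    for b in range(n_bg):
        samp = background_samples[b]
        obs_b = X[:, samp] @ M
        exp_b = np.outer(totals, f[samp] @ M)
        bg_dev[b] = (obs_b - exp_b) / exp_b
    mean_bg = bg_dev.mean(axis=0)
    sd_bg = bg_dev.std(axis=0, ddof=0)
    z = np.zeros_like(raw)
    ok = sd_bg > 1e-12   # guard: exactly-proportional matrices give sd 0 up to rounding
    z[ok] = (raw[ok] - mean_bg[ok]) / sd_bg[ok]
    if not ok.all():
        warnings.warn("zero background SD for some (cell, motif) pairs; z set to 0")
    index = (pd.Index(cell_names) if cell_names is not None
             else pd.RangeIndex(X.shape[0]))
    return DeviationResult(
        z=pd.DataFrame(z, index=index, columns=motif_names),
        raw=pd.DataFrame(raw, index=index, columns=motif_names))


def rank_differential_motifs(dev: DeviationResult, groups) -> pd.DataFrame:
    """Two-group rank-sum comparison of motif deviation z-scores.

    Exact two-sided Wilcoxon rank-sum when both groups have <= 10 cells,
    normal approximation with tie and continuity correction otherwise;
    Bonferroni adjustment over motifs; motifs ranked by adjusted p then
    by decreasing |effect| (difference of group mean z).
    """
    groups = pd.Series(np.asarray(groups), index=dev.z.index)
    labels = groups.unique()
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    g1, g2 = (dev.z[groups == lab] for lab in labels)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 cells")
    method = "exact" if (len(g1) <= 10 and len(g2) <= 10) else "asymptotic"
    rows = []
    n_motifs = dev.z.shape[1]
    for motif in dev.z.columns:
        res = stats.mannwhitneyu(g1[motif], g2[motif], alternative="two-sided",
                                 method=method, use_continuity=True)
        effect = float(g1[motif].mean() - g2[motif].mean())
        rows.append({"motif": motif, "effect": effect, "p": float(res.pvalue),
                     "p_adj": min(1.0, float(res.pvalue) * n_motifs)})
    table = pd.DataFrame(rows).sort_values(
        ["p_adj", "effect"], key=lambda s: s if s.name == "p_adj" else -s.abs(),
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    dev.comparison = table
    return table
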