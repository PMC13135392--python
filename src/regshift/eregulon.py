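"""eRegulon scoring, pseudo-bulk correlation filtering, and specificity scores.

An eRegulon couples a transcription factor with its predicted target regions
and target genes. Per-cell enrichment is a ranking AUC computed over the top
5% of each cell's feature ranking; eRegulons are kept only when TF
expression correlates strongly (|r| > 0.5 by default) with target-region
enrichment across small pseudo-bulks, classifying them as activators
(positive r) or repressors (negative r). Regulon specificity scores use the
Jensen-Shannon distance between the regulon's enrichment distribution over
cells and a cell-label indicator distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import pearsonr


@dataclass
class ERegulon:
    tf: str
    target_regions: list = field(default_factory=list)
    target_genes: list = field(default_factory=list)
    region_scores: np.ndarray | None = None   # per-cell AUC on region ranking
    gene_scores: np.ndarray | None = None
    r: float | None = None
    classification: str | None = None         # activator / repressor / dropped
    drop_reason: str | None = None


@dataclass
class Pseudobulk:
    members: list
    cell_type: str
    condition: str
    expression: pd.Series            # averaged gene profile
    accessibility: pd.Series | None = None  # averaged region profile


def auc_enrichment(ranking, feature_set, top_frac: float = 0.05) -> float:
    """Recovery-curve AUC of ``feature_set`` within the top fraction of a ranking.

    ``ranking`` is the strict ordering of all features for one cell, best
    first. With X = ceil(top_frac * n) evaluation points, the recovery curve
    y(x) counts set members among the top x ranks and
    AUC = sum_x y(x) / (X * min(|set|, X)), so a small set fully packed at
    the top scores exactly 1.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    feature_set = set(feature_set)
    if not feature_set:
        raise ValueError("empty feature set")
    n = len(ranking)
    X = math.ceil(top_frac * n)
    y = 0
    total = 0
    for x in range(X):
        if ranking[x] in feature_set:
            y += 1
        total += y
    return total / (X * min(len(feature_set), X))


def rank_features(scores: pd.Series) -> list:
    """Strict descending ordering of features by score, ties broken by feature id."""
    order = sorted(scores.index, key=lambda f: (-scores[f], f))
    return order


def score_cells(matrix: pd.DataFrame, feature_sets: dict[str, set],
                top_frac: float = 0.05) -> pd.DataFrame:
    """Per-cell AUC enrichment for several feature sets on one cells x features matrix."""
    n = matrix.shape[1]
    X = math.ceil(top_frac * n)
    # argsort once per cell: descending score, ties by column order (stable on
    # lexicographically sorted columns gives ties-by-feature-id)
    cols = np.array(sorted(matrix.columns))
    vals = matrix[cols].to_numpy(dtype=float)
    top_idx = np.argsort(-vals, axis=1, kind="stable")[:, :X]
    top_names = cols[top_idx]
    out = {}
    for name, fset in feature_sets.items():
        if not fset:
            raise ValueError(f"empty feature set for {name!r}")
        member = np.isin(top_names, sorted(fset))
        y = np.cumsum(member, axis=1)
        out[name] = y.sum(axis=1) / (X * min(len(fset), X))
    return pd.DataFrame(out, index=matrix.index)


def make_pseudobulks(metadata: pd.DataFrame, expression: pd.DataFrame,
                     accessibility: pd.DataFrame | None = None,
                     size: int = 5, n_draws: int = 50, seed: int = 0):
    """Random 5-cell pseudo-bulks within each (cell type x condition) stratum.

    Cells are sampled without replacement within a draw; strata with fewer
    than ``size`` cells are skipped with a warning. Returns
    ``(pseudobulks, skipped_strata)``.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[Pseudobulk] = []
    skipped: list[tuple[str, str]] = []
    strata = metadata.groupby(["cell_type", "condition"], sort=True, observed=True)
    for (cell_type, condition), sub in strata:
        if len(sub) < size:
            skipped.append((cell_type, condition))
            warnings.warn(
                f"stratum ({cell_type}, {condition}) has {len(sub)} < {size} "
                "cells; skipped")
            continue
        ids = np.array(sub.index)
        for _ in range(n_draws):
            members = list(ids[rng.choice(len(ids), size=size, replace=False)])
            expr = expression.loc[members].mean(axis=0)
            acc = (accessibility.loc[members].mean(axis=0)
                   if accessibility is not None else None)
            out.append(Pseudobulk(members=members, cell_type=cell_type,
                                  condition=condition, expression=expr,
                                  accessibility=acc))
    return out, skipped


def filter_eregulons(eregulons: list[ERegulon], pseudobulks: list[Pseudobulk],
                     cutoff: float = 0.5, top_frac: float = 0.05) -> list[ERegulon]:
    """Classify eRegulons by TF-expression / region-enrichment correlation.

    Region enrichment is recomputed on each pseudo-bulk's averaged
    accessibility profile; Pearson r against the pseudo-bulk TF expression
    classifies the eRegulon: r > cutoff -> activator, r < -cutoff ->
    repressor, otherwise dropped. Zero-variance TF expression drops the
    eRegulon with a recorded reason.
    """
    if len(pseudobulks) < 3:
        raise ValueError("need at least 3 pseudobulks for correlation")
    acc_matrix = pd.DataFrame([pb.accessibility for pb in pseudobulks])
    acc_matrix.index = pd.RangeIndex(len(pseudobulks))
    region_sets = {er.tf: set(er.target_regions) for er in eregulons}
    enrich = score_cells(acc_matrix, region_sets, top_frac=top_frac)
    for er in eregulons:
        tf_expr = np.array([pb.expression.get(er.tf, np.nan) for pb in pseudobulks])
        if np.isnan(tf_expr).any():
            er.classification, er.drop_reason = "dropped", "TF not in expression"
            continue
        if np.std(tf_expr) == 0 or np.std(enrich[er.tf]) == 0:
            er.classification, er.drop_reason = "dropped", "zero variance"
            continue
        r = float(pearsonr(tf_expr, enrich[er.tf]).statistic)
        er.r = r
        if r > cutoff:
            er.classification = "activator"
        elif r < -cutoff:
            er.classification = "repressor"
        else:
            er.classification, er.drop_reason = "dropped", "weak correlation"
    return eregulons


def regulon_specificity_score(enrichment: pd.DataFrame,
                              cell_labels) -> pd.DataFrame:
    """RSS = 1 - Jensen-Shannon distance between enrichment and label indicator.

    ``enrichment`` is cells x regulons with nonnegative scores summing to a
    positive value per regulon. Returns a (regulon x label) table of scores
    in [0, 1]; 1 means the regulon's enrichment mass coincides exactly with
    the label's cells.
    """
    labels = pd.Series(np.asarray(cell_labels), index=enrichment.index)
    vals = enrichment.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("enrichment must be nonnegative")
    sums = vals.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(
            f"all-zero regulon(s): {[enrichment.columns[j] for j in zero]}")
    p = vals / sums
    rows = []
    for label in sorted(labels.unique()):
        q = (labels == label).to_numpy(dtype=float)
        q = q / q.sum()
        for j, regulon in enumerate(enrichment.columns):
            dist = float(jensenshannon(p[:, j], q, base=2))
            rows.append({"regulon": regulon, "label": label, "rss": 1.0 - dist})
    out = pd.DataFrame(rows)
    out["rank_within_label"] = out.groupby("label")["rss"].rank(
        ascending=False, method="first").astype(int)
    return out
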