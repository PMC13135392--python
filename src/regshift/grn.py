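"""Condition-specific GRN fitting and in-silico TF knockout/overexpression.

The base network is a candidate TF -> gene adjacency built from motif hits
in regulatory regions linked to genes by distance. Per condition, each
target gene's log-normalized expression is regressed on its candidate
regulators with Bayesian ridge regression; the posterior mean coefficient is
the edge strength and the edge p-value is the two-sided Gaussian posterior
tail at zero. Edges are filtered at p < 0.001 and the strongest 2,000 edges
per network are retained. Perturbations clamp a TF to 0 (knockout) or 1.5x
its maximum observed expression (overexpression) and propagate the shift
through the signed weight matrix; transition scores measure whether each
cell's simulated shift points toward the other condition's centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import BayesianRidge

from .formats import GenomicInterval


@dataclass
class GRNModel:
    edges: pd.DataFrame              # regulator, target, weight, p
    condition: str
    genes: list[str]

    def weight_matrix(self) -> pd.DataFrame:
        """Genes x genes matrix W with W[target, regulator] = edge weight."""
        W = pd.DataFrame(0.0, index=self.genes, columns=self.genes)
        for e in self.edges.itertuples():
            W.loc[e.target, e.regulator] = e.weight
        return W


@dataclass
class PerturbationSpec:
    tf: str
    mode: str                        # "KO" or "OE"
    ko_value: float = 0.0
    oe_factor: float = 1.5
    n_propagation: int = 3

    def __post_init__(self) -> None:
        if self.mode not in {"KO", "OE"}:
            raise ValueError(f"mode must be KO or OE, got {self.mode!r}")
        if self.n_propagation < 1:
            raise ValueError("n_propagation must be >= 1")


@dataclass
class PerturbationResult:
    delta: pd.DataFrame                   # cells x genes expression shift
    spec: PerturbationSpec
    target_value: float
    transition_scores: pd.Series | None = None
    shift_2d: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Base GRN

def link_regions_to_genes(peaks: list[GenomicInterval],
                          genes: list[GenomicInterval],
                          max_dist: int = 100_000) -> pd.DataFrame:
    """Distance-based peak -> gene links: nearest gene start within ``max_dist``."""
    rows = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for p in peaks:
        best, best_d = None, None
        for g in sorted(by_chrom.get(p.chrom, []), key=lambda g: g.start):
            mid = (p.start + p.end) // 2
            d = abs(g.start - mid)
            if d <= max_dist and (best is None or d < best_d):
                best, best_d = g, d
        if best is not None:
            rows.append({"peak": p.name, "gene": best.name, "distance": best_d})
    return pd.DataFrame(rows, columns=["peak", "gene", "distance"])


def build_base_grn(motif_hits: pd.DataFrame, region_gene_links: pd.DataFrame,
                   min_motif_score: float = 10.0) -> pd.DataFrame:
    """Candidate TF -> gene adjacency from motif hits in linked peaks.

    ``motif_hits`` is a long table (peak, tf, score); hits with score below
    ``min_motif_score`` are discarded (the threshold itself passes).
    Self-edges are excluded.
    """
    kept = motif_hits[motif_hits["score"] >= min_motif_score]
    merged = kept.merge(region_gene_links[["peak", "gene"]], on="peak")
    merged = merged[merged["tf"] != merged["gene"]]
    adj = merged[["tf", "gene"]].drop_duplicates().reset_index(drop=True)
    if adj.empty:
        raise ValueError("empty candidate adjacency after motif-score filtering")
    return adj


# ---------------------------------------------------------------------------
# Expression helpers

def log_normalize(counts: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    """log1p of depth-normalized counts (counts per ``target_sum``)."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(counts / totals * target_sum)


def select_variable_genes(expression: pd.DataFrame, n: int = 3000) -> list[str]:
    """Top-n genes by variance of log-normalized expression (all genes if n >= count)."""
    variances = expression.var(axis=0, ddof=1)
    if n >= len(variances):
        return list(expression.columns)
    order = variances.sort_values(ascending=False, kind="stable")
    return list(order.index[:n])


# ---------------------------------------------------------------------------
# Fitting

def fit_grn(expression: pd.DataFrame, base_grn: pd.DataFrame,
            condition: str = "", ridge_prior_scale: float = 1.0,
            p_cutoff: float = 0.001, max_edges: int = 2000) -> GRNModel:
    """Bayesian-ridge GRN for one condition's cells x genes expression.

    Per target gene, expression is regressed on all candidate regulators
    present in the matrix; edge strength is the posterior mean coefficient
    and edge p the two-sided Gaussian posterior tail probability at zero.
    Edges with p < ``p_cutoff`` are kept, then the ``max_edges`` strongest
    by |strength|.
    """
    if ridge_prior_scale <= 0:
        raise ValueError("ridge_prior_scale must be > 0")
    genes = set(expression.columns)
    cand = base_grn[base_grn["tf"].isin(genes) & base_grn["gene"].isin(genes)]
    rows = []
    for target, sub in cand.groupby("gene", sort=True):
        regulators = sorted(set(sub["tf"]) - {target})
        if not regulators:
            continue
        X = expression[regulators].to_numpy()
        y = expression[target].to_numpy()
        model = BayesianRidge(lambda_init=1.0 / ridge_prior_scale,
                              fit_intercept=True)
        model.fit(X, y)
        sd = np.sqrt(np.diag(model.sigma_))
        with np.errstate(divide="ignore", invalid="ignore"):
            zs = np.where(sd > 0, np.abs(model.coef_) / sd, np.inf)
        ps = 2.0 * stats.norm.sf(zs)
        for reg, w, p in zip(regulators, model.coef_, ps):
            rows.append({"regulator": reg, "target": target,
                         "weight": float(w), "p": float(p)})
    edges = pd.DataFrame(rows, columns=["regulator", "target", "weight", "p"])
    edges = edges[edges["p"] < p_cutoff]
    edges = edges.reindex(
        edges["weight"].abs().sort_values(ascending=False, kind="stable").index)
    edges = edges.head(max_edges).reset_index(drop=True)
    return GRNModel(edges=edges, condition=condition,
                    genes=sorted(expression.columns))


# ---------------------------------------------------------------------------
# Perturbation

def simulate_perturbation(grn: GRNModel, expression: pd.DataFrame,
                          spec: PerturbationSpec) -> PerturbationResult:
    """Propagate a TF knockout/overexpression through the fitted network.

    The initial shift is (perturbed - observed) at the TF per cell. At
    propagation step k the shift reaches genes first reachable at graph
    distance k (delta_new += W . delta, applied to newly reached genes
    only), with the TF clamped to its perturbed value throughout. Genes not
    reachable from the TF keep delta 0.
    """
    if spec.tf not in grn.genes:
        raise ValueError(f"TF {spec.tf!r} not in GRN gene universe")
    if spec.tf not in expression.columns:
        raise ValueError(f"TF {spec.tf!r} not in expression matrix")
    genes = grn.genes
    gi = {g: j for j, g in enumerate(genes)}
    W = np.zeros((len(genes), len(genes)))
    targets_of: dict[str, list[str]] = {}
    for e in grn.edges.itertuples():
        W[gi[e.target], gi[e.regulator]] = e.weight
        targets_of.setdefault(e.regulator, []).append(e.target)

    # BFS distances from the TF along regulator -> target edges
    dist = {spec.tf: 0}
    frontier = [spec.tf]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in targets_of.get(u, []):
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt

    # unit propagation: shift per unit of TF perturbation
    unit = np.zeros(len(genes))
    unit[gi[spec.tf]] = 1.0
    for k in range(1, spec.n_propagation + 1):
        contrib = W @ unit
        newly = [gi[g] for g, dd in dist.items() if dd == k]
        unit[newly] += contrib[newly]
        unit[gi[spec.tf]] = 1.0

    tf_obs = expression[spec.tf].to_numpy()
    if spec.mode == "KO":
        target_value = spec.ko_value
    else:
        target_value = spec.oe_factor * float(tf_obs.max())
    init = target_value - tf_obs                    # per-cell initial shift
    delta = np.outer(init, unit)
    # align delta columns with expression columns (genes outside stay 0)
    out = pd.DataFrame(0.0, index=expression.index, columns=expression.columns)
    common = [g for g in genes if g in out.columns]
    out.loc[:, common] = delta[:, [gi[g] for g in common]]
    return PerturbationResult(delta=out, spec=spec, target_value=target_value)


def transition_vectors(result: PerturbationResult, expression: pd.DataFrame,
                       condition_labels, target_condition: str,
                       embedding: np.ndarray | None = None) -> PerturbationResult:
    """Cosine alignment of each cell's shift with the direction to a condition centroid.

    Scores live in expression space; the optional 2D embedding only receives
    a linear projection of the shift for visualization.
    """
    labels = pd.Series(np.asarray(condition_labels), index=expression.index)
    if target_condition not in set(labels):
        raise ValueError(f"condition {target_condition!r} absent from labels")
    centroid = expression[labels == target_condition].mean(axis=0).to_numpy()
    X = expression.to_numpy(dtype=float)
    D = result.delta[expression.columns].to_numpy(dtype=float)
    toward = centroid[None, :] - X
    num = (D * toward).sum(axis=1)
    denom = np.linalg.norm(D, axis=1) * np.linalg.norm(toward, axis=1)
    scores = np.where(denom > 0, num / np.where(denom == 0, 1.0, denom), 0.0)
    result.transition_scores = pd.Series(scores, index=expression.index)
    if embedding is not None:
        emb = np.asarray(embedding, dtype=float)
        if emb.shape[0] != X.shape[0] or emb.shape[1] != 2:
            raise ValueError("embedding must be cells x 2")
        Xc = X - X.mean(axis=0)
        coefs, *_ = np.linalg.lstsq(Xc, emb - emb.mean(axis=0), rcond=None)
        result.shift_2d = pd.DataFrame(D @ coefs, index=expression.index,
                                       columns=["dx", "dy"])
    return result


def pca_embedding(expression: pd.DataFrame, seed: int = 0) -> np.ndarray:
    """Deterministic 2D principal-component coordinates for visualization."""
    from sklearn.decomposition import PCA
    return PCA(n_components=2, random_state=seed).fit_transform(
        expression.to_numpy(dtype=float))
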