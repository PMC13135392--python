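"""Differential expression/accessibility and gene-set overlap statistics.

Wilcoxon rank-sum differential expression with Bonferroni adjustment and
literal log2 fold-change thresholds (0.1 / 0.25 / 0.32 conventions),
likelihood-ratio differential accessibility with a depth covariate,
cross-namespace symbol mapping, and hypergeometric / Monte-Carlo multi-set
overlap tests computed stably in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class OverlapResult:
    set_sizes: list[int]
    universe_size: int
    observed_overlap: int
    p: float
    method: str
    iterations: int | None = None
    log10_p: float | None = None  # stable value when p underflows double precision


# ---------------------------------------------------------------------------
# Differential expression

def wilcoxon_de(expression: pd.DataFrame, groups, pseudocount: float = 1.0,
                exact_max_n: int = 10, group_order=None) -> pd.DataFrame:
    """Per-gene two-sided rank-sum test with Bonferroni adjustment.

    ``expression`` holds log-normalized values (cells x genes); fold changes
    are computed on de-logged group means: log2((mu1 + pc) / (mu2 + pc)),
    group 1 being the first label in ``group_order`` (order of appearance
    when not given). The exact null distribution is used when both groups
    have at most ``exact_max_n`` cells, the tie/continuity-corrected normal
    approximation otherwise. Genes expressed in zero cells are excluded and
    counted in the ``n_excluded`` attribute of the returned frame.
    """
    groups = pd.Series(np.asarray(groups), index=expression.index)
    labels = list(group_order) if group_order is not None else list(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    m1, m2 = (groups == labels[0], groups == labels[1])
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least 2 cells")
    expressed = (expression != 0).any(axis=0)
    n_excluded = int((~expressed).sum())
    tested = expression.loc[:, expressed]
    method = "exact" if (m1.sum() <= exact_max_n and m2.sum() <= exact_max_n) \
        else "asymptotic"
    g1 = tested[m1.values].to_numpy(dtype=float)
    g2 = tested[m2.values].to_numpy(dtype=float)
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method,
                             use_continuity=True, axis=0)
    mu1 = np.expm1(g1).mean(axis=0)
    mu2 = np.expm1(g2).mean(axis=0)
    lfc = np.log2((mu1 + pseudocount) / (mu2 + pseudocount))
    n = tested.shape[1]
    out = pd.DataFrame({
        "mean_1": mu1, "mean_2": mu2, "log2fc": lfc,
        "p": np.asarray(res.pvalue, dtype=float),
        "p_adj": np.minimum(1.0, np.asarray(res.pvalue, dtype=float) * n),
    }, index=tested.columns)
    out.attrs["groups"] = labels
    out.attrs["n_excluded"] = n_excluded
    return out


def lr_differential_accessibility(accessibility: pd.DataFrame, groups,
                                  covariate) -> pd.DataFrame:
    """Likelihood-ratio test of region accessibility on group, given a covariate.

    Regions are binarized (count > 0). For each region the logistic model
    ``accessible ~ group + covariate`` is compared with the covariate-only
    model; p comes from the chi2(1) LR statistic, Bonferroni adjusted.
    Regions accessible in all or no cells get p = 1 and are flagged.
    """
    groups = pd.Series(np.asarray(groups), index=accessibility.index)
    labels = list(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    y_group = (groups == labels[0]).astype(float).to_numpy()
    cov = np.asarray(covariate, dtype=float)
    cov = (cov - cov.mean()) / (cov.std() or 1.0)
    rows = []
    B = (accessibility.to_numpy() > 0).astype(float)
    for j, region in enumerate(accessibility.columns):
        y = B[:, j]
        if y.min() == y.max():
            rows.append({"region": region, "lr_stat": 0.0, "p": 1.0,
                         "degenerate": True})
            continue
        X_full = sm.add_constant(np.column_stack([y_group, cov]))
        X_null = sm.add_constant(cov)
        try:
            full = sm.Logit(y, X_full).fit(disp=0, maxiter=100)
            null = sm.Logit(y, X_null).fit(disp=0, maxiter=100)
            lr = 2.0 * (full.llf - null.llf)
            lr = max(lr, 0.0)
            p = float(stats.chi2.sf(lr, df=1))
        except Exception:  # perfect separation and friends
            lr, p = np.nan, 1.0
        rows.append({"region": region, "lr_stat": lr, "p": p, "degenerate": False})
    out = pd.DataFrame(rows).set_index("region")
    n_tested = int((~out["degenerate"]).sum())
    out["p_adj"] = np.minimum(1.0, out["p"] * max(n_tested, 1))
    out.loc[out["degenerate"], "p_adj"] = 1.0
    return out


def threshold_de(result: pd.DataFrame, p_adj_max: float = 0.05,
                 lfc_min: float = 0.25, direction: str = "up") -> set:
    """Genes passing the significance and fold-change thresholds, strictly."""
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    sig = result["p_adj"] < p_adj_max
    if direction == "up":
        sel = sig & (result["log2fc"] > lfc_min)
    else:
        sel = sig & (result["log2fc"] < -lfc_min)
    return set(result.index[sel])


# ---------------------------------------------------------------------------
# Symbol mapping

def map_orthologs(gene_set, table: pd.DataFrame | None = None,
                  fallback_case_rule: bool = False,
                  source_col: str = "mouse", target_col: str = "human"):
    """Map symbols through a two-column ortholog table, optionally by casing.

    With the fallback on, unmapped Title-case symbols are upper-cased
    (mouse -> human direction) or upper-case symbols are Title-cased.
    Returns ``(mapped_set, unmapped_list)``; unmapped symbols are reported,
    never silently dropped.
    """
    lookup: dict[str, str] = {}
    if table is not None:
        dup = table[table.duplicated(source_col, keep=False)]
        conflicts = dup.groupby(source_col)[target_col].nunique()
        if (conflicts > 1).any():
            raise ValueError(
                f"conflicting ortholog rows for: {list(conflicts[conflicts > 1].index)}")
        lookup = dict(zip(table[source_col], table[target_col]))
    mapped, unmapped = set(), []
    for symbol in sorted(gene_set):
        if symbol in lookup:
            mapped.add(lookup[symbol])
        elif fallback_case_rule:
            converted = symbol.upper() if symbol != symbol.upper() else symbol.title()
            mapped.add(converted)
        else:
            unmapped.append(symbol)
    return mapped, unmapped


# ---------------------------------------------------------------------------
# Overlap tests

def hypergeometric_overlap(set_a, set_b, universe) -> OverlapResult:
    """Upper-tail hypergeometric probability of the observed intersection.

    p = P(X >= k) for X ~ Hypergeometric(N=|universe|, K=|A|, n=|B|),
    evaluated through the log survival function so extreme tails keep
    precision.
    """
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    stray = (set_a | set_b) - universe
    if stray:
        raise ValueError(f"sets contain elements outside the universe: "
                         f"{sorted(stray)[:10]}")
    N, K, n = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    if k == 0:
        logp = 0.0
    else:
        logp = float(stats.hypergeom.logsf(k - 1, N, K, n))
    p = float(np.exp(min(logp, 0.0)))
    if p == 0.0:
        p = np.nextafter(0.0, 1.0)   # keep p in (0, 1]; log10_p is authoritative
    return OverlapResult(set_sizes=[K, n], universe_size=N,
                         observed_overlap=k, p=min(p, 1.0),
                         method="hypergeometric",
                         log10_p=logp / np.log(10.0))


def monte_carlo_multiset_overlap(sets, universe, B: int = 100_000,
                                 seed: int = 0) -> OverlapResult:
    """Resampling null for the m-way intersection of same-sized random subsets.

    Each iteration draws ``m`` subsets of the observed sizes uniformly
    without replacement from the universe; the statistic is the m-way
    intersection size and p uses the add-one estimator
    (#{null >= observed} + 1) / (B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    universe_list = sorted(set(universe))
    N = len(universe_list)
    for s in sets:
        if not s <= set(universe_list):
            raise ValueError("every set must be a subset of the universe")
        if len(s) > N:
            raise ValueError("set larger than universe")
    observed = len(set.intersection(*sets))
    sizes = [len(s) for s in sets]
    rng = np.random.default_rng(seed)
    # indicator-count trick: intersection size = #elements hit by all m draws
    hits = 0
    counts = np.empty(N, dtype=np.int16)
    m = len(sets)
    for _ in range(B):
        counts[:] = 0
        for size in sizes:
            idx = rng.choice(N, size=size, replace=False)
            counts[idx] += 1
        if int((counts == m).sum()) >= observed:
            hits += 1
    p = (hits + 1) / (B + 1)
    return OverlapResult(set_sizes=sizes, universe_size=N,
                         observed_overlap=observed, p=p,
                         method="monte_carlo", iterations=B)


def set_enrichment(query, annotations: dict[str, set], universe) -> pd.DataFrame:
    """Hypergeometric enrichment of a query set against named annotation sets."""
    rows = []
    for name in sorted(annotations):
        res = hypergeometric_overlap(query, annotations[name], universe)
        rows.append({"annotation": name, "overlap": res.observed_overlap,
                     "size": len(annotations[name]), "p": res.p})
    out = pd.DataFrame(rows).set_index("annotation")
    out["p_adj"] = np.minimum(1.0, out["p"] * len(out))
    return out.sort_values(["p", "annotation"])
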