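import itertools
import math

import numpy as np
import pandas as pd
import pytest

from regshift.overlap import (hypergeometric_overlap,
                              lr_differential_accessibility, map_orthologs,
                              monte_carlo_multiset_overlap, set_enrichment,
                              threshold_de, wilcoxon_de)


class TestWilcoxonDe:
    def test_identical_groups_null(self):
        expr = pd.DataFrame({"g": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        res = wilcoxon_de(expr, ["a"] * 3 + ["b"] * 3)
        assert res.loc["g", "p"] == pytest.approx(1.0)
        assert res.loc["g", "log2fc"] == pytest.approx(0.0)

    def test_exact_p_matches_enumeration(self):
        # all C(6,3)=20 arrangements: only 2 give a rank-sum this extreme
        expr = pd.DataFrame({"g": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        res = wilcoxon_de(expr, ["a"] * 3 + ["b"] * 3)
        assert res.loc["g", "p"] == pytest.approx(2 / 20)

    def test_unexpressed_genes_excluded_and_counted(self):
        expr = pd.DataFrame({"on": [1.0, 0.0, 2.0, 0.0],
                             "off": [0.0, 0.0, 0.0, 0.0]})
        res = wilcoxon_de(expr, ["a", "a", "b", "b"])
        assert "off" not in res.index
        assert res.attrs["n_excluded"] == 1

    def test_group_order_controls_fold_change_sign(self):
        expr = pd.DataFrame({"g": np.log1p([10, 10, 1, 1])},
                            index=list("abcd"), dtype=float)
        groups = ["hi", "hi", "lo", "lo"]
        up = wilcoxon_de(expr, groups, group_order=["hi", "lo"])
        down = wilcoxon_de(expr, groups, group_order=["lo", "hi"])
        assert up.loc["g", "log2fc"] > 0 > down.loc["g", "log2fc"]


class TestThresholds:
    TABLE = pd.DataFrame({
        "log2fc": [0.30, 0.30, 0.20, -0.50, 0.30],
        "p_adj": [0.04, 0.05, 0.01, 0.01, 0.06]},
        index=["pass", "p_boundary", "lfc_low", "downgene", "p_high"])

    def test_inclusion_requires_both_thresholds(self):
        assert threshold_de(self.TABLE, 0.05, 0.25, "up") == {"pass"}

    def test_p_boundary_excluded_strictly(self):
        assert "p_boundary" not in threshold_de(self.TABLE, 0.05, 0.25, "up")

    def test_down_direction_sign_rule(self):
        assert threshold_de(self.TABLE, 0.05, 0.25, "down") == {"downgene"}

    def test_direction_exclusivity(self):
        up = threshold_de(self.TABLE, 0.05, 0.25, "up")
        down = threshold_de(self.TABLE, 0.05, 0.25, "down")
        assert not up & down


class TestOrthologs:
    TABLE = pd.DataFrame({"mouse": ["Fosl2", "Edn1"],
                          "human": ["FOSL2", "EDN1"]})

    def test_table_lookup(self):
        mapped, unmapped = map_orthologs({"Fosl2"}, self.TABLE)
        assert mapped == {"FOSL2"} and unmapped == []

    def test_fallback_casing_both_directions(self):
        mapped, _ = map_orthologs({"Jag2"}, self.TABLE, fallback_case_rule=True)
        assert mapped == {"JAG2"}
        mapped, _ = map_orthologs({"JAG2"}, None, fallback_case_rule=True)
        assert mapped == {"Jag2"}

    def test_unmapped_reported_not_dropped(self):
        mapped, unmapped = map_orthologs({"Fosl2", "Xyz1"}, self.TABLE)
        assert mapped == {"FOSL2"} and unmapped == ["Xyz1"]

    def test_round_trip_on_covered_symbols(self):
        fwd, _ = map_orthologs({"Fosl2", "Edn1"}, self.TABLE)
        rev, _ = map_orthologs(fwd, self.TABLE.rename(
            columns={"mouse": "human", "human": "mouse"}))
        assert rev == {"Fosl2", "Edn1"}

    def test_conflicting_rows_rejected(self):
        bad = pd.DataFrame({"mouse": ["A", "A"], "human": ["B", "C"]})
        with pytest.raises(ValueError):
            map_orthologs({"A"}, bad)


def enumeration_tail(universe, a, b_size, k):
    """Oracle: exhaustive enumeration of all |B|-subsets of the universe."""
    total, ge = 0, 0
    for bset in itertools.combinations(universe, b_size):
        total += 1
        if len(a & set(bset)) >= k:
            ge += 1
    return ge / total


class TestHypergeometric:
    UNIVERSE = set(range(20))

    def test_disjoint_sets_give_p_one(self):
        res = hypergeometric_overlap({1, 2}, {3, 4}, self.UNIVERSE)
        assert res.p == 1.0 and res.observed_overlap == 0

    def test_complete_overlap_combinatorial_value(self):
        a = {0, 1, 2, 3, 4}
        res = hypergeometric_overlap(a, a, self.UNIVERSE)
        assert res.p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        universe = set(range(12))
        for _ in range(10):
            a = set(rng.choice(12, size=5, replace=False).tolist())
            b = set(rng.choice(12, size=4, replace=False).tolist())
            res = hypergeometric_overlap(a, b, universe)
            k = len(a & b)
            assert res.p == pytest.approx(
                enumeration_tail(universe, a, 4, k), abs=1e-12)

    def test_monotone_decreasing_in_overlap(self):
        universe = set(range(30))
        ps = []
        for k in range(6):
            a = set(range(6))
            b = set(range(k)) | set(range(10, 16 - k))
            ps.append(hypergeometric_overlap(a, b, universe).p)
        assert ps == sorted(ps, reverse=True)

    def test_extreme_tail_computed_in_log_space(self):
        universe = {f"g{i}" for i in range(20_000)}
        a = {f"g{i}" for i in range(500)}
        res = hypergeometric_overlap(a, a, universe)
        assert 0 < res.p
        assert res.log10_p < -300
        # log-space value matches the exact combinatorial tail log10(1/C(N, K))
        exact = -(math.lgamma(20_001) - math.lgamma(501)
                  - math.lgamma(19_501)) / math.log(10)
        assert res.log10_p == pytest.approx(exact, rel=1e-10)

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap({"x"}, {"y"}, {"y"})


class TestMonteCarlo:
    def test_zero_overlap_gives_p_one(self):
        res = monte_carlo_multiset_overlap([{1}, {2}], set(range(10)),
                                           B=50, seed=0)
        assert res.p == 1.0

    def test_add_one_lower_bound(self):
        u = set(range(10))
        res = monte_carlo_multiset_overlap([set(range(5))] * 3, u, B=99,
                                           seed=0)
        assert res.p >= 1 / 100

    def test_two_set_case_agrees_with_hypergeometric(self, rng):
        universe = [f"g{i}" for i in range(200)]
        a = set(rng.choice(universe, 30, replace=False))
        b = set(rng.choice(universe, 40, replace=False))
        hy = hypergeometric_overlap(a, b, universe)
        mc = monte_carlo_multiset_overlap([a, b], universe, B=20_000, seed=1)
        se = np.sqrt(hy.p * (1 - hy.p) / 20_000)
        assert abs(mc.p - hy.p) <= 3 * se + 1 / 20_001

    def test_three_set_intersection_statistic(self):
        u = set(range(50))
        sets = [set(range(10)), set(range(5, 15)), set(range(8, 18))]
        res = monte_carlo_multiset_overlap(sets, u, B=10, seed=0)
        assert res.observed_overlap == len(set.intersection(*sets))

    def test_validation(self):
        with pytest.raises(ValueError):
            monte_carlo_multiset_overlap([{1}], {1, 2}, B=10)
        with pytest.raises(ValueError):
            monte_carlo_multiset_overlap([{1}, {9}], {1, 2}, B=10)


class TestSetEnrichment:
    def test_query_itself_is_most_enriched(self):
        universe = {f"g{i}" for i in range(30)}
        query = {f"g{i}" for i in range(5)}
        annos = {"self": set(query), "disjoint": {f"g{i}" for i in range(10, 15)},
                 "half": {f"g{i}" for i in range(3, 9)}}
        table = set_enrichment(query, annos, universe)
        assert table.index[0] == "self"
        assert table.loc["disjoint", "p"] == 1.0

    def test_matches_manual_per_annotation_computation(self):
        universe = {f"g{i}" for i in range(15)}
        query = {f"g{i}" for i in range(4)}
        annos = {"a": {f"g{i}" for i in range(2, 8)}}
        table = set_enrichment(query, annos, universe)
        manual = hypergeometric_overlap(query, annos["a"], universe)
        assert table.loc["a", "p"] == pytest.approx(manual.p, rel=1e-12)


class TestDifferentialAccessibility:
    def brute_force_logistic_ll(self, y, X, grid=None):
        """Oracle: maximize the Bernoulli log-likelihood on a coefficient grid."""
        from scipy.optimize import minimize

        def nll(beta):
            eta = X @ beta
            return -np.sum(y * eta - np.log1p(np.exp(eta)))
        res = minimize(nll, np.zeros(X.shape[1]), method="BFGS")
        return -res.fun

    def test_independent_labels_give_null(self, rng):
        n = 60
        cov = rng.normal(size=n)
        acc = (rng.random(n) < 1 / (1 + np.exp(-cov))).astype(float)
        table = lr_differential_accessibility(
            pd.DataFrame({"r1": acc}), rng.permutation(["a", "b"] * 30), cov)
        assert table.loc["r1", "p"] > 0.05

    def test_deviance_matches_direct_likelihood_maximization(self, rng):
        n = 8
        acc = pd.DataFrame({"r": [1, 0, 1, 1, 0, 0, 1, 0]})
        groups = ["a", "a", "a", "a", "b", "b", "b", "b"]
        cov = np.array([1.0, 2.0, 1.5, 0.5, 2.5, 1.0, 2.0, 0.5])
        table = lr_differential_accessibility(acc, groups, cov)
        y = acc["r"].to_numpy(dtype=float)
        g = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        c = (cov - cov.mean()) / cov.std()
        X_full = np.column_stack([np.ones(n), g, c])
        X_null = np.column_stack([np.ones(n), c])
        lr = 2 * (self.brute_force_logistic_ll(y, X_full)
                  - self.brute_force_logistic_ll(y, X_null))
        assert table.loc["r", "lr_stat"] == pytest.approx(lr, abs=1e-5)

    def test_constant_regions_flagged(self):
        acc = pd.DataFrame({"all": [1, 1, 1, 1], "none": [0, 0, 0, 0]})
        table = lr_differential_accessibility(acc, ["a", "a", "b", "b"],
                                              [1.0, 2.0, 1.0, 2.0])
        assert table["degenerate"].all()
        assert (table["p"] == 1.0).all()

    def test_planted_group_effect_detected(self, rng):
        n = 200
        groups = np.array(["a"] * n + ["b"] * n)
        cov = rng.normal(size=2 * n)
        p_open = np.where(groups == "a", 0.7, 0.3)
        acc = pd.DataFrame({"r": (rng.random(2 * n) < p_open).astype(int)})
        table = lr_differential_accessibility(acc, groups, cov)
        assert table.loc["r", "p_adj"] < 0.05
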