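"""Tree-derivation engine: ANOVA splitting, Bonferroni, growth, collapsing."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from psakit.engine import (
    GrowthParams,
    HoursTreeRegressor,
    best_split,
    bonferroni,
    cluster_leaf_means,
    collapse_leaves,
    derivation_validation_split,
    grow_tree,
    one_way_f,
)
from psakit.errors import ConfigurationError


class TestOneWayF:
    def test_identical_groups_no_between_variance(self):
        f, p = one_way_f([1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert f == 0.0 and p == 1.0

    def test_constant_target_defined_as_zero(self):
        f, p = one_way_f([5, 5, 5, 5], [0, 0, 1, 1])
        assert (f, p) == (0.0, 1.0)

    def test_matches_scipy_on_hand_example(self):
        f, p = one_way_f([0, 0, 1, 2, 3, 3], [0, 0, 0, 1, 1, 1])
        ref = sps.f_oneway([0, 0, 1], [2, 3, 3])
        assert f == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)
        # closed form on these six numbers: SSB = 24.5/... F = 24.5
        assert f == pytest.approx(24.5, abs=1e-9)

    def test_contract_violations(self):
        with pytest.raises(ConfigurationError):
            one_way_f([1, 2, 3], [0, 0, 0])
        with pytest.raises(ConfigurationError):
            one_way_f([1, 2], [0, 1])


class TestBonferroni:
    def test_multiplies_and_caps(self):
        assert bonferroni(0.01, 5) == pytest.approx(0.05)
        assert bonferroni(0.5, 10) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            bonferroni(1.5, 2)
        with pytest.raises(ConfigurationError):
            bonferroni(0.1, 0)

    def test_ordinal_binary_cut_count_is_levels_minus_one(self, rng):
        # with no leaf-size restriction every cut between the c distinct
        # levels is admissible, so m_variable = c - 1
        x = np.repeat([0, 1, 3, 5, 6], 20)
        y = rng.normal(0, 1, len(x)) + (x >= 3) * 50
        cand = best_split(
            pd.DataFrame({"x": x}), y,
            GrowthParams(min_leaf=1, alpha=0.9999, allow_multiway=False),
        )
        assert cand.m_variable == 4 == cand.m


class TestBestSplit:
    def test_node_too_small_for_two_leaves(self, rng):
        X = pd.DataFrame({"x": rng.integers(0, 5, 150)})
        y = rng.normal(0, 1, 150)
        assert best_split(X, y, GrowthParams(min_leaf=100)) is None

    def test_planted_step_recovered(self, rng):
        n = 2000
        X = pd.DataFrame({f"x{i}": rng.integers(0, 7, n) for i in range(5)})
        y = (X["x2"] >= 3).astype(float) + rng.normal(0, 0.5, n)
        cand = best_split(X, y, GrowthParams())
        assert cand.variable == "x2"
        assert cand.cuts == (3.0,)
        assert cand.arity == 2
        assert cand.p_adj < 0.05

    def test_pure_noise_usually_returns_none(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = pd.DataFrame({f"x{i}": r.integers(0, 7, 400) for i in range(5)})
            y = r.normal(0, 1, 400)
            hits += best_split(X, y, GrowthParams()) is not None
        assert hits <= 3

    def test_agrees_with_brute_force_on_tiny_instances(self):
        """Exhaustive-search oracle on <= 12 observations, one feature."""
        params = GrowthParams(min_leaf=1, allow_multiway=False)
        for seed in range(30):
            r = np.random.default_rng(seed)
            n = int(r.integers(4, 13))
            x = r.integers(0, 4, n)
            if len(np.unique(x)) < 2:
                continue
            y = r.normal(0, 1, n)
            cand = best_split(pd.DataFrame({"x": x}), y, params, require_significant=False)
            # brute force: scipy ANOVA at every admissible binary cut
            best = None
            levels = np.unique(x)
            for cut in levels[1:]:
                left, right = y[x < cut], y[x >= cut]
                res = sps.f_oneway(left, right)
                f, p = float(res.statistic), float(res.pvalue)
                if best is None or (p, -f) < (best[1], -best[2]):
                    best = (cut, p, f)
            assert cand is not None
            assert cand.cuts == (float(best[0]),)
            assert cand.f_stat == pytest.approx(best[2], abs=1e-10, rel=1e-10)
            assert cand.p_raw == pytest.approx(best[1], abs=1e-10, rel=1e-10)

    def test_multiway_partitions_counted_and_scored(self, rng):
        x = np.repeat([0, 1, 2, 3], 50)
        y = np.concatenate([np.zeros(50), np.ones(50) * 5, np.ones(50) * 10, np.ones(50) * 15])
        y = y + rng.normal(0, 0.1, 200)
        cand = best_split(
            pd.DataFrame({"x": x}), y, GrowthParams(min_leaf=50, allow_multiway=True)
        )
        # three true level jumps: the 3-way contiguous partition wins over binary
        assert cand.arity == 3
        binary = 3
        threeway = len(list(combinations(range(1, 4), 2)))
        assert cand.m == binary + threeway


class TestGrowTree:
    def test_depth_cap_of_one_gives_single_split(self, rng):
        X = pd.DataFrame({"x": rng.integers(0, 7, 1000)})
        y = (X["x"] >= 3) * 3 + rng.normal(0, 1, 1000)
        tree = grow_tree(X, y, GrowthParams(max_depth=1, min_leaf=50))
        assert tree.depth() == 1 and len(tree.leaves) == 2

    def test_forced_first_variable_at_root(self, rng):
        n = 1500
        X = pd.DataFrame(
            {"age": rng.integers(65, 100, n), "x": rng.integers(0, 7, n)}
        )
        y = (X["x"] >= 3) * 3 + (X["age"] >= 80) * 1.0 + rng.normal(0, 1, n)
        free = grow_tree(X, y, GrowthParams(min_leaf=100))
        assert free.nodes[free.root_id].variable == "x"  # x dominates unforced
        forced = grow_tree(X, y, GrowthParams(min_leaf=100, forced_first_variable="age"))
        assert forced.nodes[forced.root_id].variable == "age"

    def test_forced_variable_absent_is_configuration_error(self, rng):
        X = pd.DataFrame({"x": rng.integers(0, 7, 300)})
        with pytest.raises(ConfigurationError, match="age"):
            grow_tree(X, rng.normal(0, 1, 300),
                      GrowthParams(forced_first_variable="age"))

    def test_empty_data_rejected(self):
        with pytest.raises(ConfigurationError):
            grow_tree(pd.DataFrame({"x": []}), [])

    def test_three_planted_strata_recovered_with_high_purity(self, rng):
        n = 3000
        x = rng.integers(0, 6, n)
        stratum = np.digitize(x, [2, 4])  # 0,1,2
        y = stratum * 4.0 + rng.normal(0, 1, n)
        tree = grow_tree(pd.DataFrame({"x": x}), y, GrowthParams(min_leaf=100))
        est = HoursTreeRegressor(min_leaf=100).fit(pd.DataFrame({"x": x}), y)
        leaf_ids = est.apply(pd.DataFrame({"x": x}))
        purity = []
        for lid in np.unique(leaf_ids):
            strata, counts = np.unique(stratum[leaf_ids == lid], return_counts=True)
            purity.append(counts.max() / counts.sum())
        assert np.mean(purity) >= 0.9
        assert len(tree.leaves) >= 3

    def test_every_leaf_respects_min_leaf(self, rng):
        X = pd.DataFrame({f"x{i}": rng.integers(0, 5, 2000) for i in range(3)})
        y = X["x0"] * 2 + X["x1"] + rng.normal(0, 1, 2000)
        tree = grow_tree(X, y, GrowthParams(min_leaf=150, max_depth=4))
        assert all(leaf.n >= 150 for leaf in tree.leaves)
        assert tree.depth() <= 4

    def test_nesting_stricter_settings_never_deeper(self, rng):
        X = pd.DataFrame({f"x{i}": rng.integers(0, 6, 2000) for i in range(3)})
        y = X["x0"] * 1.5 + rng.normal(0, 1, 2000)
        base = grow_tree(X, y, GrowthParams(min_leaf=100, alpha=0.05)).depth()
        bigger_leaf = grow_tree(X, y, GrowthParams(min_leaf=400, alpha=0.05)).depth()
        lower_alpha = grow_tree(X, y, GrowthParams(min_leaf=100, alpha=1e-6)).depth()
        assert bigger_leaf <= base
        assert lower_alpha <= base

    def test_reproducible_serialisation(self, rng):
        X = pd.DataFrame({"x": rng.integers(0, 7, 1000)})
        y = (X["x"] >= 4) * 2 + rng.normal(0, 1, 1000)
        t1 = grow_tree(X, y, GrowthParams(min_leaf=100))
        t2 = grow_tree(X, y, GrowthParams(min_leaf=100))
        assert t1.to_dict() == t2.to_dict()


class TestCollapse:
    def _grown(self, rng, n=1200):
        X = pd.DataFrame({"x": rng.integers(0, 8, n)})
        y = X["x"] * 1.0 + rng.normal(0, 0.3, n)
        return grow_tree(X, y, GrowthParams(min_leaf=100, alpha=0.5))

    def test_exact_tie_leaves_merge(self):
        labels = cluster_leaf_means([1.0, 1.0, 5.0], [10, 10, 10], 2)
        assert labels == [0, 0, 1]

    def test_identity_when_k_equals_leaf_count(self, rng):
        tree = self._grown(rng)
        collapsed = collapse_leaves(tree, len(tree.leaves))
        groups = [leaf.group for leaf in collapsed.leaves]
        assert len(set(groups)) == len(tree.leaves)

    def test_k_above_leaf_count_rejected(self, rng):
        tree = self._grown(rng)
        with pytest.raises(ConfigurationError):
            collapse_leaves(tree, len(tree.leaves) + 1)

    def test_group_means_strictly_increasing(self, rng):
        tree = self._grown(rng)
        k = min(3, len(tree.leaves))
        collapsed = collapse_leaves(tree, k)
        means = collapsed.metadata["group_means"]
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_dp_matches_brute_force_partitioning(self, rng):
        for _ in range(20):
            L = int(rng.integers(3, 8))
            means = np.sort(rng.normal(0, 5, L))
            weights = rng.integers(1, 50, L).astype(float)
            k = int(rng.integers(1, L + 1))
            labels = cluster_leaf_means(means, weights, k)

            def sse(assign):
                total = 0.0
                for g in range(k):
                    idx = [i for i in range(L) if assign[i] == g]
                    if not idx:
                        return np.inf
                    w = weights[idx]
                    m = means[idx]
                    mu = np.average(m, weights=w)
                    total += float(np.sum(w * (m - mu) ** 2))
                return total

            # brute force over all contiguous boundary placements
            best = np.inf
            for bounds in combinations(range(1, L), k - 1):
                assign = np.zeros(L, dtype=int)
                for g, b in enumerate(bounds):
                    assign[b:] = g + 1
                best = min(best, sse(assign))
            assert sse(labels) == pytest.approx(best, abs=1e-9)


class TestSplitAndEstimator:
    def test_derivation_validation_split_seeded_70_30(self):
        df = pd.DataFrame({"v": range(1000)})
        der, val = derivation_validation_split(df, 0.7, seed=11)
        assert len(der) == 700 and len(val) == 300
        assert set(der["v"]).isdisjoint(val["v"])
        der2, _ = derivation_validation_split(df, 0.7, seed=11)
        assert list(der["v"]) == list(der2["v"])

    def test_sklearn_facade_params_round_trip(self):
        est = HoursTreeRegressor(min_leaf=10, alpha=0.01)
        assert est.get_params()["min_leaf"] == 10
        est.set_params(max_depth=2)
        assert est.max_depth == 2

    def test_estimator_score_is_partition_r2(self, rng):
        X = pd.DataFrame({"x": rng.integers(0, 7, 1500)})
        y = (X["x"] >= 3) * 4 + rng.normal(0, 1, 1500)
        est = HoursTreeRegressor(min_leaf=100).fit(X, y)
        preds = est.predict(X)
        assert set(np.round(preds, 1)) <= set(np.round(list(est.leaf_means_.values()), 1))
        assert est.score(X, y) > 0.5
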