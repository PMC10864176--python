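"""Marker and DAR testing against enumeration / closed-form oracles."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from egrnkit.differential import (
    anova_markers,
    consensus_top200,
    dar_ttest,
    fisher_enrichment,
    wilcoxon_markers,
)


def frame(x, prefix="f"):
    x = np.asarray(x, dtype=float)
    return pd.DataFrame(
        x, index=[f"{prefix}{i}" for i in range(x.shape[0])],
        columns=[f"n{i}" for i in range(x.shape[1])],
    )


def labels_for(counts, split):
    return pd.Series(
        ["g1"] * split + ["g2"] * (counts.shape[1] - split), index=counts.columns
    )


def exact_ranksum_p(x, y):
    """Exhaustive enumeration of the two-sided rank-sum null (no ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.asarray(us)
    mu = us.mean()
    return np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)


class TestWilcoxon:
    def test_identical_distributions_yield_no_significant_markers(self, rng):
        x = rng.poisson(5, size=(30, 40)).astype(float)
        counts = frame(np.log1p(x))
        out = wilcoxon_markers(counts, labels_for(counts, 20))
        # a few features may clear the fold-change filter by sampling noise,
        # but none reaches significance
        assert (out.q > 0.05).all()

    def test_exact_mode_matches_enumeration(self, rng):
        # n=4 vs 4, continuous values: no ties
        vals = rng.normal(size=(6, 8)) + 5
        counts = frame(vals)
        out = wilcoxon_markers(
            counts, labels_for(counts, 4), min_pct=0.0, logfc_min=-10, method="exact"
        )
        out = out[out.group == "g1"].set_index("feature")
        for f in counts.index:
            expected = exact_ranksum_p(vals[int(f[1:]), :4], vals[int(f[1:]), 4:])
            assert out.loc[f, "p"] == pytest.approx(expected, abs=1e-10)

    def test_min_pct_filters_rare_features(self):
        x = np.zeros((1, 40))
        x[0, [0, 25]] = 5.0  # 5% expressed on both sides
        counts = frame(x)
        out = wilcoxon_markers(counts, labels_for(counts, 20), min_pct=0.1, logfc_min=-10)
        assert len(out) == 0

    def test_strong_marker_detected_and_ranked_first(self, rng):
        x = np.log1p(rng.poisson(2, size=(10, 60)).astype(float))
        x[0, :30] = np.log1p(rng.poisson(40, 30))
        counts = frame(x)
        out = wilcoxon_markers(counts, labels_for(counts, 30))
        g1 = out[out.group == "g1"]
        assert g1.iloc[0].feature == "f0" and g1.iloc[0]["rank"] == 1

    def test_tiny_group_skipped_with_warning(self, rng):
        counts = frame(rng.normal(size=(5, 10)) + 5)
        labels = pd.Series(["solo"] + ["rest"] * 9, index=counts.columns)
        with pytest.warns(UserWarning, match="solo"):
            wilcoxon_markers(counts, labels, min_pct=0.0, logfc_min=-10)


class TestAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        x = rng.normal(size=(8, 30))
        groups = [x[:, :15], x[:, 15:]]
        f, _ = stats.f_oneway(*groups, axis=1)
        t, _ = stats.ttest_ind(*groups, axis=1)  # pooled-variance t
        np.testing.assert_allclose(f, t**2, rtol=1e-10)

    def test_hand_computed_three_group_f(self):
        data = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [6.0, 7.0, 8.0]}
        grand = np.mean(sum(data.values(), []))
        ss_between = sum(3 * (np.mean(v) - grand) ** 2 for v in data.values())
        ss_within = sum(sum((x - np.mean(v)) ** 2 for x in v) for v in data.values())
        f_hand = (ss_between / 2) / (ss_within / 6)
        counts = frame(np.array([data["a"] + data["b"] + data["c"]]))
        labels = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=counts.columns)
        out = anova_markers(counts, labels, fc_min=-10, p_max=1.0)
        f_stat, p = stats.f_oneway(data["a"], data["b"], data["c"])
        assert f_stat == pytest.approx(f_hand)
        assert out.p.iloc[0] == pytest.approx(p)

    def test_type_one_error_rate_near_nominal(self, rng):
        # equal means: the rejection rate of the F test tracks p_max
        # (values kept positive: the table contract is normalized log1p data)
        x = rng.normal(5.0, 1.0, size=(2000, 30))
        counts = frame(x)
        labels = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10, index=counts.columns)
        out = anova_markers(counts, labels, fc_min=-10, p_max=0.05)
        rate = out[out.group == "a"].feature.nunique() / 2000
        assert abs(rate - 0.05) < 0.02

    def test_zero_variance_feature_flagged_not_crashed(self):
        counts = frame(np.ones((2, 12)) * 3)
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=counts.columns)
        out = anova_markers(counts, labels)
        assert out.degenerate.all()


class TestConsensus:
    def ranked(self, features):
        return pd.DataFrame(
            {"feature": features, "group": "g", "rank": range(1, len(features) + 1)}
        )

    def test_identical_tables_return_their_top(self):
        t = self.ranked([f"f{i}" for i in range(300)])
        out = consensus_top200([t, t, t])
        assert out == {f"f{i}" for i in range(200)}

    def test_disjoint_rankings_yield_empty_set(self):
        a = self.ranked([f"a{i}" for i in range(250)])
        b = self.ranked([f"b{i}" for i in range(250)])
        assert consensus_top200([a, b]) == set()

    def test_matches_set_intersection_oracle(self, rng):
        universe = [f"f{i}" for i in range(500)]
        tables = [self.ranked(list(rng.permutation(universe))) for _ in range(3)]
        out = consensus_top200(tables, top_n=200)
        oracle = set(universe)
        for t in tables:
            oracle &= set(t.feature.head(200))
        assert out == oracle

    def test_short_table_used_whole_with_warning(self):
        a = self.ranked([f"f{i}" for i in range(50)])
        b = self.ranked([f"f{i}" for i in range(300)])
        with pytest.warns(UserWarning, match="50"):
            out = consensus_top200([a, b], top_n=200)
        assert out == {f"f{i}" for i in range(50)}


class TestDarTtest:
    def test_planted_fold_change_peak_detected(self, rng):
        base = rng.poisson(2.0, size=(50, 80)).astype(float)
        base[0, :20] = rng.poisson(16.0, 20)  # 8x in the first group
        counts = frame(base, prefix="p")
        labels = pd.Series(["grp"] * 20 + ["rest"] * 60, index=counts.columns)
        dars = dar_ttest(counts, labels)
        assert "p0" in set(dars["grp"].feature)

    def test_null_groups_rarely_yield_dars(self, rng):
        hits = 0
        for _ in range(20):
            counts = frame(rng.poisson(3.0, size=(50, 40)).astype(float), prefix="p")
            labels = labels_for(counts, 20)
            dars = dar_ttest(counts, labels)
            hits += int(sum(len(t) for t in dars.values()) > 0)
        assert hits <= 1  # empty in >= 95% of seeds

    def test_top_k_truncation(self, rng):
        n = 6000
        x = np.vstack(
            [np.concatenate([rng.normal(20, 1, 15), rng.normal(2, 1, 15)]) for _ in range(n)]
        )
        counts = frame(np.abs(x), prefix="p")
        labels = labels_for(counts, 15)
        dars = dar_ttest(counts, labels, top_k=5000)
        assert len(dars["g1"]) == 5000

    def test_monotone_in_thresholds(self, rng):
        base = rng.poisson(2.0, size=(100, 60)).astype(float)
        base[:10, :30] *= 6
        counts = frame(base, prefix="p")
        labels = labels_for(counts, 30)
        loose = set(dar_ttest(counts, labels, p_max=0.01, log2fc_min=0.5)["g1"].feature)
        strict = set(dar_ttest(counts, labels, p_max=1e-3, log2fc_min=1.0)["g1"].feature)
        assert strict <= loose


class TestFisherEnrichment:
    def test_matches_hypergeometric_closed_form(self):
        universe = {f"f{i}" for i in range(40)}
        query = {f"f{i}" for i in range(20)}
        term = {f"f{i}" for i in range(10, 30)}
        out = fisher_enrichment(query, {"t": term}, universe).set_index("term")
        k = len(query & term)
        expected = stats.hypergeom.sf(k - 1, 40, len(term), len(query))
        assert out.loc["t", "p"] == pytest.approx(expected, abs=1e-12)

    def test_disjoint_query_has_p_one(self):
        universe = set(range(100))
        out = fisher_enrichment(set(range(10)), {"t": set(range(50, 60))}, universe)
        assert out.p.iloc[0] == pytest.approx(1.0)

    def test_small_universe_matches_enumeration(self):
        # enumerate all draws of size 3 from a universe of 6
        universe = set("abcdef")
        term = set("abc")
        query = set("abd")
        out = fisher_enrichment(query, {"t": term}, universe)
        k_obs = len(query & term)
        count = 0
        total = 0
        for draw in itertools.combinations(sorted(universe), 3):
            total += 1
            if len(set(draw) & term) >= k_obs:
                count += 1
        assert out.p.iloc[0] == pytest.approx(count / total, abs=1e-12)

    def test_bh_applied_across_terms(self, rng):
        universe = {f"f{i}" for i in range(100)}
        query = set(rng.choice(sorted(universe), 30, replace=False))
        terms = {
            f"t{j}": set(rng.choice(sorted(universe), 20, replace=False)) for j in range(15)
        }
        out = fisher_enrichment(query, terms, universe)
        from egrnkit._utils import bh_qvalues

        order = out.sort_values("term").reset_index()
        np.testing.assert_allclose(
            order.q, bh_qvalues(order.p.to_numpy()), atol=1e-12
        )

    def test_empty_query_raises(self):
        with pytest.raises(ValueError, match="empty"):
            fisher_enrichment(set(), {"t": {1}}, {1, 2})
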