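"""Moderated statistics, permutation FDR, enrichment and survival."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from protstrat.errors import ConfigError
from protstrat.simulate import PanelConfig, generate_panel
from protstrat.stats import (EnrichmentParams, ModeratedTestParams, bh_fdr,
                             enrichment_1d, fisher_enrichment, km_estimate,
                             logrank_test, moderated_t, permutation_fdr)


class TestModeratedT:
    def test_equal_means_give_zero_statistic(self):
        result = moderated_t([1.0, 2.0, 3.0], [3.0, 2.0, 1.0], s0=1.0)
        assert result["statistic"] == pytest.approx(0.0)
        assert result["p"] == pytest.approx(1.0)

    def test_s0_zero_recovers_students_t(self):
        a, b = [10.0, 11.0, 13.0], [14.0, 15.5, 16.0]
        result = moderated_t(a, b, s0=0.0)
        expected = sps.ttest_ind(a, b)
        assert result["statistic"] == pytest.approx(expected.statistic)
        assert result["p"] == pytest.approx(expected.pvalue)

    def test_fixture_matches_hand_computation(self):
        # a = (10,11,12), b = (14,15,16): diff = -4, pooled sd = 1,
        # se = sqrt(2/3), statistic = -4 / (sqrt(2/3) + 2)
        result = moderated_t([10.0, 11.0, 12.0], [14.0, 15.0, 16.0], s0=2.0)
        expected = -4.0 / (math.sqrt(2.0 / 3.0) + 2.0)
        assert result["statistic"] == pytest.approx(expected)
        assert result["difference"] == pytest.approx(-4.0)

    def test_insufficient_values_rejected(self):
        with pytest.raises(ConfigError):
            moderated_t([1.0], [2.0, 3.0], s0=1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=6),
           st.lists(st.floats(-50, 50), min_size=3, max_size=6),
           st.floats(0.0, 5.0), st.floats(0.1, 5.0))
    def test_statistic_magnitude_nonincreasing_in_s0(self, a, b, s0, ds):
        lo = moderated_t(a, b, s0=s0)
        hi = moderated_t(a, b, s0=s0 + ds)
        assert abs(hi["statistic"]) <= abs(lo["statistic"]) + 1e-12


class TestPermutationFdr:
    def test_identical_groups_give_empty_set(self):
        rng = np.random.default_rng(0)
        half = rng.normal(size=(50, 5))
        values = pd.DataFrame(np.hstack([half, half]))
        labels = pd.Series(["A"] * 5 + ["B"] * 5, index=values.columns)
        out = permutation_fdr(values, labels,
                              ModeratedTestParams(s0=2.0, seed=0))
        assert out["significant"].sum() == 0

    def test_planted_eightfold_markers_all_recovered(self):
        rng = np.random.default_rng(1)
        values = rng.normal(20, 0.5, size=(200, 12))
        values[:10, :6] += 3.0  # 8-fold shift in group A
        frame = pd.DataFrame(values)
        labels = pd.Series(["A"] * 6 + ["B"] * 6, index=frame.columns)
        out = permutation_fdr(frame, labels,
                              ModeratedTestParams(s0=2.0, n_permutations=500,
                                                  fdr_threshold=0.05, seed=1))
        assert out["significant"].iloc[:10].all()
        # and essentially nothing else
        assert out["significant"].iloc[10:].mean() < 0.05

    def test_null_significant_fraction_controlled(self):
        fractions = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            values = pd.DataFrame(rng.normal(size=(150, 10)))
            labels = pd.Series(["A"] * 5 + ["B"] * 5, index=values.columns)
            out = permutation_fdr(values, labels,
                                  ModeratedTestParams(s0=2.0,
                                                      n_permutations=250,
                                                      seed=seed))
            fractions.append(out["significant"].mean())
        assert np.mean(fractions) <= 0.10  # twice the nominal 5%


class TestBhFdr:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 7), [0.2] * 7)

    def test_matches_step_up_definition_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            p = rng.uniform(size=rng.integers(5, 400))
            adjusted = bh_fdr(p)
            m = len(p)
            order = np.argsort(p)
            expected = np.empty(m)
            running = 1.0
            for rank in range(m - 1, -1, -1):
                running = min(running, p[order[rank]] * m / (rank + 1))
                expected[order[rank]] = running
            np.testing.assert_allclose(adjusted, expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            bh_fdr([0.5, 1.2])


def two_sided_fisher_oracle(a, b, c, d):
    """Sum of hypergeometric probabilities <= that of the observed table."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    observed = sps.hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= observed * (1 + 1e-7)].sum())


class TestFisherEnrichment:
    def test_balanced_table_p_one(self):
        fg = {"p1", "p2", "c1", "c2"}
        bg = fg | {"p3", "p4", "c3", "c4"}
        annotations = {"cat": {"c1", "c2", "c3", "c4"}}
        out = fisher_enrichment(fg, bg, annotations, EnrichmentParams())
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_p_matches_hypergeometric_enumeration(self):
        # table (3,1;1,5)
        fg = {"a1", "a2", "a3", "b1"}
        bg = fg | {"a4", "b2", "b3", "b4", "b5", "b6"}
        annotations = {"cat": {"a1", "a2", "a3", "a4"}}
        out = fisher_enrichment(fg, bg, annotations, EnrichmentParams())
        assert out["p"].iloc[0] == pytest.approx(
            two_sided_fisher_oracle(3, 1, 1, 5), rel=1e-9)

    def test_small_categories_not_tested(self):
        fg = {"a1"}
        bg = {f"x{i}" for i in range(20)} | {"a1", "a2", "a3"}
        annotations = {"tiny": {"a1", "a2", "a3"}}
        out = fisher_enrichment(fg, bg, annotations,
                                EnrichmentParams(min_category_size=4))
        assert len(out) == 0

    def test_foreground_must_be_subset(self):
        with pytest.raises(ConfigError):
            fisher_enrichment({"x"}, {"y"}, {"c": {"y"}})
        with pytest.raises(ConfigError):
            fisher_enrichment(set(), {"y"}, {"c": {"y"}})


class TestEnrichment1d:
    def test_top_ranks_score_plus_one(self):
        values = pd.Series(np.arange(10.0), index=[f"p{i}" for i in range(10)])
        annotations = {"top": {"p9", "p8", "p7", "p6"}}
        out = enrichment_1d(values, annotations, EnrichmentParams())
        assert out["score"].iloc[0] == pytest.approx(1.0)

    def test_symmetric_placement_scores_zero(self):
        # members at ranks (1, 2, 9, 10) of 10 -> mean ranks equal -> 0
        values = pd.Series(np.arange(10.0), index=[f"p{i}" for i in range(10)])
        annotations = {"sym": {"p0", "p1", "p8", "p9"}}
        out = enrichment_1d(values, annotations, EnrichmentParams())
        assert out["score"].iloc[0] == pytest.approx(0.0)

    def test_random_placement_mean_score_near_zero(self):
        rng = np.random.default_rng(3)
        index = [f"p{i}" for i in range(60)]
        scores = []
        for _ in range(1000):
            values = pd.Series(rng.normal(size=60), index=index)
            members = set(rng.choice(index, size=10, replace=False))
            out = enrichment_1d(values, {"cat": members}, EnrichmentParams())
            scores.append(out["score"].iloc[0])
        assert abs(np.mean(scores)) < 0.02

    def test_category_covering_all_proteins_skipped(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        out = enrichment_1d(values, {"all": set("abcd")}, EnrichmentParams())
        assert len(out) == 0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=8,
                    max_size=30, unique=True),
           st.integers(0, 1 << 30))
    def test_score_bounded_and_antisymmetric(self, values, seed):
        rng = np.random.default_rng(seed)
        index = [f"p{i}" for i in range(len(values))]
        series = pd.Series(values, index=index)
        m = int(rng.integers(4, len(values)))
        members = set(rng.choice(index, size=m, replace=False))
        params = EnrichmentParams()
        out = enrichment_1d(series, {"cat": members}, params)
        if len(out) == 0:
            return
        score = out["score"].iloc[0]
        assert -1.0 - 1e-12 <= score <= 1.0 + 1e-12
        flipped = enrichment_1d(-series, {"cat": members}, params)
        assert flipped["score"].iloc[0] == pytest.approx(-score)


class TestSurvival:
    def test_product_limit_by_hand(self):
        table = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0],
                              "event": [1, 1, 1, 1], "cluster": "A"})
        km = km_estimate(table)
        assert km.at(1.0) == pytest.approx(0.75)
        assert km.at(2.0) == pytest.approx(0.5)
        assert km.median == pytest.approx(2.0)

    def test_all_censored_curve_stays_at_one(self):
        table = pd.DataFrame({"time": [1.0, 2.0, 3.0],
                              "event": [0, 0, 0], "cluster": "A"})
        km = km_estimate(table)
        assert km.at(3.0) == pytest.approx(1.0)
        assert np.isinf(km.median)

    def test_late_censoring_does_not_change_earlier_curve(self):
        base = pd.DataFrame({"time": [1.0, 2.0, 3.0],
                             "event": [1, 1, 1], "cluster": "A"})
        extended = pd.concat([base, pd.DataFrame(
            {"time": [10.0], "event": [0], "cluster": ["A"]})],
            ignore_index=True)
        km_a, km_b = km_estimate(base), km_estimate(extended)
        # the extra subject censored after the last event changes at-risk
        # counts before it, but S is unchanged where no event occurred
        assert km_b.at(5.0) == pytest.approx(km_b.at(3.0))

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(10, size=100)
        table = pd.DataFrame({"time": times, "event": 1, "cluster": "A"})
        km = km_estimate(table)
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            assert km.at(t) == pytest.approx((times > t).mean())

    def test_logrank_symmetric_under_label_swap(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame({
            "time": rng.exponential(10, size=40),
            "event": rng.integers(0, 2, size=40),
            "cluster": ["A"] * 20 + ["B"] * 20})
        chi1, p1 = logrank_test(table)
        swapped = table.assign(cluster=table["cluster"].map(
            {"A": "B", "B": "A"}))
        chi2, p2 = logrank_test(swapped)
        assert chi1 == pytest.approx(chi2)
        assert p1 == pytest.approx(p2)

    def test_separated_arms_strongly_significant(self):
        table = pd.DataFrame({
            "time": np.concatenate([np.linspace(1, 5, 20),
                                    np.linspace(50, 60, 20)]),
            "event": 1, "cluster": ["A"] * 20 + ["B"] * 20})
        _, p = logrank_test(table)
        assert p < 0.001

    def test_single_cluster_rejected(self):
        table = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1],
                              "cluster": "A"})
        with pytest.raises(ConfigError):
            logrank_test(table)
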