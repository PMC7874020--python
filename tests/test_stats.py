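"""Cohort statistics: definitional oracles, permutation checks, ROC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from epinet.stats import (
    demographics_summary,
    difference_scores,
    roc_analysis,
    round_half_away,
    spearman_with_bonferroni,
    two_sample_ttest,
)
from epinet.synthetic import table1_fixture


def brute_force_auc(scores, labels):
    """Concordant-pair counting with ties worth 1/2 — the oracle."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestTwoSampleTtest:
    def test_identical_groups(self):
        r = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # pooled SD = 1, SE = sqrt(2/3), df = 4
        r = two_sample_ttest([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert r.statistic == pytest.approx(-3.6742346, abs=1e-6)
        assert r.p_value == pytest.approx(0.0213116, abs=1e-6)
        assert r.estimate == pytest.approx(-3.0)
        assert (r.n1, r.n2) == (3, 3)

    def test_agrees_with_scipy_pooled(self, rng):
        a, b = rng.normal(size=15), rng.normal(0.5, 1.2, size=12)
        r = two_sample_ttest(a, b)
        t_sp, p_sp = sps.ttest_ind(a, b, equal_var=True)
        assert r.statistic == pytest.approx(t_sp)
        assert r.p_value == pytest.approx(p_sp)

    def test_degenerate_separation_gives_tiny_p(self):
        r = two_sample_ttest([1.0, 1.0], [2.0, 2.0])
        assert r.p_value == np.finfo(float).tiny
        assert r.p_value > 0

    def test_insufficient_group_rejected_by_name(self):
        with pytest.raises(ValueError, match="second group"):
            two_sample_ttest([1.0, 2.0], [3.0])

    def test_matches_permutation_p_on_small_fixture(self, rng):
        a = rng.normal(0.6, 1.0, size=12)
        b = rng.normal(0.0, 1.0, size=10)
        r = two_sample_ttest(a, b)
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(perm[:12].mean() - perm[12:].mean()) >= obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        # permutation and t-based p agree within Monte-Carlo error
        assert abs(r.p_value - p_perm) < 4 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.01

    def test_welch_flag(self, rng):
        a, b = rng.normal(size=10), rng.normal(0, 5, size=25)
        r = two_sample_ttest(a, b, equal_var=False)
        t_sp, p_sp = sps.ttest_ind(a, b, equal_var=False)
        assert r.statistic == pytest.approx(t_sp)
        assert r.p_value == pytest.approx(p_sp)


class TestSpearman:
    def table(self, x, y):
        return pd.DataFrame({"x": x, "y": y})

    def test_monotone_links(self):
        x = np.array([0.3, 0.1, 0.7, 0.5, 0.9])
        t = self.table(x, 2 * x + 1)
        r = spearman_with_bonferroni(t, "x", ["y"], family_size=1)[0]
        assert r.estimate == pytest.approx(1.0)
        t = self.table(x, -(x**3))
        r = spearman_with_bonferroni(t, "x", ["y"], family_size=1)[0]
        assert r.estimate == pytest.approx(-1.0)

    def test_hand_computed_rank_formula(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 total 4 at n=5
        t = self.table([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        r = spearman_with_bonferroni(t, "x", ["y"], family_size=1)[0]
        assert r.estimate == pytest.approx(0.8)

    def test_bonferroni_adjustment_and_cap(self):
        t = self.table([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5])
        r1 = spearman_with_bonferroni(t, "x", ["y"], family_size=1)[0]
        r12 = spearman_with_bonferroni(t, "x", ["y"], family_size=12)[0]
        assert r12.p_value == r1.p_value
        assert r12.adjusted_p >= r12.p_value
        assert r12.adjusted_p == min(1.0, 12 * r12.p_value)

    def test_too_few_complete_cases_flagged(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1.0, np.nan, np.nan]})
        r = spearman_with_bonferroni(t, "x", ["y"], family_size=1)[0]
        assert not r.computable and r.n1 == 1

    def test_pairwise_deletion_effective_n(self):
        t = pd.DataFrame({
            "x": [1.0, 2, 3, 4, 5, 6],
            "y": [1.0, 2, 3, np.nan, 5, 6],
        })
        r = spearman_with_bonferroni(t, "x", ["y"], family_size=1)[0]
        assert r.n1 == 5

    def test_matches_permutation_p_on_small_fixture(self, rng):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7])
        y = np.array([2.0, 1, 4, 3, 7, 5, 6])
        r = spearman_with_bonferroni(self.table(x, y), "x", ["y"], 1)[0]
        obs = abs(sps.spearmanr(x, y).statistic)
        count = sum(
            abs(sps.spearmanr(x, rng.permutation(y)).statistic) >= obs - 1e-12
            for _ in range(5000)
        )
        p_perm = count / 5000
        assert abs(r.p_value - p_perm) < 4 * np.sqrt(p_perm * (1 - p_perm) / 5000) + 0.02


class TestDifferenceScores:
    def table(self):
        return pd.DataFrame({
            "BNT_pre": [10.0, 10.0, np.nan],
            "BNT_post": [10.0, 7.0, 5.0],
        })

    def test_post_minus_pre_and_missing_propagation(self):
        d = difference_scores(self.table(), "BNT")
        assert d[0] == 0.0
        assert d[1] == -3.0  # decline is negative
        assert np.isnan(d[2])

    def test_unknown_test_rejected_with_known_names(self):
        with pytest.raises(KeyError, match="VR-I"):
            difference_scores(self.table(), "nope")


class TestRocAnalysis:
    def test_perfect_separation(self):
        r = roc_analysis([0.1, 0.2, 0.3, 0.4], [False, False, True, True])
        assert r.auc == 1.0
        assert 0.2 < r.selected["youden"] <= 0.3
        i = np.searchsorted(r.thresholds, r.selected["youden"])
        assert r.sensitivity[i] == 1.0 and r.specificity[i] == 1.0

    def test_brute_force_pair_counting_oracle(self):
        # printed alignment: positives {0.4, 0.3} dominate negatives -> 1.0
        scores = [0.1, 0.4, 0.2, 0.3]
        assert roc_analysis(scores, [0, 1, 0, 1]).auc == brute_force_auc(scores, [0, 1, 0, 1]) == 1.0
        # 3-of-4 concordant configuration -> 0.75
        assert roc_analysis(scores, [0, 1, 1, 0]).auc == brute_force_auc(scores, [0, 1, 1, 0]) == 0.75

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_auc_matches_brute_force_and_sklearn_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, size=30).astype(float)  # heavy ties
        labels = rng.random(30) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        r = roc_analysis(scores, labels)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        from sklearn.metrics import roc_auc_score

        assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_null_scores_give_half(self, rng):
        n = 400
        labels = np.repeat([True, False], n // 2)
        scores = rng.normal(size=n)
        r = roc_analysis(scores, labels)
        bound = 3 * np.sqrt((1 / 12) * (2 / (n // 2)))
        assert abs(r.auc - 0.5) < bound

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        labels[0], labels[1] = True, False
        a1 = roc_analysis(scores, labels).auc
        a2 = roc_analysis(np.exp(3 * scores), labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_score_negation_complements_auc(self, rng):
        scores = rng.normal(size=25)  # continuous, tie-free a.s.
        labels = rng.random(25) < 0.5
        labels[0], labels[1] = True, False
        a = roc_analysis(scores, labels).auc
        b = roc_analysis(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_ci_contains_auc_and_is_truncated(self, rng):
        r = roc_analysis([0.1, 0.2, 0.3, 0.4], [False, False, True, True])
        lo, hi = r.ci95
        assert 0.0 <= lo <= r.auc <= hi <= 1.0

    def test_bootstrap_ci_close_to_delong(self, rng):
        scores = rng.normal(size=60) + np.repeat([0.8, 0.0], 30)
        labels = np.repeat([True, False], 30)
        d = roc_analysis(scores, labels, ci_method="delong")
        b = roc_analysis(scores, labels, ci_method="bootstrap", n_bootstrap=500, rng_seed=3)
        assert abs(d.ci95[0] - b.ci95[0]) < 0.1 and abs(d.ci95[1] - b.ci95[1]) < 0.1

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            roc_analysis([1.0, 2.0], [True, True])

    def test_threshold_selection_constraints(self, rng):
        scores = np.array([0.1, 0.2, 0.25, 0.3, 0.5, 0.6])
        labels = np.array([0, 0, 1, 0, 1, 1], dtype=bool)
        r = roc_analysis(scores, labels)
        for key in ("youden", "max_sensitivity", "max_specificity"):
            assert r.selected[key] in scores
        i = list(r.thresholds).index(r.selected["max_sensitivity"])
        assert r.specificity[i] > 0
        i = list(r.thresholds).index(r.selected["max_specificity"])
        assert r.sensitivity[i] > 0

    def test_simulated_cohorts_match_binormal_auc(self):
        # d = 2 SD separation at the cohort's 12/7 split:
        # E[AUC] = Phi(d / sqrt(2)) ~ 0.921, averaged over 200 cohorts
        from epinet.synthetic import CohortSpec, generate_cohort

        aucs = []
        for seed in range(200):
            t = generate_cohort(CohortSpec(rng_seed=seed))
            aucs.append(roc_analysis(t["intraconnectivity"], t["seizure_free"]).auc)
        expected = sps.norm.cdf(2.0 / np.sqrt(2.0))
        assert np.mean(aucs) == pytest.approx(expected, abs=0.05)

    def test_zero_separation_cohort_auc_near_half(self):
        from epinet.synthetic import CohortSpec, generate_cohort

        aucs = []
        for seed in range(200):
            spec = CohortSpec(mean_conn_free=0.3, mean_conn_not_free=0.3, rng_seed=seed)
            t = generate_cohort(spec)
            aucs.append(roc_analysis(t["intraconnectivity"], t["seizure_free"]).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    p=st.floats(min_value=1e-12, max_value=1.0),
    m=st.integers(min_value=1, max_value=100),
)
def test_bonferroni_properties(p, m):
    """min(1, m*p) never decreases p and saturates at 1."""
    adj = min(1.0, m * p)
    assert adj >= p
    if m * p >= 1:
        assert adj == 1.0


class TestDemographics:
    def test_table1_counts_match_printed_report(self):
        d = demographics_summary(table1_fixture())
        assert d["n_patients"] == 19
        assert d["seizure_free"]["Yes"] == {"count": 12, "percent": 63}
        assert d["seizure_free"]["No"] == {"count": 7, "percent": 37}
        assert d["surgery_side"]["Left"] == {"count": 15, "percent": 79}
        assert d["surgery_side"]["Right"] == {"count": 4, "percent": 21}
        assert d["age"]["min"] == 17

    def test_missing_columns_reported_absent(self):
        d = demographics_summary(pd.DataFrame({"id": ["a"], "age": [30]}))
        assert "gender" not in d and "age" in d

    @pytest.mark.parametrize("x,expected", [(0.5, 1), (1.5, 2), (-0.5, -1), (62.9, 63), (36.8, 37)])
    def test_rounding_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected
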