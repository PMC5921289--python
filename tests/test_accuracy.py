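"""Two-by-two construction, accuracy metrics, ROC/AUC and AUC comparison."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harmscales import (
    Comparison,
    TwoByTwo,
    accuracy_metrics,
    build_two_by_two,
    compare_auc_subgroups,
    pooled_accuracy,
    roc_curve,
)
from harmscales.accuracy import ADJACENT_LOW_MOD, ADJACENT_MOD_HIGH, BINARY, EXACT
from harmscales.datasets import reference_count_tables
from harmscales.errors import UndefinedMetricError
from harmscales.missingness import CompletedCohort
from harmscales.scales import builtin_definitions

from conftest import make_episode


def _expand(counts):
    cats, outs = {}, {}
    i = 0
    for cat, (pos, neg) in counts.items():
        for k in range(pos + neg):
            cats[f"x{i}"] = cat
            outs[f"x{i}"] = k < pos
            i += 1
    return cats, outs


class TestBuildTwoByTwo:
    def test_binary_from_reference_counts(self):
        cats, outs = _expand(reference_count_tables("repeat")["MSHR"])
        t = build_two_by_two(cats, outs, Comparison("MSHR", BINARY))
        assert (t.tp, t.fp, t.fn, t.tn, t.excluded) == (1110, 2432, 23, 435, 0)

    def test_adjacent_low_mod_excludes_high(self):
        cats, outs = _expand(reference_count_tables("repeat")["SPS"])
        t = build_two_by_two(cats, outs, Comparison("SPS", ADJACENT_LOW_MOD))
        assert (t.tp, t.fp, t.fn, t.tn) == (251, 642, 781, 2029)
        assert t.excluded == 297
        assert t.n_analysed == 4000

    def test_adjacent_mod_high_excludes_low(self):
        cats, outs = _expand(reference_count_tables("repeat")["SPS"])
        t = build_two_by_two(cats, outs, Comparison("SPS", ADJACENT_MOD_HIGH))
        assert (t.tp, t.fp, t.fn, t.tn, t.excluded) == (101, 196, 251, 642, 2810)

    def test_all_low_binary_is_degenerate(self):
        cats = {"a": "low", "b": "low"}
        outs = {"a": True, "b": False}
        t = build_two_by_two(cats, outs, Comparison("MSHR", BINARY))
        assert (t.tp, t.fp) == (0, 0)

    def test_mismatched_coverage_rejected(self):
        with pytest.raises(ValueError, match="same episodes"):
            build_two_by_two({"a": "low"}, {"b": True}, Comparison("MSHR", BINARY))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 0, 0, 0)


class TestAccuracyMetrics:
    def test_reference_binary_row(self):
        rep = accuracy_metrics(TwoByTwo(1110, 2432, 23, 435))
        assert rep.sensitivity.value == pytest.approx(0.9797, abs=5e-5)
        assert rep.specificity.value == pytest.approx(0.1517, abs=5e-5)
        assert rep.ppv.value == pytest.approx(0.3134, abs=5e-5)
        assert rep.npv.value == pytest.approx(0.9498, abs=5e-5)
        assert rep.dor.value == pytest.approx(8.632, abs=5e-3)
        assert rep.lr_pos.value == pytest.approx(1.155, abs=5e-4)
        assert rep.lr_neg.value == pytest.approx(0.134, abs=5e-4)

    def test_perfect_classifier(self):
        rep = accuracy_metrics(TwoByTwo(50, 0, 0, 50))
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            assert getattr(rep, name).value == 1.0

    def test_three_category_cells(self):
        rep = accuracy_metrics(TwoByTwo(14, 30, 99, 276))
        assert rep.sensitivity.value == pytest.approx(0.1239, abs=5e-5)
        assert rep.specificity.value == pytest.approx(0.9020, abs=5e-5)

    def test_empty_denominator_is_undefined(self):
        rep = accuracy_metrics(TwoByTwo(0, 5, 0, 5))
        assert not rep.sensitivity.defined
        assert rep.specificity.defined

    def test_zero_cell_dor_undefined_without_continuity(self):
        rep = accuracy_metrics(TwoByTwo(0, 43, 3, 369))
        assert not rep.dor.defined
        with_cc = accuracy_metrics(TwoByTwo(0, 43, 3, 369), continuity=True)
        assert with_cc.dor.defined

    def test_wilson_interval_reproduces_published_bounds(self):
        rep = accuracy_metrics(TwoByTwo(1110, 2432, 23, 435))
        assert round(100 * rep.sensitivity.ci_low) == 97
        assert round(100 * rep.sensitivity.ci_high) == 99
        assert round(100 * rep.specificity.ci_low) == 14
        assert round(100 * rep.specificity.ci_high) == 17

    def test_exact_interval_for_small_counts(self):
        rep = accuracy_metrics(TwoByTwo(16, 3494, 2, 450), proportion_ci=EXACT)
        assert round(100 * rep.sensitivity.ci_low) == 65
        assert round(100 * rep.sensitivity.ci_high) == 99

    def test_point_estimates_invariant_under_cell_scaling(self):
        a = accuracy_metrics(TwoByTwo(10, 20, 5, 40))
        b = accuracy_metrics(TwoByTwo(30, 60, 15, 120))
        for name in ("sensitivity", "specificity", "ppv", "npv",
                     "lr_pos", "lr_neg", "dor"):
            assert getattr(a, name).value == pytest.approx(getattr(b, name).value)

    def test_intervals_narrow_with_sample_size(self):
        small = accuracy_metrics(TwoByTwo(10, 20, 5, 40))
        large = accuracy_metrics(TwoByTwo(100, 200, 50, 400))
        assert (large.sensitivity.ci_high - large.sensitivity.ci_low) < (
            small.sensitivity.ci_high - small.sensitivity.ci_low
        )

    @given(
        tp=st.integers(1, 200),
        fp=st.integers(1, 200),
        fn=st.integers(1, 200),
        tn=st.integers(1, 200),
    )
    @settings(max_examples=100, deadline=None)
    def test_bayes_consistency_between_predictive_values_and_lrs(
        self, tp, fp, fn, tn
    ):
        """PPV odds = prevalence odds * LR+, NPV odds = (1/prev odds) / LR-."""
        rep = accuracy_metrics(TwoByTwo(tp, fp, fn, tn))
        prev_odds = (tp + fn) / (fp + tn)
        ppv_odds = rep.ppv.value / (1 - rep.ppv.value)
        assert ppv_odds == pytest.approx(prev_odds * rep.lr_pos.value)
        npv_odds = rep.npv.value / (1 - rep.npv.value)
        assert npv_odds == pytest.approx(1 / (prev_odds * rep.lr_neg.value))
        assert rep.dor.value == pytest.approx(
            rep.lr_pos.value / rep.lr_neg.value
        )


def brute_force_auc(scores, outcomes) -> float:
    """Mann-Whitney concordance: P(score_pos > score_neg) with ties = 1/2."""
    pos = [s for s, y in zip(scores, outcomes) if y]
    neg = [s for s, y in zip(scores, outcomes) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        roc = roc_curve([0, 1, 2, 3], [False, False, True, True])
        assert roc.auc == 1.0

    def test_chance_level_for_uninformative_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 10, size=4000)
        outcomes = rng.random(4000) < 0.3
        roc = roc_curve(list(scores), list(outcomes))
        assert roc.auc == pytest.approx(0.5, abs=0.03)

    def test_six_episode_worked_set_matches_concordance(self):
        scores = [0, 1, 1, 2, 3, 3]
        outcomes = [False, False, True, False, True, True]
        roc = roc_curve(scores, outcomes)
        assert roc.auc == pytest.approx(brute_force_auc(scores, outcomes), abs=1e-12)

    def test_single_outcome_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_curve([1, 2, 3], [True, True, True])

    def test_points_monotone_and_anchored(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 5, 100)
        outcomes = rng.random(100) < 0.4
        roc = roc_curve(list(scores), list(outcomes))
        assert (np.diff(roc.points[:, 0]) >= 0).all()
        assert (np.diff(roc.points[:, 1]) >= 0).all()
        assert tuple(roc.points[0]) == (0.0, 0.0)
        assert tuple(roc.points[-1]) == (1.0, 1.0)

    @given(st.data())
    @settings(max_examples=150, deadline=None)
    def test_trapezoidal_auc_equals_concordance(self, data):
        n = data.draw(st.integers(4, 50))
        scores = data.draw(
            st.lists(st.integers(0, 8), min_size=n, max_size=n)
        )
        outcomes = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n)
        )
        if not (any(outcomes) and not all(outcomes)):
            outcomes[0], outcomes[-1] = True, False
        roc = roc_curve(scores, outcomes)
        assert roc.auc == pytest.approx(
            brute_force_auc(scores, outcomes), abs=1e-12
        )

    def test_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        scores = rng.integers(0, 6, 500)
        outcomes = (rng.random(500) < 0.3 + 0.05 * scores).astype(bool)
        roc = roc_curve(list(scores), list(outcomes))
        assert roc.auc == pytest.approx(
            roc_auc_score(outcomes, scores), abs=1e-12
        )

    def test_binary_classifier_auc_closed_form(self):
        rng = np.random.default_rng(9)
        scores = rng.integers(0, 2, 400)
        outcomes = (rng.random(400) < 0.25 + 0.3 * scores).astype(bool)
        roc = roc_curve(list(scores), list(outcomes))
        t = build_two_by_two(
            {str(i): "moderate_high" if s else "low" for i, s in enumerate(scores)},
            {str(i): bool(o) for i, o in enumerate(outcomes)},
            Comparison("MSHR", BINARY),
        )
        rep = accuracy_metrics(t)
        closed = (rep.sensitivity.value + rep.specificity.value) / 2
        assert roc.auc == pytest.approx(closed, abs=1e-12)


class TestCompareAuc:
    def test_identical_groups_give_zero_statistic(self):
        chi2, df, p = compare_auc_subgroups([(0.7, 0.02), (0.7, 0.02)])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_two_groups_reduce_to_z_squared(self):
        chi2, df, p = compare_auc_subgroups([(0.61, 0.025), (0.51, 0.018)])
        z = (0.61 - 0.51) / math.sqrt(0.025**2 + 0.018**2)
        assert chi2 == pytest.approx(z**2)
        assert p == pytest.approx(0.0012, abs=2e-4)

    def test_three_groups_match_brute_force(self):
        groups = [(0.70, 0.02), (0.64, 0.03), (0.58, 0.025)]
        chi2, df, p = compare_auc_subgroups(groups)
        w = [1 / se**2 for _, se in groups]
        abar = sum(wi * a for wi, (a, _) in zip(w, groups)) / sum(w)
        brute = sum(wi * (a - abar) ** 2 for wi, (a, _) in zip(w, groups))
        assert chi2 == pytest.approx(brute)
        assert df == 2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_auc_subgroups([(0.7, 0.02)])


class TestPooledAccuracy:
    def _cohort(self, seed=0):
        rng = np.random.default_rng(seed)
        eps = []
        outcomes = {}
        for i in range(200):
            present = tuple(
                n for n in ("history_self_harm", "previous_psych_treatment")
                if rng.random() < 0.5
            )
            eps.append(make_episode(f"e{i}", pid=f"p{i}", present=present))
            outcomes[f"e{i}"] = bool(rng.random() < (0.4 if present else 0.15))
        return eps, outcomes

    def test_single_imputation_equals_plain_metrics(self):
        eps, outcomes = self._cohort()
        d = builtin_definitions()["MSHR"]
        comp = Comparison("MSHR", BINARY)
        pooled = pooled_accuracy([CompletedCohort(1, tuple(eps))], d, comp, outcomes)
        cats = {
            e.episode_id: ("moderate_high" if any(
                e.items[n].value == "present" for n, _ in d.items
            ) else "low")
            for e in eps
        }
        direct = accuracy_metrics(build_two_by_two(cats, outcomes, comp))
        assert pooled.sensitivity.value == pytest.approx(direct.sensitivity.value)
        assert pooled.m == 1

    def test_identical_cohorts_pool_to_single_cohort_point(self):
        eps, outcomes = self._cohort(1)
        d = builtin_definitions()["MSHR"]
        comp = Comparison("MSHR", BINARY)
        single = pooled_accuracy([CompletedCohort(1, tuple(eps))], d, comp, outcomes)
        triple = pooled_accuracy(
            [CompletedCohort(k, tuple(eps)) for k in (1, 2, 3)], d, comp, outcomes
        )
        assert triple.m == 3
        assert triple.sensitivity.value == pytest.approx(
            single.sensitivity.value, abs=1e-9
        )
        assert triple.dor.value == pytest.approx(single.dor.value, abs=1e-9)
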