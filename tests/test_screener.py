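"""Lookup-table screening rules, exhaustive search and stratified evaluation.

The exhaustive search is checked against a deliberately naive oracle written
here: plain-Python pattern tabulation per subset, and (for tiny k) direct
enumeration of every deterministic pattern -> label assignment.
"""

import itertools
import math

import numpy as np
import pytest

from apqscreen import (
    CohortValidationError,
    Cohort,
    confusion_from_labels,
    evaluate_combination,
    evaluate_lookup,
    exhaustive_search,
    fit_lookup,
    predict_lookup,
    rank_single_items,
    stratified_evaluation,
)
from apqscreen.reference import PUBLISHED_ITEMS
from apqscreen.screener import MissingResponseError, encode_patterns
from apqscreen.simulate import SimulationParams, reference_params, simulate_cohort

from conftest import make_random_cohort


# ---------------------------------------------------------------------------
# Independent oracle: naive majority-rule fitting and scoring
# ---------------------------------------------------------------------------

def oracle_fit_and_score(cohort, items):
    """Plain-dict majority fit; returns (mapping, mce, auc) by resubstitution."""
    sub = np.nan_to_num(cohort.columns(items), nan=0.0).astype(int)
    tallies = {}
    for row, label in zip(map(tuple, sub), cohort.gold_label):
        pos, neg = tallies.get(row, (0, 0))
        tallies[row] = (pos + int(label), neg + int(not label))
    mapping = {}
    for pattern in itertools.product((0, 1), repeat=len(items)):
        pos, neg = tallies.get(pattern, (0, 0))
        mapping[pattern] = pos > neg  # ties and unseen -> negative
    pred = np.array([mapping[tuple(row)] for row in sub])
    gold = cohort.gold_label
    tp = int((pred & gold).sum()); fp = int((pred & ~gold).sum())
    fn = int((~pred & gold).sum()); tn = int((~pred & ~gold).sum())
    mce = (fp + fn) / len(gold)
    auc = (tp / (tp + fn) + tn / (tn + fp)) / 2
    return mapping, mce, auc


def oracle_min_mce_over_all_mappings(cohort, items):
    """Minimum resubstitution MCE over every deterministic lookup table."""
    sub = np.nan_to_num(cohort.columns(items), nan=0.0).astype(int)
    codes = sub @ (1 << np.arange(len(items)))
    n_patterns = 2 ** len(items)
    best = math.inf
    for assignment in range(2 ** n_patterns):
        pred = np.array([(assignment >> c) & 1 for c in codes], dtype=bool)
        mce = float((pred != cohort.gold_label).mean())
        best = min(best, mce)
    return best


# ---------------------------------------------------------------------------
# Fitting, prediction and evaluation on the published reconstruction
# ---------------------------------------------------------------------------

class TestFitOnPublishedReconstruction:
    def test_mapping_matches_printed_indications(self, reconstructed_cohort,
                                                 published_table):
        clf = fit_lookup(reconstructed_cohort, PUBLISHED_ITEMS)
        for row in published_table.rows:
            if row.n > 0:
                assert clf.label_for(row.pattern) == row.indicated
            else:  # unseen patterns default to the screening-negative call
                assert clf.label_for(row.pattern) == "no asthma"

    def test_exact_tie_resolves_negative(self, reconstructed_cohort):
        clf = fit_lookup(reconstructed_cohort, PUBLISHED_ITEMS)
        assert clf.label_for((True, False, False, False)) == "no asthma"

    def test_predictions_give_204_true_positives(self, reconstructed_cohort):
        clf = fit_lookup(reconstructed_cohort, PUBLISHED_ITEMS)
        pred = predict_lookup(clf, reconstructed_cohort)
        cm = confusion_from_labels(pred, reconstructed_cohort.gold_label)
        assert cm.tp == 204
        assert cm.n_positive == 253

    def test_resubstitution_metrics(self, reconstructed_cohort):
        clf = fit_lookup(reconstructed_cohort, PUBLISHED_ITEMS)
        m = evaluate_lookup(clf, reconstructed_cohort)
        assert m.sensitivity.value == pytest.approx(204 / 253)
        assert m.specificity.value == pytest.approx(304 / 361)

    def test_single_item_ranking_led_by_wheeze(self, reconstructed_cohort):
        ranking = rank_single_items(reconstructed_cohort)
        item, m = ranking[0]
        assert item == "wheezing_today"
        assert round(m.sensitivity.value, 3) == 0.802
        assert round(m.specificity.value, 3) == 0.842


class TestLookupBasics:
    def test_perfect_item_maps_identity(self):
        rng = np.random.default_rng(0)
        gold = rng.random(50) < 0.4
        cohort = Cohort(
            responses=gold[:, None].astype(float), item_ids=("perfect",),
            gold_label=gold, age_months=rng.integers(2, 60, 50),
        )
        clf = fit_lookup(cohort, ["perfect"])
        assert clf.label_for((True,)) == "asthma"
        assert clf.label_for((False,)) == "no asthma"
        np.testing.assert_array_equal(predict_lookup(clf, cohort), gold)

    def test_unknown_item_and_empty_cohort(self, reconstructed_cohort):
        with pytest.raises(KeyError):
            fit_lookup(reconstructed_cohort, ["nonexistent"])
        empty = reconstructed_cohort.subset(
            np.zeros(reconstructed_cohort.n_children, dtype=bool))
        with pytest.raises(CohortValidationError, match="empty"):
            fit_lookup(empty, PUBLISHED_ITEMS)

    def test_missing_policy_error_names_child(self):
        cohort = Cohort(
            responses=np.array([[1.0], [np.nan]]), item_ids=("q1",),
            gold_label=[True, False], age_months=[10, 12],
            child_id=["kid_a", "kid_b"],
        )
        with pytest.raises(MissingResponseError, match="kid_b"):
            encode_patterns(cohort, ["q1"], missing_policy="error")
        clf = fit_lookup(cohort, ["q1"])  # impute_no default tolerates it
        assert len(predict_lookup(clf, cohort)) == 2

    def test_uninformative_item_has_chance_auc(self):
        rng = np.random.default_rng(3)
        n = 20_000
        cohort = Cohort(
            responses=(rng.random((n, 1)) < 0.5).astype(float),
            item_ids=("noise",),
            gold_label=rng.random(n) < 0.4,
            age_months=rng.integers(2, 60, n),
        )
        (_, m), = rank_single_items(cohort)
        assert abs(m.auc.value - 0.5) < 0.02


# ---------------------------------------------------------------------------
# Exhaustive search
# ---------------------------------------------------------------------------

class TestExhaustiveSearch:
    def test_matches_bruteforce_ranking_on_toys(self):
        rng = np.random.default_rng(42)
        for _ in range(8):
            cohort = make_random_cohort(rng, n_children=int(rng.integers(30, 120)),
                                        n_items=6)
            for k in (1, 2, 3):
                report = exhaustive_search(cohort, k=k, top_n=None)
                assert report.n_subsets_evaluated == math.comb(6, k)
                oracle = sorted(
                    (
                        (-score[2], score[1], items)
                        for items in itertools.combinations(sorted(cohort.item_ids), k)
                        for score in [oracle_fit_and_score(cohort, items)]
                    ),
                )
                assert [r.items for r in report] == [o[2] for o in oracle]
                for r, o in zip(report, oracle):
                    assert r.metrics.mce.value == pytest.approx(o[1])

    def test_fitted_rule_is_mce_optimal_for_small_k(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            cohort = make_random_cohort(rng, n_children=80, n_items=4)
            for k in (1, 2):
                for items in itertools.combinations(cohort.item_ids, k):
                    clf = fit_lookup(cohort, items)
                    m = evaluate_lookup(clf, cohort)
                    assert m.mce.value == pytest.approx(
                        oracle_min_mce_over_all_mappings(cohort, items)
                    )

    def test_perfect_item_dominates_pairs(self):
        rng = np.random.default_rng(11)
        gold = rng.random(100) < 0.5
        responses = (rng.random((100, 6)) < 0.5).astype(float)
        responses[:, 2] = gold  # plant a perfect item
        cohort = Cohort(
            responses=responses, item_ids=tuple(f"q{j}" for j in range(6)),
            gold_label=gold, age_months=rng.integers(2, 60, 100),
        )
        report = exhaustive_search(cohort, k=2, top_n=None)
        n_perfect_pairs = 5  # pairs containing the perfect item
        for r in report[:n_perfect_pairs]:
            assert "q2" in r.items
            assert r.metrics.mce.value == 0.0

    def test_k_equal_to_item_count_returns_single_combination(self):
        rng = np.random.default_rng(1)
        cohort = make_random_cohort(rng, n_children=40, n_items=3)
        report = exhaustive_search(cohort, k=3, top_n=None)
        assert len(report) == 1
        assert report.best.items == tuple(sorted(cohort.item_ids))

    def test_k_exceeding_item_count_rejected(self):
        rng = np.random.default_rng(1)
        cohort = make_random_cohort(rng, n_children=40, n_items=3)
        with pytest.raises(CohortValidationError, match="exceeds"):
            exhaustive_search(cohort, k=4)

    def test_determinism(self):
        rng = np.random.default_rng(9)
        cohort = make_random_cohort(rng, n_children=150, n_items=8)
        r1 = exhaustive_search(cohort, k=3, top_n=5)
        r2 = exhaustive_search(cohort, k=3, top_n=5)
        assert [r.items for r in r1] == [r.items for r in r2]
        assert [r.metrics.auc.value for r in r1] == [r.metrics.auc.value for r in r2]

    def test_top_n_head_matches_full_ranking(self):
        rng = np.random.default_rng(13)
        cohort = make_random_cohort(rng, n_children=100, n_items=7)
        full = exhaustive_search(cohort, k=2, top_n=None)
        head = exhaustive_search(cohort, k=2, top_n=4)
        assert [r.items for r in head] == [r.items for r in full][:4]

    def test_refinement_never_increases_mce(self):
        """Adding an item to a fixed set cannot worsen resubstitution MCE."""
        rng = np.random.default_rng(21)
        for _ in range(5):
            cohort = make_random_cohort(rng, n_children=90, n_items=5)
            items = list(cohort.item_ids)
            rng.shuffle(items)
            mces = []
            for k in range(1, 5):
                clf = fit_lookup(cohort, items[:k])
                mces.append(evaluate_lookup(clf, cohort).mce.value)
            assert all(b <= a + 1e-12 for a, b in zip(mces, mces[1:]))

    def test_mce_criterion_ordering(self):
        rng = np.random.default_rng(17)
        cohort = make_random_cohort(rng, n_children=80, n_items=5)
        report = exhaustive_search(cohort, k=2, criterion="mce", top_n=None)
        mces = [r.metrics.mce.value for r in report]
        assert mces == sorted(mces)

    def test_sensitivity_at_min_specificity_criterion(self):
        rng = np.random.default_rng(19)
        cohort = make_random_cohort(rng, n_children=120, n_items=5)
        report = exhaustive_search(
            cohort, k=2, criterion="sensitivity_at_min_specificity",
            min_specificity=0.5, top_n=None,
        )
        meeting = [r for r in report if r.metrics.specificity.value >= 0.5]
        # all combos meeting the floor rank ahead of all that miss it
        assert [r.rank for r in meeting] == list(range(1, len(meeting) + 1))
        ses = [r.metrics.sensitivity.value for r in meeting]
        assert ses == sorted(ses, reverse=True)


# ---------------------------------------------------------------------------
# Stratified evaluation and cross-validation
# ---------------------------------------------------------------------------

class TestStratifiedEvaluation:
    def test_reference_strata_composition(self):
        cohort = simulate_cohort(reference_params(seed=3, n_children=6140))
        strata = stratified_evaluation(cohort, items=["wheezing_today"])
        below, above = strata["<24mo"], strata[">=24mo"]
        n = cohort.n_children
        assert abs(below.n / n - 0.801) < 3 * np.sqrt(0.801 * 0.199 / n)
        se_prev = 3 * np.sqrt(0.39 * 0.61 / below.n)
        assert abs(below.prevalence - 0.390) < se_prev
        assert abs(above.prevalence - 0.500) < 3 * np.sqrt(0.25 / above.n)

    def test_empty_stratum_rejected(self):
        rng = np.random.default_rng(2)
        cohort = make_random_cohort(rng, n_children=30, n_items=2)
        cohort.age_months[:] = 10
        with pytest.raises(CohortValidationError, match=">=24mo"):
            stratified_evaluation(cohort, items=["q0"])

    def test_confusion_matrices_are_additive_over_strata(self):
        rng = np.random.default_rng(5)
        cohort = make_random_cohort(rng, n_children=200, n_items=3)
        clf = fit_lookup(cohort, ["q0", "q1"])
        whole = confusion_from_labels(predict_lookup(clf, cohort), cohort.gold_label)
        below = cohort.subset(cohort.age_months < 24)
        above = cohort.subset(cohort.age_months >= 24)
        parts = [
            confusion_from_labels(predict_lookup(clf, s), s.gold_label)
            for s in (below, above)
        ]
        assert parts[0] + parts[1] == whole

    def test_ranking_mode_per_stratum(self):
        cohort = simulate_cohort(reference_params(seed=8, n_children=2000))
        strata = stratified_evaluation(cohort)
        for result in strata.values():
            assert result.ranking is not None
            assert result.ranking[0][0] == "wheezing_today"


class TestCrossValidation:
    def test_cv_runs_and_is_no_more_optimistic_than_resubstitution(self):
        cohort = simulate_cohort(reference_params(seed=4, n_children=1000))
        items = ["wheezing_today", "wheezing_recent"]
        resub = evaluate_combination(cohort, items)
        cv = evaluate_combination(cohort, items, cv_folds=5, seed=0)
        assert 0.0 <= cv.auc.value <= 1.0
        assert cv.auc.value <= resub.auc.value + 0.05

    def test_cv_requires_two_folds(self):
        cohort = simulate_cohort(reference_params(seed=4, n_children=200))
        with pytest.raises(ValueError):
            evaluate_combination(cohort, ["wheezing_today"], cv_folds=1)
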