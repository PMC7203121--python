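"""Majority-rule lookup-table screening rules and exhaustive subset search.

The screening rule at the heart of this package is a lookup table: pick k
questionnaire items, and map each of the 2^k yes/no answer patterns to the
gold-standard class that is most prevalent among the children showing that
pattern.  Fitting is a pure tabulation; evaluation is resubstitution on the
fitting cohort unless cross-validation is requested.  The best rule is found
by exhaustively scoring every k-item subset — for 88 items and k=4 that is
C(88,4) = 2,331,890 subsets, which stays tractable by encoding each child's
answers on the candidate subset as a small integer pattern code and counting
codes for whole batches of subsets with vectorised bincounts.

Ties (patterns split exactly 50/50 between classes) and patterns never seen
during fitting both default to the screening-conservative "no asthma" call;
both policies are recorded on the fitted classifier and configurable.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .cohort import (
    Cohort,
    CohortValidationError,
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    PatternTable,
    pattern_table_from_cohort,
)
from .metrics import (
    DEFAULT_CI_METHOD,
    ConfusionMatrix,
    DiagnosticMetrics,
    confusion_from_labels,
    metrics_from_confusion,
)

__all__ = [
    "LookupClassifier",
    "CombinationResult",
    "SearchReport",
    "StratumResult",
    "MissingResponseError",
    "encode_patterns",
    "fit_lookup",
    "predict_lookup",
    "evaluate_lookup",
    "evaluate_combination",
    "rank_single_items",
    "exhaustive_search",
    "stratified_evaluation",
]

logger = logging.getLogger(__name__)

TIE_POLICIES = ("negative", "positive")
UNSEEN_POLICIES = ("negative", "positive")
MISSING_POLICIES = ("impute_no", "drop", "error")

DEFAULT_AGE_CUT_MONTHS = 24


class MissingResponseError(ValueError):
    """A child has a missing response on a classifier item under policy 'error'."""


def encode_patterns(
    cohort: Cohort, items: Sequence[str], missing_policy: str = "impute_no"
) -> np.ndarray:
    """Encode each child's answers over ``items`` as an integer pattern code.

    Item t contributes bit t (first item = least significant).  Under policy
    ``impute_no`` missing answers count as "no"; under ``drop`` affected
    children receive code -1; under ``error`` they raise
    :class:`MissingResponseError` naming the child.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    sub = cohort.columns(items)
    nan_rows = np.isnan(sub).any(axis=1)
    if nan_rows.any():
        if missing_policy == "error":
            idx = int(np.flatnonzero(nan_rows)[0])
            ident = cohort.child_id[idx] if cohort.child_id is not None else idx
            raise MissingResponseError(
                f"child {ident!r} has a missing response on a selected item"
            )
        sub = np.nan_to_num(sub, nan=0.0)
    bits = sub.astype(np.int64)
    weights = (1 << np.arange(len(items), dtype=np.int64))
    codes = bits @ weights
    if missing_policy == "drop":
        codes[nan_rows] = -1
    return codes


@dataclass(frozen=True)
class LookupClassifier:
    """A fitted answer-pattern -> diagnosis lookup table.

    ``mapping`` holds one boolean per pattern code (True = asthma syndrome),
    indexed by the integer code produced by :func:`encode_patterns` over
    ``items``.
    """

    items: tuple[str, ...]
    mapping: np.ndarray
    tie_policy: str = "negative"
    unseen_policy: str = "negative"

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        mapping = np.asarray(self.mapping, dtype=bool)
        object.__setattr__(self, "mapping", mapping)
        k = len(self.items)
        if k < 1:
            raise CohortValidationError("a lookup classifier needs at least one item")
        if mapping.shape != (2 ** k,):
            raise CohortValidationError(
                f"mapping must cover all {2 ** k} patterns, got shape {mapping.shape}"
            )
        if self.tie_policy not in TIE_POLICIES:
            raise ValueError(f"unknown tie policy {self.tie_policy!r}")
        if self.unseen_policy not in UNSEEN_POLICIES:
            raise ValueError(f"unknown unseen policy {self.unseen_policy!r}")

    @property
    def k(self) -> int:
        return len(self.items)

    def label_for(self, pattern: Sequence[bool]) -> str:
        """Indicated diagnosis for one yes/no answer pattern."""
        code = sum((1 << t) for t, v in enumerate(pattern) if v)
        return LABEL_POSITIVE if self.mapping[code] else LABEL_NEGATIVE

    def mapping_dict(self) -> dict[tuple[bool, ...], str]:
        k = self.k
        return {
            tuple(bool((code >> t) & 1) for t in range(k)):
                (LABEL_POSITIVE if self.mapping[code] else LABEL_NEGATIVE)
            for code in range(2 ** k)
        }


def _majority_mapping(
    counts_pos: np.ndarray,
    counts_neg: np.ndarray,
    tie_policy: str,
    unseen_policy: str,
) -> np.ndarray:
    """Majority vote per pattern with explicit tie and unseen resolution."""
    seen = (counts_pos + counts_neg) > 0
    if tie_policy == "negative":
        mapping = counts_pos > counts_neg
    else:
        mapping = seen & (counts_pos >= counts_neg)
    if unseen_policy == "positive":
        mapping = mapping | ~seen
    return mapping


def fit_lookup(
    cohort: Cohort,
    items: Sequence[str],
    tie_policy: str = "negative",
    unseen_policy: str = "negative",
    missing_policy: str = "impute_no",
) -> LookupClassifier:
    """Fit the majority-rule lookup table for an item subset.

    Each observed pattern is labelled with the majority gold-standard class
    among the children showing it; exact ties and patterns with no children
    default to "no asthma".
    """
    if cohort.n_children == 0:
        raise CohortValidationError("cannot fit a lookup classifier on an empty cohort")
    items = tuple(items)
    codes = encode_patterns(cohort, items, missing_policy=missing_policy)
    keep = codes >= 0
    n_patterns = 2 ** len(items)
    counts_pos = np.bincount(
        codes[keep & cohort.gold_label], minlength=n_patterns
    )
    counts_neg = np.bincount(
        codes[keep & ~cohort.gold_label], minlength=n_patterns
    )
    mapping = _majority_mapping(counts_pos, counts_neg, tie_policy, unseen_policy)
    return LookupClassifier(
        items=items, mapping=mapping, tie_policy=tie_policy, unseen_policy=unseen_policy
    )


def predict_lookup(
    clf: LookupClassifier, cohort: Cohort, missing_policy: str = "impute_no"
) -> np.ndarray:
    """Deterministically map each child through its answer pattern."""
    if missing_policy == "drop":
        raise ValueError("predict requires a prediction per child; use 'impute_no' or 'error'")
    codes = encode_patterns(cohort, clf.items, missing_policy=missing_policy)
    return clf.mapping[codes]


def evaluate_lookup(
    clf: LookupClassifier,
    cohort: Cohort,
    ci_method: str = DEFAULT_CI_METHOD,
    missing_policy: str = "impute_no",
) -> DiagnosticMetrics:
    """Diagnostic metrics of a fitted rule on a cohort (resubstitution when
    the cohort is the fitting cohort)."""
    predicted = predict_lookup(clf, cohort, missing_policy=missing_policy)
    cm = confusion_from_labels(predicted, cohort.gold_label)
    return metrics_from_confusion(cm, ci_method=ci_method,
                                  allow_undefined_predictive_values=True)


def _stratified_folds(
    gold: np.ndarray, n_folds: int, seed: int | None
) -> Iterator[np.ndarray]:
    """Index masks for stratified folds, balanced on the gold label."""
    rng = np.random.default_rng(seed)
    n = len(gold)
    fold_of = np.empty(n, dtype=int)
    for cls in (True, False):
        idx = np.flatnonzero(gold == cls)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % n_folds
    for f in range(n_folds):
        yield fold_of == f


def evaluate_combination(
    cohort: Cohort,
    items: Sequence[str],
    ci_method: str = DEFAULT_CI_METHOD,
    cv_folds: int | None = None,
    seed: int | None = None,
    tie_policy: str = "negative",
    missing_policy: str = "impute_no",
) -> DiagnosticMetrics:
    """Fit and score an item combination on a cohort.

    By default this is resubstitution — fit and evaluate on the same
    children, matching how lookup rules are scored during the exhaustive
    search.  With ``cv_folds`` set, out-of-fold predictions from a
    label-stratified k-fold split are pooled into a single confusion matrix,
    giving a less optimistic estimate.
    """
    items = tuple(items)
    if cv_folds is None:
        clf = fit_lookup(cohort, items, tie_policy=tie_policy,
                         missing_policy=missing_policy)
        return evaluate_lookup(clf, cohort, ci_method=ci_method,
                               missing_policy=missing_policy)
    if cv_folds < 2:
        raise ValueError("cv_folds must be at least 2")
    predicted = np.zeros(cohort.n_children, dtype=bool)
    for test_mask in _stratified_folds(cohort.gold_label, cv_folds, seed):
        train = cohort.subset(~test_mask)
        clf = fit_lookup(train, items, tie_policy=tie_policy,
                         missing_policy=missing_policy)
        predicted[test_mask] = predict_lookup(
            clf, cohort.subset(test_mask), missing_policy=missing_policy
        )
    cm = confusion_from_labels(predicted, cohort.gold_label)
    return metrics_from_confusion(cm, ci_method=ci_method,
                                  allow_undefined_predictive_values=True)


def rank_single_items(
    cohort: Cohort,
    ci_method: str = DEFAULT_CI_METHOD,
    missing_policy: str = "impute_no",
) -> list[tuple[str, DiagnosticMetrics]]:
    """Score every item as a stand-alone test, "yes" = test-positive.

    No direction optimisation is performed: an item whose "yes" answer is
    anti-associated with asthma syndrome simply scores a balanced accuracy
    below one half.  Items sort by balanced accuracy descending, ties by
    lower misclassification error then by item id.  Items with no observed
    responses are skipped with a warning.
    """
    if not cohort.gold_label.any() or cohort.gold_label.all():
        raise CohortValidationError(
            "ranking needs at least one positive and one negative child"
        )
    scored: list[tuple[str, DiagnosticMetrics]] = []
    for item in cohort.item_ids:
        col = cohort.columns([item])[:, 0]
        if np.isnan(col).all():
            warnings.warn(f"item {item!r} has no observed responses; skipped",
                          stacklevel=2)
            continue
        codes = encode_patterns(cohort, [item], missing_policy=missing_policy)
        keep = codes >= 0
        predicted = codes[keep] == 1
        cm = confusion_from_labels(predicted, cohort.gold_label[keep])
        scored.append((item, metrics_from_confusion(cm, ci_method=ci_method)))
    scored.sort(key=lambda pair: (-pair[1].auc.value, pair[1].mce.value, pair[0]))
    return scored


@dataclass(frozen=True)
class CombinationResult:
    """One scored item combination from an exhaustive search."""

    items: tuple[str, ...]
    metrics: DiagnosticMetrics
    pattern_table: PatternTable
    rank: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


@dataclass
class SearchReport:
    """Ordered results of an exhaustive combination search.

    Behaves as an ordered sequence of :class:`CombinationResult` (best
    first) and additionally records the search settings and the number of
    subsets evaluated.
    """

    combinations: list[CombinationResult]
    k: int
    criterion: str
    n_subsets_evaluated: int
    candidate_items: tuple[str, ...]

    def __iter__(self) -> Iterator[CombinationResult]:
        return iter(self.combinations)

    def __len__(self) -> int:
        return len(self.combinations)

    def __getitem__(self, i):
        return self.combinations[i]

    @property
    def best(self) -> CombinationResult:
        return self.combinations[0]


SEARCH_CRITERIA = ("auc", "mce", "sensitivity_at_min_specificity")

#: Subsets scored per vectorised batch during the exhaustive search.
_BATCH_SIZE = 4096


def _batched(iterable: Iterable, size: int) -> Iterator[list]:
    it = iter(iterable)
    while batch := list(itertools.islice(it, size)):
        yield batch


def _criterion_key(criterion: str, se, sp, auc, mce, min_specificity: float):
    """Per-subset sort score; larger is better."""
    if criterion == "auc":
        return auc
    if criterion == "mce":
        return -mce
    if criterion == "sensitivity_at_min_specificity":
        meets = sp >= min_specificity
        # combinations missing the specificity floor rank strictly below all
        # that meet it, ordered among themselves by specificity
        return np.where(meets, se, sp - 2.0)
    raise ValueError(f"unknown criterion {criterion!r}; choose from {SEARCH_CRITERIA}")


def exhaustive_search(
    cohort: Cohort,
    k: int,
    criterion: str = "auc",
    restrict_top_m: int | None = None,
    ci_method: str = DEFAULT_CI_METHOD,
    top_n: int | None = 10,
    min_specificity: float = 0.8,
    tie_policy: str = "negative",
    missing_policy: str = "impute_no",
) -> SearchReport:
    """Score every k-item subset with a majority-rule lookup classifier.

    Each subset is fitted and evaluated on the same cohort (resubstitution)
    and subsets are ranked by ``criterion`` — balanced accuracy descending
    by default — with ties broken by lower misclassification error and then
    by the lexicographic tuple of item ids.  ``restrict_top_m`` limits the
    candidate pool to the top m items by single-item balanced accuracy.
    ``top_n=None`` keeps the full ranking; otherwise only the leading
    ``top_n`` combinations are materialised (the ranking of the retained
    head is identical either way).

    The search is complete and deterministic: exactly C(m, k) subsets are
    evaluated for an m-item candidate pool.
    """
    if k < 1:
        raise CohortValidationError("subset size k must be >= 1")
    if criterion not in SEARCH_CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {SEARCH_CRITERIA}")
    if cohort.n_children == 0:
        raise CohortValidationError("cannot search an empty cohort")

    if restrict_top_m is not None:
        ranked = rank_single_items(cohort, ci_method=ci_method,
                                   missing_policy=missing_policy)
        candidates = sorted(item for item, _ in ranked[:restrict_top_m])
    else:
        candidates = sorted(cohort.item_ids)
    m = len(candidates)
    if k > m:
        raise CohortValidationError(f"k={k} exceeds the {m} candidate items")

    codes01 = np.stack(
        [encode_patterns(cohort, [item], missing_policy="impute_no")
         for item in candidates],
        axis=1,
    ).astype(np.int32)  # children x candidates, 0/1
    if missing_policy == "error":
        # trigger per-item error semantics before the batched pass
        encode_patterns(cohort, candidates, missing_policy="error")
    keep = np.ones(cohort.n_children, dtype=bool)
    if missing_policy == "drop":
        keep = ~np.isnan(cohort.columns(candidates)).any(axis=1)
    gold = cohort.gold_label[keep]
    pos = codes01[keep][gold]
    neg = codes01[keep][~gold]
    n_pos, n_neg = len(pos), len(neg)
    n_all = n_pos + n_neg
    n_patterns = 1 << k

    n_subsets = math.comb(m, k)
    logger.info("exhaustive search: %d subsets of size %d over %d items",
                n_subsets, k, m)

    kept: list[tuple[float, float, tuple[str, ...]]] = []  # (-score, mce, items)

    def counts_for(X: np.ndarray, combos: np.ndarray) -> np.ndarray:
        b = combos.shape[0]
        codes = np.zeros((X.shape[0], b), dtype=np.int32)
        for t in range(k):
            codes += X[:, combos[:, t]] << t
        offset = (np.arange(b, dtype=np.int32) << k)
        flat = (codes + offset).ravel()
        return np.bincount(flat, minlength=b << k).reshape(b, n_patterns)

    for batch in _batched(itertools.combinations(range(m), k), _BATCH_SIZE):
        combos = np.array(batch, dtype=np.int64)
        counts_pos = counts_for(pos, combos) if n_pos else np.zeros(
            (len(batch), n_patterns), dtype=np.int64)
        counts_neg = counts_for(neg, combos) if n_neg else np.zeros(
            (len(batch), n_patterns), dtype=np.int64)
        pred = _majority_mapping(counts_pos, counts_neg, tie_policy, "negative")
        tp = (counts_pos * pred).sum(axis=1)
        fp = (counts_neg * pred).sum(axis=1)
        se = tp / n_pos if n_pos else np.zeros(len(batch))
        sp = 1.0 - fp / n_neg if n_neg else np.ones(len(batch))
        auc = (se + sp) / 2.0
        mce = ((n_pos - tp) + fp) / n_all
        score = _criterion_key(criterion, se, sp, auc, mce, min_specificity)
        # stable lexsort keeps enumeration (= lexicographic) order on full ties
        order = np.lexsort((mce, -score))
        head = order if top_n is None else order[: top_n]
        for i in head:
            items_tuple = tuple(candidates[j] for j in batch[i])
            kept.append((-float(score[i]), float(mce[i]), items_tuple))
        kept.sort()
        if top_n is not None:
            del kept[top_n:]

    results: list[CombinationResult] = []
    for rank, (_, _, items_tuple) in enumerate(kept, start=1):
        clf = fit_lookup(cohort, items_tuple, tie_policy=tie_policy,
                         missing_policy=missing_policy)
        metrics = evaluate_lookup(clf, cohort, ci_method=ci_method,
                                  missing_policy=missing_policy)
        table = pattern_table_from_cohort(
            cohort, items_tuple, indicated=clf.mapping_dict(),
            missing_policy=missing_policy,
        )
        results.append(
            CombinationResult(items=items_tuple, metrics=metrics,
                              pattern_table=table, rank=rank)
        )
    return SearchReport(
        combinations=results,
        k=k,
        criterion=criterion,
        n_subsets_evaluated=n_subsets,
        candidate_items=tuple(candidates),
    )


@dataclass(frozen=True)
class StratumResult:
    """Results of one age stratum of a stratified analysis."""

    name: str
    n: int
    n_positive: int
    prevalence: float
    metrics: DiagnosticMetrics | None = None
    ranking: list[tuple[str, DiagnosticMetrics]] | None = None


def stratified_evaluation(
    cohort: Cohort,
    age_cut_months: int = DEFAULT_AGE_CUT_MONTHS,
    items: Sequence[str] | None = None,
    ci_method: str = DEFAULT_CI_METHOD,
    missing_policy: str = "impute_no",
) -> dict[str, StratumResult]:
    """Run an analysis independently in two age strata.

    The cohort splits at ``age_cut_months`` (lower stratum strictly below the
    cut, default 24 months — infants/toddlers vs children aged 2 to 5).
    With ``items`` given, a lookup rule over those items is fitted and
    evaluated per stratum; otherwise every single item is ranked per stratum.
    """
    below_mask = cohort.age_months < age_cut_months
    strata = {
        f"<{age_cut_months}mo": cohort.subset(below_mask),
        f">={age_cut_months}mo": cohort.subset(~below_mask),
    }
    for name, stratum in strata.items():
        if stratum.n_children == 0:
            raise CohortValidationError(f"age stratum {name!r} is empty")
    out: dict[str, StratumResult] = {}
    for name, stratum in strata.items():
        metrics = None
        ranking = None
        if items is not None:
            metrics = evaluate_combination(
                stratum, items, ci_method=ci_method, missing_policy=missing_policy
            )
        else:
            ranking = rank_single_items(stratum, ci_method=ci_method,
                                        missing_policy=missing_policy)
        out[name] = StratumResult(
            name=name,
            n=stratum.n_children,
            n_positive=int(stratum.gold_label.sum()),
            prevalence=stratum.prevalence,
            metrics=metrics,
            ranking=ranking,
        )
    return out
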