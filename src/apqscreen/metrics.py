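"""Confusion-matrix algebra and diagnostic-accuracy metrics.

All metrics derive from a 2x2 confusion matrix of predicted vs gold-standard
asthma-syndrome labels: sensitivity, specificity, positive and negative
predictive values, misclassification error (MCE, the fraction of children
wrongly classified) and balanced accuracy — the mean of sensitivity and
specificity, reported here under the name ``auc`` because for a single
binary rule it coincides with the area under the two-point ROC curve.

Interval estimates use standard binomial proportion methods (Wilson score
by default, Wald and Clopper-Pearson selectable); the balanced-accuracy
interval is the midpoint of the sensitivity and specificity interval bounds.

The module also inverts the reporting direction: given published
sensitivity/specificity and cohort composition it reconstructs the integer
confusion matrix, which makes printed summary tables auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .cohort import round_half_away

__all__ = [
    "ConfusionMatrix",
    "IntervalEstimate",
    "Estimate",
    "DiagnosticMetrics",
    "UndefinedMetricError",
    "confusion_from_labels",
    "metrics_from_confusion",
    "proportion_ci",
    "reconstruct_confusion_from_metrics",
    "CI_METHODS",
]

#: Supported proportion confidence-interval methods, mapped to the
#: corresponding statsmodels method names.
CI_METHODS: dict[str, str] = {
    "wald": "normal",
    "wilson": "wilson",
    "clopper_pearson": "beta",
}

DEFAULT_CI_METHOD = "wilson"
DEFAULT_LEVEL = 0.95


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for the given confusion matrix."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer 2x2 cross-tabulation; "positive" means asthma syndrome."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        """Children with the gold-standard positive label."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            tn=self.tn + other.tn,
        )


@dataclass(frozen=True)
class IntervalEstimate:
    """A two-sided confidence interval for a proportion."""

    lower: float
    upper: float
    level: float = DEFAULT_LEVEL
    method: str = DEFAULT_CI_METHOD

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise ValueError(
                f"interval must satisfy 0 <= lower <= upper <= 1, "
                f"got ({self.lower}, {self.upper})"
            )

    def __contains__(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class Estimate:
    """A point estimate with its interval."""

    value: float
    ci: IntervalEstimate

    def __float__(self) -> float:
        return self.value

    def as_percent(self, decimals: int = 1) -> str:
        """Display string on the percent scale, e.g. ``80.2 (75.0-84.8)``."""
        return (
            f"{100 * self.value:.{decimals}f} "
            f"({100 * self.ci.lower:.{decimals}f}-{100 * self.ci.upper:.{decimals}f})"
        )


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Diagnostic properties of a binary rule against the gold standard."""

    sensitivity: Estimate
    specificity: Estimate
    auc: Estimate
    ppv: Estimate
    npv: Estimate
    mce: Estimate
    prevalence: Estimate

    def to_dict(self) -> dict[str, float]:
        return {
            name: getattr(self, name).value
            for name in (
                "sensitivity", "specificity", "auc", "ppv", "npv", "mce", "prevalence"
            )
        }


def confusion_from_labels(
    predicted: Sequence[bool] | np.ndarray, truth: Sequence[bool] | np.ndarray
) -> ConfusionMatrix:
    """Cross-tabulate predicted against gold labels."""
    pred = np.asarray(predicted, dtype=bool)
    gold = np.asarray(truth, dtype=bool)
    if pred.shape != gold.shape or pred.ndim != 1:
        raise ValueError(
            f"predicted and truth must be equal-length 1-D arrays, "
            f"got shapes {pred.shape} and {gold.shape}"
        )
    if pred.size == 0:
        raise ValueError("labels must be non-empty")
    return ConfusionMatrix(
        tp=int((pred & gold).sum()),
        fp=int((pred & ~gold).sum()),
        fn=int((~pred & gold).sum()),
        tn=int((~pred & ~gold).sum()),
    )


def proportion_ci(
    x: int, n: int, method: str = DEFAULT_CI_METHOD, level: float = DEFAULT_LEVEL
) -> IntervalEstimate:
    """Confidence interval for a binomial proportion x/n.

    ``wald`` is the normal approximation truncated to [0, 1]; ``wilson`` the
    score interval; ``clopper_pearson`` the exact beta-quantile interval.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= x <= n:
        raise ValueError(f"x must satisfy 0 <= x <= n, got x={x}, n={n}")
    if method not in CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}; choose from {sorted(CI_METHODS)}")
    lower, upper = proportion_confint(x, n, alpha=1 - level, method=CI_METHODS[method])
    # statsmodels can return values a rounding error outside [0, 1]
    lower = min(max(float(lower), 0.0), 1.0)
    upper = min(max(float(upper), 0.0), 1.0)
    # at the boundaries the score and exact intervals are exactly one-sided
    if x == 0:
        lower = 0.0
    if x == n:
        upper = 1.0
    return IntervalEstimate(lower=lower, upper=upper, level=level, method=method)


def _estimate(
    x: int, n: int, method: str, level: float, name: str,
    allow_undefined: bool = False,
) -> Estimate:
    if n == 0:
        if allow_undefined:
            return Estimate(
                value=float("nan"),
                ci=IntervalEstimate(0.0, 1.0, level=level, method=method),
            )
        raise UndefinedMetricError(f"metric {name!r} undefined: zero denominator")
    return Estimate(value=x / n, ci=proportion_ci(x, n, method=method, level=level))


def metrics_from_confusion(
    cm: ConfusionMatrix,
    ci_method: str = DEFAULT_CI_METHOD,
    level: float = DEFAULT_LEVEL,
    allow_undefined_predictive_values: bool = False,
) -> DiagnosticMetrics:
    """All diagnostic metrics, with intervals, from a confusion matrix.

    The MCE interval treats misclassifications as a simple proportion of the
    cohort; the balanced-accuracy (``auc``) interval takes the midpoints of
    the sensitivity and specificity bounds.  A rule that calls every child
    the same way leaves PPV or NPV with a zero denominator; with
    ``allow_undefined_predictive_values`` those come back as NaN with a
    vacuous [0, 1] interval instead of raising, which classifier evaluation
    relies on.
    """
    if cm.total == 0:
        raise UndefinedMetricError("metrics undefined for an empty confusion matrix")
    allow = allow_undefined_predictive_values
    se = _estimate(cm.tp, cm.n_positive, ci_method, level, "sensitivity")
    sp = _estimate(cm.tn, cm.n_negative, ci_method, level, "specificity")
    ppv = _estimate(cm.tp, cm.tp + cm.fp, ci_method, level, "ppv", allow)
    npv = _estimate(cm.tn, cm.tn + cm.fn, ci_method, level, "npv", allow)
    mce = _estimate(cm.fp + cm.fn, cm.total, ci_method, level, "mce")
    prev = _estimate(cm.n_positive, cm.total, ci_method, level, "prevalence")
    auc = Estimate(
        value=(se.value + sp.value) / 2.0,
        ci=IntervalEstimate(
            lower=(se.ci.lower + sp.ci.lower) / 2.0,
            upper=(se.ci.upper + sp.ci.upper) / 2.0,
            level=level,
            method=ci_method,
        ),
    )
    return DiagnosticMetrics(
        sensitivity=se, specificity=sp, auc=auc, ppv=ppv, npv=npv, mce=mce,
        prevalence=prev,
    )


def reconstruct_confusion_from_metrics(
    sensitivity: float, specificity: float, n_total: int, n_positive: int
) -> ConfusionMatrix:
    """Rebuild the integer confusion matrix behind published se/sp values.

    ``tp = round(sensitivity * n_positive)`` and
    ``tn = round(specificity * (n_total - n_positive))`` with halves rounded
    away from zero; the remaining cells follow by complement.
    """
    if not 0.0 <= sensitivity <= 1.0 or not 0.0 <= specificity <= 1.0:
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if not 0 <= n_positive <= n_total:
        raise ValueError("n_positive must satisfy 0 <= n_positive <= n_total")
    n_negative = n_total - n_positive
    tp = round_half_away(sensitivity * n_positive)
    tn = round_half_away(specificity * n_negative)
    fn = n_positive - tp
    fp = n_negative - tn
    if fn < 0 or fp < 0:
        raise ValueError("inconsistent inputs produce a negative cell count")
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
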