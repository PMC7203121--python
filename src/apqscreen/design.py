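"""Sample-size planning for diagnostic-accuracy studies.

Implements the Buderer approach: to estimate a test's sensitivity with a
confidence interval of half-width d, one needs

    n_eff = z^2 * p * (1 - p) / d^2

truly diseased subjects (z the standard-normal quantile at 1 - alpha/2 and
p the anticipated sensitivity), and hence n_eff / prevalence recruited
subjects overall; for specificity the divisor is 1 - prevalence.  A study
targeting both metrics recruits the larger of the two totals.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

from scipy.stats import norm

__all__ = ["SampleSizeSpec", "buderer_sample_size", "required_cohort"]

_METRICS = ("sensitivity", "specificity")
_ROUNDINGS = ("half_down", "ceil")


@dataclass(frozen=True)
class SampleSizeSpec:
    """One per-metric precision requirement.

    Parameters
    ----------
    target_metric
        ``"sensitivity"`` or ``"specificity"``.
    expected_value
        Anticipated value of the metric, in (0, 1).
    precision
        Desired confidence-interval half-width d on the proportion scale.
    prevalence
        Anticipated fraction of gold-standard-positive subjects.
    alpha
        Significance level of the interval (default 0.05 for 95% CI).
    """

    target_metric: str
    expected_value: float
    precision: float = 0.05
    prevalence: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.target_metric not in _METRICS:
            raise ValueError(f"target_metric must be one of {_METRICS}")
        if not 0.0 < self.expected_value < 1.0:
            raise ValueError("expected_value must lie in (0, 1)")
        if not 0.0 < self.precision <= 0.5:
            raise ValueError("precision must lie in (0, 0.5]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def _round_final(x: float, rounding: str) -> int:
    if rounding == "ceil":
        return math.ceil(x)
    if rounding == "half_down":
        # nearest integer, exact halves rounded down
        return math.ceil(x - 0.5)
    raise ValueError(f"unknown rounding {rounding!r}; choose from {_ROUNDINGS}")


def effective_group_size(spec: SampleSizeSpec) -> float:
    """Unrounded number of subjects needed in the metric's reference group."""
    z = norm.ppf(1.0 - spec.alpha / 2.0)
    p = spec.expected_value
    return z * z * p * (1.0 - p) / (spec.precision ** 2)


def buderer_sample_size(spec: SampleSizeSpec, rounding: str = "half_down") -> int:
    """Total cohort size required to estimate one metric at the given precision.

    The effective group size is inflated by the prevalence (for sensitivity)
    or its complement (for specificity).  The final total rounds to the
    nearest integer with exact halves rounded down by default; ``ceil``
    gives the conservative alternative.
    """
    n_eff = effective_group_size(spec)
    divisor = (
        spec.prevalence if spec.target_metric == "sensitivity" else 1.0 - spec.prevalence
    )
    return _round_final(n_eff / divisor, rounding)


def required_cohort(
    sensitivity_spec: SampleSizeSpec,
    specificity_spec: SampleSizeSpec,
    rounding: str = "half_down",
) -> int:
    """Cohort size meeting both a sensitivity and a specificity requirement."""
    if sensitivity_spec.prevalence != specificity_spec.prevalence:
        raise ValueError("the two specs must share the same prevalence")
    if sensitivity_spec.alpha != specificity_spec.alpha:
        raise ValueError("the two specs must share the same alpha")
    return max(
        buderer_sample_size(sensitivity_spec, rounding=rounding),
        buderer_sample_size(specificity_spec, rounding=rounding),
    )
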