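"""Seeded latent-class simulation of questionnaire cohorts.

The original child-level study data are not deposited, so analyses are
exercised on synthetic cohorts with the same statistical skeleton: each
child belongs to a latent class (asthma syndrome or not) drawn with an
age-stratum-specific prevalence, and answers each yes/no item with a
class-conditional endorsement probability.  Within-class dependence between
items — real symptom reports are not conditionally independent — comes from
a single shared Gaussian severity score per child: item j is endorsed iff a
standard-normal variate correlated at rho with the child's severity falls
below the class-conditional quantile, a one-parameter Gaussian copula that
leaves the marginal endorsement probabilities exact.

:func:`reference_params` reproduces the published study's conditions: 614
children, 88 items, two age strata (below 2 years: 80.1% of the cohort at
39.0% prevalence; 2 up to 5 years: 19.9% at 50.0%), a strong planted
"wheezing today" item endorsed with probability 0.80 given asthma syndrome
and 0.16 otherwise, nine weaker items matching the published single-item
sensitivities and specificities, and 78 near-uninformative background items.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.stats import norm

from .cohort import Cohort, CohortValidationError, ItemCodebook
from .reference import PUBLISHED_TOP_ITEMS

__all__ = [
    "AgeStratum",
    "SimulationParams",
    "simulate_cohort",
    "reference_params",
]

#: Detailed-diagnosis composition among label-positive children (published
#: cohort: 125 bronchiolitis, 78 asthma, 50 combined of 253).
_POSITIVE_DETAILS = ("bronchiolitis", "asthma", "combined asthma and bacterial pneumonia")
_POSITIVE_DETAIL_P = (0.494, 0.308, 0.198)
#: Composition among label-negative children (167 bacterial pneumonia,
#: 163 viral pneumonia, 31 other of 361).
_NEGATIVE_DETAILS = ("bacterial pneumonia", "viral pneumonia", "other")
_NEGATIVE_DETAIL_P = (167 / 361, 163 / 361, 31 / 361)


@dataclass(frozen=True)
class AgeStratum:
    """One age stratum: month range, cohort share and class prevalence."""

    age_min_months: int
    age_max_months: int
    share: float
    prevalence: float

    def __post_init__(self) -> None:
        if not 0 <= self.age_min_months <= self.age_max_months:
            raise CohortValidationError("invalid age range")
        if not 0.0 <= self.share <= 1.0 or not 0.0 <= self.prevalence <= 1.0:
            raise CohortValidationError("share and prevalence must lie in [0, 1]")


@dataclass
class SimulationParams:
    """Parameters of the latent-class questionnaire-cohort generator.

    ``item_profiles`` holds, per item, the endorsement probabilities
    (p_yes_given_positive, p_yes_given_negative).  ``correlation`` is the
    within-class dependence rho in [0, 1): the squared loading of every item
    on the shared severity score.  ``age_strata``, when given, override the
    scalar ``prevalence``; their shares must sum to one.
    """

    n_children: int
    prevalence: float
    item_profiles: list[tuple[float, float]]
    codebook: ItemCodebook | None = None
    correlation: float = 0.0
    age_strata: list[AgeStratum] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children < 0:
            raise CohortValidationError("n_children must be nonnegative")
        probs = [self.prevalence, self.missing_rate]
        for p_pos, p_neg in self.item_profiles:
            probs.extend((p_pos, p_neg))
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise CohortValidationError("all probabilities must lie in [0, 1]")
        if not 0.0 <= self.correlation < 1.0:
            raise CohortValidationError("correlation must lie in [0, 1)")
        if self.age_strata:
            total = sum(s.share for s in self.age_strata)
            if abs(total - 1.0) > 1e-9:
                raise CohortValidationError(
                    f"stratum shares must sum to 1, got {total}"
                )
        if self.codebook is not None and len(self.codebook) != len(self.item_profiles):
            raise CohortValidationError(
                "codebook size must equal the number of item profiles"
            )

    @property
    def n_items(self) -> int:
        return len(self.item_profiles)

    def to_yaml(self, path) -> None:
        """Serialise to a YAML config recording the seed."""
        data = {
            "n_children": self.n_children,
            "prevalence": self.prevalence,
            "correlation": self.correlation,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
            "item_profiles": [
                {"item_id": iid, "p_pos": float(p), "p_neg": float(q)}
                for iid, (p, q) in zip(self._item_ids(), self.item_profiles)
            ],
            "age_strata": [
                {
                    "age_min_months": s.age_min_months,
                    "age_max_months": s.age_max_months,
                    "share": s.share,
                    "prevalence": s.prevalence,
                }
                for s in self.age_strata
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def _item_ids(self) -> tuple[str, ...]:
        if self.codebook is not None:
            return self.codebook.item_ids
        width = len(str(max(self.n_items, 1)))
        return tuple(f"q{j + 1:0{width}d}" for j in range(self.n_items))


def simulate_cohort(params: SimulationParams) -> Cohort:
    """Draw a cohort from the latent-class model; same seed, same cohort.

    Per child: an age stratum (or the whole eligible 2-59 month range when
    no strata are given), an age uniform in the stratum's month range, a
    class with the stratum's prevalence, a severity score s ~ N(0, 1), and
    per item a response

        yes  iff  sqrt(rho) * s + sqrt(1 - rho) * e_j  <  Phi^{-1}(p_class_j)

    with independent e_j ~ N(0, 1), so the marginal endorsement probability
    given the class is exactly p_class_j.  Responses are then masked
    independently at ``missing_rate``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_children
    m = params.n_items
    item_ids = params._item_ids()

    if params.age_strata:
        shares = np.array([s.share for s in params.age_strata])
        stratum_idx = rng.choice(len(params.age_strata), size=n, p=shares / shares.sum())
        ages = np.empty(n, dtype=int)
        prev = np.empty(n)
        for i, stratum in enumerate(params.age_strata):
            mask = stratum_idx == i
            ages[mask] = rng.integers(
                stratum.age_min_months, stratum.age_max_months + 1, size=mask.sum()
            )
            prev[mask] = stratum.prevalence
    else:
        ages = rng.integers(2, 60, size=n)
        prev = np.full(n, params.prevalence)

    gold = rng.random(n) < prev

    rho = params.correlation
    severity = rng.standard_normal(n)
    noise = rng.standard_normal((n, m))
    latent = np.sqrt(rho) * severity[:, None] + np.sqrt(1.0 - rho) * noise

    profiles = np.asarray(params.item_profiles, dtype=float)  # m x 2
    p_child = np.where(gold[:, None], profiles[:, 0], profiles[:, 1])  # n x m
    responses = (latent < norm.ppf(p_child)).astype(float)

    if params.missing_rate > 0:
        mask = rng.random((n, m)) < params.missing_rate
        responses[mask] = np.nan

    detail = np.empty(n, dtype=object)
    n_pos = int(gold.sum())
    detail[gold] = rng.choice(_POSITIVE_DETAILS, size=n_pos, p=_POSITIVE_DETAIL_P)
    detail[~gold] = rng.choice(_NEGATIVE_DETAILS, size=n - n_pos, p=_NEGATIVE_DETAIL_P)

    return Cohort(
        responses=responses,
        item_ids=item_ids,
        gold_label=gold,
        age_months=ages,
        diagnosis_detail=detail,
        child_id=np.array([f"c{i:05d}" for i in range(n)], dtype=object),
    )


#: Study-scale defaults mirroring the published cohort.
REFERENCE_N_CHILDREN = 614
REFERENCE_N_ITEMS = 88
REFERENCE_STRATA = (
    AgeStratum(age_min_months=2, age_max_months=23, share=0.801, prevalence=0.390),
    AgeStratum(age_min_months=24, age_max_months=59, share=0.199, prevalence=0.500),
)
#: Planted strong item: P(yes | asthma syndrome) and P(yes | no asthma
#: syndrome), i.e. sensitivity 0.80 and specificity 0.84.
REFERENCE_WHEEZE_PROFILE = (0.80, 0.16)
REFERENCE_CORRELATION = 0.3


def reference_params(seed: int = 0, n_children: int = REFERENCE_N_CHILDREN) -> SimulationParams:
    """Generator parameters calibrated to the published study conditions.

    The implied overall prevalence is 0.801 * 0.390 + 0.199 * 0.500 = 0.412.
    The first ten items carry the published top-ten single-item profiles
    (sensitivity as p_yes_given_positive, one minus specificity as
    p_yes_given_negative), led by the planted wheeze item at (0.80, 0.16);
    the remaining 78 background items get near-uninformative profiles, both
    class probabilities within 0.05 of a common item-specific base rate.
    """
    rng = np.random.default_rng(seed)
    profiles: list[tuple[float, float]] = []
    item_ids: list[str] = []
    wordings: list[str] = []
    sections: list[str] = []

    for item_id, wording, se_pct, sp_pct in PUBLISHED_TOP_ITEMS:
        profiles.append((se_pct / 100.0, 1.0 - sp_pct / 100.0))
        item_ids.append(item_id)
        wordings.append(wording)
        sections.append("top items")
    # planted wheeze item rounds to the published (0.80, 0.16) profile
    profiles[0] = REFERENCE_WHEEZE_PROFILE

    n_background = REFERENCE_N_ITEMS - len(profiles)
    base = rng.uniform(0.05, 0.50, size=n_background)
    shift = rng.uniform(-0.05, 0.05, size=(n_background, 2))
    for j in range(n_background):
        p_pos = float(np.clip(base[j] + shift[j, 0], 0.01, 0.99))
        p_neg = float(np.clip(base[j] + shift[j, 1], 0.01, 0.99))
        profiles.append((p_pos, p_neg))
        item_ids.append(f"background_{j + 1:02d}")
        wordings.append(f"Background questionnaire item {j + 1}")
        sections.append("background")

    strata = list(REFERENCE_STRATA)
    implied_prev = sum(s.share * s.prevalence for s in strata)
    return SimulationParams(
        n_children=n_children,
        prevalence=implied_prev,
        item_profiles=profiles,
        codebook=ItemCodebook(
            item_ids=tuple(item_ids),
            wordings=tuple(wordings),
            sections=tuple(sections),
        ),
        correlation=REFERENCE_CORRELATION,
        age_strata=strata,
        missing_rate=0.0,
        seed=seed,
    )
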