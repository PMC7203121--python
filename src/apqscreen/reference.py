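"""Published reference results for the Ugandan under-five asthma-syndrome study.

The study that motivated this package screened 614 children aged 2-59
months presenting with cough and/or difficult breathing, 253 (41.2%) of
whom received the composite "asthma syndrome" gold label.  Its best
four-item screening rule was published as a full 16-row pattern table:
per answer pattern, the number of children, the percentage split between
children with and without asthma syndrome, and the majority-rule indicated
diagnosis.  That table carries enough information to reconstruct the
underlying integer counts and to audit the printed diagnostic metrics,
which is what :mod:`apqscreen` uses it for.

The raw child-level study data are not public; everything here is typed in
from the published summary table.
"""

from __future__ import annotations

from .cohort import (
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    LABEL_UNDEFINED,
    PatternRow,
    PatternTable,
)

__all__ = [
    "PUBLISHED_ITEMS",
    "published_pattern_table",
    "published_single_item_metrics",
]

#: The four items of the published best-performing rule, in printed column
#: order: did the disease start with difficulty breathing; did painkillers
#: help much; wheezing/whistling today; significant cough in the last few
#: days before presenting.
PUBLISHED_ITEMS: tuple[str, ...] = (
    "breathing_difficulty_onset",
    "painkillers_helped",
    "wheezing_today",
    "cough_recent",
)

# Each row: (pattern over PUBLISHED_ITEMS as yes=True, n, indicated label,
# pct_without, pct_with).  Rows with n=0 were printed without an indicated
# diagnosis; they carry the "undefined" marker here.
_PUBLISHED_ROWS: tuple[tuple[tuple[bool, bool, bool, bool], int, str, float, float], ...] = (
    ((False, False, False, False), 1, LABEL_POSITIVE, 0.0, 100.0),
    ((True, False, False, False), 2, LABEL_NEGATIVE, 50.0, 50.0),
    ((False, True, False, False), 0, LABEL_UNDEFINED, 0.0, 0.0),
    ((True, True, False, False), 3, LABEL_NEGATIVE, 100.0, 0.0),
    ((False, False, True, False), 0, LABEL_UNDEFINED, 0.0, 0.0),
    ((True, False, True, False), 2, LABEL_POSITIVE, 0.0, 100.0),
    ((False, True, True, False), 0, LABEL_UNDEFINED, 0.0, 0.0),
    ((True, True, True, False), 0, LABEL_UNDEFINED, 0.0, 0.0),
    ((False, False, False, True), 127, LABEL_NEGATIVE, 86.6, 13.4),
    ((True, False, False, True), 40, LABEL_NEGATIVE, 85.0, 15.0),
    ((False, True, False, True), 147, LABEL_NEGATIVE, 87.8, 12.2),
    ((True, True, False, True), 34, LABEL_NEGATIVE, 79.4, 20.6),
    ((False, False, True, True), 78, LABEL_POSITIVE, 17.9, 82.1),
    ((True, False, True, True), 76, LABEL_POSITIVE, 17.1, 82.9),
    ((False, True, True, True), 57, LABEL_POSITIVE, 31.6, 68.4),
    ((True, True, True, True), 47, LABEL_POSITIVE, 25.5, 74.5),
)


def published_pattern_table() -> PatternTable:
    """The published 16-row pattern table of the best four-item rule.

    Returns a fresh :class:`~apqscreen.cohort.PatternTable` whose row counts
    sum to the study's 614 children.
    """
    return PatternTable(
        items=PUBLISHED_ITEMS,
        rows=[
            PatternRow(
                pattern=pattern,
                n=n,
                pct_without=pct_without,
                pct_with=pct_with,
                indicated=indicated,
            )
            for pattern, n, indicated, pct_without, pct_with in _PUBLISHED_ROWS
        ],
    )


#: Published diagnostic properties (percent scale) of the ten best single
#: items, ranked by balanced accuracy; used to calibrate the synthetic-cohort
#: generator's item profiles.  Values: (item_id, wording, sensitivity %,
#: specificity %).
PUBLISHED_TOP_ITEMS: tuple[tuple[str, str, float, float], ...] = (
    ("wheezing_today",
     "Your child's disease today: wheezing/whistling?", 80.2, 84.2),
    ("wheezing_recent",
     "Symptoms in the last few days: wheezing/whistling?", 50.6, 91.1),
    ("wheezing_at_onset",
     "How did the disease begin: wheezing/whistling?", 36.8, 94.2),
    ("wheezing_last_3_months",
     "In the last 3 months, wheezing/whistling?", 34.4, 92.8),
    ("wakes_from_wheezing",
     "Earlier problems: does your child wake up because of wheezing?", 29.6, 95.6),
    ("recurrent_wheezing",
     "Earlier problems: recurrent episodes of wheezing/whistling?", 32.4, 91.1),
    ("nocturnal_wheezing",
     "Earlier problems: wheezing usually in the night/early morning?", 26.5, 95.3),
    ("woke_from_breathing_difficulty",
     "Last few days: did your child wake up because of difficulty breathing?",
     60.9, 60.7),
    ("asthma_medicine_ever",
     "Earlier problems: ever taken medicine for asthma or wheezing?", 27.3, 94.2),
    ("breathing_difficulty_onset",
     "How did the disease begin: specifically with changes in breathing?",
     47.4, 73.7),
)


def published_single_item_metrics() -> dict[str, tuple[float, float]]:
    """Published (sensitivity, specificity) per top item, proportion scale."""
    return {item: (se / 100.0, sp / 100.0) for item, _, se, sp in PUBLISHED_TOP_ITEMS}
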