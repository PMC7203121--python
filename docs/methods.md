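# Methods

## The screening problem and the classifier

The package derives screening rules for "asthma syndrome" — a composite
label covering expert-panel diagnoses of asthma, bronchiolitis, or combined
asthma and bacterial pneumonia — in children aged 2–59 months presenting
with acute respiratory symptoms. Inputs are strictly binary yes/no
questionnaire items; any multi-category item must be pre-binarised by the
user, because the classifier operates on yes/no answer patterns only.

A **lookup-table classifier** over an ordered subset of k items assigns to
each of the 2^k answer patterns the gold-standard class that is most
prevalent among the children showing that pattern. Fitting is therefore a
pure cross-tabulation with two explicit edge policies:

- **Ties** (a pattern split exactly 50/50 between classes) default to
  "no asthma". This is the screening-conservative choice and matches how
  the published reference table resolves its one tied pattern. A
  "positive" tie policy is available.
- **Unseen patterns** (no child in the fitting data) also default to
  "no asthma"; the published table leaves such rows without an indicated
  diagnosis, and a screening rule must still return *something* for them.

Given the items, the fitted lookup table minimises resubstitution
misclassification error over all 2^(2^k) deterministic pattern→label
assignments — the test suite verifies this by brute force for small k.

**Missing responses** default to imputation as "no" (a caretaker who cannot
endorse a symptom is treated as not endorsing it); alternatives are
dropping the child at fit time or raising an error naming the child. No
missing-data mechanism beyond this is modelled.

## Metrics

All metrics derive from the 2x2 confusion matrix of predicted vs gold
labels ("positive" = asthma syndrome):

- sensitivity se = TP/(TP+FN), specificity sp = TN/(TN+FP),
  PPV = TP/(TP+FP), NPV = TN/(TN+FN);
- misclassification error MCE = (FP+FN)/N, identically equal to
  prev·(1−se) + (1−prev)·(1−sp);
- balanced accuracy (se+sp)/2, reported under the name **AUC**: for a single
  binary rule it coincides with the trapezoidal area under the two-point ROC
  curve, and no threshold sweep exists that would distinguish the two.

Interval estimates are binomial proportion CIs at 95% by default. The
**Wilson score interval is the default method** because it tracks the
reference study's printed intervals most closely (e.g. 203/253 → 74.9–84.7
against a printed 75.0–84.8); Wald and Clopper–Pearson are selectable, and
the reference intervals fall between Wilson and Wald, so the original
method cannot be pinned down. The MCE (and prevalence) interval treats its
numerator as a simple proportion of the whole cohort; the balanced-accuracy
interval takes the midpoints of the se and sp bounds.

Numerical conventions:

- At the boundaries x = 0 and x = n the lower/upper bound is set to exactly
  0/1 (the score and exact intervals are one-sided there; floating point
  would otherwise leave a ~1e-16 residue).
- A rule that calls every child the same way has an undefined PPV or NPV;
  classifier *evaluation* reports NaN with a vacuous [0, 1] interval for
  that metric, while direct metric computation raises an error naming the
  metric.
- Percentages printed to one decimal are converted back to integer counts
  by rounding half away from zero; this reproduces the reference cohort
  composition (253 / 361 of 614) exactly. The same rounding reconstructs
  confusion matrices from published se/sp pairs.

## Exhaustive combination search

All C(m, k) subsets are fitted and scored **by resubstitution on the same
cohort** — deliberately, since the resulting "best performance" is to be
read as an optimistic upper limit for rules of this form, not an unbiased
estimate. An optional stratified k-fold cross-validation mode
(`evaluate_combination(..., cv_folds=...)`) pools out-of-fold predictions
into one confusion matrix for a less optimistic figure; it is off by
default so that the headline numbers match the resubstitution definition.

The default selection criterion is balanced accuracy (descending), with
ties broken by lower MCE and then by the lexicographic tuple of item ids,
making the ranking complete and deterministic regardless of iteration
order. Alternative criteria: MCE ascending, and
sensitivity-at-minimum-specificity (subsets missing the specificity floor
rank strictly below all that meet it).

Scaling rests on integer pattern codes: each child's answers on a candidate
subset pack into one integer (item t contributes bit t), and batches of
4096 subsets are scored at once by offset bincounts over the positive and
negative classes separately. The full C(88,4) = 2,331,890-subset search on
a 614-child cohort completes in well under a minute on one CPU.
`restrict_top_m` (off by default) first ranks single items by balanced
accuracy and searches only the top m — with m = 40 and k = 4 that is 91,390
subsets, which this package's own study-scale experiments (and the test
suite) use as the standard quick configuration.

With `top_n` set, only the leading combinations are materialised; because
the composite sort key ends in the (unique) item-id tuple, the retained
head is provably identical to the head of the full ranking.

**Age stratification** splits at 24 months by default (lower stratum
strictly below the cut), matching the under-2 / 2-to-5 reporting
convention; each stratum is analysed independently and its size and
prevalence reported. An empty stratum is an error naming the stratum.

## Sample-size planning

The Buderer computation: to estimate sensitivity p with CI half-width d at
level 1−α, n_eff = z²·p(1−p)/d² truly positive children are needed, hence
n_eff/prevalence recruited children; for specificity the divisor is
1−prevalence, and a study targeting both recruits the larger total. With
p = 0.80, d = 0.05, prevalence 0.46 and α = 0.05 the requirement is 534
children (sensitivity binds; specificity alone needs 455).

Two conventions, both configurable: z uses the exact quantile 1.959964
rather than 1.96 (immaterial here), and the final total rounds to the
nearest integer with exact halves rounded **down** — the unrounded
sensitivity total is 534.46, and half-down reproduces the canonical 534
where a ceiling would give 535. The half-width d = 0.05 is the conventional
choice consistent with that canonical figure.

## The synthetic-cohort generator

Real child-level data for this problem are not publicly deposited, so the
generator produces cohorts with the statistical skeleton the analysis
assumes. Per child: an age stratum, an age uniform within the stratum's
month range, a latent class (asthma syndrome or not) with the stratum's
prevalence, and a standard-normal severity score s. Item j is endorsed iff

    √ρ·s + √(1−ρ)·e_j < Φ⁻¹(p_class,j),   e_j ~ N(0,1) i.i.d.,

a one-parameter Gaussian copula: the marginal endorsement probability given
the class is exactly p_class,j for any ρ, while ρ > 0 induces positive
within-class dependence between all items through shared severity.
Responses are then masked independently at `missing_rate`.

Reference defaults (`reference_params`) mirror the study conditions: 614
children; 88 items; strata (2–23 months, share 0.801, prevalence 0.390) and
(24–59 months, share 0.199, prevalence 0.500), implying overall prevalence
0.412; a planted "wheezing today" item at (p_pos, p_neg) = (0.80, 0.16),
i.e. sensitivity 0.80 / specificity 0.84; nine weaker items carrying the
published top-ten single-item (se, 1−sp) profiles; 78 background items with
both class probabilities within ±0.05 of an item-specific base rate drawn
from U(0.05, 0.50); ρ = 0.3 as a moderate-dependence convention (no
inter-item correlations are published to estimate it from); missing rate 0
(no missingness handling is reported for the original data). Detailed
diagnoses for positives are drawn as bronchiolitis/asthma/combined at
(0.494, 0.308, 0.198) and for negatives per the published composition; they
are carried for reporting only and never used by any classifier.

What the generator does **not** emulate — hence what passing tests do not
show about real data: the published median age (10 months, IQR 6–18; ages
here are uniform within strata), any item-specific dependence structure
beyond the single shared severity factor, informative missingness, recall
bias in retrospective items, and any association between symptoms and age
within a class.

## Verification against the published record

The published 16-row pattern table of the best four-item rule is typed in
as a fixture. Reconstruction audits check, end to end: the cohort
composition (253/361/614); the wheeze-item marginal confusion matrix
(203, 57, 50, 304) and its metrics (se 80.2, sp 84.2, AUC 82.2, PPV 78.1,
NPV 85.9, MCE 17.4, all to one decimal on the percent scale); and the
four-item rule's resubstitution sensitivity, 204/253 = 80.6%, within
percentage rounding of the abstract's published 80.8%.

Two published figures are documented as irreproducible from the printed
data and are **not** targeted: the results-section sensitivity/specificity
pair 78.3/86.6 for the same combination (inconsistent with the abstract's
80.8/84.7 and with the pattern table; possibly a resampled estimate), and
the combination CIs (e.g. 75.1–81.6), which are narrower than any binomial
interval at n = 253. The abstract's verbal item list also differs from the
pattern table's printed headers; the fixture follows the table.

## Known limitations

- Resubstitution metrics are optimistic; the cross-validation mode
  mitigates but external validation is out of scope.
- The search is exhaustive, not regularised: at n = 614 the non-planted
  members of the best four-item combination are seed-unstable, which is
  precisely why best-combination performance is an upper limit.
- The generator's ρ and background-item base rates are conventions, not
  estimates.
- No likelihood ratios, threshold ROC curves, or probabilistic (logistic)
  scoring; items are binary and the rule class is the lookup table.
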