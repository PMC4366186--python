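# Methods

## Screening model

The package evaluates binary index tests for two OGTT-defined outcomes —
undiagnosed diabetes and pre-diabetes (isolated IFG, isolated IGT, and
IFG+IGT pooled or separately) — in an opportunistic-screening setting.
The reference standard is the five-class fasting / 2-h post-load glucose
classification given in the README; pre-diabetes metrics always remove
diabetic subjects from the evaluation set first, so "specificity for
pre-diabetes" means the probability that a normoglycemic (NGT) subject
tests negative.

Index tests are cutoff rules with inclusive (≥) positivity — FINDRISC ≥ c
on the 0–26 questionnaire score, HbA1c ≥ c in NGSP percent — and two-test
combinations: *simultaneous* (parallel, positive on either component) and
*sequential* (serial, positive on both).  Simultaneous combination can
only raise sensitivity and lower specificity relative to both components;
sequential the reverse.  These directional facts are asserted as
invariants in the test suite on every generated cohort.

### FINDRISC scoring

The eight-item point table (documented in `findrisc.py`) follows the
original published instrument; the attainable total is exactly 0–26 and
the package verifies this by enumerating all 1728 item-category
combinations.  Category boundaries are closed on the lower-risk side (BMI
exactly 25 → 1 point; male waist exactly 94 cm → 3; age exactly 45 → 2;
exactly 30 min/day of activity → 0).  Daily physical activity is the sum
of commute, recreation and work minutes, dichotomised at 30 min/day.
Family history maps none / second-degree / first-degree to 0 / 3 / 5
points; NHANES-style relative lists must be reduced to these three levels
by the caller (nearest-relative rule), a mapping the source data leave
open.  Fruit/vegetable intake is a daily yes/no taken as given; when
deriving it from a 24-h recall, any nonzero consumption of fruit, berries
or vegetables counts as "daily".

### Eligibility cascade

Records are excluded sequentially: age < 20; fasting < 9 h or ≥ 24 h;
missing HbA1c; missing FPG; missing 2-h PG; self-reported diabetes.  A
record failing several criteria is tallied at the first failing step, so
the tally is deterministic and |retained| + Σ tally = |input|.

### Glycemic bands

The pre-diabetes FPG band is the half-open interval [100, 126) and the
2-h PG band [140, 200), closed against the diabetes thresholds
(FPG ≥ 126 or 2-h PG ≥ 200), so the five classes partition the positive
quadrant with no 125–126 or 199–200 gap.

## Metrics and derived columns

Confusion counts may be survey-weighted (weights multiply subjects).
Crude predictive values come from the weighted 2×2 directly; *adjusted*
predictive values and the screened-positive population fraction apply
Bayes' rule at an external prevalence p:

PV⁺ = se·p / (se·p + (1−sp)(1−p)),  PV⁻ = sp(1−p) / ((1−se)p + sp(1−p)),
P(positive) = se·p + (1−sp)(1−p).

With unit weights and p set to the crude sample prevalence the adjusted
and crude values coincide (tested to 1e−9 relative).  The shortest
distance statistic d = √((1−se)² + (1−sp)²) (proportion scale) scores each
operating point; the optimal cutoff minimises d, ties broken toward the
higher threshold (fewer screen-positives).

## ROC and AUC

The empirical ROC is built over every distinct observed score (one
operating point per threshold, ≥ positivity) with (0,0)/(1,1) anchors.
AUC is computed two deliberately independent ways — trapezoidal
integration of the curve and the Mann–Whitney pair statistic with ties
counting ½ — which agree to 1e−12 by construction of the empirical curve;
the rank form also accepts weights.  Correlated AUCs on the same subjects
are compared with DeLong's nonparametric test, implemented with midrank
placement values (O(n log n)), reported as a 1-df χ² with its p-value.
The DeLong variance is defined for unit weights; weighted AUC point
estimates are available but weighted DeLong variance is out of scope.
Degenerate inputs: single-class data raise; a zero variance estimate with
equal AUCs returns the null result (χ² = 0, p = 1), with unequal AUCs it
raises.

## Survey weighting

Weighted prevalence is Σw·1[condition]/Σw with Kish effective sample size
(Σw)²/Σw².  Pooling survey cycles divides each weight by the number of
cycles.  Design-based variance estimation (strata/PSU linearisation,
replicate weights) is deliberately out of scope: the metrics reproduced
here are point estimates.

## Synthetic cohort generator

Each subject draws a glycemic class from the mixture
(NGT .5375, iIFG .2708, iIGT .0437, IFG+IGT .0951, DM .0529), then:

- **(FPG, 2-h PG)** from independent normals truncated to the class's
  defining rectangle, so reclassification consistency is exact by
  construction.  The diabetic region is a union, split by a knob
  (default 0.5) between FPG-driven (FPG ≥ 126, unconstrained 2-h PG) and
  2-h-driven (2-h PG ≥ 200, FPG < 126) presentations.
- **HbA1c** from the class-conditional normal truncated to (0, ∞).
- **FINDRISC total** from the class-conditional normal truncated to
  [−0.5, 26.5], rounded to an integer; the eight item sub-scores are then
  drawn uniformly among the combinations summing to that total, and raw
  fields (age, height/weight for the BMI band, waist, activity minutes,
  flags) are back-filled uniformly within each item's category band, so
  re-scoring the raw fields returns the sampled total exactly.

Class-conditional means/SDs default to the emulated study sample's
descriptive table; missingness (HbA1c 87/4893, FPG 15/4893, 2-h PG
806/4893) and self-reported diabetes (99/4893) are independent
Bernoulli flags reproducing its eligibility-cascade proportions.  Survey
weights are log-normal (σ = 0.5), *independent of class*: the generator
therefore does not emulate the real design's weight–glycemia association
(in the study the weighted diabetes prevalence, 7.0%, exceeds the
unweighted class share, 5.3%).  Passing weighted-analysis tests on this
generator shows the weighting machinery is correct, not that design
effects of real data are reproduced.

HbA1c and FINDRISC are conditionally independent given the class by
default (the marginals are all the descriptive table provides); a
per-class Gaussian-copula correlation knob exists for sensitivity
analyses.  With the default zero correlation, test operating points have
closed form — mixture-weighted truncated-normal exceedance probabilities
(`true_operating_point`), and class means account for truncation and
discretisation (`true_class_mean`).  These closed forms are the oracles
for the parameter-recovery tests (3 Monte-Carlo SEs at n = 50,000, the
size chosen to keep each class, including the 4.4% isolated-IGT class,
above ~2,000 subjects).  Because items are back-filled independently of
everything but the total, generated cohorts do not reproduce realistic
joint demographics (e.g. age–waist correlation); they exercise the
pipeline's arithmetic, not epidemiology.

## Numerical choices

- Truncated normals are sampled by inverse-CDF from a single
  `numpy.random.default_rng(seed)` stream; identical config + seed gives a
  byte-identical cohort CSV.
- Metrics are computed in percent at full float precision; CSV reports
  round to 2 decimals at the presentation layer only, JSON keeps full
  precision.
- `sum` and `roc_distance` columns are always recomputed from the
  unrounded sensitivity/specificity of the same row.
- Undefined metrics (empty diseased or control stratum, degenerate
  predictive-value denominators) raise typed errors rather than returning
  NaN, except crude PPV/NPV which are NaN when nobody tests
  positive/negative (a legitimate sweep endpoint).

## Known limitations

- No confidence intervals for sensitivity/specificity, and no
  design-based variance under complex sampling.
- The pre-diabetes screened-positive population column of the emulated
  study's table does not follow the single-prevalence formula used here
  for the diabetes rows; the package reports the formula value for both
  outcomes and additionally the crude within-sample fraction positive.
- ROC curves are empirical only (no binormal smoothing, no partial AUC).
- The generator's self-reported-diabetes stratum is independent of the
  drawn glycemic class; it exists to exercise the cascade, not to model
  diagnosed-diabetes epidemiology.
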