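# Methods

## The design and its inference problem

A randomized, nonconcurrent multiple-baseline SCED measures each participant
weekly across four phases: baseline (A, randomized to 4, 5 or 6
measurements), intervention before the add-on (B), intervention with the
add-on (B2, starting after a randomized 0/3/6 sessions), and follow-up (C,
three weekly measurements six months post-treatment).  Each participant
serves as their own control; the staggered, randomized baseline lengths
distinguish intervention effects from time effects.  Pre/post/follow-up
assessments (T0/T1/T2) sit between phases and support group-level
contrasts and reliable-change classification.

Participants' calendars are independent (no cross-participant stagger
constraint), and the two randomizations are drawn independently and
uniformly over {4,5,6} × {0,3,6}.  Sessions are identified with weeks; a
different session calendar can be expressed by rescaling the intervention
length before scheduling.

## Randomization test

For a participant with baseline values x_A and intervention values x_B
(phases B ∪ B2 by default), the observed statistic is Cohen's
d = (x̄_A − x̄_B)/s_pooled with the (n−1)-weighted pooled SD, signed so the
hypothesized therapeutic direction is positive.  Testing is one-sided in
that direction.  Two resampling schemes are exposed:

- **label_permutation** (default): each of the `n_resamples` (default
  1,000) resamples randomly reassigns the pooled scores to pseudo-phases of
  the original sizes and recomputes d.  This treats the phase labels as
  exchangeable under the null.
- **startpoint_shift**: resamples move the intervention start point over
  the admissible positions (at least two points on each side), preserving
  temporal order — the scheme aligned with how the design actually
  randomizes (the start of the intervention), and the one to prefer when
  serial dependence is a concern.

p = #{d* ≥ d_obs}/n_resamples, floored at 1/n_resamples: a Monte-Carlo p is
never zero, so the smallest reportable value at 1,000 resamples is .001.
Degenerate resamples (zero pooled SD) map to signed infinity by the sign of
the mean difference, which makes the comparison with d_obs well defined on
tied data; a fully constant observed series raises a degenerate-variance
error rather than fabricating a p-value.  Participants with fewer than two
usable points in either phase are excluded from testing (the inclusion
rule), with the reason logged by the report layer.

**Group combination.**  With n tested participants, S = Σ pᵢ.  Under the
joint null each pᵢ ~ Uniform(0,1), so S is Irwin–Hall distributed and the
group p is the exact CDF

P(S ≤ s) = (1/n!) Σ_{k=0}^{⌊s⌋} (−1)ᵏ C(n,k)(s−k)ⁿ.

The alternating sum cancels catastrophically in floating point for
moderate n, so it is evaluated in exact rational arithmetic (the float
argument is converted exactly) and only the final ratio is rounded — the
result is correctly rounded for any practical n, and cross-checked against
`scipy.stats.irwinhall` and against 10⁶-draw Monte-Carlo estimates in the
tests.  A normal approximation Φ((S − n/2)/√(n/12)) and a Monte-Carlo
combiner are provided for comparison.

**Calibration.**  Under a ρ=0 AR(1) null generator the per-participant
test's rejection rate at α=.05 is 0.057 over 2,000 replicates (inside the
[0.03, 0.07] acceptance band; the slight excess reflects the uncorrected
Monte-Carlo p without the +1 adjustment).  The combined group p of uniform
inputs is itself uniform (KS test over 5,000 replicates).  With a level
change of 2 within-person SDs and 10 points per phase, power exceeds 0.99
at α=.05 and the injected change is recovered without detectable bias
(500 replicates).  Positive autocorrelation inflates the
label-permutation test's type-I error; beyond ρ ≈ 0.4 the inflation is
substantial, which is the documented reason the startpoint-shift scheme
exists.

## Reliable change and clinical range

RCI = (pre − post)/s_diff, improvement (symptom decrease) positive,
classification boundaries closed (|RCI| exactly at the threshold counts).
Defaults:

| instrument | s_diff | threshold | clinical cutoff |
|---|---|---|---|
| ECBI Intensity (raw 36–252) | 21.8 | 1.96 | ≥ 131 |
| ECBI Problem (raw 0–36) | 4.69 | 1.96 | ≥ 13 |
| OBVL total (T-score) | — | 1.645 | ≥ 60 |

The ECBI difference-SDs and raw clinical cutoffs are calibrated from the
study's published (raw score, RCI) pairs and clinical-range markings: with
s_diff = 21.8 every internally consistent published Intensity index
reproduces to two decimals, and with s_diff = 4.69 likewise for the Problem
scale.  The OBVL ships without a default s_diff because the published OBVL
indices are mutually inconsistent (they imply per-participant values
between ≈1.64 and ≈1.68, suggesting respondent-specific norms); supplying
`ReliabilityParams(..., s_diff=...)` — or `sd_norm` plus `reliability_r`,
from which s_diff = SD·√(2(1−r)) is derived — enables OBVL RCIs.  Four
published cells (participant 15's Intensity pre-to-follow-up pair,
participant 16's Problem column, and participant 18's Problem T1→T2 sign)
do not reproduce from their own raw scores and are treated as print
anomalies: they are shipped verbatim in `scedlab.datasets` but excluded
from calibration cross-checks.

## Group contrasts

Timepoint descriptives use the sample (n−1) SD; participants who dropped
out of the intervention but stayed in the study are excluded from T1/T2
aggregates while their T0 values are retained — the composition that
reproduces the study's published descriptive cells.  The Wilcoxon
signed-rank test drops zero differences, midranks ties, and uses the exact
sign-flip null distribution for up to 25 pairs via dynamic programming on
doubled ranks (the classic exact tables do not cover ties; scipy's exact
method refuses them, and is used as a cross-check on tie-free inputs).
Both Cohen's d variants are reported for each contrast because they answer
different questions and disagree in general: the pooled variant compares
the two timepoint distributions, the paired variant standardizes the mean
within-parent change by the change SD.  The study's published contrast
effect sizes are not recoverable from its published means/SDs under either
variant, so no published d cell is targeted.

## VR session-difference analysis

Adjacent archived sessions form a pair; a pair qualifies when at least
`min_practices` (default 1) VR practices occurred in between.  Positive
following is capped at 30 on both sides before differencing — 30 is the
mastery amount (10 labeled praises + 10 reflections + 10 behavior
descriptions), beyond which extra tallies carry no signal — while negative
leading is uncapped (the cap is a mastery construct and has no
negative-side analogue).  Pairs are adjacent *records*, not adjacent
session numbers, because tallies were archived at irregular sessions; a
`require_adjacent` flag restricts to gap-1 pairs for stricter designs.
Per-parent medians and means are both reported (the median being the more
outlier-cautious summary).  The low/high VR-use split is a fixed cutoff
(≤ 6 vs ≥ 7 total practices) rather than a recomputed median, since the
study's operational rule is the fixed cutoff.

## Synthetic data generator

The generator emulates the study conditions: 11 families, two participating
parents with probability 7/11 (expected 18 parents), baseline levels ECBI
Intensity 150, OBVL-K T 72, DPICS positive following 4 and negative leading
30.  Weekly values follow phase-level means plus a weekly intervention
slope and stationary AR(1) noise (default ρ = 0.2, range restricted to
[0, 0.6]), clamped to instrument ranges and rounded for count-like scales.
Two parents of a family share the child's ECBI series (they rate the same
child) and the family's design assignment, but have independent OBVL and
DPICS series.  VR practice counts are Poisson (default 0.8/week) and occur
only from the add-on start onward; missingness is Bernoulli per value
(default 0.10); dropout is a per-week hazard (default 0.015) truncating
later weekly data while configurably preserving assessments.

The study publishes no within-person weekly SDs, so the defaults
(Intensity 10, Problem 2.5, OBVL 4, PF 3, NL 6) and the intervention level
changes are realistic stand-ins chosen once from the scale ranges and the
published pre/post movement, not estimates of the study's actual weekly
variability.  Passing tests on synthetic data therefore demonstrate the
*machinery* (calibration, power, invariances) under the assumed model —
AR(1) Gaussian noise with level shifts — and say nothing about
non-Gaussian weekly dynamics, reactive measurement, or the study's actual
trajectories, which are not published as data.

## Numerical and edge-case conventions

- Missing values are explicit (`None`/empty field, never zero); every
  statistic is complete-case within its own comparison.
- Resample comparison `d* ≥ d_obs` uses an absolute 1e-12 tolerance so
  bitwise-equal permutations are never lost to rounding.
- Week indices are 0-based from the first baseline measurement;
  assessments carry no week ordering (stored at week 0 with T-phases).
- The phase label `B2` encodes the design's B′ (prime characters are
  hostile in file formats).
- Validation enforces instrument ranges (ECBI Intensity 36–252, Problem
  0–36, counts non-negative integers) and rejects duplicate
  (participant, measure, week, phase) rows; ranges are config-overridable
  since the instrument bounds are conventions of the standard forms.

## Problem sizes

The shipped validation suite uses 10,000-resample Monte-Carlo runs against
exhaustive enumeration on instances of ≤ 10 points, 2,000 null replicates
for type-I calibration, 5,000 replicates for group-p uniformity, 500
replicates for power/recovery, and 10⁶ draws for the Irwin–Hall
comparison; these sizes give 3-SE margins comfortably below the acceptance
bands while keeping the whole suite in a few seconds.

## Known limitations

- The label-permutation scheme assumes exchangeability; with substantial
  serial dependence its type-I error inflates (documented above).
- Exact Wilcoxon switches to a tie-corrected normal approximation beyond
  25 nonzero pairs.
- No parametric interrupted-time-series or Bayesian SCED estimators, no
  DPICS reliable change (no published norms), no modeling of VR content or
  engagement.
- Coder agreement uses a transparent per-category min/max ratio averaged
  over categories; the field also uses interval-based and kappa statistics,
  which are out of scope.
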