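# Methods

## Value model

The appraisal follows the linear additive MCDA form used by EVIDEM-style
health technology assessment committees. For rater $r$ and core criterion
$x$ (14 criteria), the raw weight $w_{rx} \in \{1..5\}$ expresses how much
the criterion matters to that rater independent of any intervention; the
raw score $s_{rx} \in \{0..3\}$ expresses how well the intervention
performs on the criterion given the synthesized evidence. Weights are
normalized within rater, $W_{rx} = w_{rx} / \sum_y w_{ry}$, so that each
rater's importance budget sums to 1; scores are rescaled by the scale
maximum, $S_{rx} = s_{rx}/3$. The rater's value estimate is
$V_r = \sum_x W_{rx} S_{rx}$.

The score divisor is applied explicitly even though additive MCDA is often
written without it: the model's anchoring — $V = 0$ when every score is 0,
$V = 1$ when every score is 3, for any weights — requires scores on [0,1],
and the equal-weights closed form $V = \overline{s}/3$ (used to check
group-level arithmetic: a grand mean score printing as 1.31 yields a value
printing as 0.44) only holds with it. The anchors are enforced exactly in
code: an all-max or all-min score vector returns 1.0 or 0.0 with no float
residue.

Committee-level outputs are the arithmetic mean of rater values, its
dispersion, the mean per-criterion contributions
$\bar V_x = \tfrac1R \sum_r W_{rx} S_{rx}$, and cluster shares
$\sum_{x \in c} \bar V_x / \bar V$, which sum to 1 whenever the committee
mean is positive. Contributions are nonnegative and sum exactly to each
rater's value (checked to 1e-9 in the invariant suite).

**Dispersion convention.** Published committee tables do not state whether
SDs use the sample or population convention. The package defaults to the
sample convention (ddof = 1, Excel's STDEV, the likelier choice for
spreadsheet-era analyses) and exposes `sd_ddof` everywhere a summary is
computed; reports name the convention used.

**Rounding.** Internal computation is full precision. Rendering rounds
half-up (not banker's): means/SDs to 1 dp, value estimates to 2 dp,
percentages to 1 dp. Half-up matters at the margins the tests exercise
(4.55 → 4.6, 0.435 → 0.44).

## Criteria registry

The registry is configuration-driven (JSON/YAML): any set of core criteria
partitioned into clusters, plus contextual criteria, can be loaded. The
default is the 14-core / 6-contextual set of the tramadol case study. Only
ten core criteria are named in the study narrative; the remaining four
(budget impact, cost-effectiveness, adherence to decisionmaking-body
requirements, completeness of evidence reporting) are completed from the
parent EVIDEM framework and carry an `inferred` flag. Cluster membership
for the default set (2/2/3/2/3/2 criteria per cluster) is likewise a
configuration choice, not a published fact — per-cluster agreement
percentages therefore depend on it, and any other partition can be
supplied.

## Contextual tool

Contextual criteria are tagged negative / neutral / positive per rater
("none" is accepted on input as a synonym for neutral), with "missing"
a legitimate fourth state that is tallied, never dropped. Tallies conserve
the rater count per criterion and are permutation-invariant in rater
order. Impacts stay qualitative: they are deliberately never folded into
the value estimate.

## Reliability

ICC(3,1) follows the Shrout–Fleiss classification: a two-way ANOVA of
units crossed with the two sessions, session effects fixed,

    BMS = k * sum_i (m_i - g)^2 / (n - 1)
    EMS = (SS_total - SS_units - SS_sessions) / ((n - 1)(k - 1))
    ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) EMS)

A constant session shift is absorbed by the fixed session effect, so a
uniform drift between test and retest does not lower the ICC — a property
the tests pin both directly and through affine invariance. Negative
estimates are reported unclamped with a warning; data with no variance
beyond a session shift raise an explicit undefined-ICC error rather than
returning 0 or 1. The engine is verified to 1e-12 against a brute-force
sum-of-squares oracle (explicit Python loops) on hundreds of random
panels, and against `pingouin.intraclass_corr`'s ICC(C,1) as an
independent library cross-check.

**Unit definition.** For weights and scores the ANOVA unit is the
rater × criterion cell pooled across criteria (126 units for a complete
9 × 14 panel), matching the published pair counts; pooling heterogeneous
criteria into one ANOVA inflates between-unit variance relative to a
per-criterion analysis and is retained here as the study's own convention.
For value estimates the unit is the rater (9 units). Pairing is complete
case: raters present in only one session are excluded with a warning.

Agreement proportions partition pairs by |test − retest| into 0, 1, 2 and
>2 points (the last possible on the 1–5 scale though not observed in the
study), kept as exact rationals until rendering. Group-level published
percentages correspond to unique integer count triples on 126 pairs
({82, 40, 4} for weights, {99, 25, 2} for scores), which the engine
reproduces exactly; where the study text (78.8%) and its table (78.6%)
disagree, the table value is the internally consistent one (99/126) and is
the one tested. Per-cluster identical percentages use the registry's
cluster map.

## Synthetic committees

Raw panel matrices were never published, so the generator emulates their
statistical structure:

* **Ratings** per criterion are normal draws around a target mean with
  target SD, rounded to the nearest point and clipped to the scale — a
  modelling convenience that produces bounded integer panels with tunable
  location and dispersion, not a behavioral claim. Clipping pulls extreme
  targets toward the interior, so sample means track targets to within
  about half a point at n = 9 (tested seed-averaged).
* **Retest** perturbs each cell independently: unchanged with p_same, ±1
  with p_diff1, ±2 with p_diff2, sign a fair coin (agreement data identify
  only magnitudes; symmetry is the minimal assumption), clipped at the
  bounds. Clipping events are logged because they shrink realized
  differences and bias observed agreement upward — visible for score
  panels whose means sit near 1 on a 0–3 scale.
* **Exact fixtures.** `calibrate_to_summary` enumerates all nondecreasing
  integer vectors on the scale (≤ 715 multisets at n = 9 on 5 points) and
  returns the lexicographically smallest whose 1-dp rounded mean/SD equal
  a printed summary, or an infeasibility report listing the nearest
  achievable summaries (a mean at a scale bound forces SD 0).
  `study_like_committee` assembles per-criterion calibrated vectors into a
  deterministic committee reproducing every published per-criterion
  summary; rater identities in it are synthetic, so within-rater
  correlation across criteria is not reproduced — committee-level
  summaries are, including the grand mean score (1.31) and hence the
  equal-weights group value (0.44).

The study-like profile transcribes the published per-criterion summaries
as targets and fills unpublished criteria with values (flagged inferred in
the source) chosen so the weight and score grand means land at the
published 3.81 and 1.31. Impact probabilities likewise transcribe the
published committee splits (8/9 positive for utility, 5/4 positive/neutral
for system capacity, 7/9 negative for efficiency, 5/9 negative for
political context, one non-responder on population priority); splits the
study leaves unstated are spread across the remaining categories.

What passing on synthetic committees does **not** show: real committees
revise ratings after discussion, correlate ratings across criteria within
a rater, and drift asymmetrically between sessions — none of which the
generator models. Pipeline-level tests are therefore properties
(proportion recovery within 3 points over 100 seeds; ICC rising
monotonically to 1 as p_same → 1) rather than reproductions of the
published ICC magnitudes.

## Problem sizes and determinism

Default analyses use the study's geometry (9 raters × 14 criteria, two
sessions); Monte-Carlo checks use 50 × 14 panels over 100 seeds and
20–30-seed averages for convergence curves. All randomness flows through
`numpy.random.default_rng` seeded explicitly; property tests run hypothesis
derandomized. The acceptance script derives every quantity at run time
from the package's own computation on inputs stated in the published
tables.

## Limitations

* No inter-rater reliability (out of scope by design: weights capture
  individual perspectives), no ICC confidence intervals, no ranking across
  interventions, no elicitation UI.
* Cluster-level agreement percentages are only as meaningful as the
  configured cluster map.
* The retest model is i.i.d. across cells; real intra-rater drift is
  likely correlated within rater and criterion.
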