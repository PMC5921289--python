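# Methods

## Analysis unit and outcomes

The analysis unit is the *episode*: one ED presentation for self-harm
(self-poisoning or self-injury). A person may contribute several index
episodes; each is followed up independently. Two outcomes are ascertained
per episode:

* **Repeat self-harm within six months** — a strictly later presentation by
  the same person no more than `window_days` after the index episode. Six
  months is not a fixed number of days; the package uses 183 days by default
  and the window is configurable. Same-day re-presentations count as repeats
  for the earlier episode, ordered by episode id. Repeat ascertainment may
  draw on an *attendance table* larger than the analysed index set, because
  monitoring systems record presentations beyond any extracted sample.
* **Suicide within six months** — a suicide death 0–183 days after the
  episode. Episodes by persons without mortality linkage are flagged lost to
  follow-up and excluded from suicide analyses (denominators shrink
  accordingly). What counts as a suicide verdict is collapsed to a
  caller-supplied boolean on the death record; verdict rules vary by
  jurisdiction and are out of scope. A suicide death dated before a
  presentation raises a data-integrity warning and is treated as no event.

The evaluation assumes every index episode has at least the full window of
observation; the synthetic generator guarantees this, and real-data users
must supply data with the same property (documented, not enforced).

## Scales and scoring

Scale definitions are data: ordered `(item, weight)` pairs plus ordered
category cut-offs, overridable from YAML so centre-specific variants need no
code changes. Built-ins: MSHR and ReACT (4 unit-weight items; 0 = low,
1+ = moderate/high), SPS (10 unit-weight items; 0–4/5–6/7–10), MSPS (10
items with depression-or-hopelessness, rational-thinking loss,
organised-or-serious attempt and stated future intent at weight 2, maximum
14; 0–5/6–8/>8).

Items are tri-state (present / absent / missing). Scoring under the primary
`treat_as_absent` policy sums weights over *present* items only; the
`require_complete` policy returns an incomplete result for any episode with
a missing item, feeding complete-case filtering. Mapping chart variables
onto item semantics (e.g. deriving "stated future intent" from an intent
questionnaire) is deliberately outside the scoring core: operationalisation
varies by centre, so the input table must already carry tri-state items.

One boundary subtlety: the SPS/MSPS *age* item follows the published
instrument wording (present iff age < 19 or age > 45, so exactly 45 scores
nothing), whereas the 45+ *subgroup* band is age ≥ 45. Both are intentional.

## Dichotomisation conventions

Binary scales are compared low vs moderate/high. Three-category scales use
adjacent-category comparisons — low vs moderate (high-risk episodes
excluded) and moderate vs high (low excluded). Excluding the third category
is the convention under which published percentage columns are internally
consistent with their count margins, and it is hard-coded as the two
`adjacent_*` conventions.

## Accuracy measures and intervals

From a 2×2 table: sensitivity, specificity, PPV, NPV, LR+, LR−, DOR. Any
measure with an empty denominator (or, for the ratio measures, a zero cell)
is reported as undefined rather than approximated, unless the Haldane 0.5
continuity correction is explicitly enabled.

Interval methods: Wilson score for proportions (default; reproduces printed
integer bounds at repeat-outcome sample sizes), Clopper–Pearson exact
selectable (the better match for very small counts such as 0/3 or 16/18
suicide cells); Woolf log method for the DOR; Simel log method for the LRs.
All at a configurable level, 95% default.

## ROC and AUC

Integer scores are thresholded over their achievable range (`score ≥ t`
positive), anchored at (0,0) and (1,1); the AUC is the trapezoidal area,
which equals the Mann–Whitney concordance probability with ties counted ½ —
a property test enforces equality to 1e-12 against a brute-force pairwise
count. For a binary score, AUC = (sensitivity + specificity)/2 exactly.
The four-item rules are thresholded on their 0–4 item count, not only on
their published dichotomy: the dichotomy alone cannot produce a non-trivial
curve. The AUC standard error is Hanley–McNeil.

Subgroup AUCs are compared with a weighted chi-square homogeneity statistic:
with weights `w_i = 1/SE_i²` and weighted mean `Ā`, `X² = Σ w_i (A_i − Ā)²`
on `k − 1` df; two groups reduce to the usual z² for independent AUCs. The
construction for more than two groups is a documented choice — standard
meta-analytic homogeneity, collapsing to the familiar two-sample test.

## Missing data

Three strategies, reflecting practice with routine clinical records:

1. **Absent rule.** For non-assessed episodes, items whose recording is
   biased toward presence (depression/hopelessness, organised/serious
   attempt, rational-thinking loss — both scales' variants of each concept)
   are recoded missing → absent before imputation. The predictable direction
   is to underestimate sensitivity and overestimate specificity; a test
   verifies the mechanism (absent-coding can never raise a score).
2. **Chained equations (MICE).** Remaining missing items are imputed by
   iterated conditional logistic models: for each target item, a
   ridge-stabilised logistic regression (IRLS, penalty 0.01, intercept
   effectively unpenalised) of the observed cells on covariate predictors
   (standardised age, sex, method, assessed status, the outcome flags) plus
   the other items' current values; coefficients are drawn from the
   approximate normal posterior `N(β̂, (X'WX + λI)⁻¹)` and missing cells
   from the implied Bernoulli predictive distribution. Ten sweeps by
   default, columns visited in order of increasing missingness, initialised
   from observed marginals. The ridge guards against perfect separation.
   One master seed spawns independent per-imputation streams
   (`SeedSequence.spawn`), making runs bitwise reproducible. `m` defaults to
   50 in `ImputationConfig`; the evaluation layer generates 5 by default
   because only the first `m_pool = 5` enter pooled accuracy analyses.
3. **Complete case.** Episodes with any missing item of a scale are dropped.
   Restricted to the four-item rules by default: with ten-item scales and
   realistic missingness nearly all episodes would be excluded (a test
   exercises the ~2% retention regime).

**Pooling.** Rubin's rules: pooled estimate = mean; total variance = mean
within-imputation variance + (1 + 1/m) × between-imputation variance.
Intervals use a normal reference on the pooled scale by default (Student's t
with the classic small-m df is selectable). Proportions are pooled on the
empirical-logit scale (Haldane-corrected at boundaries, within-variance
`1/a + 1/b`), ratio measures on the log scale, both back-transformed.
Category-by-outcome count tables from imputed data are averaged over
imputations and rounded to integers with a largest-remainder rule per
outcome column, so each printed column partitions the analysed episodes
exactly.

## Synthetic cohort generator

The generator emulates a large unselected multicentre cohort; its defaults
*are* the study conditions: 4000 episodes by 3157 persons over a two-year
enrolment window, 60% female, age mix 14%/64%/22% (<19 / 19–44 / 45+), 81%
self-poisoning, 55% assessed (assessor mix 29%/58%/13% psychiatrist / mental
health nurse / other), 69% with prior self-harm, repeat target 28.3%,
suicide target 0.5%, 1.2% of persons unlinked to mortality records.

Mechanics and their rationale:

* **Episode counts** per person come from a geometric repeat process clipped
  at 12 and repaired to the exact episode total, matching the
  episodes-per-person ratio.
* **Items** are drawn from per-item prevalences with a shared person-level
  normal random effect (SD 0.8) inducing within-person correlation; the
  per-item logit is inflated by the standard logistic-normal correction so
  marginal prevalences stay on target. Demographic items (male sex, age
  <19/>45) and the cutting-method item derive deterministically from the
  episode's demographics and method; the prior-self-harm item is forced
  present on second and later episodes, with the first-episode prevalence
  solved so the episode-level marginal hits 69%.
* **Repetition** is a logistic model on the items, with the intercept solved
  by bisection (tolerance 1e-6) so the marginal repeat fraction hits its
  target; an infeasible target raises a calibration error. The predictive
  signal sits on the four-item rules' history/recency/treatment content;
  the ten-item scales' remaining content is near zero, so SPS/MSPS
  discriminate close to chance — the qualitative pattern the evaluation is
  designed to exhibit. A positive repeat draw is realised in the dates: the
  person's next presentation falls within the window (the next index episode
  where one exists, otherwise an extra *follow-up attendance* outside the
  analysed set); a negative draw forces the next same-person gap beyond the
  window. Follow-up attendances are necessary because a 28.3% within-table
  repeat fraction is arithmetically impossible for 4000 episodes among 3157
  persons — at most 21.1% of rows can have a later same-person row — which
  mirrors how monitoring systems ascertain repeats beyond any extracted
  sample.
* **Suicide** is drawn once per person from the last episode's items, with
  the person-level intercept calibrated so the expected death count equals
  the episode-level target times the episode count. The death is timed so
  exactly the final index episode falls inside its own window (for a
  preceding in-window episode the delay is drawn beyond its residual
  window), which keeps the episode-level suicide fraction on target without
  analytic bias corrections. A 1% background of non-suicide deaths
  exercises the cause-of-death logic. Unlinked persons are sampled among
  non-suicide persons.
* **Missingness** is applied last (it never disturbs the date-based
  outcomes), per item with probabilities split by assessment status —
  around 1–2% for chart-derivable items, 5% vs 25% for record items, 8% vs
  50% for assessment-derived psychosocial items — so missingness
  concentrates in non-assessed episodes.

What the generator does **not** emulate: between-centre heterogeneity,
drug-type coding, seasonal or secular trends, the real (unknowable)
item–outcome correlation structure, or informative missingness beyond the
assessed/non-assessed split. Passing tests therefore demonstrate that the
machinery is correct and calibrated under these conditions, not that the
scales would show identical accuracy on any particular real cohort; the
exact published AUCs and subgroup statistics require the raw data and are
covered qualitatively (discrimination ordering, sensitivity/specificity
pattern, report shape).

`recover_parameters` reports empirical marginals against targets with
z-scores on the binomial standard error; the acceptance suite checks the
four key marginals (repeat, suicide, female, assessed) across 20 seeds
against three Monte-Carlo standard errors of the replicate mean.

## Numerical choices and problem sizes

* Logistic IRLS: 50 iterations max, coefficient tolerance 1e-8, linear
  predictor clipped at ±30.
* Display rounding follows the convention of published tables: percentages
  to integers (suicide PPV/NPV to one decimal), ratio measures to one
  decimal, with full-precision values retained in machine-readable sidecars;
  half-up rounding is used for display, largest-remainder for count tables.
* Test problem sizes are chosen for tight feedback: the shared generated
  fixtures use 800-episode (unit) and 4000-episode (acceptance) cohorts,
  MICE in tests runs m = 2–5 with 3–5 sweeps, and the AUC oracle sweeps
  1000 random instances of n ≤ 50. The acceptance script averages 20
  default-size replicates.

## Known limitations

* The chained-equations engine covers binary items and (minimal)
  categorical covariates; continuous-variable imputation is out of scope.
* AUC pooling across imputations is on the identity scale; for AUCs far
  from 0.5 a logit pooling scale would be marginally better behaved.
* The homogeneity chi-square treats subgroup AUCs as independent, which is
  exact for disjoint subgroups but ignores the shared imputation stage.
* Episode-level analyses treat episodes as independent observations, as the
  design being replicated does; within-person correlation is reflected in
  the generator but not in the interval estimates.
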