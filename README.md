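# harmscales

Head-to-head diagnostic-accuracy evaluation of clinical risk scales for
self-harm, on episode-level emergency-department cohorts.

## The problem

Emergency departments see large numbers of self-harm presentations, and many
hospitals use short risk scales to classify each episode as low, moderate or
high risk of further self-harm or suicide. Whether those classifications
actually predict anything is an empirical question: it requires scoring every
episode of an unselected cohort on each scale, following each episode for a
fixed window (six months here), and computing the full diagnostic-accuracy
battery for both outcomes — repeat self-harm and suicide.

`harmscales` implements that evaluation as a tested pipeline for four widely
studied instruments:

| scale | items | positive rule |
|---|---|---|
| Manchester Self-Harm Rule (MSHR) | 4, unit weight | score 0 = low, ≥1 = moderate/high |
| ReACT Self-Harm Rule (ReACT) | 4, unit weight | score 0 = low, ≥1 = moderate/high |
| SAD PERSONS Scale (SPS) | 10, unit weight | 0–4 low, 5–6 moderate, 7–10 high |
| Modified SAD PERSONS (MSPS) | 10, four weighted ×2 (max 14) | 0–5 low, 6–8 moderate, >8 high |

For a 2×2 cross-classification of test result against outcome the package
reports sensitivity `tp/(tp+fn)`, specificity `tn/(fp+tn)`, predictive
values, likelihood ratios `LR+ = sens/(1−spec)`, `LR− = (1−sens)/spec`, and
the diagnostic odds ratio `DOR = (tp·tn)/(fp·fn) = LR+/LR−`, each with a
confidence interval (Wilson score or Clopper–Pearson exact for proportions,
Woolf log method for the DOR, Simel log method for the LRs). ROC curves are
traced over every achievable score threshold; the trapezoidal AUC equals the
Mann–Whitney concordance probability (ties counted ½) and carries a
Hanley–McNeil standard error, with a chi-square homogeneity test for AUC
differences between subgroups (sex, age band, method of harm, assessor
profession, self-harm history).

Three-category scales are dichotomised by *adjacent-category* comparisons:
low vs moderate (high excluded) and moderate vs high (low excluded).

Missing item data — unavoidable in routine clinical records, and
concentrated in episodes without a psychosocial assessment — are handled by
three strategies: an *absent rule* (presence-biased items recoded
missing→absent on non-assessed episodes), multiple imputation by chained
equations with Rubin's-rules pooling, and complete-case restriction (only
feasible for the four-item rules).

Because routine clinical cohorts cannot be shared, the package includes a
calibrated synthetic-cohort generator (4000 episodes by 3157 persons, 60%
female, 81% self-poisoning, 55% assessed, 28.3% six-month repetition, 0.5%
suicide incidence, ~1% lost to mortality follow-up) so every stage is
exercisable and testable end to end.

## Worked example

Published evaluations often print the category-by-outcome counts. Those
margins are enough to recompute every accuracy measure; reference counts from
a large multicentre English cohort ship with the package:

```python
from harmscales.datasets import reference_count_tables
from harmscales.pipeline import table_from_counts

counts = reference_count_tables("repeat")["MSHR"]
# {'low': (23, 435), 'moderate_high': (1110, 2432)}
table = table_from_counts(counts, "MSHR")
print(table[["sensitivity", "specificity", "ppv", "npv", "dor"]].round(4))
```

```
   sensitivity  specificity     ppv     npv     dor
0       0.9797       0.1517  0.3134  0.9498  8.6322
```

Read: of 1133 episodes followed by repetition within six months, 98.0% had
been rated moderate/high risk (high sensitivity), but only 15.2% of
non-repeating episodes were rated low risk (low specificity); a positive
rating carried a 31.3% chance of repetition. The Woolf interval for the DOR
is (5.64, 13.21).

The same battery runs end to end from episode data:

```python
import harmscales as hs

cohort = hs.generate(hs.default_params(seed=1))
model = hs.ScaleAccuracy.from_generated(
    cohort, imputation=hs.ImputationConfig(m=5, m_pool=5, seed=7)
)
results = model.fit()
print(results.summary())
```

which prints the count tables' accuracy battery for both outcomes plus the
overall AUCs, e.g. (seed 1):

```
-- overall AUC (repeat outcome) --
MSHR   AUC 0.65 (0.63, 0.67)
ReACT  AUC 0.64 (0.62, 0.67)
SPS    AUC 0.58 (0.55, 0.60)
MSPS   AUC 0.57 (0.55, 0.59)
```

reproducing the qualitative pattern of interest: the four-item rules are
sensitive but unspecific and discriminate fairly; the ten-item scales are
specific but insensitive and sit near chance.

A `harmscales` console script wraps the same machinery
(`simulate`, `evaluate`, `run-all`, `from-counts`); see `harmscales --help`.

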