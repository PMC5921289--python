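"""Two-by-two tables, accuracy measures, ROC/AUC and subgroup comparison.

Dichotomisation conventions
---------------------------
Binary scales (MSHR, ReACT) contrast low risk (score 0) against
moderate/high risk (score >= 1).  Three-category scales (SPS, MSPS) are
evaluated with *adjacent-category* comparisons: low vs moderate (high-risk
episodes excluded from the table) and moderate vs high (low excluded).
Excluding the third category is the convention under which the published
percentage columns for these scales are internally consistent with the
category-by-outcome counts, so it is hard-coded here as the two
``adjacent_*`` conventions.

Confidence intervals
--------------------
Proportions use the Wilson score interval by default (Clopper-Pearson exact
intervals are selectable and are the better match for very small counts such
as suicide outcomes); the diagnostic odds ratio uses the Woolf log method;
likelihood ratios use the Simel log method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import UndefinedMetricError
from .scales import HIGH, LOW, MODERATE, MODERATE_HIGH, ScaleDefinition

BINARY = "binary"
ADJACENT_LOW_MOD = "adjacent_low_mod"
ADJACENT_MOD_HIGH = "adjacent_mod_high"

WILSON = "wilson"
EXACT = "exact"
_PROPORTION_METHODS = {WILSON: "wilson", EXACT: "beta"}


@dataclass(frozen=True)
class Comparison:
    """Which categories of a scale form the positive/negative test arms."""

    scale: str
    convention: str  # binary | adjacent_low_mod | adjacent_mod_high

    def __post_init__(self) -> None:
        if self.convention not in (BINARY, ADJACENT_LOW_MOD, ADJACENT_MOD_HIGH):
            raise ValueError(f"unknown convention {self.convention!r}")

    @property
    def label(self) -> str:
        return {
            BINARY: "low (0) vs moderate/high (1+)",
            ADJACENT_LOW_MOD: "low vs moderate (high excluded)",
            ADJACENT_MOD_HIGH: "moderate vs high (low excluded)",
        }[self.convention]


@dataclass(frozen=True)
class TwoByTwo:
    """Test-positive/negative by outcome-positive/negative episode counts."""

    tp: int
    fp: int
    fn: int
    tn: int
    excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn, self.excluded) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        """Episodes inside the compared categories."""
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_analysed(self) -> int:
        return self.n + self.excluded


def build_two_by_two(
    categories: Mapping[str, str],
    outcomes: Mapping[str, bool],
    comparison: Comparison,
) -> TwoByTwo:
    """Cross-tabulate risk category against outcome under a convention.

    ``categories`` and ``outcomes`` are keyed by episode id and must cover
    the same episodes.  Under the adjacent conventions, episodes in the third
    category are counted as ``excluded``.
    """
    if set(categories) != set(outcomes):
        raise ValueError("categories and outcomes must cover the same episodes")
    if comparison.convention == BINARY:
        positive, negative = {MODERATE_HIGH}, {LOW}
    elif comparison.convention == ADJACENT_LOW_MOD:
        positive, negative = {MODERATE}, {LOW}
    else:
        positive, negative = {HIGH}, {MODERATE}
    allowed = positive | negative | {LOW, MODERATE, HIGH, MODERATE_HIGH}
    tp = fp = fn = tn = excluded = 0
    for eid, cat in categories.items():
        if cat not in allowed:
            raise ValueError(
                f"category {cat!r} incompatible with convention "
                f"{comparison.convention!r}"
            )
        out = bool(outcomes[eid])
        if cat in positive:
            tp += out
            fp += not out
        elif cat in negative:
            fn += out
            tn += not out
        else:
            excluded += 1
    if comparison.convention == BINARY and excluded:
        raise ValueError("binary convention admits only low and moderate_high")
    return TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn, excluded=excluded)


@dataclass(frozen=True)
class Estimate:
    """Point estimate with a confidence interval; NaN marks undefined."""

    value: float
    ci_low: float
    ci_high: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


_UNDEFINED = Estimate(math.nan, math.nan, math.nan)


@dataclass(frozen=True)
class AccuracyReport:
    """The full accuracy battery for one 2x2 table."""

    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    lr_pos: Estimate
    lr_neg: Estimate
    dor: Estimate
    n_analysed: int
    excluded: int = 0
    m: int = 1  # imputations pooled

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for name in ("sensitivity", "specificity", "ppv", "npv",
                     "lr_pos", "lr_neg", "dor"):
            est: Estimate = getattr(self, name)
            out[name] = est.value
            out[f"{name}_ci_low"] = est.ci_low
            out[f"{name}_ci_high"] = est.ci_high
        out["n_analysed"] = self.n_analysed
        out["excluded"] = self.excluded
        out["m"] = self.m
        return out


def _proportion_estimate(count: int, nobs: int, ci_level: float, method: str) -> Estimate:
    if nobs == 0:
        return _UNDEFINED
    lo, hi = proportion_confint(
        count, nobs, alpha=1 - ci_level, method=_PROPORTION_METHODS[method]
    )
    return Estimate(count / nobs, float(lo), float(hi))


def _log_method_estimate(value: float, se_log: float, z: float) -> Estimate:
    if not math.isfinite(value) or value <= 0 or not math.isfinite(se_log):
        return _UNDEFINED
    log_v = math.log(value)
    return Estimate(value, math.exp(log_v - z * se_log), math.exp(log_v + z * se_log))


def accuracy_metrics(
    t: TwoByTwo,
    ci_level: float = 0.95,
    proportion_ci: str = WILSON,
    continuity: bool = False,
) -> AccuracyReport:
    """Compute sensitivity, specificity, PPV, NPV, LR+, LR-, DOR with CIs.

    Metrics whose denominator is empty are returned as undefined (NaN); the
    DOR and the likelihood ratios are undefined when a needed cell is zero
    unless ``continuity`` adds the Haldane 0.5 correction to every cell.
    """
    z = stats.norm.ppf(0.5 + ci_level / 2)
    sens = _proportion_estimate(t.tp, t.tp + t.fn, ci_level, proportion_ci)
    spec = _proportion_estimate(t.tn, t.fp + t.tn, ci_level, proportion_ci)
    ppv = _proportion_estimate(t.tp, t.tp + t.fp, ci_level, proportion_ci)
    npv = _proportion_estimate(t.tn, t.fn + t.tn, ci_level, proportion_ci)

    tp, fp, fn, tn = t.tp, t.fp, t.fn, t.tn
    if continuity and 0 in (tp, fp, fn, tn):
        tp, fp, fn, tn = (c + 0.5 for c in (tp, fp, fn, tn))

    n_pos, n_neg = tp + fn, fp + tn
    if n_pos and n_neg and fp and sens.defined:
        lr_pos_val = (tp / n_pos) / (fp / n_neg)
        se = math.sqrt(
            max(1 / tp - 1 / n_pos + 1 / fp - 1 / n_neg, 0.0)
        ) if tp else math.inf
        lr_pos = _log_method_estimate(lr_pos_val, se, z)
    else:
        lr_pos = _UNDEFINED
    if n_pos and n_neg and tn and fn:
        lr_neg_val = (fn / n_pos) / (tn / n_neg)
        se = math.sqrt(max(1 / fn - 1 / n_pos + 1 / tn - 1 / n_neg, 0.0))
        lr_neg = _log_method_estimate(lr_neg_val, se, z)
    else:
        lr_neg = _UNDEFINED
    if all(c > 0 for c in (tp, fp, fn, tn)):
        dor_val = (tp * tn) / (fp * fn)
        se = math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)  # Woolf
        dor = _log_method_estimate(dor_val, se, z)
    else:
        dor = _UNDEFINED
    return AccuracyReport(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        dor=dor,
        n_analysed=t.n_analysed,
        excluded=t.excluded,
    )


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class RocCurve:
    """ROC points over every achievable score threshold, with trapezoidal AUC.

    ``points`` is an ``(k, 2)`` array of ``(1 - specificity, sensitivity)``
    pairs anchored at (0, 0) and (1, 1); ``auc_se`` is the Hanley-McNeil
    standard error.
    """

    points: np.ndarray
    auc: float
    auc_se: float
    n_positive: int
    n_negative: int


def roc_curve(
    scores: Mapping[str, int] | Sequence[int],
    outcomes: Mapping[str, bool] | Sequence[bool],
) -> RocCurve:
    """ROC curve for integer scores against a boolean outcome.

    A point is generated for every threshold ``t`` in the achievable score
    range, classifying ``score >= t`` as test positive.  The trapezoidal
    area equals the Mann-Whitney concordance probability with ties counted
    one half.
    """
    if isinstance(scores, Mapping):
        keys = list(scores)
        if not isinstance(outcomes, Mapping) or set(keys) != set(outcomes):
            raise ValueError("scores and outcomes must cover the same episodes")
        s = np.asarray([scores[k] for k in keys], dtype=float)
        y = np.asarray([bool(outcomes[k]) for k in keys], dtype=bool)
    else:
        s = np.asarray(scores, dtype=float)
        y = np.asarray(outcomes, dtype=bool)
        if s.shape != y.shape:
            raise ValueError("scores and outcomes must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC needs at least one positive and one negative")
    thresholds = np.unique(s)
    pts = [(1.0, 1.0)]  # threshold at/below min score: everyone positive
    for t in thresholds:
        sens = float((s[y] >= t).sum() / n_pos)
        fpr = float((s[~y] >= t).sum() / n_neg)
        pts.append((fpr, sens))
    pts.append((0.0, 0.0))  # threshold above max score
    points = np.array(sorted(set(pts)), dtype=float)
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return RocCurve(
        points=points,
        auc=auc,
        auc_se=hanley_mcneil_se(auc, n_pos, n_neg),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def hanley_mcneil_se(auc: float, n_positive: int, n_negative: int) -> float:
    """Hanley-McNeil standard error of a trapezoidal AUC."""
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (
        a * (1 - a)
        + (n_positive - 1) * (q1 - a * a)
        + (n_negative - 1) * (q2 - a * a)
    ) / (n_positive * n_negative)
    return math.sqrt(max(var, 0.0))


def compare_auc_subgroups(
    curves: Iterable,
) -> tuple[float, int, float]:
    """Chi-square homogeneity test of AUCs across independent subgroups.

    Accepts :class:`RocCurve` objects (or any objects with ``auc`` and
    ``auc_se``, or ``(auc, se)`` pairs).  With weights ``w_i = 1 / SE_i**2``
    and weighted mean ``A-bar``, the statistic ``sum w_i (A_i - A-bar)**2``
    is referred to chi-square on ``k - 1`` degrees of freedom; for two
    groups this is the square of the usual two-sample z for independent
    AUCs.
    """
    aucs, ses = [], []
    for c in curves:
        if hasattr(c, "auc"):
            aucs.append(c.auc)
            ses.append(c.auc_se)
        else:
            a, se = c
            aucs.append(a)
            ses.append(se)
    if len(aucs) < 2:
        raise ValueError("need at least two subgroups")
    if any(not math.isfinite(se) or se <= 0 for se in ses):
        raise UndefinedMetricError("undefined AUC standard error in a subgroup")
    a = np.asarray(aucs)
    w = 1.0 / np.asarray(ses) ** 2
    abar = float(np.sum(w * a) / np.sum(w))
    chi2 = float(np.sum(w * (a - abar) ** 2))
    df = len(aucs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


# ---------------------------------------------------------------------------
# Pooling across imputations


def _pool_transformed(
    values: Sequence[float],
    variances: Sequence[float],
    transform: str,
    ci_level: float,
):
    """Rubin-pool on a transformed scale, back-transform the CI."""
    from .missingness import rubin_pool

    pooled = rubin_pool(list(values), list(variances), ci_level=ci_level)
    if transform == "logit":
        inv = lambda x: 1 / (1 + math.exp(-x))  # noqa: E731
    elif transform == "log":
        inv = math.exp
    else:
        inv = lambda x: x  # noqa: E731
    return Estimate(inv(pooled.estimate), inv(pooled.ci_low), inv(pooled.ci_high))


def _logit_and_var(count: float, nobs: float) -> tuple[float, float]:
    # Haldane-corrected empirical logit keeps boundary proportions finite.
    if nobs == 0:
        return math.nan, math.nan
    a, b = count, nobs - count
    if a == 0 or b == 0:
        a, b = a + 0.5, b + 0.5
    return math.log(a / b), 1 / a + 1 / b


def pooled_accuracy(
    completed: Sequence,
    definition: ScaleDefinition,
    comparison: Comparison,
    outcomes: Mapping[str, bool],
    ci_level: float = 0.95,
    m_pool: int | None = None,
) -> AccuracyReport:
    """Accuracy battery pooled over multiply imputed cohorts.

    Each completed cohort is scored and cross-tabulated; proportions are
    pooled on the empirical-logit scale and ratio measures on the log scale
    via Rubin's rules, then back-transformed.  ``m_pool`` limits pooling to
    the first imputations (the published convention pools m = 1-5).
    """
    from .scales import TREAT_AS_ABSENT, score_episode

    cohorts = list(completed)[: m_pool or None]
    if not cohorts:
        raise ValueError("no completed cohorts supplied")
    tables: list[TwoByTwo] = []
    for cc in cohorts:
        cats = {
            e.episode_id: score_episode(e, definition, TREAT_AS_ABSENT).category
            for e in cc.episodes
            if e.episode_id in outcomes
        }
        tables.append(build_two_by_two(cats, {k: outcomes[k] for k in cats}, comparison))
    if len(tables) == 1:
        rep = accuracy_metrics(tables[0], ci_level=ci_level)
        return AccuracyReport(**{**rep.__dict__, "m": 1})

    def pool_prop(counts: list[tuple[int, int]]) -> Estimate:
        pairs = [_logit_and_var(c, n) for c, n in counts]
        if any(math.isnan(v) for v, _ in pairs):
            return _UNDEFINED
        return _pool_transformed(
            [v for v, _ in pairs], [v for _, v in pairs], "logit", ci_level
        )

    def pool_ratio(values: list[float], variances: list[float]) -> Estimate:
        if any(not math.isfinite(v) or v <= 0 for v in values):
            return _UNDEFINED
        return _pool_transformed(
            [math.log(v) for v in values], variances, "log", ci_level
        )

    sens = pool_prop([(t.tp, t.tp + t.fn) for t in tables])
    spec = pool_prop([(t.tn, t.fp + t.tn) for t in tables])
    ppv = pool_prop([(t.tp, t.tp + t.fp) for t in tables])
    npv = pool_prop([(t.tn, t.fn + t.tn) for t in tables])

    def ratio_parts(t: TwoByTwo, which: str) -> tuple[float, float]:
        tp, fp, fn, tn = t.tp, t.fp, t.fn, t.tn
        if 0 in (tp, fp, fn, tn):
            tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
        n_pos, n_neg = tp + fn, fp + tn
        if which == "lr_pos":
            return (tp / n_pos) / (fp / n_neg), 1 / tp - 1 / n_pos + 1 / fp - 1 / n_neg
        if which == "lr_neg":
            return (fn / n_pos) / (tn / n_neg), 1 / fn - 1 / n_pos + 1 / tn - 1 / n_neg
        return (tp * tn) / (fp * fn), 1 / tp + 1 / fp + 1 / fn + 1 / tn

    reports = {}
    for which in ("lr_pos", "lr_neg", "dor"):
        parts = [ratio_parts(t, which) for t in tables]
        reports[which] = pool_ratio([v for v, _ in parts], [v for _, v in parts])
    return AccuracyReport(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=reports["lr_pos"],
        lr_neg=reports["lr_neg"],
        dor=reports["dor"],
        n_analysed=tables[0].n_analysed,
        excluded=round(float(np.mean([t.excluded for t in tables]))),
        m=len(tables),
    )
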