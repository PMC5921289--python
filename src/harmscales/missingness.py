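"""Missing-data strategies: absent-rule recoding, chained-equation multiple
imputation, Rubin pooling and complete-case filtering.

Three strategies are supported, mirroring routine practice with clinical
cohorts where item completeness depends on whether a psychosocial assessment
took place:

1. **Absent rule** — for *non-assessed* episodes, selected items whose
   recording is biased toward presence (clinicians note them when present,
   not when absent) are recoded missing -> absent before imputation.  The
   predictable effect is to underestimate sensitivity and overestimate
   specificity.
2. **Chained equations (MICE)** — remaining missing tri-state items are
   imputed by iterated conditional logistic models.  Each sweep fits a
   ridge-stabilised logistic regression of one item on the covariate
   predictors, the outcome flags and the other items' current values, draws
   coefficients from the approximate normal posterior and then draws the
   missing cells from the implied Bernoulli predictive distribution.  The
   ridge penalty guards against perfect separation.
3. **Complete case** — restrict to episodes with every item of a scale
   observed.  Only feasible for short scales; with ten-item scales nearly
   all episodes are dropped.

Estimates from multiply imputed data are combined with Rubin's rules:
pooled point estimate is the mean, total variance is the mean
within-imputation variance plus ``(1 + 1/m)`` times the between-imputation
variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import Episode, ItemState
from .errors import HarmScalesError
from .scales import ITEM_VOCABULARY, ScaleDefinition

DEFAULT_ABSENT_RULE_ITEMS = (
    # presence-biased recording concerns the depression/hopelessness,
    # organised/serious-attempt and rational-thinking-loss content of the
    # ten-item scales; both scales' variants of each concept are listed
    "depression",
    "depression_or_hopelessness",
    "organised_plan",
    "organised_or_serious_attempt",
    "rational_thinking_loss",
)

DEFAULT_PREDICTORS = ("age", "sex", "method", "assessed", "repeat_6m", "suicide_6m")


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for :func:`mice_impute`.

    ``m`` completed datasets are generated; pooled accuracy analyses use the
    first ``m_pool`` of them.  ``predictors`` names episode covariates and
    outcome flags entering every conditional model; other items' current
    values are additionally included when ``condition_on_items`` is true.
    """

    m: int = 50
    m_pool: int = 5
    seed: int = 0
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    absent_rule_items: tuple[str, ...] = DEFAULT_ABSENT_RULE_ITEMS
    sweeps: int = 10
    ridge: float = 1e-2
    condition_on_items: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.m_pool <= self.m:
            raise ValueError("need 1 <= m_pool <= m")
        unknown = set(self.absent_rule_items) - set(ITEM_VOCABULARY)
        if unknown:
            raise ValueError(f"absent_rule_items outside vocabulary: {sorted(unknown)}")


@dataclass(frozen=True)
class CompletedCohort:
    """One imputed copy of the cohort; no missing item states remain."""

    imputation_index: int
    episodes: tuple[Episode, ...]


def apply_absent_rule(
    episodes: Sequence[Episode],
    absent_rule_items: Sequence[str] = DEFAULT_ABSENT_RULE_ITEMS,
) -> tuple[list[Episode], int]:
    """Recode selected missing items to absent on non-assessed episodes.

    Returns a modified copy of the cohort and the number of changed cells.
    Assessed episodes are untouched; the operation is idempotent and never
    creates missing states.
    """
    out: list[Episode] = []
    changed = 0
    rule = set(absent_rule_items)
    for e in episodes:
        if e.assessed:
            out.append(e)
            continue
        items = dict(e.items)
        touched = False
        for name in rule & set(items):
            if items[name] is ItemState.MISSING:
                items[name] = ItemState.ABSENT
                changed += 1
                touched = True
        out.append(replace(e, items=items) if touched else e)
    return out, changed


def code_not_present(episodes: Sequence[Episode]) -> list[Episode]:
    """Sensitivity-analysis coding: every missing item becomes absent."""
    out = []
    for e in episodes:
        if any(s is ItemState.MISSING for s in e.items.values()):
            items = {
                k: (ItemState.ABSENT if v is ItemState.MISSING else v)
                for k, v in e.items.items()
            }
            out.append(replace(e, items=items))
        else:
            out.append(e)
    return out


def complete_case_filter(
    episodes: Sequence[Episode], definition: ScaleDefinition
) -> tuple[list[Episode], float]:
    """Retain episodes with all of a scale's items observed.

    Returns the retained episodes (input order preserved) and the retained
    fraction.
    """
    names = definition.item_names
    kept = [
        e
        for e in episodes
        if all(e.items.get(n, ItemState.MISSING) is not ItemState.MISSING for n in names)
    ]
    frac = len(kept) / len(episodes) if episodes else 0.0
    return kept, frac


# ---------------------------------------------------------------------------
# Chained-equations engine


def _ridge_logit(X: np.ndarray, y: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-penalised logistic fit by IRLS; returns (beta, covariance)."""
    n, p = X.shape
    beta = np.zeros(p)
    pen = alpha * np.eye(p)
    pen[0, 0] = 1e-8  # effectively unpenalised intercept
    for _ in range(50):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1 / (1 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        xtw = X.T * w
        h = xtw @ X + pen
        beta_new = np.linalg.solve(h, xtw @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    eta = np.clip(X @ beta, -30, 30)
    mu = 1 / (1 + np.exp(-eta))
    w = np.maximum(mu * (1 - mu), 1e-10)
    h = (X.T * w) @ X + pen
    cov = np.linalg.inv(h)
    return beta, cov


def _covariate_design(
    episodes: Sequence[Episode],
    predictors: Sequence[str],
    outcomes: Mapping[str, Mapping[str, object]] | None,
) -> np.ndarray:
    """Fixed (non-item) part of the conditional-model design matrix."""
    from .cohort import SELF_INJURY, YES

    cols: list[np.ndarray] = [np.ones(len(episodes))]
    ages = np.array([e.age for e in episodes], dtype=float)
    for name in predictors:
        if name == "age":
            sd = ages.std() or 1.0
            cols.append((ages - ages.mean()) / sd)
        elif name == "sex":
            cols.append(np.array([e.sex == "female" for e in episodes], float))
        elif name == "method":
            cols.append(np.array([e.method == SELF_INJURY for e in episodes], float))
        elif name == "assessed":
            cols.append(np.array([e.assessed for e in episodes], float))
        elif name in ("repeat_6m", "suicide_6m"):
            if outcomes is None:
                continue  # outcomes not supplied; predictor silently dropped
            if name == "repeat_6m":
                cols.append(
                    np.array(
                        [bool(outcomes[e.episode_id]["repeat_6m"]) for e in episodes],
                        float,
                    )
                )
            else:
                cols.append(
                    np.array(
                        [outcomes[e.episode_id]["suicide_6m"] == YES for e in episodes],
                        float,
                    )
                )
        else:
            raise ValueError(f"unknown predictor {name!r}")
    return np.column_stack(cols)


def mice_impute(
    episodes: Sequence[Episode],
    config: ImputationConfig,
    outcomes: Mapping[str, Mapping[str, object]] | None = None,
) -> list[CompletedCohort]:
    """Multiple imputation of missing tri-state items by chained equations.

    ``outcomes`` optionally maps episode id to ``{"repeat_6m": bool,
    "suicide_6m": str}`` so the outcome flags can enter the imputation model
    (recommended: imputation models should contain everything the analysis
    model uses).  Fully reproducible given ``config.seed``; per-imputation
    random streams are spawned deterministically from the master seed.
    """
    item_names = [
        n
        for n in ITEM_VOCABULARY
        if any(n in e.items for e in episodes)
    ]
    n = len(episodes)
    if n == 0:
        return [CompletedCohort(k + 1, ()) for k in range(config.m)]
    # tri-state matrix: 1 present, 0 absent, nan missing
    code = {ItemState.PRESENT: 1.0, ItemState.ABSENT: 0.0, ItemState.MISSING: np.nan}
    mat = np.array(
        [[code[e.items[nm]] if nm in e.items else np.nan for nm in item_names]
         for e in episodes],
        dtype=float,
    )
    miss_mask = np.isnan(mat)
    targets = [j for j in range(len(item_names)) if miss_mask[:, j].any()]
    for j in targets:
        if miss_mask[:, j].all():
            raise HarmScalesError(
                f"item {item_names[j]!r} is 100% missing; cannot initialise"
            )
    base = _covariate_design(episodes, config.predictors, outcomes)
    # impute columns in order of increasing missingness
    targets.sort(key=lambda j: miss_mask[:, j].sum())

    streams = np.random.SeedSequence(config.seed).spawn(config.m)
    completed: list[CompletedCohort] = []
    for k in range(config.m):
        rng = np.random.default_rng(streams[k])
        filled = mat.copy()
        if targets:
            # initialise missing cells from observed marginals
            for j in targets:
                obs = mat[~miss_mask[:, j], j]
                p0 = obs.mean() if obs.size else 0.5
                idx = miss_mask[:, j]
                filled[idx, j] = rng.random(idx.sum()) < p0
            for _ in range(config.sweeps):
                for j in targets:
                    obs_rows = ~miss_mask[:, j]
                    mis_rows = miss_mask[:, j]
                    if config.condition_on_items:
                        others = [c for c in range(len(item_names)) if c != j]
                        X = np.column_stack([base, filled[:, others]])
                    else:
                        X = base
                    y = filled[obs_rows, j]
                    if y.min() == y.max():
                        # constant observed column: draw from that constant
                        filled[mis_rows, j] = y[0]
                        continue
                    beta, cov = _ridge_logit(X[obs_rows], y, config.ridge)
                    draw = rng.multivariate_normal(beta, cov, method="cholesky")
                    p = 1 / (1 + np.exp(-np.clip(X[mis_rows] @ draw, -30, 30)))
                    filled[mis_rows, j] = rng.random(mis_rows.sum()) < p
        eps = []
        for i, e in enumerate(episodes):
            if not miss_mask[i].any():
                eps.append(e)
                continue
            items = dict(e.items)
            for c, nm in enumerate(item_names):
                if nm in items:
                    items[nm] = (
                        ItemState.PRESENT if filled[i, c] == 1.0 else ItemState.ABSENT
                    )
            eps.append(replace(e, items=items))
        completed.append(CompletedCohort(k + 1, tuple(eps)))
    return completed


# ---------------------------------------------------------------------------
# Rubin's rules


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    variance: float
    ci_low: float
    ci_high: float
    m: int


def rubin_pool(
    estimates: Sequence[float],
    variances: Sequence[float],
    ci_level: float = 0.95,
    df_method: str = "normal",
) -> PooledEstimate:
    """Combine estimates across imputations with Rubin's rules.

    Pooled estimate is the mean; total variance is the mean within-imputation
    variance plus ``(1 + 1/m)`` times the between-imputation variance.  The
    interval uses a normal reference by default, or Student's t with the
    Barnard-Rubin degrees of freedom (``df_method="barnard_rubin"``, small-m
    correction without a complete-data df).
    """
    if len(estimates) != len(variances):
        raise ValueError("estimates and variances must have equal length")
    m = len(estimates)
    if m == 0:
        raise ValueError("need at least one estimate")
    if any(v < 0 for v in variances):
        raise ValueError("variances must be non-negative")
    q = float(np.mean(estimates))
    ubar = float(np.mean(variances))
    b = float(np.var(estimates, ddof=1)) if m > 1 else 0.0
    total = ubar + (1 + 1 / m) * b
    se = math.sqrt(total)
    alpha = 1 - ci_level
    if df_method == "barnard_rubin" and m > 1 and b > 0:
        # classic (old-style) Rubin df; adequate without a complete-data df
        r = (1 + 1 / m) * b / ubar if ubar > 0 else math.inf
        nu = (m - 1) * (1 + 1 / r) ** 2 if math.isfinite(r) else m - 1
        crit = stats.t.ppf(1 - alpha / 2, nu)
    else:
        crit = stats.norm.ppf(1 - alpha / 2)
    return PooledEstimate(q, total, q - crit * se, q + crit * se, m)
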