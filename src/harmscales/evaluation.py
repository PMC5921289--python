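"""Model/Results interface tying the whole evaluation together.

:class:`ScaleAccuracy` is built from episode-level data (plus deaths and
mortality-linkage information) and a missing-data strategy; ``fit()`` runs
outcome ascertainment, the missing-data handling, scoring, and the full
accuracy battery, returning a :class:`ScaleAccuracyResults` carrying the
category-by-outcome count tables, pooled accuracy reports for both outcomes,
overall and subgroup AUCs with homogeneity tests, ROC points, and a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .accuracy import (
    ADJACENT_LOW_MOD,
    ADJACENT_MOD_HIGH,
    BINARY,
    WILSON,
    Comparison,
    RocCurve,
    accuracy_metrics,
    build_two_by_two,
    compare_auc_subgroups,
    pooled_accuracy,
    roc_curve,
)
from .cohort import (
    LOST_TO_FOLLOWUP,
    SIX_MONTHS_DAYS,
    YES,
    DeathRecord,
    Episode,
    assign_subgroups,
    flag_repeat_within_window,
    flag_suicide_within_window,
    read_cohort,
    read_deaths,
)
from .errors import UndefinedMetricError
from .missingness import (
    CompletedCohort,
    ImputationConfig,
    apply_absent_rule,
    code_not_present,
    complete_case_filter,
    mice_impute,
    rubin_pool,
)
from .scales import (
    TREAT_AS_ABSENT,
    ScaleDefinition,
    builtin_definitions,
    score_episode,
)

ABSENT_RULE_MICE = "absent_rule_mice"
NOT_PRESENT = "not_present"
COMPLETE_CASE = "complete_case"

#: scales short enough for complete-case restriction to retain most episodes
COMPLETE_CASE_SCALES = ("MSHR", "ReACT")


def default_comparisons(
    definitions: Mapping[str, ScaleDefinition]
) -> dict[str, list[Comparison]]:
    """Binary comparison for two-band scales, both adjacent ones otherwise."""
    out: dict[str, list[Comparison]] = {}
    for name, d in definitions.items():
        if len(d.categories) == 2:
            out[name] = [Comparison(name, BINARY)]
        else:
            out[name] = [
                Comparison(name, ADJACENT_LOW_MOD),
                Comparison(name, ADJACENT_MOD_HIGH),
            ]
    return out


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style rounding: halves away from zero (display convention)."""
    if math.isnan(x):
        return x
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def _round_preserving_sum(values: Sequence[float]) -> list[int]:
    """Round to integers keeping the (integral) total: largest remainder."""
    floors = [math.floor(v) for v in values]
    remainder = round(sum(values) - sum(floors))
    order = sorted(
        range(len(values)), key=lambda i: values[i] - floors[i], reverse=True
    )
    out = list(floors)
    for i in order[:remainder]:
        out[i] += 1
    return out


_SUBGROUP_DIMENSIONS = ("sex", "age", "method", "assessor", "history")


class ScaleAccuracy:
    """Diagnostic-accuracy evaluation of risk scales on an episode cohort.

    Parameters
    ----------
    episodes
        Index episodes (the analysis units).
    deaths, linked
        Mortality records and the set of persons with mortality linkage;
        ``linked=None`` treats every person as linked.
    attendances
        Optional extra self-harm presentations (beyond the index episodes)
        used for repeat ascertainment only.
    strategy
        ``absent_rule_mice`` (absent-rule recoding then chained-equation
        imputation, the primary analysis), ``not_present`` (all missing
        items coded absent) or ``complete_case`` (episodes with any missing
        scale item dropped; restricted to the short scales by default).
    """

    def __init__(
        self,
        episodes: Sequence[Episode],
        deaths: Sequence[DeathRecord] = (),
        linked: frozenset[str] | set[str] | None = None,
        attendances: Sequence[Episode] = (),
        definitions: Mapping[str, ScaleDefinition] | None = None,
        comparisons: Mapping[str, Sequence[Comparison]] | None = None,
        strategy: str = ABSENT_RULE_MICE,
        imputation: ImputationConfig | None = None,
        window_days: int = SIX_MONTHS_DAYS,
        ci_level: float = 0.95,
        proportion_ci: str = WILSON,
    ) -> None:
        if strategy not in (ABSENT_RULE_MICE, NOT_PRESENT, COMPLETE_CASE):
            raise ValueError(f"unknown strategy {strategy!r}")
        self.episodes = list(episodes)
        self.deaths = list(deaths)
        self.linked = (
            frozenset(linked)
            if linked is not None
            else frozenset(e.person_id for e in self.episodes)
        )
        self.attendances = list(attendances)
        self.definitions = dict(definitions or builtin_definitions())
        self.comparisons = (
            {k: list(v) for k, v in comparisons.items()}
            if comparisons is not None
            else default_comparisons(self.definitions)
        )
        if strategy == COMPLETE_CASE:
            self.definitions = {
                k: v
                for k, v in self.definitions.items()
                if k in COMPLETE_CASE_SCALES
            }
            self.comparisons = {
                k: v for k, v in self.comparisons.items() if k in self.definitions
            }
        self.strategy = strategy
        self.imputation = imputation or ImputationConfig(m=5, m_pool=5)
        self.window_days = window_days
        self.ci_level = ci_level
        self.proportion_ci = proportion_ci

    @classmethod
    def from_files(
        cls,
        cohort_path,
        deaths_path=None,
        linked_path=None,
        attendances_path=None,
        dialect=None,
        **kwargs,
    ) -> "ScaleAccuracy":
        episodes = read_cohort(cohort_path, dialect)
        deaths = read_deaths(deaths_path, dialect) if deaths_path else []
        linked = None
        if linked_path:
            with open(linked_path) as fh:
                linked = frozenset(
                    line.strip() for line in fh if line.strip()
                ) - {"person_id"}
        attendances = (
            read_cohort(attendances_path, dialect) if attendances_path else ()
        )
        return cls(episodes, deaths, linked, attendances, **kwargs)

    @classmethod
    def from_generated(cls, cohort, **kwargs) -> "ScaleAccuracy":
        """Build from a :class:`~harmscales.synthetic.GeneratedCohort`."""
        return cls(
            cohort.episodes,
            cohort.deaths,
            cohort.linked,
            attendances=cohort.followups,
            **kwargs,
        )

    # -- fitting ------------------------------------------------------------

    def _outcomes(self) -> tuple[dict[str, bool], dict[str, str]]:
        rep = flag_repeat_within_window(
            self.episodes + self.attendances, self.window_days
        )
        index_ids = {e.episode_id for e in self.episodes}
        rep = {k: v for k, v in rep.items() if k in index_ids}
        sui = flag_suicide_within_window(
            self.episodes, self.deaths, self.linked, self.window_days
        )
        return rep, sui

    def _completed(self, outcomes_map) -> tuple[list[CompletedCohort], int]:
        if self.strategy == ABSENT_RULE_MICE:
            recoded, n_changed = apply_absent_rule(
                self.episodes, self.imputation.absent_rule_items
            )
            return mice_impute(recoded, self.imputation, outcomes_map), n_changed
        if self.strategy == NOT_PRESENT:
            return [CompletedCohort(1, tuple(code_not_present(self.episodes)))], 0
        raise AssertionError("complete_case handled separately")

    def fit(self) -> "ScaleAccuracyResults":
        rep_flags, sui_flags = self._outcomes()
        outcomes_map = {
            e.episode_id: {
                "repeat_6m": rep_flags[e.episode_id],
                "suicide_6m": sui_flags[e.episode_id],
            }
            for e in self.episodes
        }
        sui_bool = {
            k: v == YES for k, v in sui_flags.items() if v != LOST_TO_FOLLOWUP
        }
        n_lost_episodes = len(sui_flags) - len(sui_bool)

        if self.strategy == COMPLETE_CASE:
            return self._fit_complete_case(rep_flags, sui_bool, n_lost_episodes)

        completed, n_changed = self._completed(outcomes_map)
        m_pool = min(self.imputation.m_pool, len(completed))
        pool = completed[:m_pool]

        counts = self._count_table(completed, rep_flags, sui_bool)
        acc_rows = []
        for name, comps in self.comparisons.items():
            definition = self.definitions[name]
            for comp in comps:
                for outcome_name, flags in (("repeat", rep_flags), ("suicide", sui_bool)):
                    rep = pooled_accuracy(
                        pool, definition, comp, flags, self.ci_level
                    )
                    acc_rows.append(
                        {"scale": name, "comparison": comp.convention,
                         "outcome": outcome_name, **rep.as_dict()}
                    )
        accuracy = pd.DataFrame(acc_rows)

        scores_by_imp = [self._score_frames(cc.episodes) for cc in pool]
        auc_overall, auc_subgroups, rocs = self._auc_tables(
            scores_by_imp, rep_flags, pool[0].episodes
        )
        return ScaleAccuracyResults(
            model=self,
            counts=counts,
            accuracy=accuracy,
            auc_overall=auc_overall,
            auc_subgroups=auc_subgroups,
            roc_curves=rocs,
            n_episodes=len(self.episodes),
            n_suicide_analysed=len(sui_bool),
            n_lost_episodes=n_lost_episodes,
            n_absent_rule_cells=n_changed,
            m=len(completed),
            m_pool=m_pool,
        )

    def _fit_complete_case(self, rep_flags, sui_bool, n_lost_episodes):
        acc_rows = []
        count_rows = []
        rocs: dict[str, RocCurve] = {}
        auc_rows = []
        for name, comps in self.comparisons.items():
            definition = self.definitions[name]
            kept, frac = complete_case_filter(self.episodes, definition)
            cats = {
                e.episode_id: score_episode(e, definition).category for e in kept
            }
            scores = {
                e.episode_id: score_episode(e, definition).score for e in kept
            }
            for cat in definition.categories:
                ids = [k for k, c in cats.items() if c == cat]
                count_rows.append(
                    {
                        "scale": name,
                        "category": cat,
                        "repeat_yes": sum(rep_flags[i] for i in ids),
                        "repeat_no": sum(not rep_flags[i] for i in ids),
                        "total": len(ids),
                    }
                )
            for comp in comps:
                for outcome_name, flags in (("repeat", rep_flags), ("suicide", sui_bool)):
                    sub_cats = {k: v for k, v in cats.items() if k in flags}
                    t = build_two_by_two(
                        sub_cats, {k: flags[k] for k in sub_cats}, comp
                    )
                    rep = accuracy_metrics(
                        t, self.ci_level, self.proportion_ci
                    )
                    acc_rows.append(
                        {"scale": name, "comparison": comp.convention,
                         "outcome": outcome_name, "retained_fraction": frac,
                         **rep.as_dict()}
                    )
            rep_scores = {k: v for k, v in scores.items() if k in rep_flags}
            try:
                roc = roc_curve(rep_scores, {k: rep_flags[k] for k in rep_scores})
                rocs[name] = roc
                auc_rows.append(
                    {"scale": name, "auc": roc.auc, "auc_se": roc.auc_se,
                     "ci_low": roc.auc - 1.96 * roc.auc_se,
                     "ci_high": roc.auc + 1.96 * roc.auc_se, "m": 1}
                )
            except UndefinedMetricError:
                pass
        return ScaleAccuracyResults(
            model=self,
            counts=pd.DataFrame(count_rows),
            accuracy=pd.DataFrame(acc_rows),
            auc_overall=pd.DataFrame(auc_rows),
            auc_subgroups=pd.DataFrame(),
            roc_curves=rocs,
            n_episodes=len(self.episodes),
            n_suicide_analysed=len(sui_bool),
            n_lost_episodes=n_lost_episodes,
            n_absent_rule_cells=0,
            m=1,
            m_pool=1,
        )

    # -- helpers ------------------------------------------------------------

    def _score_frames(self, episodes: Sequence[Episode]) -> pd.DataFrame:
        data = {}
        for name, definition in self.definitions.items():
            res = [score_episode(e, definition, TREAT_AS_ABSENT) for e in episodes]
            data[(name, "score")] = [r.score for r in res]
            data[(name, "category")] = [r.category for r in res]
        frame = pd.DataFrame(
            data, index=pd.Index([e.episode_id for e in episodes], name="episode_id")
        )
        frame.columns = pd.MultiIndex.from_tuples(frame.columns)
        return frame

    def _count_table(self, completed, rep_flags, sui_bool) -> pd.DataFrame:
        """Category-by-outcome counts from imputed data.

        Cell counts are averaged over imputations and rounded to integers
        with a sum-preserving (largest-remainder) rule within each outcome
        column, so each column partitions the analysed episodes exactly,
        the way a printed count table does."""
        accum: dict[tuple[str, str, str], float] = {}
        m = len(completed)
        for cc in completed:
            frames = self._score_frames(cc.episodes)
            for name in self.definitions:
                cats = frames[(name, "category")]
                for eid, cat in cats.items():
                    key_r = (name, cat, "repeat_yes" if rep_flags[eid] else "repeat_no")
                    accum[key_r] = accum.get(key_r, 0) + 1
                    if eid in sui_bool:
                        key_s = (
                            name, cat,
                            "suicide_yes" if sui_bool[eid] else "suicide_no",
                        )
                        accum[key_s] = accum.get(key_s, 0) + 1
        rows = []
        for name, definition in self.definitions.items():
            cats = list(definition.categories)
            cells: dict[str, list[int]] = {}
            for k in ("repeat_yes", "repeat_no", "suicide_yes", "suicide_no"):
                cells[k] = _round_preserving_sum(
                    [accum.get((name, c, k), 0) / m for c in cats]
                )
            for i, cat in enumerate(cats):
                rows.append(
                    {
                        "scale": name,
                        "category": cat,
                        **{k: cells[k][i] for k in cells},
                        "total": cells["repeat_yes"][i] + cells["repeat_no"][i],
                        "suicide_total": cells["suicide_yes"][i]
                        + cells["suicide_no"][i],
                    }
                )
        return pd.DataFrame(rows)

    def _auc_tables(self, scores_by_imp, rep_flags, first_episodes):
        subgroups = {
            e.episode_id: assign_subgroups(e) for e in first_episodes
        }

        auc_rows = []
        sub_rows = []
        rocs: dict[str, RocCurve] = {}
        for name in self.definitions:
            # overall
            est = self._pool_auc(scores_by_imp, name, list(rep_flags), rep_flags)
            if est is not None:
                auc_rows.append(
                    {"scale": name, "auc": est[0], "auc_se": est[1],
                     "ci_low": est[2], "ci_high": est[3],
                     "m": len(scores_by_imp)}
                )
            rocs[name] = roc_curve(
                scores_by_imp[0][(name, "score")].to_dict(), rep_flags
            )
            for dim in _SUBGROUP_DIMENSIONS:
                level_of = {
                    eid: getattr(sg, f"{dim}_group") for eid, sg in subgroups.items()
                }
                levels = sorted({v for v in level_of.values() if v is not None})
                level_ests = []
                for level in levels:
                    ids = [
                        eid for eid in rep_flags if level_of.get(eid) == level
                    ]
                    est = self._pool_auc(scores_by_imp, name, ids, rep_flags)
                    level_ests.append((level, len(ids), est))
                defined = [(lv, n, e) for lv, n, e in level_ests if e is not None]
                chi2 = df = p = math.nan
                if len(defined) >= 2:
                    try:
                        chi2, df, p = compare_auc_subgroups(
                            [(e[0], e[1]) for _, _, e in defined]
                        )
                    except UndefinedMetricError:
                        pass
                for level, n_level, e in level_ests:
                    sub_rows.append(
                        {
                            "scale": name,
                            "dimension": dim,
                            "level": level,
                            "n": n_level,
                            "auc": e[0] if e else math.nan,
                            "auc_se": e[1] if e else math.nan,
                            "ci_low": e[2] if e else math.nan,
                            "ci_high": e[3] if e else math.nan,
                            "chi2": chi2,
                            "df": df,
                            "p": p,
                        }
                    )
        return pd.DataFrame(auc_rows), pd.DataFrame(sub_rows), rocs

    def _pool_auc(self, scores_by_imp, scale, ids, rep_flags):
        """Pool the AUC over imputations (Rubin, identity scale)."""
        aucs, variances = [], []
        for frames in scores_by_imp:
            s = frames[(scale, "score")]
            sub = {i: s[i] for i in ids}
            try:
                roc = roc_curve(sub, {i: rep_flags[i] for i in ids})
            except UndefinedMetricError:
                return None
            aucs.append(roc.auc)
            variances.append(roc.auc_se**2)
        pooled = rubin_pool(aucs, variances, ci_level=self.ci_level)
        return (
            pooled.estimate,
            math.sqrt(pooled.variance),
            pooled.ci_low,
            pooled.ci_high,
        )


@dataclass
class ScaleAccuracyResults:
    """Fitted accuracy battery; all tables are plain DataFrames."""

    model: ScaleAccuracy
    counts: pd.DataFrame
    accuracy: pd.DataFrame
    auc_overall: pd.DataFrame
    auc_subgroups: pd.DataFrame
    roc_curves: dict[str, RocCurve]
    n_episodes: int
    n_suicide_analysed: int
    n_lost_episodes: int
    n_absent_rule_cells: int
    m: int
    m_pool: int

    def summary(self) -> str:
        """Human-readable report with the display rounding conventions:
        percentages to integers (suicide PPV/NPV to one decimal), ratio
        measures to one decimal."""
        lines = [
            "Risk-scale diagnostic accuracy",
            "=" * 62,
            f"episodes analysed: {self.n_episodes}"
            f" | suicide follow-up: {self.n_suicide_analysed}"
            f" ({self.n_lost_episodes} episodes lost to mortality follow-up)",
            f"strategy: {self.model.strategy} | imputations: m={self.m},"
            f" pooled m={self.m_pool}",
            "",
        ]
        for outcome in ("repeat", "suicide"):
            block = self.accuracy[self.accuracy["outcome"] == outcome]
            if block.empty:
                continue
            lines.append(f"-- outcome: {outcome} --")
            lines.append(
                f"{'scale':<6} {'comparison':<18} {'sens%':>6} {'spec%':>6}"
                f" {'PPV%':>6} {'NPV%':>6} {'LR+':>6} {'LR-':>6} {'DOR':>6}"
            )
            pv_digits = 1 if outcome == "suicide" else 0

            def fmt_pct(x, nd=0):
                if math.isnan(x):
                    return "-"
                v = round_half_up(100 * x, nd)
                return f"{v:.0f}" if nd == 0 else f"{v:.1f}"

            def fmt_ratio(x):
                return "-" if math.isnan(x) else f"{round_half_up(x, 1):.1f}"

            for _, r in block.iterrows():
                lines.append(
                    f"{r['scale']:<6} {r['comparison']:<18}"
                    f" {fmt_pct(r['sensitivity']):>6} {fmt_pct(r['specificity']):>6}"
                    f" {fmt_pct(r['ppv'], pv_digits):>6}"
                    f" {fmt_pct(r['npv'], pv_digits):>6}"
                    f" {fmt_ratio(r['lr_pos']):>6} {fmt_ratio(r['lr_neg']):>6}"
                    f" {fmt_ratio(r['dor']):>6}"
                )
            lines.append("")
        if not self.auc_overall.empty:
            lines.append("-- overall AUC (repeat outcome) --")
            for _, r in self.auc_overall.iterrows():
                lines.append(
                    f"{r['scale']:<6} AUC {r['auc']:.2f}"
                    f" ({r['ci_low']:.2f}, {r['ci_high']:.2f})"
                )
        return "\n".join(lines)
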