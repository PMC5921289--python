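"""Synthetic episode-level self-harm cohorts with realistic outcome structure.

The generator emulates a large unselected multicentre ED cohort: 4000
episodes by ~3157 persons over a two-year enrolment window, 60% female, 81%
self-poisoning, 55% psychosocially assessed, 69% with prior self-harm, a
28.3% six-month repeat rate, a 0.5% six-month suicide incidence and ~1.2% of
persons lost to mortality follow-up.  Every index episode is guaranteed at
least six months of observation, mirroring complete follow-up.

Mechanics
---------
* Persons receive episode counts from a clipped geometric repeat process
  repaired to the exact episode total, so the episode/person ratio matches.
* Scale items are drawn from per-item prevalences with a shared person-level
  random effect inducing within-person correlation; demographic items
  (male sex, age <19 or >45) and the cutting-method item are derived
  deterministically from the episode's demographics and method.
* Repetition is simulated from a logistic model on the items whose intercept
  is solved by bisection so the marginal repeat fraction hits its target.
  A positive draw is realised in the dates: the person's next presentation
  falls within the follow-up window (using the next index episode where one
  exists, otherwise an extra follow-up attendance outside the analysed set);
  a negative draw forces the next same-person gap beyond the window.
* Suicide is simulated per person from the last episode's items (a person
  dies at most once); the death is timed so exactly the final index episode
  falls inside its own six-month window, which keeps the episode-level
  suicide fraction at its calibrated target.
* Item missingness is applied last, split by assessment status, so
  missingness concentrates in non-assessed episodes and never disturbs the
  date-based outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import (
    FEMALE,
    MALE,
    MENTAL_HEALTH_NURSE,
    NO_ASSESSOR,
    OTHER_ASSESSOR,
    PSYCHIATRIST,
    SELF_INJURY,
    SELF_POISONING,
    DeathRecord,
    Episode,
    ItemState,
    flag_repeat_within_window,
    flag_suicide_within_window,
)
from .errors import CalibrationError
from .scales import ITEM_VOCABULARY

# items fixed by demographics/method rather than drawn from a prevalence
DERIVED_ITEMS = ("sex_male", "age_under19_or_over45", "cutting_index_method")

_DEFAULT_PREVALENCES: dict[str, float] = {
    "history_self_harm": 0.69,
    "previous_psych_treatment": 0.45,
    "benzodiazepine_index": 0.20,
    "current_psych_treatment": 0.35,
    "recent_self_harm_past_year": 0.55,
    "living_alone_or_homeless": 0.25,
    "cutting_index_method": 0.68,  # conditional on self-injury method
    "depression": 0.35,
    "previous_attempt": 0.60,
    "ethanol_abuse": 0.25,
    "rational_thinking_loss": 0.10,
    "social_supports_lacking": 0.30,
    "organised_plan": 0.15,
    "no_spouse": 0.60,
    "sickness": 0.10,
    "depression_or_hopelessness": 0.40,
    "previous_attempt_or_psych_care": 0.65,
    "ethanol_or_drug_abuse": 0.30,
    "separated_divorced_widowed": 0.15,
    "organised_or_serious_attempt": 0.18,
    "no_social_support": 0.30,
    "stated_future_intent": 0.20,
}

# association of items with six-month repetition (log-odds).  The four-item
# rules' history/recency/treatment content carries the predictive signal;
# the ten-item scales' remaining content is set near zero so those scales
# discriminate at about chance level, the qualitative pattern the evaluation
# is designed to exhibit.
_DEFAULT_LOG_ODDS_REPEAT: dict[str, float] = {
    "history_self_harm": 1.10,
    "recent_self_harm_past_year": 0.90,
    "previous_psych_treatment": 0.50,
    "current_psych_treatment": 0.45,
    "living_alone_or_homeless": 0.25,
    "benzodiazepine_index": 0.20,
    "cutting_index_method": 0.35,
    "depression": 0.10,
    "ethanol_abuse": 0.15,
}

_DEFAULT_LOG_ODDS_SUICIDE: dict[str, float] = {
    "stated_future_intent": 0.50,
    "organised_or_serious_attempt": 0.40,
    "sex_male": 0.40,
}

_RECORD_ITEMS = (
    "history_self_harm",
    "previous_psych_treatment",
    "benzodiazepine_index",
    "current_psych_treatment",
    "recent_self_harm_past_year",
    "living_alone_or_homeless",
)


def _default_missing(assessed: bool) -> dict[str, float]:
    out: dict[str, float] = {}
    for item in ITEM_VOCABULARY:
        if item in DERIVED_ITEMS:
            out[item] = 0.01 if assessed else 0.02
        elif item in _RECORD_ITEMS:
            out[item] = 0.05 if assessed else 0.25
        else:  # assessment-derived psychosocial content
            out[item] = 0.08 if assessed else 0.50
    return out


@dataclass(frozen=True)
class CohortParams:
    """Generator targets and mechanics; defaults match the emulated cohort."""

    n_episodes: int = 4000
    n_persons: int = 3157
    p_female: float = 0.60
    age_mix: tuple[float, float, float] = (0.14, 0.64, 0.22)  # <19, 19-44, 45+
    p_self_poisoning: float = 0.81
    p_assessed: float = 0.55
    assessor_mix: tuple[float, float, float] = (0.289, 0.577, 0.134)
    p_history: float = 0.69
    target_repeat: float = 0.283
    target_suicide: float = 0.005
    p_lost_followup: float = 0.012
    item_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCES)
    )
    item_log_odds_repeat: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LOG_ODDS_REPEAT)
    )
    item_log_odds_suicide: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LOG_ODDS_SUICIDE)
    )
    missing_assessed: Mapping[str, float] = field(
        default_factory=lambda: _default_missing(True)
    )
    missing_unassessed: Mapping[str, float] = field(
        default_factory=lambda: _default_missing(False)
    )
    person_effect_sd: float = 0.8
    p_other_death: float = 0.01
    window_days: int = 183
    start: date = date(2010, 1, 1)
    enrol_days: int = 730
    n_centres: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.p_female, self.p_self_poisoning, self.p_assessed,
            self.p_history, self.target_repeat, self.target_suicide,
            self.p_lost_followup, self.p_other_death,
            *self.item_prevalences.values(),
            *self.missing_assessed.values(),
            *self.missing_unassessed.values(),
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        for mix in (self.age_mix, self.assessor_mix):
            if abs(sum(mix) - 1) > 1e-9:
                raise ValueError("mixture proportions must sum to 1")
        if self.n_persons > self.n_episodes:
            raise ValueError("need n_persons <= n_episodes")
        unknown = set(self.item_prevalences) - set(ITEM_VOCABULARY)
        if unknown:
            raise ValueError(f"unknown items in prevalences: {sorted(unknown)}")


def default_params(**overrides) -> CohortParams:
    """The calibrated default :class:`CohortParams` (keyword overrides allowed)."""
    return CohortParams(**overrides)


@dataclass
class GeneratedCohort:
    """A generated cohort plus everything needed to evaluate and verify it."""

    episodes: list[Episode]
    deaths: list[DeathRecord]
    linked: frozenset[str]
    followups: list[Episode]
    truth: dict
    params: CohortParams

    def attendance_table(self) -> list[Episode]:
        """Index episodes plus follow-up attendances, for repeat ascertainment."""
        return list(self.episodes) + list(self.followups)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


def _calibrate_intercept(lin: np.ndarray, target: float, tol: float = 1e-6) -> float:
    """Bisect the logistic intercept so mean probability equals ``target``."""
    lo, hi = -30.0, 30.0
    f = lambda a: float(np.mean(_sigmoid(a + lin)))  # noqa: E731
    if not (f(lo) - tol <= target <= f(hi) + tol):
        raise CalibrationError(
            f"target {target} unreachable for supplied item effects"
        )
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if f(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol / 10:
            break
    return 0.5 * (lo + hi)


_ZEGER_C = 16 * math.sqrt(3) / (15 * math.pi)


def _adjusted_logit(p: float, sd: float) -> float:
    """Logit inflated so the logistic-normal marginal stays near ``p``."""
    if p <= 0:
        return -math.inf
    if p >= 1:
        return math.inf
    return math.log(p / (1 - p)) * math.sqrt(1 + (_ZEGER_C * sd) ** 2)


def generate(params: CohortParams | None = None) -> GeneratedCohort:
    """Generate a cohort; fully reproducible given ``params.seed``."""
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed)
    n_ep, n_pe = params.n_episodes, params.n_persons

    # --- episode counts per person: clipped geometric, repaired to the total
    counts = np.minimum(rng.geometric(n_pe / n_ep, size=n_pe), 12)
    diff = int(counts.sum()) - n_ep
    while diff > 0:
        i = int(rng.integers(n_pe))
        if counts[i] > 1:
            counts[i] -= 1
            diff -= 1
    while diff < 0:
        counts[int(rng.integers(n_pe))] += 1
        diff += 1

    # --- person attributes
    sexes = np.where(rng.random(n_pe) < params.p_female, FEMALE, MALE)
    bands = rng.choice(3, size=n_pe, p=list(params.age_mix))
    lo_age, hi_age = np.array([12, 19, 45]), np.array([18, 44, 75])
    ages = rng.integers(lo_age[bands], hi_age[bands] + 1)
    effects = rng.normal(0.0, params.person_effect_sd, size=n_pe)

    # first-episode history prevalence solving the episode-level target:
    # later episodes always carry a prior episode, first episodes draw
    q_first = (params.p_history * n_ep - (n_ep - n_pe)) / n_pe
    q_first = min(max(q_first, 0.0), 1.0)

    sd = params.person_effect_sd
    stochastic_items = [
        it for it in ITEM_VOCABULARY if it not in DERIVED_ITEMS
    ]
    adj_logits = {
        it: _adjusted_logit(params.item_prevalences.get(it, 0.0), sd)
        for it in stochastic_items
    }

    # --- per-episode arrays (vectorised)
    person_of = np.repeat(np.arange(n_pe), counts)
    ordinal = np.concatenate([np.arange(k) for k in counts])
    methods = np.where(
        rng.random(n_ep) < params.p_self_poisoning, SELF_POISONING, SELF_INJURY
    )
    assessed_arr = rng.random(n_ep) < params.p_assessed
    assessor_codes = rng.choice(3, size=n_ep, p=list(params.assessor_mix))
    assessor_names = np.array([PSYCHIATRIST, MENTAL_HEALTH_NURSE, OTHER_ASSESSOR])
    assessors = np.where(assessed_arr, assessor_names[assessor_codes], NO_ASSESSOR)
    centres = np.array(
        [f"centre_{1 + i % params.n_centres}" for i in range(n_ep)]
    )

    # item presence matrix over the full vocabulary
    vocab = list(ITEM_VOCABULARY)
    col = {it: c for c, it in enumerate(vocab)}
    present = np.zeros((n_ep, len(vocab)), dtype=bool)
    present[:, col["sex_male"]] = sexes[person_of] == MALE
    ep_ages = ages[person_of]
    present[:, col["age_under19_or_over45"]] = (ep_ages < 19) | (ep_ages > 45)
    present[:, col["cutting_index_method"]] = (methods == SELF_INJURY) & (
        rng.random(n_ep) < params.item_prevalences["cutting_index_method"]
    )
    for it in stochastic_items:
        if it == "history_self_harm":
            present[:, col[it]] = (ordinal > 0) | (rng.random(n_ep) < q_first)
        else:
            p = _sigmoid(adj_logits[it] + effects[person_of])
            present[:, col[it]] = rng.random(n_ep) < p

    # --- repetition: logistic on items, intercept solved for the target
    beta = np.array([params.item_log_odds_repeat.get(it, 0.0) for it in vocab])
    lin_rep = present @ beta
    alpha_rep = _calibrate_intercept(lin_rep, params.target_repeat)
    will_repeat = rng.random(n_ep) < _sigmoid(alpha_rep + lin_rep)

    # --- dates realising the repeat draws
    dates = np.empty(n_ep, dtype=object)
    idx_by_person: dict[int, list[int]] = {}
    for i, pi in enumerate(person_of):
        idx_by_person.setdefault(int(pi), []).append(i)
    w = params.window_days
    for pi, idxs in idx_by_person.items():
        d = params.start + timedelta(days=int(rng.integers(0, params.enrol_days)))
        for k, i in enumerate(idxs):
            dates[i] = d
            if k + 1 < len(idxs):
                gap = (
                    int(rng.integers(1, w + 1))
                    if will_repeat[i]
                    else int(rng.integers(w + 1, 2 * w))
                )
                d = d + timedelta(days=gap)

    # --- suicide: per person from the last episode's items
    last_idx = np.array([idxs[-1] for idxs in idx_by_person.values()])
    gamma = np.array([params.item_log_odds_suicide.get(it, 0.0) for it in vocab])
    lin_sui = present[last_idx] @ gamma
    person_target = params.target_suicide * n_ep / n_pe
    alpha_sui = _calibrate_intercept(lin_sui, person_target)
    dies = rng.random(n_pe) < _sigmoid(alpha_sui + lin_sui)

    deaths: list[DeathRecord] = []
    suicide_persons: set[int] = set()
    death_delay: dict[int, int] = {}
    for pj, pi in enumerate(idx_by_person.keys()):
        if not dies[pj]:
            continue
        idxs = idx_by_person[pi]
        li = idxs[-1]
        # time the death so only the final index episode sits in-window
        if len(idxs) > 1 and will_repeat[idxs[-2]]:
            prev_gap = (dates[li] - dates[idxs[-2]]).days
            delay = int(rng.integers(max(w - prev_gap + 1, 1), w + 1))
        else:
            delay = int(rng.integers(7, 151))
        deaths.append(
            DeathRecord(f"P{pi:05d}", dates[li] + timedelta(days=delay), True)
        )
        suicide_persons.add(pi)
        death_delay[pi] = delay

    # some non-suicide mortality, after follow-up ends where possible
    for pi, idxs in idx_by_person.items():
        if pi in suicide_persons:
            continue
        if rng.random() < params.p_other_death:
            deaths.append(
                DeathRecord(
                    f"P{pi:05d}",
                    dates[idxs[-1]] + timedelta(days=int(rng.integers(200, 501))),
                    False,
                )
            )

    # --- follow-up attendances realising last-episode repeats
    followups: list[Episode] = []
    for pi, idxs in idx_by_person.items():
        li = idxs[-1]
        if will_repeat[li]:
            # a dying person's final repeat attendance cannot postdate death
            hi = min(w, death_delay.get(pi, w))
            att = dates[li] + timedelta(days=int(rng.integers(1, hi + 1)))
            followups.append(
                Episode(
                    episode_id=f"F{len(followups):05d}",
                    person_id=f"P{pi:05d}",
                    presentation_date=att,
                    age=int(ages[pi]),
                    sex=str(sexes[pi]),
                    method=SELF_POISONING
                    if rng.random() < params.p_self_poisoning
                    else SELF_INJURY,
                    assessed=False,
                    assessor=NO_ASSESSOR,
                    centre=str(centres[li]),
                    items={},
                )
            )

    # --- mortality linkage
    lost_candidates = [pi for pi in range(n_pe) if pi not in suicide_persons]
    n_lost = int(round(params.p_lost_followup * n_pe))
    lost = set(
        int(x) for x in rng.choice(lost_candidates, size=n_lost, replace=False)
    )
    linked = frozenset(f"P{pi:05d}" for pi in range(n_pe) if pi not in lost)

    # --- assemble episodes, applying missingness last (vectorised mask)
    miss_a = np.array([params.missing_assessed.get(it, 0.0) for it in vocab])
    miss_u = np.array([params.missing_unassessed.get(it, 0.0) for it in vocab])
    miss_p = np.where(assessed_arr[:, None], miss_a[None, :], miss_u[None, :])
    missing_mask = rng.random((n_ep, len(vocab))) < miss_p

    episodes: list[Episode] = []
    for i in range(n_ep):
        items: dict[str, ItemState] = {}
        for c, it in enumerate(vocab):
            if missing_mask[i, c]:
                items[it] = ItemState.MISSING
            else:
                items[it] = ItemState.PRESENT if present[i, c] else ItemState.ABSENT
        pi = int(person_of[i])
        episodes.append(
            Episode(
                episode_id=f"E{i:05d}",
                person_id=f"P{pi:05d}",
                presentation_date=dates[i],
                age=int(ages[pi]),
                sex=str(sexes[pi]),
                method=str(methods[i]),
                assessed=bool(assessed_arr[i]),
                assessor=str(assessors[i]),
                centre=str(centres[i]),
                items=items,
            )
        )

    truth = {
        "seed": params.seed,
        "targets": {
            "repeat": params.target_repeat,
            "suicide": params.target_suicide,
            "female": params.p_female,
            "assessed": params.p_assessed,
            "self_poisoning": params.p_self_poisoning,
            "history": params.p_history,
        },
        "alpha_repeat": alpha_rep,
        "alpha_suicide": alpha_sui,
        "n_suicides": len(suicide_persons),
        "n_lost_persons": n_lost,
        "will_repeat_fraction": float(will_repeat.mean()),
        "item_prevalences": {
            it: params.item_prevalences.get(it) for it in stochastic_items
        },
    }
    return GeneratedCohort(
        episodes=episodes,
        deaths=deaths,
        linked=linked,
        followups=followups,
        truth=truth,
        params=params,
    )


def recover_parameters(cohort: GeneratedCohort) -> pd.DataFrame:
    """Empirical marginals against generator targets, with z-scores.

    The z-score uses the binomial standard error at the target, so |z| < 3
    is the natural acceptance band for a single cohort.  Item prevalences are
    measured on observed (non-missing) cells, which is unbiased here because
    generated missingness depends only on assessment status.
    """
    eps = cohort.episodes
    n = len(eps)
    rep_flags = flag_repeat_within_window(
        cohort.attendance_table(), cohort.params.window_days
    )
    index_ids = {e.episode_id for e in eps}
    rep_frac = sum(rep_flags[i] for i in index_ids) / n
    sui_flags = flag_suicide_within_window(
        eps, cohort.deaths, cohort.linked, cohort.params.window_days
    )
    analysable = [v for v in sui_flags.values() if v != "lost_to_followup"]
    sui_frac = sum(v == "yes" for v in analysable) / len(analysable)

    rows = []

    def add(name: str, observed: float, target: float, nn: int) -> None:
        se = math.sqrt(target * (1 - target) / nn) if 0 < target < 1 else math.nan
        rows.append(
            {
                "quantity": name,
                "target": target,
                "observed": observed,
                "n": nn,
                "z": (observed - target) / se if se and se > 0 else math.nan,
            }
        )

    t = cohort.truth["targets"]
    add("repeat_6m", rep_frac, t["repeat"], n)
    add("suicide_6m", sui_frac, t["suicide"], len(analysable))
    add("female", sum(e.sex == FEMALE for e in eps) / n, t["female"], n)
    add("assessed", sum(e.assessed for e in eps) / n, t["assessed"], n)
    add(
        "self_poisoning",
        sum(e.method == SELF_POISONING for e in eps) / n,
        t["self_poisoning"],
        n,
    )
    hist_obs = [
        e.items["history_self_harm"] is ItemState.PRESENT
        for e in eps
        if e.items.get("history_self_harm", ItemState.MISSING) is not ItemState.MISSING
    ]
    add("history", sum(hist_obs) / len(hist_obs), t["history"], len(hist_obs))
    for it, p in cohort.truth["item_prevalences"].items():
        if it == "history_self_harm" or p is None:
            continue
        obs = [
            e.items[it] is ItemState.PRESENT
            for e in eps
            if e.items.get(it, ItemState.MISSING) is not ItemState.MISSING
        ]
        if obs:
            add(f"item:{it}", sum(obs) / len(obs), p, len(obs))
    return pd.DataFrame(rows)
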