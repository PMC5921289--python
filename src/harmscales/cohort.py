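"""Episode-level cohort model, delimited-text I/O and outcome ascertainment.

The analysis unit is the *episode*: one emergency-department presentation
for self-harm.  One person can contribute several index episodes, and every
episode is followed up for its own six-month window, so outcome flags are
computed per episode, never per person.

Two outcomes are ascertained:

* **repeat self-harm** — a strictly later presentation by the same person
  within the follow-up window (183 days by default);
* **suicide** — a suicide death within the window; episodes by persons with
  no mortality linkage are marked lost to follow-up and excluded from
  suicide analyses.

Cohort and deaths tables are plain delimited text with ISO-8601 dates; item
columns are tri-state (present / absent / missing) encoded by configurable
tokens, ``"1"`` / ``"0"`` / empty by default.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

from .errors import IntegrityError, SchemaError
from .scales import ITEM_VOCABULARY

SIX_MONTHS_DAYS = 183  # follow-up window; six calendar months is not a fixed
# number of days, so the window is expressed in days and configurable

MALE, FEMALE = "male", "female"
SELF_POISONING, SELF_INJURY = "self_poisoning", "self_injury"
PSYCHIATRIST, MENTAL_HEALTH_NURSE, OTHER_ASSESSOR, NO_ASSESSOR = (
    "psychiatrist",
    "mental_health_nurse",
    "other",
    "none",
)

YES, NO, LOST_TO_FOLLOWUP = "yes", "no", "lost_to_followup"


class ItemState(enum.Enum):
    """Tri-state value of one scale item on one episode."""

    PRESENT = "present"
    ABSENT = "absent"
    MISSING = "missing"


@dataclass
class Episode:
    """One ED self-harm presentation."""

    episode_id: str
    person_id: str
    presentation_date: date
    age: int
    sex: str
    method: str
    assessed: bool
    assessor: str
    centre: str
    items: dict[str, ItemState] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"episode {self.episode_id!r}: negative age")
        if (self.assessor == NO_ASSESSOR) != (not self.assessed):
            raise ValueError(
                f"episode {self.episode_id!r}: assessor must be 'none' "
                "exactly when assessed is False"
            )
        unknown = set(self.items) - set(ITEM_VOCABULARY)
        if unknown:
            raise ValueError(
                f"episode {self.episode_id!r}: unregistered items {sorted(unknown)}"
            )


@dataclass(frozen=True)
class DeathRecord:
    """Mortality-register entry for one person."""

    person_id: str
    death_date: date
    suicide: bool


@dataclass(frozen=True)
class OutcomeFlags:
    """Six-month outcomes for one episode."""

    repeat_6m: bool
    suicide_6m: str  # yes / no / lost_to_followup


@dataclass(frozen=True)
class SubgroupLabels:
    """Deterministic subgroup assignment for one episode.

    ``assessor_group`` is ``None`` for non-assessed episodes (they do not
    enter the by-assessor comparison).  Age bands: <=18, 19-44, >=45.
    """

    sex_group: str
    age_group: str
    method_group: str
    assessor_group: str | None
    history_group: str

    AGE_UNDER19 = "under19"
    AGE_19_44 = "19to44"
    AGE_45_PLUS = "45plus"
    HISTORY = "prior_self_harm"
    NO_HISTORY = "no_prior_self_harm"


def assign_subgroups(episode: Episode, history_item: bool | None = None) -> SubgroupLabels:
    """Label an episode for subgroup analyses.

    ``history_item`` is the prior-self-harm indicator; when ``None`` it is
    read from the episode's ``history_self_harm`` item (missing counts as no
    history, matching the treat-as-absent scoring convention).
    """
    if history_item is None:
        state = episode.items.get("history_self_harm", ItemState.MISSING)
        history_item = state is ItemState.PRESENT
    if episode.age <= 18:
        age_group = SubgroupLabels.AGE_UNDER19
    elif episode.age <= 44:
        age_group = SubgroupLabels.AGE_19_44
    else:
        age_group = SubgroupLabels.AGE_45_PLUS
    return SubgroupLabels(
        sex_group=episode.sex,
        age_group=age_group,
        method_group=episode.method,
        assessor_group=episode.assessor if episode.assessed else None,
        history_group=(
            SubgroupLabels.HISTORY if history_item else SubgroupLabels.NO_HISTORY
        ),
    )


def flag_repeat_within_window(
    episodes: Sequence[Episode], window_days: int = SIX_MONTHS_DAYS
) -> dict[str, bool]:
    """Flag each episode that is followed by a repeat presentation.

    Episode *e* is flagged when the same person has a strictly later
    presentation no more than ``window_days`` after *e*.  Same-day
    re-presentations count as repeats for the earlier episode, with episode
    order on a shared date broken by ``episode_id``.  The supplied table may
    include follow-up attendances beyond the analysed index episodes; they
    contribute as repeat events and receive flags like any other row.
    """
    by_person: dict[str, list[Episode]] = {}
    for e in episodes:
        by_person.setdefault(e.person_id, []).append(e)
    flags: dict[str, bool] = {}
    for eps in by_person.values():
        eps.sort(key=lambda e: (e.presentation_date, e.episode_id))
        for i, e in enumerate(eps):
            flags[e.episode_id] = (
                i + 1 < len(eps)
                and (eps[i + 1].presentation_date - e.presentation_date).days
                <= window_days
            )
    return flags


def flag_suicide_within_window(
    episodes: Sequence[Episode],
    deaths: Iterable[DeathRecord],
    linked: set[str] | frozenset[str],
    window_days: int = SIX_MONTHS_DAYS,
) -> dict[str, str]:
    """Flag suicide within the window after each episode.

    ``linked`` is the set of persons matched to mortality records; episodes
    by unmatched persons are ``lost_to_followup`` and must be excluded from
    suicide analyses.  A suicide death dated before a presentation by the
    same person is a data-integrity problem: it raises a warning and the
    episode is flagged ``no``.
    """
    suicide_dates: dict[str, date] = {}
    seen: dict[str, date] = {}
    for d in deaths:
        if d.person_id in seen and seen[d.person_id] != d.death_date:
            raise IntegrityError(
                f"person {d.person_id!r} has two distinct death dates"
            )
        seen[d.person_id] = d.death_date
        if d.suicide:
            suicide_dates[d.person_id] = d.death_date
    flags: dict[str, str] = {}
    for e in episodes:
        if e.person_id not in linked:
            flags[e.episode_id] = LOST_TO_FOLLOWUP
            continue
        dd = suicide_dates.get(e.person_id)
        if dd is None:
            flags[e.episode_id] = NO
            continue
        delta = (dd - e.presentation_date).days
        if delta < 0:
            warnings.warn(
                f"person {e.person_id!r}: suicide death precedes episode "
                f"{e.episode_id!r}; flagged 'no'",
                stacklevel=2,
            )
            flags[e.episode_id] = NO
        else:
            flags[e.episode_id] = YES if delta <= window_days else NO
    return flags


# ---------------------------------------------------------------------------
# Delimited-text I/O


@dataclass(frozen=True)
class CohortDialect:
    """Format options shared by all readers/writers."""

    delimiter: str = ","
    present_token: str = "1"
    absent_token: str = "0"
    missing_token: str = ""
    date_format: str | None = None  # None -> ISO-8601 via date.fromisoformat


MANDATORY_COLUMNS = (
    "episode_id",
    "person_id",
    "presentation_date",
    "age",
    "sex",
    "method",
    "assessed",
    "assessor",
    "centre",
)


def _parse_date(text: str, dialect: CohortDialect) -> date:
    if dialect.date_format is None:
        return date.fromisoformat(text)
    from datetime import datetime

    return datetime.strptime(text, dialect.date_format).date()


def read_cohort(path, dialect: CohortDialect | None = None) -> list[Episode]:
    """Read an episode table; returns episodes in file order.

    Raises :class:`SchemaError` when mandatory columns are absent or rows
    fail to parse (the message lists offending line numbers) and
    :class:`IntegrityError` on duplicate ``episode_id``.
    """
    dialect = dialect or CohortDialect()
    token_map = {
        dialect.present_token: ItemState.PRESENT,
        dialect.absent_token: ItemState.ABSENT,
        dialect.missing_token: ItemState.MISSING,
    }
    episodes: list[Episode] = []
    bad_lines: list[tuple[int, str]] = []
    seen_ids: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        missing_cols = [c for c in MANDATORY_COLUMNS if c not in header]
        if missing_cols:
            raise SchemaError(f"{path}: missing mandatory columns {missing_cols}")
        item_cols = [c for c in header if c in ITEM_VOCABULARY]
        for lineno, row in enumerate(reader, start=2):
            try:
                items = {}
                for c in item_cols:
                    raw = (row[c] or "").strip() if row[c] is not None else ""
                    if raw not in token_map:
                        raise ValueError(f"item {c!r}: unknown token {raw!r}")
                    items[c] = token_map[raw]
                ep = Episode(
                    episode_id=row["episode_id"],
                    person_id=row["person_id"],
                    presentation_date=_parse_date(row["presentation_date"], dialect),
                    age=int(row["age"]),
                    sex=row["sex"],
                    method=row["method"],
                    assessed=row["assessed"].strip() in ("1", "true", "True"),
                    assessor=row["assessor"],
                    centre=row["centre"],
                    items=items,
                )
            except (ValueError, KeyError) as exc:
                bad_lines.append((lineno, str(exc)))
                continue
            if ep.episode_id in seen_ids:
                raise IntegrityError(f"{path}: duplicate episode_id {ep.episode_id!r}")
            seen_ids.add(ep.episode_id)
            episodes.append(ep)
    if bad_lines:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad_lines[:10])
        raise SchemaError(f"{path}: {len(bad_lines)} unparseable rows ({detail})")
    return episodes


def write_cohort(episodes: Sequence[Episode], path, dialect: CohortDialect | None = None) -> None:
    """Write an episode table round-trippable by :func:`read_cohort`."""
    dialect = dialect or CohortDialect()
    state_map = {
        ItemState.PRESENT: dialect.present_token,
        ItemState.ABSENT: dialect.absent_token,
        ItemState.MISSING: dialect.missing_token,
    }
    item_cols = [c for c in ITEM_VOCABULARY if any(c in e.items for e in episodes)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(list(MANDATORY_COLUMNS) + item_cols)
        for e in episodes:
            writer.writerow(
                [
                    e.episode_id,
                    e.person_id,
                    e.presentation_date.isoformat(),
                    e.age,
                    e.sex,
                    e.method,
                    "1" if e.assessed else "0",
                    e.assessor,
                    e.centre,
                ]
                + [
                    state_map[e.items[c]] if c in e.items else dialect.missing_token
                    for c in item_cols
                ]
            )


def read_deaths(path, dialect: CohortDialect | None = None) -> list[DeathRecord]:
    """Read a deaths table (``person_id, death_date, suicide``)."""
    dialect = dialect or CohortDialect()
    records: list[DeathRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        needed = ["person_id", "death_date", "suicide"]
        missing_cols = [c for c in needed if c not in header]
        if missing_cols:
            raise SchemaError(f"{path}: missing mandatory columns {missing_cols}")
        for row in reader:
            records.append(
                DeathRecord(
                    person_id=row["person_id"],
                    death_date=_parse_date(row["death_date"], dialect),
                    suicide=row["suicide"].strip() in ("1", "true", "True"),
                )
            )
    return records


def write_deaths(records: Sequence[DeathRecord], path, dialect: CohortDialect | None = None) -> None:
    dialect = dialect or CohortDialect()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(["person_id", "death_date", "suicide"])
        for r in records:
            writer.writerow([r.person_id, r.death_date.isoformat(), int(r.suicide)])
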