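"""Risk-scale definitions, episode scoring and cohort-wide categorisation.

Four scales are built in:

* **MSHR** — Manchester Self-Harm Rule: four unit-weight items, any positive
  item puts the episode in the moderate/high band (score 0 = low risk).
* **ReACT** — ReACT Self-Harm Rule: same structure with four different items.
* **SPS** — SAD PERSONS Scale: ten unit-weight items; 0-4 low, 5-6 moderate,
  7-10 high.
* **MSPS** — Modified SAD PERSONS Scale: ten items of which four carry weight
  two (maximum score 14); 0-5 low, 6-8 moderate, >8 high.

Definitions are plain data and can be overridden from a YAML/dict config so
centre-specific item operationalisations can be expressed without code
changes.  Item *semantics* (how a chart variable maps onto, say, "rational
thinking loss") are deliberately outside the scoring core: the cohort table
must already carry tri-state item columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

from .errors import VocabularyError

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import Episode

# Tri-state item columns an episode table may carry.  The union of the four
# scales' item sets; names describe the clinical content, not any one centre's
# chart variable.
MSHR_ITEMS = (
    "history_self_harm",
    "previous_psych_treatment",
    "benzodiazepine_index",
    "current_psych_treatment",
)
REACT_ITEMS = (
    "recent_self_harm_past_year",
    "living_alone_or_homeless",
    "cutting_index_method",
    "current_psych_treatment",
)
SPS_ITEMS = (
    "sex_male",
    "age_under19_or_over45",
    "depression",
    "previous_attempt",
    "ethanol_abuse",
    "rational_thinking_loss",
    "social_supports_lacking",
    "organised_plan",
    "no_spouse",
    "sickness",
)
MSPS_ITEMS = (
    "sex_male",
    "age_under19_or_over45",
    "depression_or_hopelessness",
    "previous_attempt_or_psych_care",
    "ethanol_or_drug_abuse",
    "rational_thinking_loss",
    "separated_divorced_widowed",
    "organised_or_serious_attempt",
    "no_social_support",
    "stated_future_intent",
)
MSPS_WEIGHT2_ITEMS = (
    "depression_or_hopelessness",
    "rational_thinking_loss",
    "organised_or_serious_attempt",
    "stated_future_intent",
)

ITEM_VOCABULARY: tuple[str, ...] = tuple(
    dict.fromkeys(MSHR_ITEMS + REACT_ITEMS + SPS_ITEMS + MSPS_ITEMS)
)

LOW = "low"
MODERATE = "moderate"
HIGH = "high"
MODERATE_HIGH = "moderate_high"


@dataclass(frozen=True)
class ScaleDefinition:
    """A scoring rule: weighted items plus ordered category cut-offs.

    Parameters
    ----------
    name
        Scale identifier (``MSHR``, ``ReACT``, ``SPS``, ``MSPS`` or a custom
        label).
    items
        Ordered ``(item_name, weight)`` pairs; weights are positive integers.
    cuts
        Ordered ``(upper_bound, category)`` pairs: a total score ``s`` falls
        in the first band with ``s <= upper_bound``.  Bands must tile
        ``0..max_score`` without gaps.
    """

    name: str
    items: tuple[tuple[str, int], ...]
    cuts: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        unknown = [n for n, _ in self.items if n not in ITEM_VOCABULARY]
        if unknown:
            raise VocabularyError(
                f"scale {self.name!r} uses unregistered items: {unknown}"
            )
        if any(w < 1 for _, w in self.items):
            raise ValueError(f"scale {self.name!r} has non-positive weights")
        uppers = [u for u, _ in self.cuts]
        if uppers != sorted(uppers) or len(set(uppers)) != len(uppers):
            raise ValueError(f"scale {self.name!r}: cut bounds must strictly increase")
        if uppers[-1] != self.max_score:
            raise ValueError(
                f"scale {self.name!r}: top band must end at max score "
                f"{self.max_score}, got {uppers[-1]}"
            )

    @property
    def max_score(self) -> int:
        return sum(w for _, w in self.items)

    @property
    def item_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.items)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(c for _, c in self.cuts)

    def category(self, score: int) -> str:
        """Risk band containing ``score``."""
        if not 0 <= score <= self.max_score:
            raise ValueError(f"score {score} outside 0..{self.max_score}")
        for upper, label in self.cuts:
            if score <= upper:
                return label
        raise AssertionError("unreachable: cuts tile 0..max_score")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScaleDefinition":
        items = tuple((str(n), int(w)) for n, w in d["items"])
        cuts = tuple((int(u), str(c)) for u, c in d["cuts"])
        return cls(name=str(d["name"]), items=items, cuts=cuts)


def builtin_definitions() -> dict[str, ScaleDefinition]:
    """The four built-in scale definitions, keyed by name."""
    unit = lambda names: tuple((n, 1) for n in names)  # noqa: E731
    return {
        "MSHR": ScaleDefinition(
            "MSHR", unit(MSHR_ITEMS), ((0, LOW), (4, MODERATE_HIGH))
        ),
        "ReACT": ScaleDefinition(
            "ReACT", unit(REACT_ITEMS), ((0, LOW), (4, MODERATE_HIGH))
        ),
        "SPS": ScaleDefinition(
            "SPS", unit(SPS_ITEMS), ((4, LOW), (6, MODERATE), (10, HIGH))
        ),
        "MSPS": ScaleDefinition(
            "MSPS",
            tuple(
                (n, 2 if n in MSPS_WEIGHT2_ITEMS else 1) for n in MSPS_ITEMS
            ),
            ((5, LOW), (8, MODERATE), (14, HIGH)),
        ),
    }


def load_definitions(source) -> dict[str, ScaleDefinition]:
    """Load scale definitions from a YAML path or a list of dicts."""
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        import yaml

        with open(source) as fh:  # type: ignore[arg-type]
            raw = yaml.safe_load(fh)
    else:
        raw = source
    defs = [ScaleDefinition.from_dict(d) for d in raw]
    return {d.name: d for d in defs}


@dataclass(frozen=True)
class RiskResult:
    """Score and risk band for one episode on one scale.

    ``score``/``category`` are ``None`` under the ``require_complete`` policy
    when any item is missing (an *incomplete* result, consumed by
    complete-case filtering).  ``items_missing`` counts items that were in
    state ``missing`` at scoring time regardless of policy.
    """

    scale: str
    score: int | None
    category: str | None
    items_missing: int

    @property
    def complete(self) -> bool:
        return self.items_missing == 0


TREAT_AS_ABSENT = "treat_as_absent"
REQUIRE_COMPLETE = "require_complete"


def score_episode(
    episode: "Episode",
    definition: ScaleDefinition,
    missing_policy: str = TREAT_AS_ABSENT,
) -> RiskResult:
    """Score one episode on one scale.

    Under ``treat_as_absent`` (the primary analysis convention) missing items
    contribute zero, i.e. only items positively recorded as present count
    toward the score.  Under ``require_complete`` an episode with any missing
    item yields an incomplete result (``score is None``).
    """
    from .cohort import ItemState  # local import to avoid a cycle

    if missing_policy not in (TREAT_AS_ABSENT, REQUIRE_COMPLETE):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    score = 0
    n_missing = 0
    for name, weight in definition.items:
        try:
            state = episode.items[name]
        except KeyError:
            raise VocabularyError(
                f"episode {episode.episode_id!r} lacks item {name!r} "
                f"required by scale {definition.name!r}"
            ) from None
        if state is ItemState.PRESENT:
            score += weight
        elif state is ItemState.MISSING:
            n_missing += 1
    if missing_policy == REQUIRE_COMPLETE and n_missing:
        return RiskResult(definition.name, None, None, n_missing)
    return RiskResult(definition.name, score, definition.category(score), n_missing)


def categorize_cohort(
    episodes: Sequence["Episode"],
    definitions: Mapping[str, ScaleDefinition] | Iterable[ScaleDefinition] | None = None,
    missing_policy: str = TREAT_AS_ABSENT,
) -> pd.DataFrame:
    """Score every episode on every scale.

    Returns a DataFrame indexed by ``episode_id`` with MultiIndex columns
    ``(scale, field)`` where field is ``score``, ``category`` or
    ``items_missing``.
    """
    if definitions is None:
        definitions = builtin_definitions()
    if not isinstance(definitions, Mapping):
        definitions = {d.name: d for d in definitions}
    data: dict[tuple[str, str], list] = {}
    for name, definition in definitions.items():
        results = [score_episode(e, definition, missing_policy) for e in episodes]
        data[(name, "score")] = [r.score for r in results]
        data[(name, "category")] = [r.category for r in results]
        data[(name, "items_missing")] = [r.items_missing for r in results]
    frame = pd.DataFrame(data, index=pd.Index([e.episode_id for e in episodes],
                                              name="episode_id"))
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["scale", "field"])
    return frame
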