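"""Shared fixtures: a handcrafted micro-cohort and one generated cohort."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from harmscales import ItemState, default_params, generate
from harmscales.cohort import (
    FEMALE,
    MENTAL_HEALTH_NURSE,
    NO_ASSESSOR,
    SELF_POISONING,
    Episode,
)
from harmscales.scales import ITEM_VOCABULARY


def make_episode(
    eid: str,
    pid: str = "p1",
    day: int = 0,
    age: int = 30,
    sex: str = FEMALE,
    method: str = SELF_POISONING,
    assessed: bool = True,
    present: tuple[str, ...] = (),
    missing: tuple[str, ...] = (),
    **kwargs,
) -> Episode:
    """Episode with the full item vocabulary, defaulting every item to absent."""
    items = {name: ItemState.ABSENT for name in ITEM_VOCABULARY}
    for name in present:
        items[name] = ItemState.PRESENT
    for name in missing:
        items[name] = ItemState.MISSING
    return Episode(
        episode_id=eid,
        person_id=pid,
        presentation_date=date(2011, 1, 1) + timedelta(days=day),
        age=age,
        sex=sex,
        method=method,
        assessed=assessed,
        assessor=kwargs.pop("assessor", MENTAL_HEALTH_NURSE if assessed else NO_ASSESSOR),
        centre=kwargs.pop("centre", "centre_1"),
        items=items,
        **kwargs,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter generated cohort, shared across tests."""
    return generate(default_params(seed=11))


@pytest.fixture(scope="session")
def small_params():
    """Down-scaled generator parameters for fast end-to-end tests."""
    return default_params(n_episodes=800, n_persons=640, seed=5)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return generate(small_params)
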