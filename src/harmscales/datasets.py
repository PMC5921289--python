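"""Reference count tables from a published multicentre ED self-harm cohort.

Category-by-outcome episode counts for the four scales, as reported for a
large unselected English cohort (4000 episodes, 2010-2012; 3962 episodes
with mortality follow-up, 38 persons unlinked).  These counts are a
count-level entry point: run through the two-by-two construction and the
accuracy battery they reproduce the published accuracy tables, which makes
them a convenient worked example and an exact regression surface.
"""

from __future__ import annotations

N_EPISODES = 4000
N_SUICIDE_ANALYSED = 3962
N_LOST_PERSONS = 38

# {outcome: {scale: {category: (outcome_positive, outcome_negative)}}}
_REFERENCE: dict[str, dict[str, dict[str, tuple[int, int]]]] = {
    "repeat": {
        "MSHR": {"low": (23, 435), "moderate_high": (1110, 2432)},
        "ReACT": {"low": (63, 665), "moderate_high": (1070, 2202)},
        "SPS": {"low": (781, 2029), "moderate": (251, 642), "high": (101, 196)},
        "MSPS": {"low": (1020, 2561), "moderate": (99, 276), "high": (14, 30)},
    },
    "suicide": {
        "MSHR": {"low": (2, 450), "moderate_high": (16, 3494)},
        "ReACT": {"low": (4, 719), "moderate_high": (14, 3225)},
        "SPS": {"low": (12, 2766), "moderate": (4, 885), "high": (2, 293)},
        "MSPS": {"low": (15, 3532), "moderate": (3, 369), "high": (0, 43)},
    },
}


def reference_count_tables(outcome: str = "repeat") -> dict[str, dict[str, tuple[int, int]]]:
    """Published category-by-outcome counts for ``outcome`` (deep copy)."""
    if outcome not in _REFERENCE:
        raise KeyError(f"outcome must be one of {sorted(_REFERENCE)}")
    return {s: dict(cats) for s, cats in _REFERENCE[outcome].items()}
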