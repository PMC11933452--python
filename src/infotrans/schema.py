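"""Shared column-name conventions for participant tables and profiles.

All tabular interchange in the package is UTF-8 CSV with a header row,
comma separator and '.' decimal. The wide participant table carries one
row per participant; per-text ratings live in columns named
``{sentiment}_{stimulus_id}``.
"""

from __future__ import annotations

# Big Five trait columns, fixed order (also the regressor order after entropy).
TRAITS: tuple[str, ...] = (
    "openness",
    "conscientiousness",
    "extraversion",
    "agreeableness",
    "neuroticism",
)

# Sentiment dimensions rated per text, on the 1-7 analog scale.
SENTIMENTS: tuple[str, ...] = (
    "information",
    "boredom",
    "creativity",
    "affect",
    "arousal",
)

# Psychometric sum-score scales used for cohort characterization.
SCALES: tuple[str, ...] = ("bps", "msbs", "stai_y", "brs")

RATING_MIN: float = 1.0
RATING_MAX: float = 7.0

ID_COL = "participant_id"
COHORT_COL = "cohort"


def rating_col(sentiment: str, stimulus_id: str) -> str:
    """Column name for one sentiment rating of one stimulus."""
    return f"{sentiment}_{stimulus_id}"


def rating_cols(sentiment: str, stimulus_ids: list[str]) -> list[str]:
    return [rating_col(sentiment, s) for s in stimulus_ids]
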