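"""Scoring rubric for the VIENNA spatial-navigation assessment.

VIENNA presents 12 main trials ("items").  In each trial the participant
watches a passive first-person walk through a virtual hallway and then marks,
on an allocentric map, the door at which the walk ended.  Each item is scored
on a three-point scale:

* 2 points — the correct door was chosen;
* 1 point  — a door parallel or adjacent to the correct one (a *spatial
  updating* error) or the door opposite the correct one (a *perspective
  rotation* error);
* 0 points — any other door.

The total score over the 12 main items (range 0-24) is the primary outcome;
the counts of updating and rotation errors are auxiliary outcomes.

Door geometry is never derived here: each item carries a configuration
(:class:`ItemConfig`) listing its doors, the correct door, and the two sets of
one-point doors.  Door identifiers are 1-based integers within an item.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ItemType",
    "ErrorType",
    "ItemConfig",
    "ScoredResponse",
    "ParticipantScore",
    "InvalidResponseError",
    "ConfigurationError",
    "score_response",
    "score_participant",
    "expected_item_score",
]

logger = logging.getLogger(__name__)


class ItemType(str, Enum):
    """Turn complexity of an item; difficulty increases along this order."""

    NO_TURN = "no-turn"
    SINGLE_TURN = "single-turn"
    DOUBLE_TURN = "double-turn"
    FULL_TURN = "full-turn"


#: canonical ordering used for difficulty summaries
ITEM_TYPE_ORDER: tuple[ItemType, ...] = (
    ItemType.NO_TURN,
    ItemType.SINGLE_TURN,
    ItemType.DOUBLE_TURN,
    ItemType.FULL_TURN,
)


class ErrorType(str, Enum):
    NONE = "none"
    UPDATING = "updating"
    ROTATION = "rotation"
    OTHER = "other"


class ConfigurationError(ValueError):
    """Raised for inconsistent item configurations or unknown items."""


class InvalidResponseError(ValueError):
    """Raised when a chosen door is outside the item's door range."""


@dataclass(frozen=True)
class ItemConfig:
    """Door geometry and turn type of one VIENNA trial.

    Parameters
    ----------
    item_id:
        Label of the item, e.g. ``"i7"``.
    item_type:
        Turn category of the trial.
    n_doors:
        Number of doors in the hallway (>= 1); doors are numbered 1..n_doors.
    correct_door:
        The two-point door.
    updating_doors:
        One-point doors parallel or adjacent to the correct door
        (spatial-updating errors).
    rotation_doors:
        One-point doors opposite the correct door (perspective-rotation
        errors).
    is_main:
        Whether the item counts towards the 0-24 total.  Practice and
        instruction trials are configured with ``is_main=False``.
    """

    item_id: str
    item_type: ItemType
    n_doors: int
    correct_door: int
    updating_doors: frozenset[int] = field(default_factory=frozenset)
    rotation_doors: frozenset[int] = field(default_factory=frozenset)
    is_main: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_type", ItemType(self.item_type))
        object.__setattr__(self, "updating_doors", frozenset(self.updating_doors))
        object.__setattr__(self, "rotation_doors", frozenset(self.rotation_doors))
        if self.n_doors < 1:
            raise ConfigurationError(f"{self.item_id}: n_doors must be >= 1")
        doors = range(1, self.n_doors + 1)
        if self.correct_door not in doors:
            raise ConfigurationError(
                f"{self.item_id}: correct door {self.correct_door} outside 1..{self.n_doors}"
            )
        one_point = self.updating_doors | self.rotation_doors
        if self.correct_door in one_point:
            raise ConfigurationError(
                f"{self.item_id}: correct door also listed as a one-point door"
            )
        if self.updating_doors & self.rotation_doors:
            raise ConfigurationError(
                f"{self.item_id}: updating and rotation door sets overlap"
            )
        if not one_point <= set(doors):
            bad = sorted(one_point - set(doors))
            raise ConfigurationError(
                f"{self.item_id}: one-point doors {bad} outside 1..{self.n_doors}"
            )

    @property
    def n_one_point(self) -> int:
        return len(self.updating_doors) + len(self.rotation_doors)

    @property
    def zero_doors(self) -> frozenset[int]:
        """Doors scoring zero points."""
        return frozenset(range(1, self.n_doors + 1)) - self.updating_doors \
            - self.rotation_doors - {self.correct_door}


@dataclass(frozen=True)
class ScoredResponse:
    participant_id: str
    item_id: str
    points: int
    error_type: ErrorType


@dataclass(frozen=True)
class ParticipantScore:
    """Aggregate outcome of one participant over the main items."""

    participant_id: str
    total: int
    n_updating: int
    n_rotation: int
    n_items_scored: int


def score_response(
    config: ItemConfig, chosen: int, participant_id: str = ""
) -> ScoredResponse:
    """Score a single chosen door against the item's rubric.

    The rubric partitions the doors: the correct door scores 2 (no error),
    updating/rotation doors score 1 with the matching error type, and every
    other door scores 0 with error type ``other``.
    """
    if not (1 <= chosen <= config.n_doors):
        raise InvalidResponseError(
            f"participant {participant_id!r}, item {config.item_id}: "
            f"door {chosen} outside 1..{config.n_doors}"
        )
    if chosen == config.correct_door:
        points, error = 2, ErrorType.NONE
    elif chosen in config.updating_doors:
        points, error = 1, ErrorType.UPDATING
    elif chosen in config.rotation_doors:
        points, error = 1, ErrorType.ROTATION
    else:
        points, error = 0, ErrorType.OTHER
    return ScoredResponse(participant_id, config.item_id, points, error)


def score_participant(
    configs: Sequence[ItemConfig],
    responses: Iterable[tuple[str, int]] | Mapping[str, int],
    participant_id: str = "",
) -> ParticipantScore:
    """Aggregate one participant's responses over the configured main items.

    Duplicate responses to one item and responses to unconfigured items are
    rejected.  A main item with no response is scored 0 / ``other`` and a
    warning is logged; the protocol has no refusal code because premature
    terminations do not occur under standardized administration.
    """
    by_id = {c.item_id: c for c in configs}
    if isinstance(responses, Mapping):
        pairs = list(responses.items())
    else:
        pairs = list(responses)
    seen: dict[str, int] = {}
    for item_id, chosen in pairs:
        if item_id not in by_id:
            raise ConfigurationError(
                f"participant {participant_id!r}: response to unknown item {item_id!r}"
            )
        if item_id in seen:
            raise InvalidResponseError(
                f"participant {participant_id!r}: duplicate response to item {item_id!r}"
            )
        seen[item_id] = chosen

    total = n_upd = n_rot = n_scored = 0
    for config in configs:
        if not config.is_main:
            continue
        n_scored += 1
        if config.item_id not in seen:
            logger.warning(
                "participant %r: no response for item %s, scored 0/other",
                participant_id,
                config.item_id,
            )
            continue
        scored = score_response(config, seen[config.item_id], participant_id)
        total += scored.points
        n_upd += scored.error_type is ErrorType.UPDATING
        n_rot += scored.error_type is ErrorType.ROTATION
    return ParticipantScore(participant_id, total, n_upd, n_rot, n_scored)


def expected_item_score(config: ItemConfig) -> Fraction:
    """Expected points E under a uniform random door choice.

    ``E = (2 + number of one-point doors) / n_doors``, returned as an exact
    rational so that report rounding is the only rounding applied.  E is the
    chance-level benchmark for the difficulty ratio M̄/E.
    """
    return Fraction(2 + config.n_one_point, config.n_doors)
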