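"""Per-user state: biography tags, learned profile, rating history.

A new user starts from biography tags B_u only (interests and biographic
background entered at onboarding).  As the user rates content, the profile
tag set P_u accumulates the union of tags of all positively rated items,
and the history size n drives the weight w_p that shifts scoring from
biography toward learned preferences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path

from .catalog import ContentItem
from .semnet import SemanticNetwork

__all__ = [
    "SMILEY_VALUES",
    "Biography",
    "RatingEvent",
    "UserProfile",
    "init_profile",
    "update_profile",
    "mark_used",
    "history_weight",
]

logger = logging.getLogger(__name__)

#: Three-level smiley rating, normalised to [0, 1].
SMILEY_VALUES = {"negative": 0.0, "neutral": 0.5, "positive": 1.0}


@dataclass(frozen=True)
class Biography:
    """Onboarding information: interest tags, birth date, exclusions.

    ``exclusions`` may contain item ids or concept tags; excluded content is
    never recommended, unconditionally.
    """

    user_id: str
    bio_tags: frozenset[str] = field(default_factory=frozenset)
    birth_date: date | None = None
    exclusions: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bio_tags", frozenset(self.bio_tags))
        object.__setattr__(self, "exclusions", frozenset(self.exclusions))

    @classmethod
    def load(cls, path: str | Path, network: SemanticNetwork | None = None) -> "Biography":
        """Read a per-user JSON file.

        ``bio_tags`` are stored as words; when a network is given they are
        resolved to concepts at load time (unresolvable words dropped with a
        warning), otherwise kept verbatim.
        """
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        words = data.get("bio_tags", [])
        tags = network.resolve_words(words) if network is not None else set(words)
        birth = data.get("birth_date")
        return cls(
            user_id=data["user_id"],
            bio_tags=frozenset(tags),
            birth_date=date.fromisoformat(birth) if birth else None,
            exclusions=frozenset(data.get("exclusions", [])),
        )

    def save(self, path: str | Path) -> None:
        data = {
            "user_id": self.user_id,
            "bio_tags": sorted(self.bio_tags),
            "birth_date": self.birth_date.isoformat() if self.birth_date else None,
            "exclusions": sorted(self.exclusions),
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class RatingEvent:
    """One explicit smiley rating, optionally with an implicit score.

    An aborted activation maps to ``implicit_score`` 0 and counts as
    non-positive regardless of the smiley.
    """

    user_id: str
    item_id: str
    timestamp: datetime
    smiley: str
    implicit_score: float | None = None

    def __post_init__(self) -> None:
        if self.smiley not in SMILEY_VALUES:
            raise ValueError(f"smiley must be one of {sorted(SMILEY_VALUES)}")
        if self.implicit_score is not None and not 0.0 <= self.implicit_score <= 1.0:
            raise ValueError("implicit_score must lie in [0, 1]")

    @property
    def normalized_value(self) -> float:
        return SMILEY_VALUES[self.smiley]

    @property
    def is_positive(self) -> bool:
        """Positive smiley and not an implicit abort."""
        if self.implicit_score is not None and self.implicit_score == 0.0:
            return False
        return self.smiley == "positive"


@dataclass(frozen=True)
class UserProfile:
    """Evolving profile: P_u tag set, history count n, last-use timestamps."""

    user_id: str
    profile_tags: frozenset[str] = field(default_factory=frozenset)
    history_count: int = 0
    per_item_last_use: "dict[str, datetime]" = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "profile_tags", frozenset(self.profile_tags))

    def save(self, path: str | Path) -> None:
        data = {
            "user_id": self.user_id,
            "profile_tags": sorted(self.profile_tags),
            "history_count": self.history_count,
            "per_item_last_use": {
                k: v.isoformat() for k, v in sorted(self.per_item_last_use.items())
            },
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "UserProfile":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            user_id=data["user_id"],
            profile_tags=frozenset(data.get("profile_tags", [])),
            history_count=int(data.get("history_count", 0)),
            per_item_last_use={
                k: datetime.fromisoformat(v)
                for k, v in data.get("per_item_last_use", {}).items()
            },
        )


def init_profile(biography: Biography, network: SemanticNetwork | None = None) -> UserProfile:
    """Cold-start profile: empty P_u, n = 0.

    When a network is given, biography tags that do not resolve to concepts
    are ignored downstream (the biography itself is kept verbatim); a warning
    is logged per unresolvable tag.
    """
    if network is not None:
        for tag in sorted(biography.bio_tags):
            if tag not in network:
                logger.warning(
                    "biography tag %r for user %s not in network", tag, biography.user_id
                )
    return UserProfile(user_id=biography.user_id)


def update_profile(
    profile: UserProfile, rating: RatingEvent, item: ContentItem
) -> UserProfile:
    """Fold one rating into the profile.

    Increments the history count; on a positive rating the item's tags join
    P_u.  The item's last-use timestamp is set to the rating time.
    """
    if rating.item_id != item.item_id:
        raise ValueError(
            f"rating is for {rating.item_id!r} but item is {item.item_id!r}"
        )
    tags = profile.profile_tags | item.tags if rating.is_positive else profile.profile_tags
    last_use = dict(profile.per_item_last_use)
    last_use[item.item_id] = rating.timestamp
    return replace(
        profile,
        profile_tags=tags,
        history_count=profile.history_count + 1,
        per_item_last_use=last_use,
    )


def mark_used(profile: UserProfile, item_id: str, when: datetime) -> UserProfile:
    """Record that content started playing (drives the 24 h recency rule)."""
    last_use = dict(profile.per_item_last_use)
    last_use[item_id] = when
    return replace(profile, per_item_last_use=last_use)


def history_weight(n: int, k: float = 10.0, w_max: float = 0.9) -> float:
    """Profile weight w_p as a function of history size n.

    ``w_p = min(w_max, n / (n + k))``: zero with no history (biography-only
    scoring), rising smoothly and saturating at ``w_max`` so biography is
    never fully discarded.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if k <= 0:
        raise ValueError("k must be > 0")
    if not 0.0 < w_max <= 1.0:
        raise ValueError("w_max must lie in (0, 1]")
    return min(w_max, n / (n + k))
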