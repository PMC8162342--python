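"""Content scoring, filtering, ranking and diversity-preserving selection.

The scoring backbone is the Dice coefficient between an item's tag set T_i
and (a) the learned profile P_u and (b) the biography B_u, blended by the
history weight w_p:

    sim(T_i, P_u, B_u) = w_p * sim_dice(T_i, P_u) + (1 - w_p) * sim_dice(T_i, B_u)

The Dice similarity itself is "softened" through the semantic network: the
exact intersection is replaced by a greedy one-to-one matching over pairwise
concept similarities, so near-synonymous tags still contribute.  A seasonal
term with high weight boosts content tied to calendar events (Christmas,
the user's birthday).  Candidates above a score threshold that were not
used in the past 24 h are sorted by average liking and drawn into the slate
with fitness-proportionate selection over content types, preserving type
diversity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .catalog import Catalog, ContentItem
from .semnet import DEFAULT_D_MAX, SemanticNetwork
from .user_model import Biography, UserProfile, history_weight

__all__ = [
    "ScoredItem",
    "RecommenderConfig",
    "LikingStats",
    "dice",
    "soft_dice",
    "combined_similarity",
    "seasonal_bonus",
    "eligible_candidates",
    "rank_by_liking",
    "fitness_proportionate_select",
    "SoftDiceCache",
    "recommend",
    "baseline_recommend",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoredItem:
    """An item with its score decomposition for one user at one moment."""

    item_id: str
    content_type: str
    similarity: float
    seasonal_bonus: float
    average_liking: float

    @property
    def final_score(self) -> float:
        return self.similarity + self.seasonal_bonus


@dataclass
class RecommenderConfig:
    """All tunables of the recommendation pipeline.

    threshold
        Minimum final score (similarity + seasonal bonus) for candidacy;
        the boundary is inclusive.
    recency_hours
        Content used within this window is never re-recommended.
    slate_size
        Number of items per recommendation slate.
    k_smoothing, w_max
        Parameters of the history weight w_p = min(w_max, n / (n + k)).
    seasonal_weight
        Additive bonus for content matching a current calendar event; the
        default 1.0 guarantees seasonal items clear any threshold.
    liking_prior, liking_prior_weight
        Laplace smoothing of per-item average liking; unrated items sit at
        the prior.
    d_max
        Maximum graph distance contributing to soft tag similarity.
    selection_mode
        "roulette" (randomised fitness-proportionate selection) or
        "largest_remainder" (deterministic apportionment, for testing).
    """

    threshold: float = 0.1
    recency_hours: float = 24.0
    slate_size: int = 6
    k_smoothing: float = 10.0
    w_max: float = 0.9
    seasonal_weight: float = 1.0
    liking_prior: float = 0.5
    liking_prior_weight: float = 1.0
    d_max: int = DEFAULT_D_MAX
    selection_mode: str = "roulette"
    rng_seed: int | None = None
    seasonal_windows: dict = field(
        default_factory=lambda: {"christmas": ("12-01", "12-26")}
    )
    birthday_window_days: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0 + self.seasonal_weight:
            raise ValueError("threshold out of range")
        if self.slate_size < 1:
            raise ValueError("slate_size must be >= 1")
        if self.selection_mode not in ("roulette", "largest_remainder"):
            raise ValueError("selection_mode must be 'roulette' or 'largest_remainder'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RecommenderConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


class LikingStats:
    """Per-item average liking over all users and sessions.

    Laplace-smoothed: ``(prior * prior_weight + sum) / (prior_weight + n)``,
    so an unrated item sits exactly at the prior (default 0.5).
    """

    def __init__(self, prior: float = 0.5, prior_weight: float = 1.0) -> None:
        self.prior = prior
        self.prior_weight = prior_weight
        self._sum: dict[str, float] = {}
        self._count: dict[str, int] = {}

    def add_rating(self, item_id: str, normalized_value: float) -> None:
        self._sum[item_id] = self._sum.get(item_id, 0.0) + normalized_value
        self._count[item_id] = self._count.get(item_id, 0) + 1

    def average(self, item_id: str) -> float:
        s = self._sum.get(item_id, 0.0)
        n = self._count.get(item_id, 0)
        return (self.prior * self.prior_weight + s) / (self.prior_weight + n)


# ---------------------------------------------------------------------------
# similarity primitives
# ---------------------------------------------------------------------------

def dice(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Classical Dice coefficient 2|A∩B| / (|A|+|B|); 0 when both empty."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 0.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def soft_dice(
    set_a: Iterable[str],
    set_b: Iterable[str],
    network: SemanticNetwork,
    d_max: int = DEFAULT_D_MAX,
) -> float:
    """Semantically softened Dice coefficient.

    The intersection count is replaced by the mass M of a greedy one-to-one
    matching: repeatedly pair the remaining cross pair with the highest
    positive concept similarity, remove both concepts, and sum the
    similarities.  Returns ``2 M / (|A| + |B|)``.

    On a network without edges only identical concepts have positive
    similarity, so the result reduces exactly to the classical Dice
    coefficient.  Unknown concepts raise ``KeyError``.
    """
    a = sorted(set(set_a))
    b = sorted(set(set_b))
    if not a or not b:
        return 0.0
    sims = network.similarity_matrix(a, b, d_max=d_max)
    mass = 0.0
    # greedy: argmax over the remaining matrix; sorted inputs make the
    # first-flat-index tie-break lexicographic, hence deterministic
    for _ in range(min(len(a), len(b))):
        flat = int(np.argmax(sims))
        i, j = divmod(flat, sims.shape[1])
        best = sims[i, j]
        if best <= 0.0:
            break
        mass += float(best)
        sims[i, :] = -1.0
        sims[:, j] = -1.0
    return 2.0 * mass / (len(a) + len(b))


class SoftDiceCache:
    """Memoized soft Dice for repeated scoring of a fixed catalog.

    Tag sets recur heavily during simulation (item tags are fixed, profile
    tag sets change only when a positive rating contributes new tags), so
    caching on the frozen set pair removes almost all similarity work.
    """

    def __init__(self, network: SemanticNetwork, d_max: int = DEFAULT_D_MAX) -> None:
        self.network = network
        self.d_max = d_max
        self._cache: dict[tuple[frozenset, frozenset], float] = {}

    def __call__(self, set_a: Iterable[str], set_b: Iterable[str]) -> float:
        key = (frozenset(set_a), frozenset(set_b))
        value = self._cache.get(key)
        if value is None:
            value = soft_dice(key[0], key[1], self.network, self.d_max)
            self._cache[key] = value
        return value


def combined_similarity(
    item: ContentItem,
    profile: UserProfile,
    biography: Biography,
    w_p: float,
    network: SemanticNetwork,
    d_max: int = DEFAULT_D_MAX,
    sim_fn=None,
) -> float:
    """Weighted blend of profile and biography similarity.

    ``w_p * soft_dice(T_i, P_u) + (1 - w_p) * soft_dice(T_i, B_u)``;
    linear in w_p and bounded in [0, 1].  ``sim_fn`` may supply a cached
    soft-Dice implementation (see :class:`SoftDiceCache`).
    """
    if not 0.0 <= w_p <= 1.0:
        raise ValueError("w_p must lie in [0, 1]")
    if sim_fn is None:
        sim_fn = lambda a, b: soft_dice(a, b, network, d_max)  # noqa: E731
    sim_p = sim_fn(item.tags, profile.profile_tags) if w_p > 0 else 0.0
    sim_b = sim_fn(item.tags, biography.bio_tags) if w_p < 1 else 0.0
    return w_p * sim_p + (1.0 - w_p) * sim_b


def _md(today: date) -> tuple[int, int]:
    return (today.month, today.day)


def _window_contains(today: date, start_md: str, end_md: str) -> bool:
    sm, sd = (int(x) for x in start_md.split("-"))
    em, ed = (int(x) for x in end_md.split("-"))
    t, s, e = _md(today), (sm, sd), (em, ed)
    if s <= e:
        return s <= t <= e
    return t >= s or t <= e  # window wraps over new year


def seasonal_bonus(
    item: ContentItem,
    today: date,
    biography: Biography,
    w_s: float = 1.0,
    windows: Mapping[str, tuple[str, str]] | None = None,
    birthday_window_days: int = 3,
) -> float:
    """Bonus w_s if any event tag's date window contains ``today``, else 0.

    ``birthday`` is special-cased to a window of +/- ``birthday_window_days``
    around the anniversary of the biography's birth date.
    """
    if not item.event_tags:
        return 0.0
    windows = windows if windows is not None else {"christmas": ("12-01", "12-26")}
    for tag in item.event_tags:
        if tag == "birthday":
            if biography.birth_date is None:
                continue
            for delta in range(-birthday_window_days, birthday_window_days + 1):
                d = today + timedelta(days=delta)
                if _md(d) == _md(biography.birth_date):
                    return w_s
        elif tag in windows:
            start_md, end_md = windows[tag]
            if _window_contains(today, start_md, end_md):
                return w_s
    return 0.0


# ---------------------------------------------------------------------------
# filtering, ranking, selection
# ---------------------------------------------------------------------------

def _is_excluded(item: ContentItem, biography: Biography | None) -> bool:
    if biography is None:
        return False
    if item.item_id in biography.exclusions:
        return True
    return bool(item.tags & biography.exclusions)


def _recency_ok(
    item_id: str, profile: UserProfile | None, now: datetime, recency_hours: float
) -> bool:
    if profile is None:
        return True
    last = profile.per_item_last_use.get(item_id)
    return last is None or (now - last) >= timedelta(hours=recency_hours)


def score_item(
    item: ContentItem,
    profile: UserProfile,
    biography: Biography,
    liking: LikingStats,
    network: SemanticNetwork,
    config: RecommenderConfig,
    now: datetime,
    w_p: float | None = None,
    sim_fn=None,
) -> ScoredItem:
    """Full score decomposition of one item for one user."""
    if w_p is None:
        w_p = history_weight(profile.history_count, config.k_smoothing, config.w_max)
    sim = combined_similarity(item, profile, biography, w_p, network, config.d_max, sim_fn)
    bonus = seasonal_bonus(
        item, now.date(), biography, config.seasonal_weight,
        config.seasonal_windows, config.birthday_window_days,
    )
    return ScoredItem(
        item_id=item.item_id,
        content_type=item.content_type,
        similarity=sim,
        seasonal_bonus=bonus,
        average_liking=liking.average(item.item_id),
    )


def eligible_candidates(
    catalog: Catalog,
    profile: UserProfile,
    biography: Biography,
    liking: LikingStats,
    network: SemanticNetwork,
    config: RecommenderConfig,
    now: datetime,
    sim_fn=None,
) -> list[ScoredItem]:
    """Score the catalog and keep recommendation candidates.

    An item qualifies when its final score is >= the threshold (inclusive),
    it was not used within the recency window, and it is not excluded by the
    biography (by id or by tag).  Exclusions dominate unconditionally.
    """
    w_p = history_weight(profile.history_count, config.k_smoothing, config.w_max)
    out: list[ScoredItem] = []
    for item in catalog:
        if _is_excluded(item, biography):
            continue
        if not _recency_ok(item.item_id, profile, now, config.recency_hours):
            continue
        scored = score_item(item, profile, biography, liking, network, config, now, w_p, sim_fn)
        if scored.final_score >= config.threshold:
            out.append(scored)
    return out


def rank_by_liking(candidates: Sequence[ScoredItem]) -> list[ScoredItem]:
    """Descending average liking; ties by final score, then item id."""
    return sorted(
        candidates,
        key=lambda s: (-s.average_liking, -s.final_score, s.item_id),
    )


def fitness_proportionate_select(
    candidates: Sequence[ScoredItem],
    k: int,
    rng: np.random.Generator,
    mode: str = "roulette",
) -> list[ScoredItem]:
    """Draw a slate of up to k items, preserving content-type proportions.

    Candidates are grouped by content type and ranked by liking within each
    type.  In "roulette" mode each draw first picks a type with probability
    proportional to that type's remaining candidate count, then pops the
    type's top-ranked item; in "largest_remainder" mode per-type quotas are
    apportioned deterministically.  Fewer than k candidates: all returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not candidates:
        logger.warning("fitness-proportionate selection over empty candidate set")
        return []
    by_type: dict[str, list[ScoredItem]] = {}
    for s in rank_by_liking(candidates):
        by_type.setdefault(s.content_type, []).append(s)
    if len(candidates) <= k:
        return rank_by_liking(candidates)

    slate: list[ScoredItem] = []
    if mode == "largest_remainder":
        types = sorted(by_type)
        total = len(candidates)
        quotas = {t: k * len(by_type[t]) / total for t in types}
        counts = {t: int(np.floor(quotas[t])) for t in types}
        short = k - sum(counts.values())
        leftovers = sorted(
            types, key=lambda t: (-(quotas[t] - counts[t]), -len(by_type[t]), t)
        )
        for t in leftovers[:short]:
            counts[t] += 1
        for t in types:
            take = min(counts[t], len(by_type[t]))
            slate.extend(by_type[t][:take])
        # type pools may be shorter than their quota; fill from global ranking
        if len(slate) < k:
            chosen = {s.item_id for s in slate}
            for s in rank_by_liking(candidates):
                if s.item_id not in chosen:
                    slate.append(s)
                    if len(slate) == k:
                        break
        return slate[:k]

    while len(slate) < k and by_type:
        types = sorted(by_type)
        weights = np.array([len(by_type[t]) for t in types], dtype=float)
        t = types[rng.choice(len(types), p=weights / weights.sum())]
        slate.append(by_type[t].pop(0))
        if not by_type[t]:
            del by_type[t]
    return slate


# ---------------------------------------------------------------------------
# top-level entry points
# ---------------------------------------------------------------------------

def _popularity_fallback(
    catalog: Catalog,
    profile: UserProfile | None,
    biography: Biography | None,
    liking: LikingStats,
    config: RecommenderConfig,
    now: datetime,
    exclude_items: frozenset[str],
) -> list[ScoredItem]:
    """Top-liked recency-eligible items; used when no candidate clears θ."""
    pool = [
        ScoredItem(
            item_id=item.item_id,
            content_type=item.content_type,
            similarity=0.0,
            seasonal_bonus=0.0,
            average_liking=liking.average(item.item_id),
        )
        for item in catalog
        if item.item_id not in exclude_items
        and not _is_excluded(item, biography)
        and _recency_ok(item.item_id, profile, now, config.recency_hours)
    ]
    return rank_by_liking(pool)[: config.slate_size]


def recommend(
    catalog: Catalog,
    profile: UserProfile,
    biography: Biography,
    liking: LikingStats,
    network: SemanticNetwork,
    config: RecommenderConfig,
    now: datetime,
    rng: np.random.Generator | None = None,
    exclude_items: Iterable[str] = (),
    sim_fn=None,
) -> list[ScoredItem]:
    """Produce a personalized recommendation slate.

    Pipeline: history weight w_p -> blended similarity + seasonal bonus ->
    threshold / recency / exclusion filtering -> per-type ranking by average
    liking -> fitness-proportionate selection.  Deterministic for a fixed
    rng (or ``config.rng_seed``).  ``exclude_items`` removes content already
    shown in this interaction (reload support).

    With an empty biography and no history every similarity is 0 and no
    candidate clears the threshold; the slate then falls back to the
    globally top-liked eligible items (popularity baseline).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    exclude = frozenset(exclude_items)
    candidates = [
        c
        for c in eligible_candidates(catalog, profile, biography, liking, network, config, now, sim_fn)
        if c.item_id not in exclude
    ]
    if not candidates:
        return _popularity_fallback(
            catalog, profile, biography, liking, config, now, exclude
        )
    return fitness_proportionate_select(
        candidates, config.slate_size, rng, mode=config.selection_mode
    )


def baseline_recommend(
    catalog: Catalog,
    liking: LikingStats,
    config: RecommenderConfig,
    rng: np.random.Generator,
    now: datetime | None = None,
    profile: UserProfile | None = None,
    exclude_items: Iterable[str] = (),
) -> list[ScoredItem]:
    """Non-personalized comparison slate: popularity-weighted random draw.

    Draws ``slate_size`` items without replacement with probability
    proportional to average liking, among items outside the recency window.
    Carries no user model; ``profile`` only supplies last-use timestamps.
    """
    exclude = frozenset(exclude_items)
    now = now or datetime.now()
    pool = [
        item
        for item in catalog
        if item.item_id not in exclude
        and _recency_ok(item.item_id, profile, now, config.recency_hours)
    ]
    if not pool:
        logger.warning("baseline recommendation over empty pool")
        return []
    weights = np.array([liking.average(it.item_id) for it in pool], dtype=float)
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    k = min(config.slate_size, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False, p=weights / weights.sum())
    return [
        ScoredItem(
            item_id=pool[i].item_id,
            content_type=pool[i].content_type,
            similarity=0.0,
            seasonal_bonus=0.0,
            average_liking=liking.average(pool[i].item_id),
        )
        for i in idx
    ]
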