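"""Synthetic tandem-session simulator.

Generates a concept network, a content catalog, simulated users with
latent topic affinities, and full multi-session event logs, so that the
recommender, the analytics and the A-B evaluation harness can be exercised
end to end without any study data.

The behavioural model is deliberately minimal but moment-calibrated:

* per-session activation counts follow a shifted negative binomial with
  mean 5.9, SD 6.3 and support >= 1 (overdispersed counts; SD > mean rules
  out a Poisson model);
* a user's internal liking of an item is the soft Dice similarity between
  the item's tags and the support of the user's true affinity, weighted by
  a per-type preference — the same similarity the recommender optimises, so
  "matched recommender" is well defined;
* noise enters only at the rating/selection layer (smiley flips with a
  configurable probability);
* a user accepts the best slate item whose liking clears an acceptance
  threshold, otherwise reloads (up to a cap) and finally falls back to
  direct search for their best available item.

All randomness flows through one explicitly threaded numpy generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np

from .catalog import CONTENT_TYPES, Catalog, ContentItem, default_stop_words, tag_content
from .evaluation import ConditionAssignment
from .recommender import (
    LikingStats,
    RecommenderConfig,
    ScoredItem,
    SoftDiceCache,
    eligible_candidates,
    fitness_proportionate_select,
    rank_by_liking,
    baseline_recommend,
    _popularity_fallback,
)
from .semnet import SemanticNetwork
from .session_log import EventLog, SessionEvent
from .text import StopWordList
from .user_model import (
    Biography,
    RatingEvent,
    UserProfile,
    init_profile,
    mark_used,
    update_profile,
)

__all__ = [
    "SimUser",
    "SimConfig",
    "generate_network",
    "generate_catalog",
    "generate_users",
    "largest_remainder_counts",
    "user_liking",
    "simulate_session",
    "run_ab_study",
    "StudyResult",
]


# ---------------------------------------------------------------------------
# configuration and users
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimUser:
    """A simulated tandem with a latent, concentrated topic affinity."""

    user_id: str
    true_affinity: "dict[str, float]"  # concept -> weight in [0, 1]
    type_preference: "dict[str, float]"  # content_type -> weight in (0, 1]
    biography_fidelity: float = 0.5
    rating_noise: float = 0.1
    acceptance_threshold: float = 0.25
    birth_date: date | None = None

    @property
    def affinity_support(self) -> frozenset[str]:
        return frozenset(c for c, w in self.true_affinity.items() if w > 0)


@dataclass
class SimConfig:
    """Study-scale and behavioural parameters of the simulator.

    Activation-count moments default to the field calibration (mean 5.9
    activations per session, SD 6.3, median 5); the catalog defaults give
    twelve topic clusters over seven content types in equal proportions.
    ``arms`` wires each A-B condition label to a recommender arm, so a null
    study can wire both conditions to "baseline".
    """

    n_users: int = 25
    n_sessions_per_user: int = 16
    catalog_size: int = 120
    n_clusters: int = 12
    concepts_per_cluster: int = 7
    tags_per_item: tuple = (3, 5)  # inclusive range
    personal_fraction: float = 0.1
    seasonal_fraction: float = 0.05
    type_proportions: "dict[str, float]" = field(
        default_factory=lambda: {t: 1.0 / len(CONTENT_TYPES) for t in CONTENT_TYPES}
    )
    activation_mean: float = 5.9
    activation_sd: float = 6.3
    reload_cap: int = 2
    duration_log_median: float = math.log(120.0)  # seconds
    duration_log_sigma: float = 0.6
    positive_cut: float = 0.5
    negative_cut: float = 0.2
    rating_noise: float = 0.1
    acceptance_threshold: float = 0.25
    biography_fidelity: float = 0.5
    start: datetime = field(default_factory=lambda: datetime(2024, 1, 8, 9, 0))
    arms: "dict[str, str]" = field(
        default_factory=lambda: {"baseline": "baseline", "personalized": "personalized"}
    )
    rng_seed: int = 0


def largest_remainder_counts(total: int, proportions: "dict[str, float]") -> "dict[str, int]":
    """Apportion ``total`` into integer counts matching the proportions.

    Hamilton's method: floor the exact quotas, then give the remaining
    units to the largest fractional remainders (ties by key order).
    """
    if total < 0:
        raise ValueError("total must be >= 0")
    norm = sum(proportions.values())
    keys = sorted(proportions)
    quotas = {k: total * proportions[k] / norm for k in keys}
    counts = {k: int(math.floor(quotas[k])) for k in keys}
    short = total - sum(counts.values())
    for k in sorted(keys, key=lambda k: (-(quotas[k] - counts[k]), k))[:short]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# synthetic network / catalog / users
# ---------------------------------------------------------------------------

def generate_network(
    n_clusters: int = 12, concepts_per_cluster: int = 7
) -> SemanticNetwork:
    """Deterministic clustered concept graph.

    Each topic cluster is a star around a hub; hubs form a ring connecting
    the clusters.  Members of the same cluster are thus at distance <= 2,
    members of adjacent clusters at distance >= 3, and members of remote
    clusters beyond the default similarity horizon.
    """
    concepts: list[str] = []
    edges: list[tuple[str, str]] = []
    surface: dict[str, list[str]] = {}
    hubs: list[str] = []
    for c in range(n_clusters):
        hub = f"c{c:02d}hub"
        hubs.append(hub)
        concepts.append(hub)
        surface[hub] = [hub]
        for j in range(concepts_per_cluster - 1):
            node = f"c{c:02d}n{j:02d}"
            concepts.append(node)
            surface[node] = [node]
            edges.append((hub, node))
    for i, hub in enumerate(hubs):
        edges.append((hub, hubs[(i + 1) % len(hubs)]))
    return SemanticNetwork(concepts, edges, surface)


def cluster_concepts(network: SemanticNetwork, n_clusters: int) -> "list[list[str]]":
    """Concept lists per cluster of a :func:`generate_network` graph."""
    out = []
    for c in range(n_clusters):
        prefix = f"c{c:02d}"
        out.append(sorted(n for n in network.concepts if n.startswith(prefix)))
    return out


_DESCRIPTION_TEMPLATES = [
    "a {type} about {words}",
    "memories of {words} and more",
    "the {type} shows {words}",
    "{words} from the old days",
]


def generate_catalog(
    config: SimConfig,
    network: SemanticNetwork,
    rng: np.random.Generator,
    stop_words: StopWordList | None = None,
) -> Catalog:
    """Synthesize a tagged catalog over the toy network.

    Content types follow the configured proportions via largest-remainder
    apportionment; each item's description is composed from the surface
    forms of concepts sampled within one topic cluster, then tagged through
    the ordinary description-tagging pipeline.
    """
    stop_words = stop_words or default_stop_words()
    clusters = cluster_concepts(network, config.n_clusters)
    type_counts = largest_remainder_counts(config.catalog_size, config.type_proportions)
    types: list[str] = [t for t in sorted(type_counts) for _ in range(type_counts[t])]
    lo, hi = config.tags_per_item
    items = []
    for i, ctype in enumerate(types):
        cluster = clusters[int(rng.integers(len(clusters)))]
        n_tags = int(rng.integers(lo, hi + 1))
        words = [str(w) for w in rng.choice(cluster, size=min(n_tags, len(cluster)), replace=False)]
        template = _DESCRIPTION_TEMPLATES[int(rng.integers(len(_DESCRIPTION_TEMPLATES)))]
        description = template.format(type=ctype, words=" and ".join(words))
        provenance = "personal" if rng.random() < config.personal_fraction else "general"
        event_tags = (
            frozenset([str(rng.choice(["christmas", "birthday"]))])
            if rng.random() < config.seasonal_fraction
            else frozenset()
        )
        item = ContentItem(
            item_id=f"item{i:04d}",
            content_type=ctype,
            title=f"{ctype} {i:04d}",
            description=description,
            provenance=provenance,
            event_tags=event_tags,
        )
        items.append(tag_content(item, network, stop_words))
    return Catalog(items)


def generate_users(
    config: SimConfig, network: SemanticNetwork, rng: np.random.Generator
) -> "list[SimUser]":
    """Users with affinity concentrated on one cluster each.

    The biography exposes a ``biography_fidelity`` fraction of the true
    affinity support; type preferences are drawn uniformly from [0.6, 1.0].
    """
    clusters = cluster_concepts(network, config.n_clusters)
    users = []
    for u in range(config.n_users):
        cluster = clusters[int(rng.integers(len(clusters)))]
        affinity = {c: 1.0 for c in cluster}
        prefs = {t: float(rng.uniform(0.4, 1.0)) for t in CONTENT_TYPES}
        birth = date(1940, 1, 1) + timedelta(days=int(rng.integers(0, 365 * 15)))
        users.append(
            SimUser(
                user_id=f"user{u:02d}",
                true_affinity=affinity,
                type_preference=prefs,
                biography_fidelity=config.biography_fidelity,
                rating_noise=config.rating_noise,
                acceptance_threshold=config.acceptance_threshold,
                birth_date=birth,
            )
        )
    return users


def make_biography(
    user: SimUser, rng: np.random.Generator
) -> Biography:
    """Expose a random ``biography_fidelity`` fraction of the affinity."""
    support = sorted(user.affinity_support)
    n_bio = max(1, int(round(user.biography_fidelity * len(support))))
    bio = [str(c) for c in rng.choice(support, size=min(n_bio, len(support)), replace=False)]
    return Biography(
        user_id=user.user_id, bio_tags=frozenset(bio), birth_date=user.birth_date
    )


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def draw_activation_count(
    rng: np.random.Generator, mean: float = 5.9, sd: float = 6.3
) -> int:
    """Shifted negative-binomial activation count, support >= 1.

    The count is 1 + NB(r, p) with r and p chosen so that the *shifted*
    variate has exactly the configured mean and SD.  The shift implements
    the >= 1 truncation without inflating the calibrated mean.
    """
    mu = mean - 1.0
    var = sd * sd
    if var <= mu:
        raise ValueError("requires overdispersion: sd^2 > mean - 1")
    r = mu * mu / (var - mu)
    p = r / (r + mu)
    return 1 + int(rng.negative_binomial(r, p))


def user_liking(
    user: SimUser,
    item: ContentItem,
    network: SemanticNetwork,
    sim_fn=None,
    d_max: int = 4,
) -> float:
    """Internal liking: affinity soft-Dice weighted by type preference."""
    if sim_fn is None:
        from .recommender import soft_dice

        sim_fn = lambda a, b: soft_dice(a, b, network, d_max)  # noqa: E731
    return sim_fn(item.tags, user.affinity_support) * user.type_preference[item.content_type]


def _smiley_for(liking: float, config: SimConfig, rng: np.random.Generator) -> str:
    if liking >= config.positive_cut:
        smiley = "positive"
    elif liking < config.negative_cut:
        smiley = "negative"
    else:
        smiley = "neutral"
    if rng.random() < config.rating_noise:
        others = [s for s in ("negative", "neutral", "positive") if s != smiley]
        smiley = str(rng.choice(others))
    return smiley


class _Clock:
    def __init__(self, start: datetime) -> None:
        self.t = start

    def tick(self, seconds: float = 1.0) -> datetime:
        self.t += timedelta(seconds=seconds)
        return self.t


def simulate_session(
    user: SimUser,
    arm: str,
    catalog: Catalog,
    network: SemanticNetwork,
    profile: UserProfile,
    biography: Biography,
    liking_stats: LikingStats,
    rec_config: RecommenderConfig,
    sim_config: SimConfig,
    now: datetime,
    rng: np.random.Generator,
    session_id: str,
    condition: str | None = None,
    sim_cache: SoftDiceCache | None = None,
    liking_map: "dict[str, float] | None" = None,
) -> tuple["list[SessionEvent]", UserProfile]:
    """Simulate one tandem session and return its events and the profile.

    ``arm`` is "personalized" (threshold/recency filtered, liking-ranked,
    fitness-proportionate slates from the blended Dice score) or "baseline"
    (popularity-weighted random slates).  Reloads re-draw a slate from the
    remaining candidates; after ``reload_cap`` unsuccessful slates the user
    searches directly for their best available item.
    """
    if arm not in ("personalized", "baseline"):
        raise ValueError(f"unknown arm: {arm!r}")
    condition = condition or arm
    if sim_cache is None:
        sim_cache = SoftDiceCache(network, rec_config.d_max)
    if liking_map is None:
        liking_map = {
            it.item_id: user_liking(user, it, network, sim_cache) for it in catalog
        }
    clock = _Clock(now)
    events: list[SessionEvent] = []

    def emit(event_type: str, payload: dict | None = None, dt: float = 1.0) -> None:
        events.append(
            SessionEvent(
                timestamp=clock.tick(dt),
                session_id=session_id,
                user_id=user.user_id,
                event_type=event_type,
                payload=payload or {},
            )
        )

    emit("session_start", {"condition": condition})
    emit("daily_condition", {"level": int(rng.integers(1, 6))})

    n_activations = draw_activation_count(
        rng, sim_config.activation_mean, sim_config.activation_sd
    )
    for _ in range(n_activations):
        shown: set[str] = set()
        chosen_id: str | None = None
        source = "search"

        if arm == "personalized":
            candidates = eligible_candidates(
                catalog, profile, biography, liking_stats, network,
                rec_config, clock.t, sim_cache,
            )
        for attempt in range(sim_config.reload_cap + 1):
            if arm == "personalized":
                remaining = [c for c in candidates if c.item_id not in shown]
                if remaining:
                    slate = fitness_proportionate_select(
                        remaining, rec_config.slate_size, rng, rec_config.selection_mode
                    )
                else:
                    slate = _popularity_fallback(
                        catalog, profile, biography, liking_stats, rec_config,
                        clock.t, frozenset(shown),
                    )
            else:
                slate = baseline_recommend(
                    catalog, liking_stats, rec_config, rng,
                    now=clock.t, profile=profile, exclude_items=shown,
                )
            emit(
                "recommendation_shown",
                {"item_ids": [s.item_id for s in slate], "condition": condition},
            )
            if slate:
                best = max(slate, key=lambda s: (liking_map[s.item_id], s.item_id))
                if liking_map[best.item_id] >= user.acceptance_threshold:
                    chosen_id = best.item_id
                    source = "recommendation"
                    break
            shown.update(s.item_id for s in slate)
            if attempt < sim_config.reload_cap:
                emit("reload", {})
        if chosen_id is None:
            # direct search: best-liked item outside the recency window
            ranked = sorted(
                liking_map, key=lambda i: (-liking_map[i], i)
            )
            for item_id in ranked:
                last = profile.per_item_last_use.get(item_id)
                if last is None or (clock.t - last) >= timedelta(
                    hours=rec_config.recency_hours
                ):
                    chosen_id = item_id
                    break
            else:
                chosen_id = ranked[0]
            source = "search"

        item = catalog[chosen_id]
        emit("content_selected", {"item_id": chosen_id, "source": source})
        emit(
            "content_start",
            {
                "item_id": chosen_id,
                "content_type": item.content_type,
                "provenance": item.provenance,
            },
        )
        profile = mark_used(profile, chosen_id, clock.t)
        duration = float(
            rng.lognormal(sim_config.duration_log_median, sim_config.duration_log_sigma)
        )
        emit("content_end", {"item_id": chosen_id}, dt=duration)
        smiley = _smiley_for(liking_map[chosen_id], sim_config, rng)
        rating = RatingEvent(
            user_id=user.user_id,
            item_id=chosen_id,
            timestamp=clock.tick(2.0),
            smiley=smiley,
        )
        events.append(
            SessionEvent(
                timestamp=rating.timestamp,
                session_id=session_id,
                user_id=user.user_id,
                event_type="rating",
                payload={
                    "item_id": chosen_id,
                    "smiley": smiley,
                    "normalized_value": rating.normalized_value,
                },
            )
        )
        profile = update_profile(profile, rating, item)
        liking_stats.add_rating(chosen_id, rating.normalized_value)

    emit("session_end", {})
    return events, profile


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    log: EventLog
    assignment: ConditionAssignment
    catalog: Catalog
    network: SemanticNetwork
    users: "list[SimUser]"
    biographies: "dict[str, Biography]"
    profiles: "dict[str, UserProfile]"


def run_ab_study(
    config: SimConfig, rec_config: RecommenderConfig | None = None
) -> StudyResult:
    """Run a full multi-user A-B study and return its artefacts.

    Each session is assigned 50/50 to the "baseline" or "personalized"
    condition at session start; ``config.arms`` maps the condition label to
    the recommender arm actually serving it (wiring both to "baseline"
    yields a null study).  Profiles and the global liking statistics evolve
    across all sessions regardless of condition.  Fully determined by
    ``config.rng_seed``.
    """
    rec_config = rec_config or RecommenderConfig()
    master = np.random.default_rng(config.rng_seed)
    net_rng, cat_rng, user_rng, assign_seed, sess_seed = (
        master.spawn(5)
    )
    network = generate_network(config.n_clusters, config.concepts_per_cluster)
    catalog = generate_catalog(config, network, cat_rng)
    users = generate_users(config, network, user_rng)
    assignment = ConditionAssignment(
        seed=int(assign_seed.integers(0, 2**31 - 1))
    )
    sess_rng = np.random.default_rng(sess_seed.integers(0, 2**31 - 1))

    sim_cache = SoftDiceCache(network, rec_config.d_max)
    biographies = {u.user_id: make_biography(u, user_rng) for u in users}
    profiles = {
        u.user_id: init_profile(biographies[u.user_id], network) for u in users
    }
    liking_maps = {
        u.user_id: {
            it.item_id: user_liking(u, it, network, sim_cache) for it in catalog
        }
        for u in users
    }
    liking_stats = LikingStats(rec_config.liking_prior, rec_config.liking_prior_weight)

    log = EventLog()
    for s in range(config.n_sessions_per_user):
        day = config.start + timedelta(days=s)
        for ui, user in enumerate(users):
            session_id = f"{user.user_id}-s{s:03d}"
            condition = assignment.assign(session_id)
            arm = config.arms[condition]
            now = day + timedelta(minutes=18 * ui)
            events, profiles[user.user_id] = simulate_session(
                user, arm, catalog, network,
                profiles[user.user_id], biographies[user.user_id],
                liking_stats, rec_config, config, now, sess_rng,
                session_id, condition=condition,
                sim_cache=sim_cache, liking_map=liking_maps[user.user_id],
            )
            for e in events:
                log.append(e)
    log.sort()
    return StudyResult(
        log=log,
        assignment=assignment,
        catalog=catalog,
        network=network,
        users=users,
        biographies=biographies,
        profiles=profiles,
    )
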