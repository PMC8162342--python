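import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tandemrec import (
    Biography,
    Catalog,
    ContentItem,
    LikingStats,
    RecommenderConfig,
    SemanticNetwork,
    StopWordList,
    UserProfile,
    default_network,
    default_stop_words,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def network() -> SemanticNetwork:
    """Packaged toy concept network (themed everyday-life clusters)."""
    return default_network()


@pytest.fixture(scope="session")
def stop_words() -> StopWordList:
    return default_stop_words()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_network() -> SemanticNetwork:
    """Five concepts: a-b-c path, d isolated, e adjacent to a."""
    return SemanticNetwork(
        concepts=["a", "b", "c", "d", "e"],
        edges=[("a", "b"), ("b", "c"), ("a", "e")],
        surface_forms={c: [c] for c in "abcde"},
    )


def make_item(item_id, ctype="image", tags=(), **kw) -> ContentItem:
    return ContentItem(item_id=item_id, content_type=ctype, tags=frozenset(tags), **kw)


@pytest.fixture()
def garden_catalog(network) -> Catalog:
    """Small hand-built catalog over the packaged network."""
    return Catalog(
        [
            make_item("g1", "image", {"garden", "flower", "rose"}),
            make_item("g2", "video", {"garden", "tree"}),
            make_item("m1", "audio", {"music", "song", "choir"}),
            make_item("m2", "video", {"piano", "melody"}),
            make_item("k1", "quiz", {"cooking", "bread", "cake"}),
            make_item("t1", "story", {"travel", "mountain"}),
            make_item("x1", "image", {"christmas", "family"}, event_tags={"christmas"}),
            make_item("p1", "image", {"home", "child"}, provenance="personal"),
        ]
    )


@pytest.fixture()
def fresh_profile() -> UserProfile:
    return UserProfile(user_id="u1")


@pytest.fixture()
def garden_bio() -> Biography:
    return Biography(user_id="u1", bio_tags=frozenset({"garden", "flower"}))


@pytest.fixture()
def config() -> RecommenderConfig:
    return RecommenderConfig(rng_seed=7)


@pytest.fixture()
def liking() -> LikingStats:
    return LikingStats()
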