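"""Activation-content catalog and semantic tagging.

Each content item carries a free-text description entered by a catalog
maintainer.  Tagging lowercases and tokenises the description, removes stop
words, stems the remaining tokens and maps each stem to a concept of the
semantic network; unresolvable stems are dropped.  The resulting concept
set T_i is what the recommender scores against user profiles.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .semnet import SemanticNetwork
from .text import StopWordList, tokenize_and_stem

__all__ = [
    "CONTENT_TYPES",
    "PROVENANCES",
    "ContentItem",
    "Catalog",
    "map_to_concepts",
    "tag_content",
    "default_stop_words",
    "default_network",
]

logger = logging.getLogger(__name__)

#: The seven activation-content categories.
CONTENT_TYPES = ("video", "quiz", "game", "story", "image", "audio", "phrase")

#: Content provenance: general library, cohort-specific, or personal uploads.
PROVENANCES = ("general", "cohort", "personal")


@dataclass(frozen=True)
class ContentItem:
    """One activation content unit."""

    item_id: str
    content_type: str
    title: str = ""
    description: str = ""
    tags: frozenset[str] = field(default_factory=frozenset)
    provenance: str = "general"
    event_tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.content_type not in CONTENT_TYPES:
            raise ValueError(
                f"content_type {self.content_type!r} not in {CONTENT_TYPES}"
            )
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance {self.provenance!r} not in {PROVENANCES}")
        object.__setattr__(self, "tags", frozenset(self.tags))
        object.__setattr__(self, "event_tags", frozenset(self.event_tags))


class Catalog:
    """Ordered collection of :class:`ContentItem` with unique ids."""

    def __init__(self, items: Iterable[ContentItem] = ()) -> None:
        self._items: dict[str, ContentItem] = {}
        for item in items:
            self.add(item)

    def add(self, item: ContentItem) -> None:
        if item.item_id in self._items:
            raise ValueError(f"duplicate item_id: {item.item_id!r}")
        self._items[item.item_id] = item

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items.values())

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._items

    def __getitem__(self, item_id: str) -> ContentItem:
        return self._items[item_id]

    @property
    def items(self) -> list[ContentItem]:
        return list(self._items.values())

    def tag_all(
        self, network: SemanticNetwork, stop_words: StopWordList
    ) -> "Catalog":
        """Return a new catalog with every item (re-)tagged."""
        return Catalog(tag_content(it, network, stop_words) for it in self)

    # -- I/O -----------------------------------------------------------------

    _COLUMNS = ["item_id", "content_type", "title", "description", "provenance", "event_tags"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "item_id": it.item_id,
                "content_type": it.content_type,
                "title": it.title,
                "description": it.description,
                "provenance": it.provenance,
                "event_tags": ";".join(sorted(it.event_tags)),
                "tags": ";".join(sorted(it.tags)),
            }
            for it in self
        ]
        return pd.DataFrame(rows, columns=self._COLUMNS + ["tags"])

    def save(self, path: str | Path) -> None:
        """Write CSV (``.csv``) or JSON Lines (anything else)."""
        path = Path(path)
        frame = self.to_frame()
        if path.suffix == ".csv":
            frame.to_csv(path, index=False)
        else:
            with path.open("w", encoding="utf-8") as fh:
                for row in frame.to_dict("records"):
                    fh.write(json.dumps(row, ensure_ascii=False) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Catalog":
        path = Path(path)
        if path.suffix == ".csv":
            frame = pd.read_csv(path, keep_default_na=False)
            records = frame.to_dict("records")
        else:
            records = [
                json.loads(line)
                for line in path.read_text(encoding="utf-8").splitlines()
                if line.strip()
            ]
        items = []
        for rec in records:
            items.append(
                ContentItem(
                    item_id=str(rec["item_id"]),
                    content_type=rec["content_type"],
                    title=rec.get("title", "") or "",
                    description=rec.get("description", "") or "",
                    provenance=rec.get("provenance", "general") or "general",
                    event_tags=frozenset(
                        t for t in str(rec.get("event_tags", "") or "").split(";") if t
                    ),
                    tags=frozenset(
                        t for t in str(rec.get("tags", "") or "").split(";") if t
                    ),
                )
            )
        return cls(items)


def map_to_concepts(stems: Sequence[str], network: SemanticNetwork) -> set[str]:
    """Resolve word stems to network concepts; drop what does not resolve.

    The result is a deduplicated set.  Each unresolved stem is logged at
    warning level, never raised: descriptions legitimately contain words
    outside the concept graph.
    """
    out: set[str] = set()
    for stem in stems:
        concept = network.resolve(stem)
        if concept is None:
            logger.warning("unresolved stem dropped during tagging: %r", stem)
        else:
            out.add(concept)
    return out


def tag_content(
    item: ContentItem, network: SemanticNetwork, stop_words: StopWordList
) -> ContentItem:
    """Derive an item's tag set from its description.

    Deterministic and idempotent for a fixed network and stop-word list;
    any pre-existing tags are replaced.
    """
    stems = tokenize_and_stem(item.description, stop_words)
    return replace(item, tags=frozenset(map_to_concepts(stems, network)))


_DATA_DIR = Path(__file__).parent / "data"


def default_stop_words() -> StopWordList:
    """Small packaged English stop-word list."""
    return StopWordList.load(_DATA_DIR / "stopwords_en.txt")


def default_network() -> SemanticNetwork:
    """Packaged toy concept network (themed clusters of everyday concepts)."""
    return SemanticNetwork.load(_DATA_DIR)
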