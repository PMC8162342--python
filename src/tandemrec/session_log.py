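"""Session event logs and usage analytics.

Tablet interactions are recorded as timestamped events — session start and
end, daily-condition queries, recommendation slates, reloads, content
selection, playback start/end, and ratings — one JSON object per line.
Analytics aggregate the log into per-session summaries (activation counts,
per-type durations, type-diversity entropy S = -sum_i P_i log P_i with P_i
the relative duration share of content type i, personalization share, mean
rating) and into study-level tables across users and weeks.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .catalog import CONTENT_TYPES, Catalog

__all__ = [
    "EVENT_TYPES",
    "SCHEMA_VERSION",
    "SessionEvent",
    "EventLog",
    "LogError",
    "SessionSummary",
    "read_log",
    "write_log",
    "summarize_session",
    "type_entropy",
    "aggregate_study",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

EVENT_TYPES = (
    "session_start",
    "session_end",
    "daily_condition",
    "recommendation_shown",
    "reload",
    "content_selected",
    "content_start",
    "content_end",
    "rating",
)


@dataclass(frozen=True)
class SessionEvent:
    """One timestamped interaction event.

    ``payload`` keys are fixed per event type, e.g. ``content_selected``
    carries ``item_id`` and ``source`` ("recommendation" or "search"),
    ``recommendation_shown`` carries the slate's ``item_ids`` and the
    ``condition`` label, ``daily_condition`` an ordinal ``level``.
    """

    timestamp: datetime
    session_id: str
    user_id: str
    event_type: str
    device_id: str = ""
    payload: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type: {self.event_type!r}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "timestamp": self.timestamp.isoformat(),
                "session_id": self.session_id,
                "user_id": self.user_id,
                "device_id": self.device_id,
                "event_type": self.event_type,
                "payload": dict(self.payload),
            },
            ensure_ascii=False,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "SessionEvent":
        data = json.loads(line)
        return cls(
            timestamp=datetime.fromisoformat(data["timestamp"]),
            session_id=data["session_id"],
            user_id=data["user_id"],
            device_id=data.get("device_id", ""),
            event_type=data["event_type"],
            payload=data.get("payload", {}),
        )


@dataclass(frozen=True)
class LogError:
    """A malformed log line, preserved instead of silently dropped."""

    line_number: int
    line: str
    message: str


class EventLog:
    """Events sorted by timestamp, grouped on demand by session or user."""

    def __init__(self, events: Iterable[SessionEvent] = ()) -> None:
        self.events: list[SessionEvent] = sorted(events, key=lambda e: e.timestamp)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def append(self, event: SessionEvent) -> None:
        self.events.append(event)

    def sort(self) -> None:
        self.events.sort(key=lambda e: e.timestamp)

    def sessions(self) -> "dict[str, list[SessionEvent]]":
        out: dict[str, list[SessionEvent]] = {}
        for e in self.events:
            out.setdefault(e.session_id, []).append(e)
        return out

    def users(self) -> "dict[str, list[SessionEvent]]":
        out: dict[str, list[SessionEvent]] = {}
        for e in self.events:
            out.setdefault(e.user_id, []).append(e)
        return out


def write_log(log: EventLog, path: str | Path) -> None:
    """JSON Lines with a version header line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(json.dumps({"schema": "tandemrec-log", "version": SCHEMA_VERSION}) + "\n")
        for event in log:
            fh.write(event.to_json() + "\n")


def read_log(path: str | Path) -> tuple[EventLog, list[LogError]]:
    """Parse a JSONL event log; malformed lines become error records.

    Events come back sorted by timestamp.  The header line (an object with
    a ``schema`` key) is accepted and skipped; logs without a header parse
    too.
    """
    events: list[SessionEvent] = []
    errors: list[LogError] = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        try:
            data = json.loads(line)
        except json.JSONDecodeError as exc:
            errors.append(LogError(i, line, f"invalid JSON: {exc}"))
            continue
        if isinstance(data, dict) and "schema" in data:
            continue  # header
        try:
            events.append(SessionEvent.from_json(line))
        except (KeyError, ValueError) as exc:
            errors.append(LogError(i, line, str(exc)))
    return EventLog(events), errors


# ---------------------------------------------------------------------------
# analytics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionSummary:
    session_id: str
    user_id: str
    start: datetime | None
    n_activations: int
    type_durations: "dict[str, float]"  # content_type -> seconds
    entropy: float
    personalized_share: float
    mean_rating: float | None
    condition: str | None = None


def type_entropy(
    durations: Mapping[str, float], log_base: float = math.e
) -> float:
    """Diversity entropy of a session's content-type mix.

    ``S = -sum_i P_i log(P_i)`` with P_i = duration_i / total.  Types with
    zero duration contribute nothing; a single present type gives S = 0.
    All-zero (or empty) durations are an error.
    """
    total = float(sum(durations.values()))
    if total <= 0:
        raise ValueError("type_entropy requires at least one positive duration")
    s = 0.0
    for d in durations.values():
        if d < 0:
            raise ValueError("durations must be >= 0")
        if d > 0:
            p = d / total
            s -= p * math.log(p)
    return s / math.log(log_base)


def _provenance_of(event: SessionEvent, catalog: Catalog | None) -> str:
    prov = event.payload.get("provenance")
    if prov:
        return prov
    if catalog is not None:
        item_id = event.payload.get("item_id")
        if item_id in catalog:
            return catalog[item_id].provenance
    return "general"


def summarize_session(
    events: "list[SessionEvent]",
    catalog: Catalog | None = None,
    log_base: float = math.e,
) -> SessionSummary:
    """Aggregate the events of one session.

    Durations come from content_start/content_end pairs matched by item id;
    an unpaired content_start runs until session end (with a warning).
    Entropy is 0 by convention when the session has no activations.
    """
    if not events:
        raise ValueError("summarize_session needs at least one event")
    session_id = events[0].session_id
    user_id = events[0].user_id
    events = sorted(events, key=lambda e: e.timestamp)
    start = next((e.timestamp for e in events if e.event_type == "session_start"), None)
    end = next(
        (e.timestamp for e in reversed(events) if e.event_type == "session_end"),
        events[-1].timestamp,
    )
    condition = next(
        (e.payload.get("condition") for e in events if e.event_type == "session_start"),
        None,
    )

    open_starts: dict[str, SessionEvent] = {}
    type_durations: dict[str, float] = {}
    personal_seconds = 0.0
    total_seconds = 0.0
    n_activations = 0
    ratings: list[float] = []

    def _close(ev: SessionEvent, until: datetime) -> None:
        nonlocal personal_seconds, total_seconds
        seconds = max(0.0, (until - ev.timestamp).total_seconds())
        ctype = ev.payload.get("content_type", "video")
        type_durations[ctype] = type_durations.get(ctype, 0.0) + seconds
        total_seconds += seconds
        if _provenance_of(ev, catalog) == "personal":
            personal_seconds += seconds

    for e in events:
        if e.event_type == "content_start":
            n_activations += 1
            open_starts[e.payload.get("item_id", "")] = e
        elif e.event_type == "content_end":
            started = open_starts.pop(e.payload.get("item_id", ""), None)
            if started is not None:
                _close(started, e.timestamp)
        elif e.event_type == "rating":
            value = e.payload.get("normalized_value")
            if value is not None:
                ratings.append(float(value))
    for item_id, started in open_starts.items():
        logger.warning(
            "unpaired content_start for %r in session %s; counting to session end",
            item_id, session_id,
        )
        _close(started, end)

    entropy = type_entropy(type_durations, log_base) if total_seconds > 0 else 0.0
    share = personal_seconds / total_seconds if total_seconds > 0 else 0.0
    return SessionSummary(
        session_id=session_id,
        user_id=user_id,
        start=start,
        n_activations=n_activations,
        type_durations=type_durations,
        entropy=entropy,
        personalized_share=share,
        mean_rating=float(np.mean(ratings)) if ratings else None,
        condition=condition,
    )


def aggregate_study(
    log: EventLog,
    catalog: Catalog | None = None,
    log_base: float = math.e,
) -> "dict[str, pd.DataFrame]":
    """Study-level tables across all users and sessions.

    Returns a dict of DataFrames:

    ``type_durations``  total activation seconds per content type;
    ``session_summaries``  one row per session (activations, entropy,
    personalization share, mean rating, condition);
    ``entropy_series``  per-user session-ordered entropy time series;
    ``personalization_by_week``  duration-weighted personal-content share
    per study week (weeks counted from the first session);
    ``rating_histogram``  smiley counts per content type and provenance.
    """
    summaries = [
        summarize_session(evts, catalog, log_base) for evts in log.sessions().values()
    ]
    summaries.sort(key=lambda s: (s.start or datetime.min, s.session_id))

    totals = {t: 0.0 for t in CONTENT_TYPES}
    for s in summaries:
        for t, d in s.type_durations.items():
            totals[t] = totals.get(t, 0.0) + d
    type_durations = pd.DataFrame(
        {"content_type": list(totals), "total_seconds": list(totals.values())}
    )

    session_summaries = pd.DataFrame(
        [
            {
                "session_id": s.session_id,
                "user_id": s.user_id,
                "start": s.start,
                "n_activations": s.n_activations,
                "entropy": s.entropy,
                "personalized_share": s.personalized_share,
                "mean_rating": s.mean_rating,
                "condition": s.condition,
                "total_seconds": sum(s.type_durations.values()),
            }
            for s in summaries
        ]
    )

    entropy_rows = []
    for user_id, group in session_summaries.groupby("user_id"):
        for i, (_, row) in enumerate(group.sort_values("start").iterrows(), 1):
            entropy_rows.append(
                {"user_id": user_id, "session_index": i, "entropy": row["entropy"]}
            )
    entropy_series = pd.DataFrame(entropy_rows)

    week_rows = []
    if summaries and any(s.start for s in summaries):
        t0 = min(s.start for s in summaries if s.start)
        by_week: dict[int, list[SessionSummary]] = {}
        for s in summaries:
            if s.start is None:
                continue
            by_week.setdefault((s.start - t0).days // 7, []).append(s)
        for week in sorted(by_week):
            sess = by_week[week]
            tot = sum(sum(s.type_durations.values()) for s in sess)
            pers = sum(
                s.personalized_share * sum(s.type_durations.values()) for s in sess
            )
            week_rows.append(
                {
                    "week": week,
                    "personalized_share": pers / tot if tot > 0 else 0.0,
                    "n_sessions": len(sess),
                }
            )
    personalization_by_week = pd.DataFrame(week_rows)

    hist_rows: dict[tuple[str, str, str], int] = {}
    started: dict[tuple[str, str], SessionEvent] = {}
    for e in log:
        if e.event_type == "content_start":
            started[(e.session_id, e.payload.get("item_id", ""))] = e
        elif e.event_type == "rating":
            smiley = e.payload.get("smiley")
            if smiley is None:
                continue
            start_ev = started.get((e.session_id, e.payload.get("item_id", "")))
            ctype = start_ev.payload.get("content_type", "video") if start_ev else "video"
            prov = _provenance_of(start_ev or e, catalog)
            key = (ctype, prov, smiley)
            hist_rows[key] = hist_rows.get(key, 0) + 1
    rating_histogram = pd.DataFrame(
        [
            {"content_type": c, "provenance": p, "smiley": s, "count": n}
            for (c, p, s), n in sorted(hist_rows.items())
        ],
        columns=["content_type", "provenance", "smiley", "count"],
    )

    return {
        "type_durations": type_durations,
        "session_summaries": session_summaries,
        "entropy_series": entropy_series,
        "personalization_by_week": personalization_by_week,
        "rating_histogram": rating_histogram,
    }
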