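"""Event-log round-trips and session/study analytics."""

import math
from datetime import datetime, timedelta

import numpy as np
import pytest

from tandemrec import (
    EventLog,
    SessionEvent,
    aggregate_study,
    read_log,
    summarize_session,
    type_entropy,
    write_log,
)

T0 = datetime(2024, 4, 1, 10, 0)


def ev(event_type, seconds, session="s1", user="u1", **payload):
    return SessionEvent(
        timestamp=T0 + timedelta(seconds=seconds),
        session_id=session,
        user_id=user,
        event_type=event_type,
        payload=payload,
    )


def two_activation_session(session="s1", user="u1"):
    return [
        ev("session_start", 0, session, user, condition="personalized"),
        ev("daily_condition", 1, session, user, level=3),
        ev("content_selected", 5, session, user, item_id="v1", source="recommendation"),
        ev("content_start", 6, session, user, item_id="v1", content_type="video",
           provenance="general"),
        ev("content_end", 66, session, user, item_id="v1"),
        ev("rating", 68, session, user, item_id="v1", smiley="positive",
           normalized_value=1.0),
        ev("content_selected", 70, session, user, item_id="q1", source="search"),
        ev("content_start", 71, session, user, item_id="q1", content_type="quiz",
           provenance="personal"),
        ev("content_end", 131, session, user, item_id="q1"),
        ev("rating", 133, session, user, item_id="q1", smiley="neutral",
           normalized_value=0.5),
        ev("session_end", 140, session, user),
    ]


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        log = EventLog(two_activation_session())
        write_log(log, tmp_path / "log.jsonl")
        loaded, errors = read_log(tmp_path / "log.jsonl")
        assert errors == []
        assert [e.to_json() for e in loaded] == [e.to_json() for e in log]

    def test_malformed_line_becomes_error_record(self, tmp_path):
        log = EventLog(two_activation_session())
        write_log(log, tmp_path / "log.jsonl")
        with (tmp_path / "log.jsonl").open("a") as fh:
            fh.write("{not json\n")
            fh.write('{"timestamp": "2024-04-01T10:00:00", "session_id": "s", '
                     '"user_id": "u", "event_type": "teleport", "payload": {}}\n')
        loaded, errors = read_log(tmp_path / "log.jsonl")
        assert len(loaded) == len(log)
        assert len(errors) == 2

    def test_empty_file_gives_empty_log(self, tmp_path):
        (tmp_path / "log.jsonl").write_text("")
        loaded, errors = read_log(tmp_path / "log.jsonl")
        assert len(loaded) == 0 and errors == []

    def test_events_sorted_on_read(self, tmp_path):
        events = two_activation_session()
        shuffled = EventLog(events)
        shuffled.events = list(reversed(shuffled.events))
        with (tmp_path / "log.jsonl").open("w") as fh:
            for e in shuffled.events:
                fh.write(e.to_json() + "\n")
        loaded, _ = read_log(tmp_path / "log.jsonl")
        times = [e.timestamp for e in loaded]
        assert times == sorted(times)


class TestEntropy:
    def test_single_type_is_zero(self):
        assert type_entropy({"video": 300.0}) == 0.0

    def test_uniform_seven_types_is_ln7(self):
        durations = {t: 60.0 for t in
                     ("video", "quiz", "game", "story", "image", "audio", "phrase")}
        assert type_entropy(durations) == pytest.approx(math.log(7))

    def test_three_to_one_split(self):
        got = type_entropy({"video": 180.0, "quiz": 60.0})
        expected = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.5623, abs=1e-4)

    def test_zero_duration_types_do_not_change_entropy(self):
        base = type_entropy({"video": 100.0, "quiz": 50.0})
        assert type_entropy({"video": 100.0, "quiz": 50.0, "game": 0.0}) == base

    def test_configurable_log_base(self):
        assert type_entropy({"a": 1.0, "b": 1.0}, log_base=2) == pytest.approx(1.0)

    def test_all_zero_durations_error(self):
        with pytest.raises(ValueError):
            type_entropy({"video": 0.0})

    def test_uniform_maximises_entropy(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            k = int(rng.integers(2, 8))
            d = {f"t{i}": float(rng.uniform(0.1, 10)) for i in range(k)}
            assert type_entropy(d) <= math.log(k) + 1e-12


class TestSummarize:
    def test_per_type_durations(self):
        s = summarize_session(two_activation_session())
        assert s.type_durations == {"video": 60.0, "quiz": 60.0}
        assert s.n_activations == 2
        assert s.mean_rating == pytest.approx(0.75)
        assert s.entropy == pytest.approx(math.log(2))
        assert s.personalized_share == pytest.approx(0.5)
        assert s.condition == "personalized"

    def test_no_activations_zero_summary(self):
        events = [ev("session_start", 0), ev("session_end", 10)]
        s = summarize_session(events)
        assert s.n_activations == 0
        assert s.entropy == 0.0
        assert s.mean_rating is None

    def test_unpaired_start_counts_to_session_end(self):
        events = [
            ev("session_start", 0),
            ev("content_start", 10, item_id="v1", content_type="video"),
            ev("session_end", 100),
        ]
        s = summarize_session(events)
        assert s.type_durations == {"video": 90.0}

    def test_durations_sum_to_total(self):
        s = summarize_session(two_activation_session())
        assert sum(s.type_durations.values()) == pytest.approx(120.0)


class TestAggregate:
    def _log(self):
        events = two_activation_session("s1", "u1")
        events += two_activation_session("s2", "u2")
        return EventLog(events)

    def test_totals_equal_hand_sums(self):
        tables = aggregate_study(self._log())
        td = tables["type_durations"].set_index("content_type")["total_seconds"]
        assert td["video"] == pytest.approx(120.0)
        assert td["quiz"] == pytest.approx(120.0)
        assert td["game"] == 0.0

    def test_all_general_content_gives_zero_share(self):
        events = [
            ev("session_start", 0),
            ev("content_start", 1, item_id="v1", content_type="video",
               provenance="general"),
            ev("content_end", 61, item_id="v1"),
            ev("session_end", 70),
        ]
        tables = aggregate_study(EventLog(events))
        assert tables["session_summaries"]["personalized_share"].eq(0.0).all()

    def test_all_positive_ratings_concentrate_histogram(self):
        tables = aggregate_study(self._log())
        hist = tables["rating_histogram"]
        assert set(hist["smiley"]) == {"positive", "neutral"}
        pos = hist[hist["smiley"] == "positive"]["count"].sum()
        assert pos == 2

    def test_entropy_series_per_user(self):
        tables = aggregate_study(self._log())
        series = tables["entropy_series"]
        assert set(series["user_id"]) == {"u1", "u2"}
        assert (series["session_index"] == 1).all()
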