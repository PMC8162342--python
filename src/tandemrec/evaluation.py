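"""A-B evaluation protocol for the recommender.

Sessions are randomly assigned (50/50, decided once at session start) to a
``personalized`` or ``baseline`` condition.  Three metrics compare the
conditions per participant:

* selection rate — fraction of content selections taken from the
  recommendation slate rather than direct search (higher is better);
* reloads per activation — slate reloads divided by started activations
  (lower is better);
* mean rating of recommended content — average normalised smiley rating of
  items that were selected from recommendations (higher is better).

Per-participant values are unweighted means over that participant's
sessions in each condition; conditions are then compared with a one-sided
paired t-test across participants, directed at the personalized condition
being better.  No multiple-testing correction is applied across the three
metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .session_log import EventLog

__all__ = [
    "CONDITIONS",
    "METRICS",
    "ConditionAssignment",
    "MetricTest",
    "ABResult",
    "assign_condition",
    "compute_metrics",
]

CONDITIONS = ("baseline", "personalized")

#: metric name -> direction in which the personalized condition should win
METRICS = {
    "selection_rate": "greater",
    "reloads_per_activation": "less",
    "mean_rating": "greater",
}


class ConditionAssignment:
    """Immutable per-session condition lookup, reproducible under a seed.

    The condition is drawn once, the first time a session id is queried,
    and cached; re-querying returns the same condition.
    """

    def __init__(self, seed: int | None = None, p_personalized: float = 0.5) -> None:
        self.seed = seed
        self.p_personalized = p_personalized
        self._rng = np.random.default_rng(seed)
        self._assigned: dict[str, str] = {}

    def assign(self, session_id: str) -> str:
        cond = self._assigned.get(session_id)
        if cond is None:
            cond = (
                "personalized"
                if self._rng.random() < self.p_personalized
                else "baseline"
            )
            self._assigned[session_id] = cond
        return cond

    def __getitem__(self, session_id: str) -> str:
        return self.assign(session_id)

    def as_dict(self) -> "dict[str, str]":
        return dict(self._assigned)

    def save(self, path: str | Path) -> None:
        data = {"seed": self.seed, "assignments": self._assigned}
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ConditionAssignment":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        obj = cls(seed=data.get("seed"))
        obj._assigned = dict(data["assignments"])
        return obj


def assign_condition(
    session_id: str, assignment: ConditionAssignment
) -> str:
    """Condition for a session, decided once at session start."""
    return assignment.assign(session_id)


@dataclass(frozen=True)
class MetricTest:
    """Paired one-sided t-test for one metric across participants."""

    metric: str
    direction: str
    mean_baseline: float
    mean_personalized: float
    t_statistic: float | None
    p_value: float | None
    n_pairs: int
    computable: bool


@dataclass(frozen=True)
class ABResult:
    per_participant: pd.DataFrame
    tests: "dict[str, MetricTest]"
    n_participants: int
    unpaired_participants: "list[str]" = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "unpaired_participants": list(self.unpaired_participants),
            "metrics": {
                name: {
                    "direction": t.direction,
                    "mean_baseline": t.mean_baseline,
                    "mean_personalized": t.mean_personalized,
                    "t_statistic": t.t_statistic,
                    "p_value": t.p_value,
                    "n_pairs": t.n_pairs,
                    "computable": t.computable,
                }
                for name, t in self.tests.items()
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        )


def _session_metrics(events) -> "dict[str, float | None]":
    """Raw metric values of one session (None where undefined)."""
    n_selected = 0
    n_from_rec = 0
    n_reloads = 0
    n_activations = 0
    rec_items: set[str] = set()
    ratings_of_rec: list[float] = []
    for e in sorted(events, key=lambda e: e.timestamp):
        if e.event_type == "content_selected":
            n_selected += 1
            if e.payload.get("source") == "recommendation":
                n_from_rec += 1
                rec_items.add(e.payload.get("item_id", ""))
        elif e.event_type == "reload":
            n_reloads += 1
        elif e.event_type == "content_start":
            n_activations += 1
        elif e.event_type == "rating":
            if e.payload.get("item_id") in rec_items:
                value = e.payload.get("normalized_value")
                if value is not None:
                    ratings_of_rec.append(float(value))
    return {
        "selection_rate": n_from_rec / n_selected if n_selected else None,
        "reloads_per_activation": n_reloads / n_activations if n_activations else None,
        "mean_rating": float(np.mean(ratings_of_rec)) if ratings_of_rec else None,
    }


def _one_sided_paired_t(
    personalized: np.ndarray, baseline: np.ndarray, direction: str
) -> tuple[float, float]:
    """t and one-sided p for H1: personalized `direction` baseline.

    The t statistic is computed on personalized - baseline differences; a
    degenerate all-zero difference vector yields t = 0, p = 0.5.
    """
    diffs = personalized - baseline
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            return 0.0, 0.5
        # constant nonzero difference: infinitely strong evidence either way
        sign = float(np.sign(diffs.mean()))
        t = sign * np.inf
        better = (sign > 0) == (direction == "greater")
        return t, 0.0 if better else 1.0
    res = stats.ttest_rel(personalized, baseline, alternative=direction)
    return float(res.statistic), float(res.pvalue)


def compute_metrics(
    log: EventLog, assignment: ConditionAssignment | "dict[str, str]"
) -> ABResult:
    """Per-participant, per-condition metrics and the three paired tests.

    Participants lacking sessions (with a defined metric value) in either
    condition are excluded from that metric's pairing and reported in
    ``unpaired_participants``.  Fewer than two paired participants leaves
    the test marked not computable; the means are still reported.
    """
    lookup = assignment.as_dict() if isinstance(assignment, ConditionAssignment) else dict(assignment)

    rows = []
    for session_id, events in log.sessions().items():
        cond = lookup.get(session_id)
        if cond is None:
            continue
        metrics = _session_metrics(events)
        rows.append(
            {"user_id": events[0].user_id, "session_id": session_id, "condition": cond, **metrics}
        )
    sessions = pd.DataFrame(rows)

    per_participant = (
        sessions.groupby(["user_id", "condition"])[list(METRICS)].mean().reset_index()
        if len(sessions)
        else pd.DataFrame(columns=["user_id", "condition", *METRICS])
    )

    tests: dict[str, MetricTest] = {}
    unpaired: set[str] = set()
    for metric, direction in METRICS.items():
        pivot = per_participant.pivot(index="user_id", columns="condition", values=metric)
        for cond in CONDITIONS:
            if cond not in pivot.columns:
                pivot[cond] = np.nan
        paired = pivot.dropna(subset=list(CONDITIONS))
        unpaired |= set(pivot.index) - set(paired.index)
        mean_b = float(pivot["baseline"].mean()) if pivot["baseline"].notna().any() else float("nan")
        mean_p = float(pivot["personalized"].mean()) if pivot["personalized"].notna().any() else float("nan")
        if len(paired) >= 2:
            t, p = _one_sided_paired_t(
                paired["personalized"].to_numpy(float),
                paired["baseline"].to_numpy(float),
                direction,
            )
            tests[metric] = MetricTest(
                metric, direction, mean_b, mean_p, t, p, len(paired), True
            )
        else:
            tests[metric] = MetricTest(
                metric, direction, mean_b, mean_p, None, None, len(paired), False
            )

    n_participants = sessions["user_id"].nunique() if len(sessions) else 0
    return ABResult(
        per_participant=per_participant,
        tests=tests,
        n_participants=int(n_participants),
        unpaired_participants=sorted(unpaired),
    )
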