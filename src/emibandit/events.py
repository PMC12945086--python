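"""Event data model for the daily set/review cycle of a behavior study.

A study log is a JSON-Lines file: one header line carrying per-user metadata
(timezone, RNG seed, baseline covariates), then one event per line tagged with
``type`` in {set, review, mood, weight} and an ISO-8601 timestamp.

The analysis pipeline pairs each evening review with the set event it reviews
(strictly 12-36 h earlier), scores the nine 0-100 visual-analog mood items
into three subscales on [0, 1], computes the daily outcome Y (preselected
behaviors performed plus ad-hoc extras), and exports an analysis-ready long
table with one row per paired record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import IO, Iterable, Mapping, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorItem",
    "SetEvent",
    "ReviewEvent",
    "MoodObservation",
    "MoodSubscales",
    "WeightObservation",
    "PairedRecord",
    "EventLog",
    "DropReport",
    "MalformedLogError",
    "DEFAULT_MOOD_MAPPING",
    "pair_set_review",
    "score_mood",
    "compute_daily_outcome",
    "compute_use_rate",
    "weight_deltas",
    "build_analysis_table",
]


class MalformedLogError(ValueError):
    """The event log violates a structural invariant."""


PAIRING_MIN_HOURS = 12.0  # strict: gap must exceed this
PAIRING_MAX_HOURS = 36.0  # strict: gap must stay below this
MOOD_PAIRING_MAX_HOURS = 24.0  # mood must precede the review within this window

#: Default assignment of the nine visual-analog items to subscales.  The
#: instrument's exact item order is configuration, not contract: pass your own
#: mapping to score_mood / build_analysis_table if your deployment differs.
DEFAULT_MOOD_MAPPING: dict[str, tuple[int, int, int]] = {
    "depression": (0, 1, 2),
    "anxiety": (3, 4, 5),
    "positive_affect": (6, 7, 8),
}


def _parse_ts(s: str) -> datetime:
    ts = datetime.fromisoformat(s)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts


@dataclass(frozen=True)
class BehaviorItem:
    """A selectable behavior: predefined by the catalog or user-created."""

    arm_id: str
    label: str = ""
    source: str = "predefined"  # or "user_created"
    specification: str | None = None

    def __post_init__(self) -> None:
        if self.source not in ("predefined", "user_created"):
            raise MalformedLogError(f"unknown behavior source {self.source!r}")


@dataclass(frozen=True)
class SetEvent:
    """Evening selection of behaviors to perform the following day."""

    user_id: str
    timestamp: datetime
    selected: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.selected:
            raise MalformedLogError("set event with empty selection")
        if len(set(self.selected)) != len(self.selected):
            raise MalformedLogError("set event with duplicate arm_ids")


@dataclass(frozen=True)
class ReviewEvent:
    """Next-evening review: per selected behavior, was it performed; plus any
    additional (unselected) behaviors the user logged."""

    user_id: str
    timestamp: datetime
    performed: Mapping[str, bool]
    extras: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.extras) & set(self.performed):
            raise MalformedLogError("extras overlap the reviewed selection")
        if len(set(self.extras)) != len(self.extras):
            raise MalformedLogError("duplicate extras in review")


@dataclass(frozen=True)
class MoodObservation:
    """Nine mood items, each on a 0-100 visual analog scale."""

    user_id: str
    timestamp: datetime
    items: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 9:
            raise MalformedLogError(f"mood needs exactly 9 items, got {len(self.items)}")
        for v in self.items:
            if not (0.0 <= v <= 100.0):
                raise MalformedLogError(f"mood item {v} outside [0, 100]")


@dataclass(frozen=True)
class MoodSubscales:
    """Anxiety / positive-affect / depression scores, each the mean of its
    three items rescaled to [0, 1]."""

    anxiety: float
    positive_affect: float
    depression: float


@dataclass(frozen=True)
class WeightObservation:
    user_id: str
    timestamp: datetime
    weight_kg: float

    def __post_init__(self) -> None:
        if not self.weight_kg > 0:
            raise MalformedLogError(f"non-positive weight {self.weight_kg}")


@dataclass(frozen=True)
class PairedRecord:
    """A review matched to the set event it reviews; the unit of analysis.

    ``daily_outcome`` is Y: the number of preselected behaviors actually
    performed plus the number of extras.  ``week_index`` counts study weeks
    (1-4 in a 28-day study) from the user's first set event.
    """

    set_event: SetEvent
    review_event: ReviewEvent
    gap_hours: float
    week_index: int

    def __post_init__(self) -> None:
        if not (PAIRING_MIN_HOURS < self.gap_hours < PAIRING_MAX_HOURS):
            raise MalformedLogError(
                f"pairing gap {self.gap_hours:.2f} h outside "
                f"({PAIRING_MIN_HOURS:g}, {PAIRING_MAX_HOURS:g})"
            )
        if not set(self.review_event.performed) <= set(self.set_event.selected):
            raise MalformedLogError("review performs behaviors that were not selected")

    @property
    def daily_outcome(self) -> int:
        return compute_daily_outcome(self)


def compute_daily_outcome(record: PairedRecord) -> int:
    """Y = (# preselected behaviors performed) + (# extra behaviors)."""
    review = record.review_event
    return int(sum(bool(v) for v in review.performed.values()) + len(review.extras))


@dataclass
class DropReport:
    """Bookkeeping for events excluded during pairing."""

    unmatched_reviews: list[ReviewEvent] = field(default_factory=list)
    unmatched_sets: list[SetEvent] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.unmatched_reviews) + len(self.unmatched_sets)


Event = SetEvent | ReviewEvent | MoodObservation | WeightObservation


@dataclass
class EventLog:
    """A full study log: header metadata plus time-ordered events.

    ``users`` maps user_id to metadata (timezone, bandit seed, and baseline
    covariates such as sex, bmi_start, psych_comorbidity).
    """

    users: dict[str, dict] = field(default_factory=dict)
    events: list[Event] = field(default_factory=list)

    def sorted_events(self) -> list[Event]:
        return sorted(self.events, key=lambda e: (e.user_id, e.timestamp))

    def events_of(self, kind: type, user_id: str | None = None) -> list:
        out = [e for e in self.events if isinstance(e, kind)]
        if user_id is not None:
            out = [e for e in out if e.user_id == user_id]
        return sorted(out, key=lambda e: e.timestamp)

    def user_timezone(self, user_id: str) -> ZoneInfo:
        name = self.users.get(user_id, {}).get("timezone", "UTC")
        return ZoneInfo(name)

    # -- JSON Lines I/O ------------------------------------------------

    def write_jsonl(self, fh: IO[str]) -> None:
        fh.write(json.dumps({"type": "header", "users": self.users}, sort_keys=True))
        fh.write("\n")
        for e in self.sorted_events():
            fh.write(json.dumps(_event_to_obj(e), sort_keys=True))
            fh.write("\n")

    @classmethod
    def read_jsonl(cls, fh: IO[str]) -> "EventLog":
        log = cls()
        first = True
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            kind = obj.get("type")
            if kind == "header":
                if not first:
                    raise MalformedLogError("header line must come first")
                log.users = obj.get("users", {})
            else:
                log.events.append(_event_from_obj(obj))
            first = False
        return log

    def dumps(self) -> str:
        import io

        buf = io.StringIO()
        self.write_jsonl(buf)
        return buf.getvalue()

    @classmethod
    def loads(cls, s: str) -> "EventLog":
        import io

        return cls.read_jsonl(io.StringIO(s))


def _event_to_obj(e: Event) -> dict:
    ts = e.timestamp.isoformat()
    if isinstance(e, SetEvent):
        return {"type": "set", "user_id": e.user_id, "timestamp": ts,
                "selected": list(e.selected)}
    if isinstance(e, ReviewEvent):
        return {"type": "review", "user_id": e.user_id, "timestamp": ts,
                "performed": {k: bool(v) for k, v in e.performed.items()},
                "extras": list(e.extras)}
    if isinstance(e, MoodObservation):
        return {"type": "mood", "user_id": e.user_id, "timestamp": ts,
                "items": list(e.items)}
    if isinstance(e, WeightObservation):
        return {"type": "weight", "user_id": e.user_id, "timestamp": ts,
                "weight_kg": e.weight_kg}
    raise TypeError(f"unknown event {e!r}")


def _event_from_obj(obj: Mapping) -> Event:
    kind = obj.get("type")
    ts = _parse_ts(obj["timestamp"])
    uid = obj["user_id"]
    if kind == "set":
        return SetEvent(uid, ts, tuple(obj["selected"]))
    if kind == "review":
        return ReviewEvent(uid, ts, dict(obj["performed"]), tuple(obj.get("extras", ())))
    if kind == "mood":
        return MoodObservation(uid, ts, tuple(float(v) for v in obj["items"]))
    if kind == "weight":
        return WeightObservation(uid, ts, float(obj["weight_kg"]))
    raise MalformedLogError(f"unknown event type {kind!r}")


# ---------------------------------------------------------------------------
# pairing


def _week_index(set_ts: datetime, study_start: datetime, tz: ZoneInfo) -> int:
    d0 = study_start.astimezone(tz).date()
    d = set_ts.astimezone(tz).date()
    return (d - d0).days // 7 + 1


def pair_set_review(
    events: Sequence[Event],
    timezones: Mapping[str, ZoneInfo] | None = None,
) -> tuple[list[PairedRecord], DropReport]:
    """Match each review to the most recent prior set event of the same user
    whose gap lies strictly inside (12 h, 36 h).

    Pairing is one-to-one: if two reviews fall inside one set's window the
    earlier review claims it and the later one is dropped.  Unmatched reviews
    and sets are excluded and reported, never raised, except that a review
    whose performed keys are not a subset of its matched selection is a
    malformed log.
    """
    timezones = timezones or {}
    by_user: dict[str, list[Event]] = {}
    for e in sorted(events, key=lambda e: e.timestamp):
        by_user.setdefault(e.user_id, []).append(e)

    records: list[PairedRecord] = []
    report = DropReport()
    for user_id, evs in sorted(by_user.items()):
        tz = timezones.get(user_id, ZoneInfo("UTC"))
        sets = [e for e in evs if isinstance(e, SetEvent)]
        reviews = [e for e in evs if isinstance(e, ReviewEvent)]
        if not sets:
            report.unmatched_reviews.extend(reviews)
            continue
        study_start = sets[0].timestamp
        claimed: set[int] = set()
        for rev in reviews:
            match_idx: int | None = None
            for i, st in enumerate(sets):
                gap = (rev.timestamp - st.timestamp).total_seconds() / 3600.0
                if gap <= PAIRING_MIN_HOURS:
                    break  # sets are time-ordered; later ones are even closer
                if gap < PAIRING_MAX_HOURS:
                    match_idx = i  # keep scanning: most recent prior set wins
            if match_idx is None or match_idx in claimed:
                report.unmatched_reviews.append(rev)
                continue
            st = sets[match_idx]
            if not set(rev.performed) <= set(st.selected):
                raise MalformedLogError(
                    f"user {user_id!r}: review at {rev.timestamp.isoformat()} "
                    "performs behaviors absent from its matched selection"
                )
            claimed.add(match_idx)
            gap = (rev.timestamp - st.timestamp).total_seconds() / 3600.0
            records.append(
                PairedRecord(
                    set_event=st,
                    review_event=rev,
                    gap_hours=gap,
                    week_index=_week_index(st.timestamp, study_start, tz),
                )
            )
        report.unmatched_sets.extend(
            st for i, st in enumerate(sets) if i not in claimed
        )
    return records, report


# ---------------------------------------------------------------------------
# mood scoring


def score_mood(
    obs: MoodObservation,
    mapping: Mapping[str, Sequence[int]] = DEFAULT_MOOD_MAPPING,
) -> MoodSubscales:
    """Score nine 0-100 items into three subscales on [0, 1].

    Each subscale is the arithmetic mean of its three assigned items divided
    by 100.  Positive affect is reported as its own subscale and is never
    reverse-scored into depression.
    """
    keys = set(mapping)
    if keys != {"anxiety", "positive_affect", "depression"}:
        raise ValueError(f"mapping must name the three subscales, got {sorted(keys)}")
    assigned = [i for idxs in mapping.values() for i in idxs]
    if sorted(assigned) != list(range(9)):
        raise ValueError("mapping must assign each of items 0-8 to exactly one subscale")
    score = {
        name: float(np.mean([obs.items[i] for i in idxs]) / 100.0)
        for name, idxs in mapping.items()
    }
    return MoodSubscales(**score)


# ---------------------------------------------------------------------------
# feasibility and covariates


def compute_use_rate(
    log: EventLog,
    scheduled_days: int | Mapping[str, int] = 28,
) -> dict[str, float]:
    """Per-user app use rate: 100 x (distinct local calendar days with a
    review) / scheduled days.

    ``scheduled_days`` may be a single count (default 28) or a per-user map
    for participants with shortened schedules.  Rates are exact floats; round
    to one decimal for reporting.
    """
    rates: dict[str, float] = {}
    user_ids = set(log.users) | {e.user_id for e in log.events}
    for user_id in sorted(user_ids):
        sched = (
            scheduled_days.get(user_id, 28)
            if isinstance(scheduled_days, Mapping)
            else scheduled_days
        )
        if sched < 1:
            raise ValueError(f"scheduled_days must be >= 1, got {sched}")
        tz = log.user_timezone(user_id)
        days = {
            e.timestamp.astimezone(tz).date()
            for e in log.events_of(ReviewEvent, user_id)
        }
        if len(days) > sched:
            raise MalformedLogError(
                f"user {user_id!r}: {len(days)} recorded days exceed "
                f"{sched} scheduled days"
            )
        rates[user_id] = 100.0 * len(days) / sched
    return rates


def weight_deltas(
    weights: Sequence[WeightObservation], at: datetime
) -> tuple[float, float | None]:
    """Weight change (kg) at a review time: (from baseline, from previous).

    Uses the latest observation strictly before ``at``; baseline is the
    user's first observation.  The previous-observation delta is None when
    only one observation precedes ``at`` (callers drop such records from
    models that need it rather than imputing).
    """
    prior = sorted(
        (w for w in weights if w.timestamp < at), key=lambda w: w.timestamp
    )
    if not prior:
        raise ValueError(f"no weight observation before {at.isoformat()}")
    latest = prior[-1]
    baseline = prior[0]
    d_base = latest.weight_kg - baseline.weight_kg
    d_prev = latest.weight_kg - prior[-2].weight_kg if len(prior) >= 2 else None
    return d_base, d_prev


# ---------------------------------------------------------------------------
# analysis-ready export

ANALYSIS_COLUMNS = [
    "user_id", "day", "week", "y",
    "depression", "anxiety", "positive_affect",
    "delta_weight_baseline", "delta_weight_previous",
    "sex", "bmi_centered", "psych_comorbidity",
]


def build_analysis_table(
    log: EventLog,
    mood_mapping: Mapping[str, Sequence[int]] = DEFAULT_MOOD_MAPPING,
) -> pd.DataFrame:
    """One row per paired set/review record: the long table the mixed model
    consumes.

    Mood covariates come from the latest mood observation strictly before the
    review and within 24 h of it; weight deltas from `weight_deltas`.  Rows
    missing a covariate keep NaN there (complete-case handling happens at fit
    time).  Level-2 covariates (sex, BMI centered at 35, psychiatric
    comorbidity) are pulled from the log header when present.
    """
    records, _ = pair_set_review(
        log.events, {u: log.user_timezone(u) for u in log.users}
    )
    rows = []
    for rec in records:
        uid = rec.review_event.user_id
        tz = log.user_timezone(uid)
        meta = log.users.get(uid, {})
        moods = [
            m for m in log.events_of(MoodObservation, uid)
            if m.timestamp < rec.review_event.timestamp
            and (rec.review_event.timestamp - m.timestamp).total_seconds()
            <= MOOD_PAIRING_MAX_HOURS * 3600
        ]
        sub = score_mood(moods[-1], mood_mapping) if moods else None
        weights = log.events_of(WeightObservation, uid)
        try:
            d_base, d_prev = weight_deltas(weights, rec.review_event.timestamp)
        except ValueError:
            d_base, d_prev = np.nan, None
        sets0 = log.events_of(SetEvent, uid)[0].timestamp.astimezone(tz).date()
        day = (rec.review_event.timestamp.astimezone(tz).date() - sets0).days
        bmi = meta.get("bmi_start")
        rows.append({
            "user_id": uid,
            "day": day,
            "week": rec.week_index,
            "y": rec.daily_outcome,
            "depression": sub.depression if sub else np.nan,
            "anxiety": sub.anxiety if sub else np.nan,
            "positive_affect": sub.positive_affect if sub else np.nan,
            "delta_weight_baseline": d_base,
            "delta_weight_previous": d_prev if d_prev is not None else np.nan,
            "sex": meta.get("sex", np.nan),
            "bmi_centered": (bmi - 35.0) if bmi is not None else np.nan,
            "psych_comorbidity": meta.get("psych_comorbidity", np.nan),
        })
    df = pd.DataFrame(rows, columns=ANALYSIS_COLUMNS)
    return df.sort_values(["user_id", "day"], kind="stable").reset_index(drop=True)
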