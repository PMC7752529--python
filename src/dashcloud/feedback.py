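"""Tailored feedback composition and message scheduling.

The intervention cadence: daily feedback texts at 12:00 study time for the
first two weeks after enrollment (proximal feedback), weekly feedback
thereafter (reduced burden), and a separate Sunday-afternoon topic message
each week linking an educational video.  Messages are composed
deterministically from the previous day's DASH score, the participant's
best and struggle components, and cycling tip/topic banks, so identical
inputs always yield identical texts.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence
from zoneinfo import ZoneInfo, ZoneInfoNotFoundError

import yaml

from .intake import NUTRIENTS, NutrientDensityProfile
from .scoring import NO_SCORE, DashScore, TargetSet

logger = logging.getLogger(__name__)

DEFAULT_TIMEZONE = "America/New_York"  # study clock; "EST" incl. DST
DAILY_FEEDBACK_DAYS = 14
DAILY_TIME = dt.time(12, 0)
WEEKLY_TIME = dt.time(12, 0)
TOPIC_TIME = dt.time(15, 0)  # "Sunday afternoons"; configurable

MESSAGE_KINDS = ("daily_feedback", "weekly_feedback", "topic", "auto_reply")

#: Direction-aware phrasing for struggle components; directions are a fixed
#: property of the nutrient index (less fat/satfat/cholesterol/sodium, more
#: of the rest).
_STRUGGLE_PHRASE = {
    "total_fat": "cutting back on total fat",
    "saturated_fat": "reducing saturated fat",
    "cholesterol": "cutting back on cholesterol",
    "sodium": "cutting back on sodium",
    "protein": "getting enough protein",
    "fiber": "boosting your fiber intake",
    "magnesium": "getting enough magnesium",
    "calcium": "getting enough calcium",
    "potassium": "getting enough potassium",
}

AUTO_REPLY_BODY = (
    "Thanks for your message! This number is not monitored. "
    "For support, please reach out to our study staff by email."
)


def display_name(nutrient: str) -> str:
    return nutrient.replace("_", " ")


@dataclass(frozen=True)
class FeedbackMessage:
    """A composed outbound text: the transport-agnostic message payload."""

    participant_id: str
    kind: str
    scheduled_time: dt.datetime
    body: str
    referenced_score: Optional[float] = None  # NO_SCORE when untracked
    best_components: tuple[str, ...] = ()
    struggle_components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in MESSAGE_KINDS:
            raise ValueError(f"unknown message kind {self.kind!r}")
        if set(self.best_components) & set(self.struggle_components):
            raise ValueError("best and struggle components must be disjoint")


@dataclass(frozen=True)
class MessageSchedule:
    """Ordered (scheduled_time, kind) plan for one participant's study."""

    participant_id: str
    enrollment_date: dt.date
    entries: tuple[tuple[dt.datetime, str], ...]

    def of_kind(self, kind: str) -> list[dt.datetime]:
        return [t for t, k in self.entries if k == kind]


def load_tip_bank(path: Optional[str | Path] = None) -> dict[str, list[str]]:
    """Tips keyed by nutrient; defaults to the packaged bank."""
    if path is None:
        text = resources.files("dashcloud").joinpath("data/tips.yaml").read_text()
    else:
        text = Path(path).read_text()
    bank = yaml.safe_load(text)
    missing = [n for n in NUTRIENTS if not bank.get(n)]
    if missing:
        raise ValueError(f"tip bank must hold >=1 tip per nutrient; missing {missing}")
    return bank


def load_topic_bank(path: Optional[str | Path] = None) -> list[dict]:
    """Ordered weekly topics (title + video link)."""
    if path is None:
        text = resources.files("dashcloud").joinpath("data/topics.yaml").read_text()
    else:
        text = Path(path).read_text()
    topics = yaml.safe_load(text)["topics"]
    if not topics:
        raise ValueError("topic bank is empty")
    return topics


def classify_components(
    score: DashScore,
    targets: TargetSet,
    profile: NutrientDensityProfile,
    cap: int = 2,
) -> tuple[list[str], list[str]]:
    """Pick the components to praise and to coach, at most ``cap`` each.

    Best: full-credit components, closest call first (smallest relative
    margin beyond target).  Struggle: zero-credit components, farthest from
    target first (largest relative distance).  Half-credit components fill
    either list only when its cap is unfilled: best backfills with the
    nearest-to-target half credits, struggle with the farthest.  The two
    lists never share a component.
    """
    if score is NO_SCORE or score is None:
        raise ValueError("cannot classify components without a score")

    def rel_distance(nutrient: str) -> float:
        spec = targets[nutrient]
        return abs(profile[nutrient] - spec.target) / spec.target

    ones = [n for n in NUTRIENTS if score.component_credits[n] == 1.0]
    halves = [n for n in NUTRIENTS if score.component_credits[n] == 0.5]
    zeros = [n for n in NUTRIENTS if score.component_credits[n] == 0.0]

    best = sorted(ones, key=rel_distance)[:cap]
    if len(best) < cap:
        backfill = sorted(halves, key=rel_distance)
        best += backfill[: cap - len(best)]
    remaining_halves = [n for n in halves if n not in best]
    struggle = sorted(zeros, key=rel_distance, reverse=True)[:cap]
    if len(struggle) < cap:
        backfill = sorted(remaining_halves, key=rel_distance, reverse=True)
        struggle += backfill[: cap - len(struggle)]
    return best, struggle


def _tip_for(nutrient: str, tip_bank: Mapping[str, list[str]], study_day: int) -> str:
    tips = tip_bank[nutrient]
    return tips[study_day % len(tips)]


def compose_daily_message(
    participant_id: str,
    first_name: str,
    score: Optional[DashScore],
    best: Sequence[str],
    struggle: Sequence[str],
    tip_bank: Mapping[str, list[str]],
    date: dt.date,
    study_day: int = 1,
    tz: str = DEFAULT_TIMEZONE,
) -> FeedbackMessage:
    """Compose one daily feedback text about yesterday's score.

    Body = greeting + numeric score (one decimal) or a tracked-nothing
    prompt + best/struggle sentence + one tip targeting the top struggle
    component.  Tip selection cycles by study-day index, never randomly.
    """
    when = dt.datetime.combine(date, DAILY_TIME, tzinfo=_zone(tz))
    greeting = f"Hello, {first_name}!"
    if score is NO_SCORE or score is None:
        cycle_nutrient = NUTRIENTS[study_day % len(NUTRIENTS)]
        body = (
            f"{greeting} We didn't see any food logged yesterday, so there is "
            "no DASH score to share. Every day you track counts - try logging "
            f"today's meals! {_tip_for(cycle_nutrient, tip_bank, study_day)}"
        )
        return FeedbackMessage(participant_id, "daily_feedback", when, body, NO_SCORE)

    parts = [greeting, f"Your DASH score yesterday was {score.total:.1f}."]
    best, struggle = list(best), list(struggle)
    if struggle:
        sentence = "You did best with " + " and ".join(display_name(n) for n in best)
        sentence += " and seemed to struggle with " + " and ".join(
            _STRUGGLE_PHRASE[n] for n in struggle
        )
        parts.append(sentence + ".")
        parts.append(_tip_for(struggle[0], tip_bank, study_day))
    else:
        parts.append(
            "Fantastic work - you met every DASH target! Keep up what's working, "
            "especially your " + " and ".join(display_name(n) for n in best) + "."
        )
        parts.append(_tip_for(best[0], tip_bank, study_day) if best else "")
    body = " ".join(p for p in parts if p)
    return FeedbackMessage(
        participant_id,
        "daily_feedback",
        when,
        body,
        referenced_score=score.total,
        best_components=tuple(best),
        struggle_components=tuple(struggle),
    )


def compose_weekly_message(
    participant_id: str,
    first_name: str,
    week_scores: Sequence[float],
    tip_bank: Mapping[str, list[str]],
    date: dt.date,
    study_day: int,
    best: Sequence[str] = (),
    struggle: Sequence[str] = (),
    tz: str = DEFAULT_TIMEZONE,
) -> FeedbackMessage:
    """Weekly feedback referencing the mean of the prior week's valid-day scores."""
    when = dt.datetime.combine(date, WEEKLY_TIME, tzinfo=_zone(tz))
    greeting = f"Hello, {first_name}!"
    if not week_scores:
        body = (
            f"{greeting} We didn't see any valid tracking days this past week. "
            "Logging your meals is the first step toward your DASH goals - "
            "give it another go today!"
        )
        return FeedbackMessage(participant_id, "weekly_feedback", when, body, NO_SCORE)
    weekly_mean = sum(week_scores) / len(week_scores)
    parts = [greeting, f"Your average DASH score this past week was {weekly_mean:.1f}."]
    if struggle:
        parts.append(
            "This week, focus on "
            + " and ".join(_STRUGGLE_PHRASE[n] for n in struggle)
            + "."
        )
        parts.append(_tip_for(struggle[0], tip_bank, study_day))
    else:
        parts.append("Keep up the great work on every DASH target!")
        parts.append(_tip_for(best[0] if best else NUTRIENTS[0], tip_bank, study_day))
    return FeedbackMessage(
        participant_id,
        "weekly_feedback",
        when,
        " ".join(parts),
        referenced_score=weekly_mean,
        best_components=tuple(best),
        struggle_components=tuple(struggle),
    )


def _zone(tz: str) -> ZoneInfo:
    try:
        return ZoneInfo(tz)
    except (ZoneInfoNotFoundError, ValueError) as exc:
        raise ValueError(f"invalid timezone {tz!r}") from exc


def build_schedule(
    participant_id: str,
    enrollment_date: dt.date,
    study_length_days: int = 90,
    tz: str = DEFAULT_TIMEZONE,
    topic_time: dt.time = TOPIC_TIME,
) -> MessageSchedule:
    """Plan the full message cadence from enrollment (study day 0).

    Daily feedback at 12:00 on study days 1-14; weekly feedback at 12:00 on
    days 21, 28, ... (the enrollment weekday); one topic message on each
    Sunday afternoon inside the study window.
    """
    if study_length_days < DAILY_FEEDBACK_DAYS:
        raise ValueError(f"study_length_days must be >= {DAILY_FEEDBACK_DAYS}")
    zone = _zone(tz)
    entries: list[tuple[dt.datetime, str]] = []
    for day in range(1, study_length_days + 1):
        date = enrollment_date + dt.timedelta(days=day)
        if day <= DAILY_FEEDBACK_DAYS:
            entries.append((dt.datetime.combine(date, DAILY_TIME, tzinfo=zone), "daily_feedback"))
        elif day % 7 == 0:
            entries.append((dt.datetime.combine(date, WEEKLY_TIME, tzinfo=zone), "weekly_feedback"))
        if date.weekday() == 6:  # Sunday
            entries.append((dt.datetime.combine(date, topic_time, tzinfo=zone), "topic"))
    entries.sort(key=lambda e: (e[0], e[1]))
    return MessageSchedule(participant_id, enrollment_date, tuple(entries))


def compose_topic_message(
    week_index: int,
    topic_bank: Sequence[Mapping[str, str]],
    participant_id: str = "",
    scheduled_time: Optional[dt.datetime] = None,
) -> FeedbackMessage:
    """Sunday topic message; topics rotate in order and wrap when exhausted."""
    if week_index < 1:
        raise ValueError(f"week_index must be >= 1, got {week_index}")
    if not topic_bank:
        raise ValueError("topic bank is empty")
    topic = topic_bank[(week_index - 1) % len(topic_bank)]
    body = (
        f"This week's DASH topic: {topic['title']}. "
        f"Watch the short video here: {topic['link']}"
    )
    when = scheduled_time or dt.datetime.combine(dt.date.today(), TOPIC_TIME, tzinfo=_zone(DEFAULT_TIMEZONE))
    return FeedbackMessage(participant_id, "topic", when, body)


@dataclass(frozen=True)
class InboundMessage:
    """A text received from a phone number; participant_id is None when the
    sender is not on the roster."""

    participant_id: Optional[str]
    body: str
    received_time: dt.datetime
    from_system: bool = False  # guards against replying to our own messages


def auto_reply(inbound: InboundMessage) -> Optional[FeedbackMessage]:
    """Fixed-body reply to any participant text; never replies to itself.

    Unknown senders are logged and dropped (returns None).
    """
    if inbound.from_system:
        return None
    if inbound.participant_id is None:
        logger.info("dropping inbound message from unknown sender")
        return None
    return FeedbackMessage(
        participant_id=inbound.participant_id,
        kind="auto_reply",
        scheduled_time=inbound.received_time,
        body=AUTO_REPLY_BODY,
    )
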