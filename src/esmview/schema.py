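"""Typed data model for single-subject ESM questionnaires and response datasets.

An ESM (experience sampling method) study sends a short questionnaire to a
participant's phone several times a day at fixed clock times.  This module
defines the questionnaire schema (items with response kinds, polarity and
conditionality), the prompt schedule, and the dataset container holding one
record per scheduled prompt — answered or not.  Missingness is a first-class
value (:data:`MISSING`), distinct from a score of zero and from a "no" answer,
so that downstream renderers can choose how to display it.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Any, Iterator, Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "MISSING",
    "Polarity",
    "ResponseKind",
    "Slot",
    "SLOTS",
    "ItemDefinition",
    "Questionnaire",
    "PromptSchedule",
    "PromptRecord",
    "ESMDataset",
    "ValidationFinding",
    "SchemaError",
    "build_default_questionnaire",
    "validate_dataset",
    "slot_of",
]


class _Missing:
    """Sentinel for an item the participant did not answer (singleton)."""

    _instance: Optional["_Missing"] = None

    def __new__(cls) -> "_Missing":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"

    def __bool__(self) -> bool:
        return False

    def __deepcopy__(self, memo: dict) -> "_Missing":
        return self

    def __copy__(self) -> "_Missing":
        return self


MISSING = _Missing()

Polarity = Literal["positive", "negative", "neutral", "event"]
ResponseKind = Literal["slider_0_100", "yes_no", "likert_count", "free_text"]
AssessmentWindow = Literal["momentary", "since_last"]
Slot = Literal["morning", "afternoon", "evening"]

SLOTS: tuple[Slot, Slot, Slot] = ("morning", "afternoon", "evening")


class SchemaError(ValueError):
    """A structural problem: unknown item code, malformed schema, bad layout."""


class ItemDefinition(BaseModel):
    """One questionnaire item.

    Parameters
    ----------
    code:
        Short identifier used as column name and glyph label (e.g. ``"Alon"``).
    label:
        Full display text shown in legends.
    polarity:
        ``positive`` (resilience-related, blue), ``negative`` (symptom-related,
        pink), ``neutral`` (context) or ``event``.
    response_kind:
        ``slider_0_100`` (visual-analogue 0–100), ``yes_no``, ``likert_count``
        (integer 0..likert_max) or ``free_text``.
    likert_max:
        Maximum count for ``likert_count`` items; forbidden otherwise.
    assessment_window:
        Whether the item asks about the current moment or about the interval
        since the previous prompt.
    conditional_on:
        ``(parent_code, required_answer)`` — the item is only asked when the
        parent item got that answer.
    """

    model_config = {"frozen": True}

    code: str = Field(min_length=1)
    label: str
    polarity: Polarity
    response_kind: ResponseKind
    likert_max: Optional[int] = None
    assessment_window: AssessmentWindow = "momentary"
    conditional_on: Optional[tuple[str, str]] = None

    @model_validator(mode="after")
    def _check_likert_max(self) -> "ItemDefinition":
        if self.response_kind == "likert_count":
            if self.likert_max is None or self.likert_max < 1:
                raise ValueError(f"item {self.code!r}: likert_count requires likert_max >= 1")
        elif self.likert_max is not None:
            raise ValueError(f"item {self.code!r}: likert_max only allowed for likert_count")
        return self


class Questionnaire(BaseModel):
    """Ordered collection of items with unique codes and valid conditionality."""

    model_config = {"frozen": True}

    items: tuple[ItemDefinition, ...]

    @model_validator(mode="after")
    def _check_items(self) -> "Questionnaire":
        seen: set[str] = set()
        for item in self.items:
            if item.code in seen:
                raise ValueError(f"duplicate item code {item.code!r}")
            if item.conditional_on is not None:
                parent, _ = item.conditional_on
                if parent not in seen:
                    raise ValueError(
                        f"item {item.code!r}: conditional_on parent {parent!r} "
                        "must appear earlier in item order"
                    )
            seen.add(item.code)
        return self

    def __iter__(self) -> Iterator[ItemDefinition]:  # type: ignore[override]
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    @property
    def codes(self) -> list[str]:
        return [i.code for i in self.items]

    def item(self, code: str) -> ItemDefinition:
        for i in self.items:
            if i.code == code:
                return i
        raise SchemaError(f"unknown item code {code!r}")

    def __contains__(self, code: object) -> bool:
        return any(i.code == code for i in self.items)

    @property
    def positive_codes(self) -> list[str]:
        return [i.code for i in self.items if i.polarity == "positive"]

    @property
    def negative_codes(self) -> list[str]:
        return [i.code for i in self.items if i.polarity == "negative"]

    def slider_codes(self, polarity: Optional[Polarity] = None) -> list[str]:
        """Codes of 0–100 slider items, optionally restricted to one polarity."""
        return [
            i.code
            for i in self.items
            if i.response_kind == "slider_0_100"
            and (polarity is None or i.polarity == polarity)
        ]


class PromptSchedule(BaseModel):
    """Fixed daily prompt times plus the delivery-window constants.

    Defaults mirror a three-beep protocol: prompts at 09:00, 15:00 and 21:00,
    instruction to answer within 15 minutes, a reminder after 30 minutes, and
    link deactivation after 60 minutes.
    """

    model_config = {"frozen": True}

    daily_times: tuple[dt.time, ...] = (dt.time(9), dt.time(15), dt.time(21))
    instruction_window_min: int = 15
    reminder_offset_min: int = 30
    expiry_offset_min: int = 60

    @model_validator(mode="after")
    def _check(self) -> "PromptSchedule":
        times = self.daily_times
        if not times or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("daily_times must be strictly increasing within a day")
        if not (0 < self.instruction_window_min <= self.reminder_offset_min < self.expiry_offset_min):
            raise ValueError(
                "require 0 < instruction_window_min <= reminder_offset_min < expiry_offset_min"
            )
        return self

    @property
    def prompts_per_day(self) -> int:
        return len(self.daily_times)


Value = Any  # numeric | "yes"/"no" | str | MISSING


@dataclass
class PromptRecord:
    """All answers given at one scheduled prompt.

    ``values`` maps item code to a numeric value, a ``"yes"``/``"no"`` string,
    free text, or :data:`MISSING`.  An unanswered prompt has ``answered=False``
    and every value MISSING.
    """

    scheduled_time: dt.datetime
    slot: Slot
    answered: bool
    values: dict[str, Value] = field(default_factory=dict)
    comment: Optional[str] = None

    @property
    def date(self) -> dt.date:
        return self.scheduled_time.date()

    def get(self, code: str) -> Value:
        return self.values.get(code, MISSING)

    @classmethod
    def unanswered(
        cls, scheduled_time: dt.datetime, slot: Slot, questionnaire: Questionnaire
    ) -> "PromptRecord":
        return cls(
            scheduled_time=scheduled_time,
            slot=slot,
            answered=False,
            values={c: MISSING for c in questionnaire.codes},
        )


@dataclass
class ESMDataset:
    """A questionnaire, a schedule and one record per scheduled prompt."""

    questionnaire: Questionnaire
    schedule: PromptSchedule
    records: list[PromptRecord]
    study_start: dt.date
    study_end: dt.date

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PromptRecord]:
        return iter(self.records)

    @property
    def n_days(self) -> int:
        return (self.study_end - self.study_start).days + 1

    def record_at(self, date: dt.date, slot: Slot) -> Optional[PromptRecord]:
        for r in self.records:
            if r.date == date and r.slot == slot:
                return r
        return None

    def values_frame(self, codes: Optional[list[str]] = None) -> "pd.DataFrame":
        """Numeric wide view: rows = prompts, columns = items, MISSING → NaN.

        Yes/no answers become 1.0/0.0; free-text items are excluded unless
        explicitly requested (then they become NaN).
        """
        import numpy as np
        import pandas as pd

        if codes is None:
            codes = [
                i.code
                for i in self.questionnaire.items
                if i.response_kind in ("slider_0_100", "yes_no", "likert_count")
            ]
        data = {}
        for code in codes:
            col = []
            for r in self.records:
                v = r.get(code)
                if v is MISSING or isinstance(v, str) and v not in ("yes", "no"):
                    col.append(np.nan)
                elif v == "yes":
                    col.append(1.0)
                elif v == "no":
                    col.append(0.0)
                else:
                    col.append(float(v))
            data[code] = col
        index = pd.DatetimeIndex([r.scheduled_time for r in self.records], name="scheduled_time")
        return pd.DataFrame(data, index=index)


# ---------------------------------------------------------------------------
# Default questionnaire
# ---------------------------------------------------------------------------

def build_default_questionnaire() -> Questionnaire:
    """The packaged 23-item OCD/resilience questionnaire.

    Items 1–8 are momentary; 9–23 cover the interval since the last prompt.
    Negative (symptom-related) items: 1–3, 8, 10–13, 18.  Positive
    (resilience-related) items: 4–6, 9, 15–17, 19–20.  Neutral context: 7, 14.
    Events: 21–23.  Sleep quality (15) is asked only after sleeping ("yes" on
    14); event intensities (22, 23) only after an event ("yes" on 21).
    """
    I = ItemDefinition
    items = (
        I(code="Ctrl", label="I am afraid to lose control", polarity="negative",
          response_kind="slider_0_100"),
        I(code="Sad", label="I feel sad / useless / meaningless", polarity="negative",
          response_kind="slider_0_100"),
        I(code="Intr", label="How convincing are the intrusions", polarity="negative",
          response_kind="slider_0_100"),
        I(code="Enco", label="I can encourage myself", polarity="positive",
          response_kind="slider_0_100"),
        I(code="Fun", label="I feel like doing something fun", polarity="positive",
          response_kind="slider_0_100"),
        I(code="CanDo", label='I have the feeling that "I can do this"', polarity="positive",
          response_kind="slider_0_100"),
        I(code="Comp", label="Are you in company?", polarity="neutral",
          response_kind="yes_no"),
        I(code="Alon", label="How afraid are you of being alone?", polarity="negative",
          response_kind="slider_0_100"),
        I(code="Cont", label="How often have you been in contact with someone you feel safe with?",
          polarity="positive", response_kind="likert_count", likert_max=4,
          assessment_window="since_last"),
        I(code="ThCon", label="How often have you thought of contacting someone you feel safe with?",
          polarity="negative", response_kind="slider_0_100", assessment_window="since_last"),
        I(code="Appo", label="How strong was your inclination to cancel appointments?",
          polarity="negative", response_kind="slider_0_100", assessment_window="since_last"),
        I(code="Canc", label="Have you actually cancelled appointments?", polarity="negative",
          response_kind="yes_no", assessment_window="since_last"),
        I(code="Couch", label="Have you laid on the couch or in bed since the last measurement point?",
          polarity="negative", response_kind="slider_0_100", assessment_window="since_last"),
        I(code="Slep", label="Have you slept since the last measurement point?", polarity="neutral",
          response_kind="yes_no", assessment_window="since_last"),
        I(code="SlQu", label="If yes: How did you sleep?", polarity="positive",
          response_kind="slider_0_100", assessment_window="since_last",
          conditional_on=("Slep", "yes")),
        I(code="Out", label="Did you leave the house?", polarity="positive",
          response_kind="slider_0_100", assessment_window="since_last"),
        I(code="Eat", label="How did you eat?", polarity="positive",
          response_kind="slider_0_100", assessment_window="since_last"),
        I(code="Avoi", label="Have you avoided everyday things?", polarity="negative",
          response_kind="slider_0_100", assessment_window="since_last"),
        I(code="Usef", label="Have you done useful (important) things?", polarity="positive",
          response_kind="slider_0_100", assessment_window="since_last"),
        I(code="Enjo", label="Have you enjoyed your activities?", polarity="positive",
          response_kind="slider_0_100", assessment_window="since_last"),
        I(code="Event", label="Since the last measurement point, have you experienced any "
          "(un)pleasant everyday occurrences?", polarity="event", response_kind="yes_no",
          assessment_window="since_last"),
        I(code="Pleas", label="Yes, something pleasant: How pleasant was this experience?",
          polarity="event", response_kind="slider_0_100", assessment_window="since_last",
          conditional_on=("Event", "yes")),
        I(code="Unpl", label="Yes, something unpleasant: How unpleasant was this experience?",
          polarity="event", response_kind="slider_0_100", assessment_window="since_last",
          conditional_on=("Event", "yes")),
    )
    return Questionnaire(items=items)


# ---------------------------------------------------------------------------
# Slot assignment
# ---------------------------------------------------------------------------

def slot_of(timestamp: dt.datetime | dt.time, schedule: PromptSchedule) -> Slot:
    """Map a clock time to morning/afternoon/evening.

    The slot is the nearest scheduled daily time; ties go to the earlier slot.
    Requires a 3-beep schedule (the week grid assumes 3 rows).
    """
    if schedule.prompts_per_day != 3:
        raise SchemaError(
            f"slot layout requires exactly 3 daily times, got {schedule.prompts_per_day}"
        )
    t = timestamp.time() if isinstance(timestamp, dt.datetime) else timestamp
    minutes = t.hour * 60 + t.minute + t.second / 60
    best: Slot = SLOTS[0]
    best_dist = float("inf")
    for slot, sched in zip(SLOTS, schedule.daily_times):
        dist = abs(minutes - (sched.hour * 60 + sched.minute))
        if dist < best_dist:  # strict: earlier slot wins ties
            best, best_dist = slot, dist
    return best


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationFinding:
    """One violated rule at one record/item; data problem, not an exception."""

    scheduled_time: dt.datetime
    item_code: Optional[str]
    rule: str
    message: str

    def __str__(self) -> str:
        where = f" [{self.item_code}]" if self.item_code else ""
        return f"{self.scheduled_time:%Y-%m-%d %H:%M}{where}: {self.message} ({self.rule})"


def _check_value(item: ItemDefinition, v: Value) -> Optional[str]:
    """Return a violation message for one value, or None."""
    if item.response_kind == "slider_0_100":
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            return f"expected numeric slider value, got {v!r}"
        if not 0 <= v <= 100:
            return f"value {v!r} out of range [0,100]"
    elif item.response_kind == "yes_no":
        if v not in ("yes", "no"):
            return f"expected 'yes' or 'no', got {v!r}"
    elif item.response_kind == "likert_count":
        if not isinstance(v, (int, float)) or isinstance(v, bool) or v != int(v):
            return f"expected integer count, got {v!r}"
        if not 0 <= v <= (item.likert_max or 0):
            return f"count {v!r} out of range [0,{item.likert_max}]"
    elif item.response_kind == "free_text":
        if not isinstance(v, str):
            return f"expected text, got {v!r}"
    return None


def validate_dataset(dataset: ESMDataset) -> list[ValidationFinding]:
    """Check every type invariant; return findings (empty list iff clean).

    Pure and idempotent: the dataset is not mutated.  Data problems become
    findings; a structurally malformed dataset (a value keyed by an item code
    the questionnaire does not define) raises :class:`SchemaError`.
    """
    q = dataset.questionnaire
    known = set(q.codes)
    findings: list[ValidationFinding] = []

    seen_slots: set[tuple[dt.date, str]] = set()
    prev_time: Optional[dt.datetime] = None
    for rec in dataset.records:
        for code in rec.values:
            if code not in known:
                raise SchemaError(f"unknown item code {code!r} at {rec.scheduled_time}")

        if prev_time is not None and rec.scheduled_time <= prev_time:
            findings.append(ValidationFinding(
                rec.scheduled_time, None, "records_sorted",
                "records not strictly sorted by scheduled time"))
        prev_time = rec.scheduled_time

        key = (rec.date, rec.slot)
        if key in seen_slots:
            findings.append(ValidationFinding(
                rec.scheduled_time, None, "one_record_per_slot",
                f"duplicate record for {rec.date} {rec.slot}"))
        seen_slots.add(key)

        for item in q.items:
            v = rec.get(item.code)
            if v is MISSING:
                continue
            if not rec.answered:
                findings.append(ValidationFinding(
                    rec.scheduled_time, item.code, "unanswered_all_missing",
                    "value present on an unanswered prompt"))
                continue
            msg = _check_value(item, v)
            if msg is not None:
                findings.append(ValidationFinding(
                    rec.scheduled_time, item.code, "value_range", msg))
            if item.conditional_on is not None:
                parent, required = item.conditional_on
                if rec.get(parent) != required:
                    findings.append(ValidationFinding(
                        rec.scheduled_time, item.code, "conditionality",
                        f"answered although parent {parent!r} != {required!r}"))
    return findings
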