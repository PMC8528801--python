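"""Reading and writing ESM response tables and questionnaire configs.

The canonical on-disk format is CSV (RFC-4180 quoting via the stdlib/pandas
writers).  Two orientations are supported: *wide* (one row per answered
prompt, one column per item — the default, since one-row-per-prompt matches
the circle figure's unit of display) and *long* (one row per prompt × item).
Unanswered prompts are never stored; they are materialized at read time from
the schedule so that missingness is explicit in the in-memory dataset.
Questionnaire schemas round-trip through YAML/JSON config files.
"""

from __future__ import annotations

import csv
import datetime as dt
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, Field

from .schema import (
    MISSING,
    ESMDataset,
    ItemDefinition,
    PromptRecord,
    PromptSchedule,
    Questionnaire,
    SchemaError,
    slot_of,
)
from .simulate import generate_prompt_times

__all__ = [
    "TableDialect",
    "read_dataset",
    "write_dataset",
    "load_questionnaire_config",
    "save_questionnaire_config",
]

_TIME_FORMAT = "%Y-%m-%d %H:%M"


class TableDialect(BaseModel):
    """How a response table is laid out on disk."""

    model_config = {"frozen": True}

    orientation: str = Field(default="wide", pattern="^(wide|long)$")
    missing_codes: tuple[str, ...] = ("", "NA")
    timestamp_column: str = "timestamp"
    item_column: str = "item"      # long orientation only
    value_column: str = "value"    # long orientation only
    comment_column: str = "comment"

    @property
    def missing_token(self) -> str:
        return self.missing_codes[0]


def _format_value(value, dialect: TableDialect) -> str:
    if value is MISSING:
        return dialect.missing_token
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def _parse_value(text: str, item: ItemDefinition, dialect: TableDialect):
    if text in dialect.missing_codes:
        return MISSING
    if item.response_kind == "yes_no":
        return text
    if item.response_kind == "free_text":
        return text
    try:
        num = float(text)
    except ValueError as exc:
        raise SchemaError(f"unparseable value {text!r} for item {item.code!r}") from exc
    return int(num) if num == int(num) else num


def _parse_timestamp(text: str, row_number: int) -> dt.datetime:
    try:
        return dt.datetime.fromisoformat(text)
    except ValueError as exc:
        raise SchemaError(f"unparseable timestamp {text!r} at row {row_number}") from exc


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

def write_dataset(
    dataset: ESMDataset,
    path: Union[str, Path],
    dialect: Optional[TableDialect] = None,
) -> Path:
    """Write the answered records of a dataset to CSV.

    Only answered prompts are stored (unanswered ones are re-materialized on
    read).  Missing item values are written as the dialect's first missing
    code so that answered-but-skipped items round-trip exactly.
    """
    dialect = dialect or TableDialect()
    path = Path(path)
    codes = dataset.questionnaire.codes
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        if dialect.orientation == "wide":
            writer.writerow([dialect.timestamp_column, *codes, dialect.comment_column])
            for rec in dataset.records:
                if not rec.answered:
                    continue
                row = [rec.scheduled_time.strftime(_TIME_FORMAT)]
                row += [_format_value(rec.get(c), dialect) for c in codes]
                row.append(rec.comment if rec.comment is not None else dialect.missing_token)
                writer.writerow(row)
        else:
            writer.writerow([dialect.timestamp_column, dialect.item_column, dialect.value_column])
            for rec in dataset.records:
                if not rec.answered:
                    continue
                ts = rec.scheduled_time.strftime(_TIME_FORMAT)
                for c in codes:
                    writer.writerow([ts, c, _format_value(rec.get(c), dialect)])
                if rec.comment is not None:
                    writer.writerow([ts, dialect.comment_column, rec.comment])
    return path


def read_dataset(
    path: Union[str, Path],
    questionnaire: Questionnaire,
    schedule: Optional[PromptSchedule] = None,
    dialect: Optional[TableDialect] = None,
    study_start: Optional[dt.date] = None,
    study_end: Optional[dt.date] = None,
) -> ESMDataset:
    """Read a response table into an :class:`ESMDataset`.

    Every scheduled prompt in ``[study_start, study_end]`` (defaulting to the
    date span of the rows present) gets a record; prompts with no row become
    ``answered=False`` records so missingness is explicit.  Unknown columns
    or item codes raise :class:`SchemaError` naming the offender.
    """
    dialect = dialect or TableDialect()
    schedule = schedule or PromptSchedule()
    path = Path(path)
    known = set(questionnaire.codes)

    by_time: dict[dt.datetime, PromptRecord] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, no header")

        if dialect.orientation == "wide":
            if dialect.timestamp_column not in header:
                raise SchemaError(f"missing column {dialect.timestamp_column!r}")
            ts_i = header.index(dialect.timestamp_column)
            comment_i = header.index(dialect.comment_column) if dialect.comment_column in header else None
            item_cols: list[tuple[int, ItemDefinition]] = []
            for i, name in enumerate(header):
                if i == ts_i or i == comment_i:
                    continue
                if name not in known:
                    raise SchemaError(f"unknown column {name!r} (not a questionnaire item)")
                item_cols.append((i, questionnaire.item(name)))
            for row_no, row in enumerate(reader, start=2):
                if not row:
                    continue
                when = _parse_timestamp(row[ts_i], row_no)
                values = {item.code: _parse_value(row[i], item, dialect) for i, item in item_cols}
                comment = None
                if comment_i is not None and row[comment_i] not in dialect.missing_codes:
                    comment = row[comment_i]
                if when in by_time:
                    continue  # duplicate submission for one prompt: keep the first
                by_time[when] = PromptRecord(
                    scheduled_time=when, slot=slot_of(when, schedule),
                    answered=True, values=values, comment=comment)
        else:
            for col in (dialect.timestamp_column, dialect.item_column, dialect.value_column):
                if col not in header:
                    raise SchemaError(f"missing column {col!r}")
            ts_i = header.index(dialect.timestamp_column)
            item_i = header.index(dialect.item_column)
            val_i = header.index(dialect.value_column)
            for row_no, row in enumerate(reader, start=2):
                if not row:
                    continue
                when = _parse_timestamp(row[ts_i], row_no)
                rec = by_time.get(when)
                if rec is None:
                    rec = PromptRecord(
                        scheduled_time=when, slot=slot_of(when, schedule),
                        answered=True, values={})
                    by_time[when] = rec
                name = row[item_i]
                if name == dialect.comment_column:
                    if row[val_i] not in dialect.missing_codes:
                        rec.comment = row[val_i]
                    continue
                if name not in known:
                    raise SchemaError(f"unknown item code {name!r} at row {row_no}")
                rec.values[name] = _parse_value(row[val_i], questionnaire.item(name), dialect)

    # fill unmentioned items of long-format records with MISSING
    for rec in by_time.values():
        for c in known:
            rec.values.setdefault(c, MISSING)

    if study_start is None:
        study_start = min(by_time).date() if by_time else dt.date.today()
    if study_end is None:
        study_end = max(by_time).date() if by_time else study_start

    records: list[PromptRecord] = []
    for when in generate_prompt_times(study_start, study_end, schedule):
        rec = by_time.pop(when, None)
        if rec is None:
            rec = PromptRecord.unanswered(when, slot_of(when, schedule), questionnaire)
        records.append(rec)
    # rows at unscheduled times (off-grid submissions) are kept, sorted in
    for when in sorted(by_time):
        records.append(by_time[when])
    records.sort(key=lambda r: r.scheduled_time)

    return ESMDataset(
        questionnaire=questionnaire, schedule=schedule, records=records,
        study_start=study_start, study_end=study_end)


# ---------------------------------------------------------------------------
# Questionnaire / schedule configs
# ---------------------------------------------------------------------------

def save_questionnaire_config(
    questionnaire: Questionnaire,
    path: Union[str, Path],
    schedule: Optional[PromptSchedule] = None,
) -> Path:
    """Serialize a questionnaire (and optional schedule) to YAML or JSON."""
    path = Path(path)
    doc: dict = {"items": []}
    for item in questionnaire.items:
        entry: dict = {
            "code": item.code,
            "label": item.label,
            "polarity": item.polarity,
            "response_kind": item.response_kind,
            "assessment_window": item.assessment_window,
        }
        if item.likert_max is not None:
            entry["likert_max"] = item.likert_max
        if item.conditional_on is not None:
            entry["conditional_on"] = list(item.conditional_on)
        doc["items"].append(entry)
    if schedule is not None:
        doc["schedule"] = {
            "daily_times": [t.strftime("%H:%M") for t in schedule.daily_times],
            "instruction_window_min": schedule.instruction_window_min,
            "reminder_offset_min": schedule.reminder_offset_min,
            "expiry_offset_min": schedule.expiry_offset_min,
        }
    with path.open("w") as fh:
        if path.suffix.lower() == ".json":
            import json
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
    return path


def load_questionnaire_config(
    path: Union[str, Path],
) -> tuple[Questionnaire, Optional[PromptSchedule]]:
    """Load a questionnaire (and schedule, if present) from YAML/JSON."""
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "items" not in doc:
        raise SchemaError(f"{path}: expected a mapping with an 'items' list")
    items = []
    for entry in doc["items"]:
        if "conditional_on" in entry and entry["conditional_on"] is not None:
            entry = dict(entry)
            entry["conditional_on"] = tuple(entry["conditional_on"])
        items.append(ItemDefinition(**entry))
    questionnaire = Questionnaire(items=tuple(items))
    schedule = None
    if "schedule" in doc:
        s = doc["schedule"]
        times = tuple(dt.time(*map(int, t.split(":"))) for t in s["daily_times"])
        schedule = PromptSchedule(
            daily_times=times,
            instruction_window_min=s.get("instruction_window_min", 15),
            reminder_offset_min=s.get("reminder_offset_min", 30),
            expiry_offset_min=s.get("expiry_offset_min", 60),
        )
    return questionnaire, schedule
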