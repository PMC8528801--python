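import datetime as dt

import pytest

import esmview as ev
from esmview.schema import MISSING, PromptRecord


@pytest.fixture(scope="session")
def questionnaire():
    return ev.build_default_questionnaire()


@pytest.fixture(scope="session")
def schedule():
    return ev.PromptSchedule()


@pytest.fixture(scope="session")
def four_week_dataset():
    """A small but realistic simulated study: 4 weeks, one episode, gaps."""
    cfg = ev.default_config(
        seed=11,
        study_start=dt.date(2017, 3, 6),
        study_end=dt.date(2017, 4, 2),
        episodes=[ev.EpisodeSpec(start_date=dt.date(2017, 3, 13),
                                 end_date=dt.date(2017, 3, 26),
                                 negative_shift=30, positive_shift=20,
                                 ramp_days=2)],
        block_missing_windows=[(dt.date(2017, 3, 29), dt.date(2017, 3, 30))],
    )
    return ev.simulate_dataset(cfg)


def make_record(questionnaire, when, overrides=None, answered=True, comment=None):
    """Hand-build a clean record: neutral defaults, then targeted overrides."""
    values = {}
    for item in questionnaire.items:
        if item.response_kind == "slider_0_100":
            values[item.code] = 50
        elif item.response_kind == "yes_no":
            values[item.code] = "yes"
        elif item.response_kind == "likert_count":
            values[item.code] = 2
        else:
            values[item.code] = MISSING
    if not answered:
        values = {c: MISSING for c in questionnaire.codes}
    values.update(overrides or {})
    return PromptRecord(
        scheduled_time=when,
        slot=ev.slot_of(when, ev.PromptSchedule()),
        answered=answered,
        values=values,
        comment=comment,
    )


def assert_datasets_equal(a, b):
    assert a.study_start == b.study_start and a.study_end == b.study_end
    assert len(a.records) == len(b.records)
    for ra, rb in zip(a.records, b.records):
        assert ra.scheduled_time == rb.scheduled_time
        assert ra.slot == rb.slot
        assert ra.answered == rb.answered
        assert ra.comment == rb.comment
        keys = set(ra.values) | set(rb.values)
        for k in keys:
            va, vb = ra.get(k), rb.get(k)
            assert va is vb or va == vb, (
                f"{ra.scheduled_time} [{k}]: {va!r} != {vb!r}")
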