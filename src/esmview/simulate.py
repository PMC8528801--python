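"""Synthetic single-subject ESM datasets.

The generator emulates a year-long, three-beeps-a-day self-monitoring study:
each item follows an AR(1) latent process on the 0–100 scale around its
baseline mean, relapse episodes shift negative items up and positive items
down with linear on/off ramps, prompts go unanswered at random (plus whole
block-missing windows, like a two-week non-compliance period), occasional
pleasant/unpleasant events carry an intensity, and answered prompts sometimes
get a free-text comment.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .schema import (
    MISSING,
    ESMDataset,
    PromptRecord,
    PromptSchedule,
    Questionnaire,
    build_default_questionnaire,
    slot_of,
)

__all__ = [
    "EpisodeSpec",
    "SimulationConfig",
    "generate_prompt_times",
    "simulate_dataset",
    "default_config",
]


class EpisodeSpec(BaseModel):
    """A relapse-like episode: negative items rise, positive items fall.

    Shifts are in 0–100 scale units and apply to the latent means; the onset
    and offset are linear ramps of ``ramp_days`` days inside the episode.
    """

    model_config = {"frozen": True}

    start_date: dt.date
    end_date: dt.date
    negative_shift: float = Field(ge=0)
    positive_shift: float = Field(ge=0)
    ramp_days: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "EpisodeSpec":
        if self.start_date >= self.end_date:
            raise ValueError("episode start_date must be before end_date")
        return self

    def weight(self, when: dt.datetime) -> float:
        """Ramp weight in [0, 1] at a time point (0 outside the episode)."""
        t = when.date() if isinstance(when, dt.datetime) else when
        if t < self.start_date or t > self.end_date:
            return 0.0
        if self.ramp_days <= 0:
            return 1.0
        up = ((t - self.start_date).days) / self.ramp_days
        down = ((self.end_date - t).days) / self.ramp_days
        return float(min(1.0, up, down)) if min(up, down) < 1 else 1.0


# Default baselines (0-100 latent units).  Negatives sit low with floor
# pile-up at 0 after clipping; positives sit clearly higher — the subject
# typically scores higher on resilience items, rarely above 80.
_DEFAULT_MEANS = {
    "Ctrl": 22.0, "Sad": 25.0, "Intr": 20.0, "Enco": 60.0, "Fun": 50.0,
    "CanDo": 55.0, "Comp": 55.0, "Alon": 15.0, "Cont": 45.0, "ThCon": 25.0,
    "Appo": 28.0, "Canc": 15.0, "Couch": 30.0, "Slep": 62.0, "SlQu": 55.0,
    "Out": 50.0, "Eat": 55.0, "Avoi": 18.0, "Usef": 45.0, "Enjo": 50.0,
    "Pleas": 55.0, "Unpl": 50.0,
}
_DEFAULT_SD = 15.0

#: Latent→probability scale for yes/no items: P(yes) = logistic((x-50)/scale).
_LOGISTIC_SCALE = 15.0


def _default_episodes() -> list[EpisodeSpec]:
    # Two setbacks in a March-to-March year: one peaking late April, one
    # building from late September into a deeper December relapse.
    return [
        EpisodeSpec(start_date=dt.date(2017, 4, 10), end_date=dt.date(2017, 5, 7),
                    negative_shift=30.0, positive_shift=20.0, ramp_days=7.0),
        EpisodeSpec(start_date=dt.date(2017, 9, 18), end_date=dt.date(2017, 12, 24),
                    negative_shift=35.0, positive_shift=25.0, ramp_days=14.0),
    ]


class SimulationConfig(BaseModel):
    """Everything the generator needs; defaults emulate the year-long study."""

    model_config = {"arbitrary_types_allowed": True}

    questionnaire: Questionnaire = Field(default_factory=build_default_questionnaire)
    schedule: PromptSchedule = Field(default_factory=PromptSchedule)
    study_start: dt.date = dt.date(2017, 3, 6)   # a Monday; 52 full ISO weeks
    study_end: dt.date = dt.date(2018, 3, 4)
    item_means: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_MEANS))
    item_sds: dict[str, float] = Field(default_factory=dict)
    default_sd: float = Field(default=_DEFAULT_SD, ge=0)
    phi: float = Field(default=0.4, ge=0, lt=1)
    episodes: list[EpisodeSpec] = Field(default_factory=_default_episodes)
    compliance_prob: float = Field(default=0.9, ge=0, le=1)
    block_missing_windows: list[tuple[dt.date, dt.date]] = Field(
        default_factory=lambda: [(dt.date(2017, 5, 10), dt.date(2017, 5, 23))])
    event_prob: float = Field(default=0.18, ge=0, le=1)
    comment_prob: float = Field(default=0.15, ge=0, le=1)
    comment_templates: list[str] = Field(default_factory=lambda: [
        "A lot of anxiety today, I feel like I am back at square one.",
        "Went for a walk with my parents, that helped.",
        "Busy day at the day programme, but I managed.",
        "Could not stop checking before leaving the house.",
        "Had a nice evening with my boyfriend.",
        "I have to travel soon and it worries me.",
    ])
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.study_start > self.study_end:
            raise ValueError("study_start must be on or before study_end")
        for c, m in self.item_means.items():
            if not 0 <= m <= 100:
                raise ValueError(f"item mean for {c!r} must be in [0,100], got {m}")
        for c, s in self.item_sds.items():
            if s < 0:
                raise ValueError(f"item sd for {c!r} must be >= 0")
        for a, b in self.block_missing_windows:
            if a > b:
                raise ValueError("block-missing window start after end")
        return self

    def mean_of(self, code: str) -> float:
        return self.item_means.get(code, 50.0)

    def sd_of(self, code: str) -> float:
        return self.item_sds.get(code, self.default_sd)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The packaged study conditions with a seed (and optional overrides)."""
    return SimulationConfig(seed=seed, **overrides)


def generate_prompt_times(
    study_start: dt.date, study_end: dt.date, schedule: PromptSchedule
) -> list[dt.datetime]:
    """All scheduled prompt timestamps, sorted: one per (day, daily time)."""
    if study_start > study_end:
        raise ValueError("study_start must be on or before study_end")
    times: list[dt.datetime] = []
    day = study_start
    while day <= study_end:
        for t in schedule.daily_times:
            times.append(dt.datetime.combine(day, t))
        day += dt.timedelta(days=1)
    return times


def _episode_shift(config: SimulationConfig, when: dt.datetime, polarity: str) -> float:
    """Signed latent-mean shift at a time point (+ for negative items)."""
    shift = 0.0
    for ep in config.episodes:
        w = ep.weight(when)
        if w == 0.0:
            continue
        if polarity == "negative":
            shift += w * ep.negative_shift
        elif polarity == "positive":
            shift -= w * ep.positive_shift
    return shift


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise: marginal sd = ``sd`` at every lag."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + eps[t - 1]
    return e


def simulate_dataset(config: SimulationConfig) -> ESMDataset:
    """Generate a full ESM dataset from the configured study conditions.

    Per item ``i`` and prompt ``t`` the latent is
    ``x = mean_i ± episode_shift(t) + e_t`` with AR(1) noise ``e``.
    Sliders observe ``round(clip(x, 0, 100))``; yes/no items draw from a
    logistic transform of the latent; counts bin the clipped latent into
    ``likert_max + 1`` equal-width bins.  Conditional children only exist
    when their parent condition holds; event intensities only when that event
    occurred (each event kind independently with ``event_prob``).  Prompts go
    unanswered with probability ``1 - compliance_prob`` and always inside
    block-missing windows.
    """
    q = config.questionnaire
    rng = np.random.default_rng(config.seed)
    prompt_times = generate_prompt_times(config.study_start, config.study_end, config.schedule)
    n = len(prompt_times)

    # latent AR(1) paths, one per item needing a latent (fixed item order)
    latent: dict[str, np.ndarray] = {}
    for item in q.items:
        if item.response_kind == "free_text":
            continue
        noise = _ar1(rng, n, config.sd_of(item.code), config.phi)
        shifts = np.array([_episode_shift(config, t, item.polarity) for t in prompt_times])
        latent[item.code] = config.mean_of(item.code) + shifts + noise

    answered_draw = rng.random(n)
    event_items = [i.code for i in q.items
                   if i.polarity == "event" and i.response_kind == "slider_0_100"]
    event_draw = {c: rng.random(n) for c in event_items}
    comment_draw = rng.random(n)
    comment_pick = rng.integers(0, max(1, len(config.comment_templates)), size=n)

    def in_block(day: dt.date) -> bool:
        return any(a <= day <= b for a, b in config.block_missing_windows)

    records: list[PromptRecord] = []
    for t_idx, when in enumerate(prompt_times):
        slot = slot_of(when, config.schedule)
        answered = answered_draw[t_idx] < config.compliance_prob and not in_block(when.date())
        if not answered:
            records.append(PromptRecord.unanswered(when, slot, q))
            continue

        values: dict[str, object] = {}
        occurred = {c: event_draw[c][t_idx] < config.event_prob for c in event_items}
        for item in q.items:
            code = item.code
            if item.response_kind == "free_text":
                values[code] = MISSING
                continue
            x = float(latent[code][t_idx])
            if item.polarity == "event":
                if item.response_kind == "yes_no":
                    values[code] = "yes" if any(occurred.values()) else "no"
                else:  # intensity slider, present only when that event occurred
                    values[code] = (
                        int(round(np.clip(x, 0, 100))) if occurred[code] else MISSING
                    )
                continue
            if item.conditional_on is not None:
                parent, required = item.conditional_on
                if values.get(parent) != required:
                    values[code] = MISSING
                    continue
            if item.response_kind == "slider_0_100":
                values[code] = int(round(np.clip(x, 0, 100)))
            elif item.response_kind == "yes_no":
                p = 1.0 / (1.0 + np.exp(-(x - 50.0) / _LOGISTIC_SCALE))
                values[code] = "yes" if rng.random() < p else "no"
            elif item.response_kind == "likert_count":
                n_bins = item.likert_max + 1
                clipped = float(np.clip(x, 0, 100))
                values[code] = min(int(clipped / (100.0 / n_bins)), item.likert_max)

        comment = None
        if comment_draw[t_idx] < config.comment_prob and config.comment_templates:
            comment = config.comment_templates[comment_pick[t_idx]]
        records.append(PromptRecord(
            scheduled_time=when, slot=slot, answered=True, values=values, comment=comment))

    return ESMDataset(
        questionnaire=q,
        schedule=config.schedule,
        records=records,
        study_start=config.study_start,
        study_end=config.study_end,
    )
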