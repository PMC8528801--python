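"""Static figures: circle glyphs, week grids, smoothed timelines, boxplots,
and the all-responses poster.

The circle glyph shows every answer from one prompt at once: the 0–100
slider items sit as nodes on a ring (negative/symptom items on the left
half, positive/resilience items on the right, both starting at 12 o'clock),
each node filled bottom-up in proportion to its score; context and event
answers appear as badges in the middle (an "S" square shaded green by sleep
quality, a "c" square for a cancelled appointment, a digit for the safe-
contact count, shaded "+"/"!" squares for pleasant/unpleasant events); a
free-text comment becomes a text box next to the circle.  By default a grey
node is visually ambiguous between "scored zero" and "not filled in" — the
legend says so — but an opt-in hatch can disambiguate, since the data model
keeps the distinction.
"""

from __future__ import annotations

import datetime as dt
import io as _io
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.backends.backend_pdf import PdfPages
from matplotlib.patches import Circle, Rectangle

from .schema import (
    MISSING,
    ESMDataset,
    PromptRecord,
    Questionnaire,
    SchemaError,
    Slot,
    SLOTS,
)
from . import stats as _stats
from .stats import DEFAULT_BANDWIDTH, SmoothCurve

__all__ = [
    "COLORS",
    "DEFAULT_BADGE_ROLES",
    "NodeSpec",
    "BadgeSpec",
    "CircleGlyphSpec",
    "TimelineSpec",
    "build_circle_spec",
    "render_circle",
    "render_legend",
    "build_week_grid",
    "week_figure",
    "render_week",
    "build_timeline_spec",
    "draw_timeline_panels",
    "timeline_figure",
    "render_timeline",
    "boxplot_figure",
    "render_boxplots",
    "make_poster",
]

#: Default colours (hues overridable; negative pink, positive blue).
COLORS = {
    "negative": "#E8638C",
    "positive": "#4C86C6",
    "missing": "#C9C9C9",
    "sleep_low": "#D9F0D3",
    "sleep_high": "#1B7837",
    "highlight": "#4C86C6",
    "gap": "#BBBBBB",
}

#: Which questionnaire codes feed each centre badge (packaged questionnaire
#: defaults; override for a custom questionnaire).
DEFAULT_BADGE_ROLES: dict[str, tuple[str, ...]] = {
    "company": ("Comp",),
    "contact_count": ("Cont",),
    "cancelled_appointment": ("Canc",),
    "sleep": ("Slep", "SlQu"),
    "pleasant_event": ("Pleas",),
    "unpleasant_event": ("Unpl",),
}


@dataclass(frozen=True)
class NodeSpec:
    """One ring node: a slider item at one prompt."""

    item_code: str
    angle_deg: float          # clockwise from 12 o'clock
    radius_frac: float        # fraction of glyph radius
    fill_fraction: float      # value / 100; 0 when missing
    color: str
    missing: bool


@dataclass(frozen=True)
class BadgeSpec:
    """One centre badge (sleep, company, events, comment marker...)."""

    kind: str
    present: bool
    intensity: Optional[float] = None   # [0,1] shade for sleep/event kinds
    text: str = ""


@dataclass(frozen=True)
class CircleGlyphSpec:
    """Resolved description of one prompt's circle figure."""

    scheduled_time: dt.datetime
    slot: Slot
    nodes: tuple[NodeSpec, ...]
    badges: tuple[BadgeSpec, ...]
    comment: Optional[str]
    answered: bool


@dataclass
class TimelineSpec:
    """Two smoothed panels (negative, positive) plus overlays."""

    negative_curves: list[SmoothCurve]
    positive_curves: list[SmoothCurve]
    raw_series: dict[str, tuple[np.ndarray, np.ndarray]]  # code -> (times, values)
    highlight: Optional[tuple[dt.datetime, dt.datetime]]
    gaps: list[tuple[dt.datetime, dt.datetime, int]]
    bandwidth: float


def ring_item_codes(questionnaire: Questionnaire) -> list[str]:
    """Slider items shown as ring nodes: positive/negative polarity, not
    conditional children (those fold into centre badges)."""
    return [
        i.code for i in questionnaire.items
        if i.response_kind == "slider_0_100"
        and i.polarity in ("positive", "negative")
        and i.conditional_on is None
    ]


# ---------------------------------------------------------------------------
# Glyph specs
# ---------------------------------------------------------------------------

def _num(value) -> Optional[float]:
    if value is MISSING or isinstance(value, str):
        return None
    return float(value)


def build_circle_spec(
    record: PromptRecord,
    questionnaire: Questionnaire,
    badge_roles: Optional[dict[str, tuple[str, ...]]] = None,
    colors: Optional[dict[str, str]] = None,
) -> CircleGlyphSpec:
    """Resolve one prompt record into glyph geometry, colours and badges.

    Deterministic: the same record always yields the same spec.  Negative
    items occupy the left semicircle, positive items the right, both evenly
    spaced from 12 o'clock in questionnaire order; ``fill_fraction`` is the
    score divided by 100.
    """
    colors = {**COLORS, **(colors or {})}
    roles = badge_roles if badge_roles is not None else DEFAULT_BADGE_ROLES
    for kind, codes in roles.items():
        for c in codes:
            if c not in questionnaire:
                raise SchemaError(f"badge {kind!r} refers to unknown item {c!r}")

    ring = [questionnaire.item(c) for c in ring_item_codes(questionnaire)]
    neg = [i for i in ring if i.polarity == "negative"]
    pos = [i for i in ring if i.polarity == "positive"]

    nodes: list[NodeSpec] = []
    for j, item in enumerate(pos):  # right half, top to bottom
        angle = 180.0 * (j + 1) / (len(pos) + 1)
        v = _num(record.get(item.code)) if record.answered else None
        nodes.append(NodeSpec(
            item_code=item.code, angle_deg=angle, radius_frac=1.0,
            fill_fraction=0.0 if v is None else v / 100.0,
            color=colors["positive"], missing=v is None))
    for j, item in enumerate(neg):  # left half, top to bottom
        angle = 360.0 - 180.0 * (j + 1) / (len(neg) + 1)
        v = _num(record.get(item.code)) if record.answered else None
        nodes.append(NodeSpec(
            item_code=item.code, angle_deg=angle, radius_frac=1.0,
            fill_fraction=0.0 if v is None else v / 100.0,
            color=colors["negative"], missing=v is None))

    badges: list[BadgeSpec] = []
    if record.answered:
        def val(kind: str, which: int = 0):
            codes = roles.get(kind, ())
            return record.get(codes[which]) if len(codes) > which else MISSING

        if val("company") == "yes":
            badges.append(BadgeSpec(kind="company", present=True, text="C"))
        cont = _num(val("contact_count"))
        if cont is not None and cont >= 1:
            badges.append(BadgeSpec(kind="contact_count", present=True, text=str(int(cont))))
        if val("cancelled_appointment") == "yes":
            badges.append(BadgeSpec(kind="cancelled_appointment", present=True, text="c"))
        if val("sleep") == "yes":
            quality = _num(val("sleep", 1))
            badges.append(BadgeSpec(
                kind="sleep", present=True, text="S",
                intensity=None if quality is None else quality / 100.0))
        for kind, glyph in (("pleasant_event", "+"), ("unpleasant_event", "!")):
            v = _num(val(kind))
            if v is not None:
                badges.append(BadgeSpec(kind=kind, present=True, text=glyph,
                                        intensity=v / 100.0))
        if record.comment:
            badges.append(BadgeSpec(kind="comment", present=True, text="…"))

    return CircleGlyphSpec(
        scheduled_time=record.scheduled_time,
        slot=record.slot,
        nodes=tuple(nodes),
        badges=tuple(badges),
        comment=record.comment,
        answered=record.answered,
    )


# ---------------------------------------------------------------------------
# Glyph rendering
# ---------------------------------------------------------------------------

_NODE_R = 0.16
_BADGE_POS = {
    "sleep": (-0.42, 0.28),
    "contact_count": (0.0, 0.28),
    "company": (0.42, 0.28),
    "cancelled_appointment": (-0.42, -0.28),
    "pleasant_event": (0.0, -0.28),
    "unpleasant_event": (0.42, -0.28),
    "comment": (0.0, -0.72),
}


def _blend(hex_color: str, white_frac: float) -> tuple[float, float, float]:
    r, g, b = (int(hex_color[i:i + 2], 16) / 255 for i in (1, 3, 5))
    return tuple(c + (1 - c) * white_frac for c in (r, g, b))


def _badge_face(kind: str, intensity: Optional[float], colors: dict[str, str]):
    if intensity is None:
        return "white"
    if kind == "sleep":
        lo = np.array(_blend(colors["sleep_low"], 0.0))
        hi = np.array(_blend(colors["sleep_high"], 0.0))
        return tuple(lo + intensity * (hi - lo))
    base = colors["positive"] if kind == "pleasant_event" else colors["negative"]
    return _blend(base, 1.0 - 0.85 * intensity)


def draw_glyph(
    ax,
    spec: CircleGlyphSpec,
    colors: Optional[dict[str, str]] = None,
    show_labels: bool = False,
    missing_hatch: bool = False,
) -> None:
    """Draw one circle glyph onto an axes (coordinates in [-1.6, 1.6])."""
    colors = {**COLORS, **(colors or {})}
    ax.set_xlim(-1.6, 1.6)
    ax.set_ylim(-1.6, 1.6)
    ax.set_aspect("equal")
    ax.axis("off")

    if not spec.answered:
        ax.add_patch(Circle((0, 0), 1.0, facecolor="none",
                            edgecolor=colors["missing"], linestyle=":", linewidth=1.2))
        ax.text(0, 0, "no\nresponse", ha="center", va="center",
                fontsize=7, color="#777777")
        return

    for node in spec.nodes:
        theta = math.radians(node.angle_deg)
        cx, cy = node.radius_frac * math.sin(theta), node.radius_frac * math.cos(theta)
        base = Circle((cx, cy), _NODE_R, facecolor=colors["missing"],
                      edgecolor=node.color, linewidth=1.1,
                      hatch="////" if (node.missing and missing_hatch) else None)
        ax.add_patch(base)
        if node.fill_fraction > 0:
            fill = Rectangle((cx - _NODE_R, cy - _NODE_R),
                             2 * _NODE_R, 2 * _NODE_R * node.fill_fraction,
                             facecolor=node.color, edgecolor="none")
            fill.set_clip_path(Circle((cx, cy), _NODE_R, transform=ax.transData))
            ax.add_patch(fill)
        if show_labels:
            lx, ly = 1.38 * math.sin(theta), 1.38 * math.cos(theta)
            ax.text(lx, ly, node.item_code, ha="center", va="center", fontsize=6)

    for badge in spec.badges:
        if not badge.present or badge.kind == "comment":
            continue
        x, y = _BADGE_POS[badge.kind]
        side = 0.34
        ax.add_patch(Rectangle((x - side / 2, y - side / 2), side, side,
                               facecolor=_badge_face(badge.kind, badge.intensity, colors),
                               edgecolor="#444444", linewidth=0.8))
        ax.text(x, y, badge.text, ha="center", va="center", fontsize=7, color="black")


def _figure_bytes(fig, fmt: str = "png") -> bytes:
    buf = _io.BytesIO()
    fig.savefig(buf, format=fmt, dpi=100)
    plt.close(fig)
    return buf.getvalue()


def render_circle(
    spec: CircleGlyphSpec,
    size: float = 3.0,
    fmt: str = "png",
    show_labels: bool = True,
    missing_hatch: bool = False,
    colors: Optional[dict[str, str]] = None,
) -> bytes:
    """Render one glyph to image bytes (PNG or SVG); deterministic."""
    fig, ax = plt.subplots(figsize=(size, size * 1.15 if spec.comment else size))
    draw_glyph(ax, spec, colors=colors, show_labels=show_labels,
               missing_hatch=missing_hatch)
    ax.set_title(f"{spec.scheduled_time:%Y-%m-%d %H:%M} ({spec.slot})", fontsize=8)
    if spec.comment:
        ax.text(0, -1.55, spec.comment, ha="center", va="top", fontsize=6,
                wrap=True, bbox=dict(boxstyle="round", facecolor="#FFF8DC",
                                     edgecolor="#999999"))
    return _figure_bytes(fig, fmt)


def render_legend(
    questionnaire: Questionnaire,
    fmt: str = "png",
    colors: Optional[dict[str, str]] = None,
) -> bytes:
    """The always-included legend: node labels, colours, badge meanings, and
    the grey-ambiguity caveat."""
    colors = {**COLORS, **(colors or {})}
    ring = [questionnaire.item(c) for c in ring_item_codes(questionnaire)]
    badge_lines = [
        ("S", "slept since last prompt (darker green = better sleep quality)"),
        ("C", "in company"),
        ("c", "cancelled an appointment"),
        ("1-4", "times in contact with someone who feels safe"),
        ("+", "pleasant event (darker blue = more pleasant)"),
        ("!", "unpleasant event (darker pink = more unpleasant)"),
    ]
    n_rows = len(ring) + len(badge_lines) + 3
    fig, ax = plt.subplots(figsize=(6.5, 0.28 * n_rows + 1))
    ax.axis("off")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, n_rows + 1)
    row = n_rows
    ax.text(0.02, row, "Ring nodes (fill = score / 100):", fontsize=9, weight="bold")
    row -= 1
    for item in ring:
        ax.add_patch(Circle((0.045, row + 0.18), 0.012 * n_rows / 6,
                            facecolor=colors[item.polarity], edgecolor="none",
                            transform=ax.transData, clip_on=False))
        ax.text(0.09, row, f"{item.code} — {item.label}", fontsize=8)
        row -= 1
    ax.text(0.02, row, "Centre badges:", fontsize=9, weight="bold")
    row -= 1
    for glyph, meaning in badge_lines:
        ax.text(0.04, row, glyph, fontsize=8, weight="bold")
        ax.text(0.12, row, meaning, fontsize=8)
        row -= 1
    ax.text(0.02, row,
            "A grey node or absent badge can mean either that the item was not\n"
            "filled in, or that it was indeed scored zero / absent.",
            fontsize=8, style="italic", va="top")
    return _figure_bytes(fig, fmt)


# ---------------------------------------------------------------------------
# Week grid
# ---------------------------------------------------------------------------

def _record_index(dataset: ESMDataset) -> dict[tuple[dt.date, str], PromptRecord]:
    return {(r.date, r.slot): r for r in dataset.records}


def build_week_grid(
    dataset: ESMDataset,
    week_start: dt.date,
    badge_roles: Optional[dict[str, tuple[str, ...]]] = None,
) -> list[list[Optional[CircleGlyphSpec]]]:
    """3 slot rows × 7 weekday columns of glyph specs.

    Columns run from ``week_start``; cells outside the study range are None;
    prompts inside the range with no record become "no response" glyphs.
    """
    if dataset.schedule.prompts_per_day != 3:
        raise SchemaError("week grid requires a 3-prompt daily schedule")
    index = _record_index(dataset)
    grid: list[list[Optional[CircleGlyphSpec]]] = []
    for slot in SLOTS:
        row: list[Optional[CircleGlyphSpec]] = []
        for d in range(7):
            day = week_start + dt.timedelta(days=d)
            if day < dataset.study_start or day > dataset.study_end:
                row.append(None)
                continue
            rec = index.get((day, slot))
            if rec is None:
                when = dt.datetime.combine(
                    day, dataset.schedule.daily_times[SLOTS.index(slot)])
                rec = PromptRecord.unanswered(when, slot, dataset.questionnaire)
            row.append(build_circle_spec(rec, dataset.questionnaire, badge_roles))
        grid.append(row)
    return grid


def _draw_week(fig, subspec, dataset: ESMDataset, week_start: dt.date,
               missing_hatch: bool = False, label_week: bool = True) -> None:
    grid = build_week_grid(dataset, week_start)
    gs = subspec.subgridspec(3, 7, wspace=0.05, hspace=0.05)
    for r in range(3):
        for c in range(7):
            ax = fig.add_subplot(gs[r, c])
            ax.axis("off")
            spec = grid[r][c]
            if spec is not None:
                draw_glyph(ax, spec, missing_hatch=missing_hatch)
                if spec.comment:
                    ax.text(0, -1.5, "[c]", ha="center", fontsize=5,
                            color="#996600")
            if r == 0:
                day = week_start + dt.timedelta(days=c)
                ax.set_title(day.strftime("%a %d %b"), fontsize=6)
            if c == 6:
                ax.text(1.75, 0, SLOTS[r], rotation=270, va="center",
                        fontsize=7, transform=ax.transData)
    if label_week:
        iso = week_start.isocalendar()
        fig.text(subspec.get_position(fig).x0 + 0.005,
                 subspec.get_position(fig).y1 - 0.005,
                 f"week {iso.week}, {iso.year}", fontsize=8, weight="bold",
                 va="top")


def week_figure(dataset: ESMDataset, week_start: dt.date,
                missing_hatch: bool = False):
    """Figure with one week of circle glyphs (weekdays × 3 slots)."""
    fig = plt.figure(figsize=(11, 5))
    gs = fig.add_gridspec(1, 1, top=0.92)
    _draw_week(fig, gs[0], dataset, week_start, missing_hatch=missing_hatch,
               label_week=True)
    return fig


def render_week(dataset: ESMDataset, week_start: dt.date, fmt: str = "png",
                missing_hatch: bool = False) -> bytes:
    return _figure_bytes(week_figure(dataset, week_start, missing_hatch), fmt)


# ---------------------------------------------------------------------------
# Timeline
# ---------------------------------------------------------------------------

def build_timeline_spec(
    dataset: ESMDataset,
    bandwidth: float = DEFAULT_BANDWIDTH,
    highlight: Optional[tuple[dt.datetime, dt.datetime]] = None,
    items: Optional[Sequence[str]] = None,
) -> TimelineSpec:
    """Smooth every positive/negative slider item for the two panels."""
    if highlight is not None:
        lo = dt.datetime.combine(dataset.study_start, dt.time.min)
        hi = dt.datetime.combine(dataset.study_end, dt.time.max)
        if highlight[0] > hi or highlight[1] < lo:
            raise ValueError("highlight window outside the study range")
    frame = dataset.values_frame()
    curves: dict[str, list[SmoothCurve]] = {"negative": [], "positive": []}
    raw: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for polarity in ("negative", "positive"):
        for code in dataset.questionnaire.slider_codes(polarity):
            if items is not None and code not in items:
                continue
            series = frame[code].dropna()
            if len(series) < 3:
                continue
            raw[code] = (series.index.values, series.values)
            curves[polarity].append(_stats.loess_smooth(
                series.index.values, series.values, bandwidth=bandwidth,
                item_code=code))
    n_answered = sum(1 for r in dataset.records if r.answered)
    if n_answered < 3 or not (curves["negative"] or curves["positive"]):
        raise _stats.InsufficientDataError(
            "timeline needs at least 3 answered prompts")
    gaps = _stats.missingness_summary(dataset).gaps
    return TimelineSpec(
        negative_curves=curves["negative"],
        positive_curves=curves["positive"],
        raw_series=raw,
        highlight=highlight,
        gaps=[g for g in gaps if g[2] >= 3],  # mark gaps of a day or more
        bandwidth=bandwidth,
    )


def _shades(base: str, n: int) -> list:
    return [_blend(base, 0.55 * (1 - (i + 1) / n)) for i in range(n)]


def draw_timeline_panels(
    axes,
    spec: TimelineSpec,
    show_raw: bool = False,
    highlight: Optional[tuple[dt.datetime, dt.datetime]] = None,
) -> None:
    """Draw the two smoothed panels onto a pair of axes.

    ``highlight`` overrides the spec's own highlight window (used by the
    movie frames, which re-use one smoothed spec for every week)."""
    hl = highlight if highlight is not None else spec.highlight
    panels = (
        (axes[0], spec.negative_curves, COLORS["negative"], "negative (symptom-related)"),
        (axes[1], spec.positive_curves, COLORS["positive"], "positive (resilience-related)"),
    )
    for ax, curves, base, title in panels:
        shades = _shades(base, max(len(curves), 1))
        for curve, color in zip(curves, shades):
            ax.plot(curve.grid_times, curve.fitted, color=color, linewidth=1.4,
                    label=curve.item_code)
            if show_raw:
                t, v = spec.raw_series[curve.item_code]
                ax.plot(t, v, ".", color=color, markersize=1.5, alpha=0.35)
        for start, end, _n in spec.gaps:
            ax.axvspan(start, end, color=COLORS["gap"], alpha=0.25, linewidth=0)
        if hl is not None:
            ax.axvspan(*hl, color=COLORS["highlight"], alpha=0.25, linewidth=0)
        ax.set_title(title, fontsize=10)
        ax.set_ylim(0, 100)
        ax.legend(fontsize=6, ncol=2, loc="upper right", frameon=False)
        ax.tick_params(axis="x", labelsize=7, rotation=30)
    axes[0].set_ylabel("score (0–100)")


def timeline_figure(
    dataset: ESMDataset,
    bandwidth: float = DEFAULT_BANDWIDTH,
    highlight: Optional[tuple[dt.datetime, dt.datetime]] = None,
    show_raw: bool = False,
    items: Optional[Sequence[str]] = None,
    spec: Optional[TimelineSpec] = None,
):
    """Two-panel LOESS overview: negative items left, positive items right."""
    spec = spec or build_timeline_spec(dataset, bandwidth, highlight, items)
    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=True)
    draw_timeline_panels(axes, spec, show_raw=show_raw, highlight=highlight)
    fig.suptitle(f"Smoothed course of all items (LOESS, bandwidth {spec.bandwidth})",
                 fontsize=11)
    fig.tight_layout()
    return fig


def render_timeline(dataset: ESMDataset, bandwidth: float = DEFAULT_BANDWIDTH,
                    highlight=None, show_raw: bool = False,
                    fmt: str = "png") -> bytes:
    return _figure_bytes(
        timeline_figure(dataset, bandwidth, highlight, show_raw), fmt)


# ---------------------------------------------------------------------------
# Boxplots
# ---------------------------------------------------------------------------

def boxplot_figure(dataset: ESMDataset, ascending: bool = True):
    """Polarity-coloured Tukey boxplots of the always-asked slider items,
    ordered on median within each polarity group.

    Event items, counts and conditional children (not present at every time
    point) are excluded.
    """
    frame = dataset.values_frame()
    codes = ring_item_codes(dataset.questionnaire)
    polarity_of = {c: dataset.questionnaire.item(c).polarity for c in codes}
    summaries = {}
    for code in codes:
        values = frame[code].dropna().values
        if values.size:
            summaries[code] = _stats.boxplot_summary(values, code)
    if not summaries:
        raise _stats.InsufficientDataError("no non-missing slider values")
    order = _stats.order_items_by_median(
        list(summaries.values()),
        {c: polarity_of[c] for c in summaries},
        ascending=ascending,
    )
    bxp_stats = [
        {
            "label": code,
            "med": summaries[code].median,
            "q1": summaries[code].q1,
            "q3": summaries[code].q3,
            "whislo": summaries[code].whisker_low,
            "whishi": summaries[code].whisker_high,
            "fliers": list(summaries[code].outliers),
        }
        for code in order
    ]
    fig, ax = plt.subplots(figsize=(10, 4.5))
    artists = ax.bxp(bxp_stats, patch_artist=True, showfliers=True)
    for patch, code in zip(artists["boxes"], order):
        patch.set_facecolor(COLORS[polarity_of[code]])
        patch.set_alpha(0.8)
    for med in artists["medians"]:
        med.set_color("black")
        med.set_linewidth(2)
    ax.set_ylabel("score (0–100)")
    ax.set_title("Item distributions, ordered on median "
                 "(pink = negative, blue = positive)", fontsize=10)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    return fig


def render_boxplots(dataset: ESMDataset, ascending: bool = True,
                    fmt: str = "png") -> bytes:
    return _figure_bytes(boxplot_figure(dataset, ascending), fmt)


# ---------------------------------------------------------------------------
# Poster
# ---------------------------------------------------------------------------

def study_week_starts(dataset: ESMDataset) -> list[dt.date]:
    """Mondays of every ISO week intersecting the study range."""
    first = dataset.study_start - dt.timedelta(days=dataset.study_start.weekday())
    weeks = []
    w = first
    while w <= dataset.study_end:
        weeks.append(w)
        w += dt.timedelta(days=7)
    return weeks


def make_poster(dataset: ESMDataset, path, weeks_per_page: int = 4,
                missing_hatch: bool = False) -> int:
    """Multi-page PDF of all circle figures, stacked week grids in
    chronological order.  Returns the page count."""
    weeks = study_week_starts(dataset)
    n_pages = math.ceil(len(weeks) / weeks_per_page)
    with PdfPages(path) as pdf:
        for p in range(n_pages):
            chunk = weeks[p * weeks_per_page:(p + 1) * weeks_per_page]
            fig = plt.figure(figsize=(11, 3.2 * len(chunk)))
            gs = fig.add_gridspec(len(chunk), 1, hspace=0.35, top=0.96,
                                  bottom=0.02)
            for i, week_start in enumerate(chunk):
                _draw_week(fig, gs[i], dataset, week_start,
                           missing_hatch=missing_hatch)
            pdf.savefig(fig)
            plt.close(fig)
    return n_pages
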