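"""Per-week movie frames, video encoding, and the standalone feedback report.

Each movie frame pairs the macro view (the full-study smoothed timeline with
a translucent blue overlay on one week) with the micro view (that week's
circle-glyph grid), so overall trends and single measurements can be read
together.  Frames encode to an animated GIF (or MP4 where an ffmpeg backend
is available).  The interactive report is a single self-contained HTML file
— all data and images embedded, no server, no network assets — with
client-side toggles for item visibility, comments, a zoom window, and a
raw-data overlay.
"""

from __future__ import annotations

import base64
import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
import matplotlib.pyplot as plt
from pydantic import BaseModel

from .schema import ESMDataset
from .stats import DEFAULT_BANDWIDTH
from . import viz

__all__ = [
    "FrameSpec",
    "ReportToggles",
    "VideoEncoderUnavailableError",
    "build_week_frames",
    "render_frame",
    "encode_video",
    "make_movie",
    "build_report",
]


class VideoEncoderUnavailableError(RuntimeError):
    """MP4 requested but no ffmpeg backend is importable."""


@dataclass(frozen=True)
class FrameSpec:
    """One movie frame: a study week and its timeline-overlay window."""

    week_index: int
    week_start: dt.date

    @property
    def week_end(self) -> dt.date:
        return self.week_start + dt.timedelta(days=6)

    @property
    def highlight(self) -> tuple[dt.datetime, dt.datetime]:
        return (
            dt.datetime.combine(self.week_start, dt.time.min),
            dt.datetime.combine(self.week_end, dt.time.max),
        )


def build_week_frames(dataset: ESMDataset,
                      bandwidth: float = DEFAULT_BANDWIDTH) -> list[FrameSpec]:
    """One frame per ISO week intersecting the study range, chronological."""
    del bandwidth  # geometry only; smoothing happens at render time
    return [
        FrameSpec(week_index=i, week_start=w)
        for i, w in enumerate(viz.study_week_starts(dataset))
    ]


def render_frame(
    dataset: ESMDataset,
    frame: FrameSpec,
    timeline_spec: Optional[viz.TimelineSpec] = None,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> np.ndarray:
    """Compose one frame (timeline on top, week grid below) as an RGB array.

    Pass a precomputed ``timeline_spec`` when rendering many frames so the
    LOESS fits are done once.
    """
    spec = timeline_spec or viz.build_timeline_spec(dataset, bandwidth)
    fig = plt.figure(figsize=(11, 8), dpi=100)
    gs = fig.add_gridspec(2, 1, height_ratios=[1.0, 1.15], hspace=0.25,
                          top=0.95, bottom=0.03)
    top = gs[0].subgridspec(1, 2, wspace=0.08)
    axes = [fig.add_subplot(top[0]), fig.add_subplot(top[1])]
    viz.draw_timeline_panels(axes, spec, highlight=frame.highlight)
    viz._draw_week(fig, gs[1], dataset, frame.week_start)
    fig.canvas.draw()
    buf = np.asarray(fig.canvas.buffer_rgba())[:, :, :3].copy()
    plt.close(fig)
    return buf


def encode_video(frames: Sequence[np.ndarray], fps: float,
                 path: Union[str, Path]) -> Path:
    """Write frames as GIF (default) or MP4 at ``fps`` frames per second.

    MP4 needs an ffmpeg backend; without one a
    :class:`VideoEncoderUnavailableError` explains the ``.gif`` fallback.
    """
    if not frames:
        raise ValueError("need at least one frame")
    if fps <= 0:
        raise ValueError("fps must be positive")
    path = Path(path)
    stack = np.stack([np.asarray(f) for f in frames])
    if path.suffix.lower() == ".gif":
        iio.imwrite(path, stack, duration=1000.0 / fps, loop=0)
        return path
    if path.suffix.lower() == ".mp4":
        try:
            import imageio  # legacy writer API routes to the ffmpeg plugin
            writer = imageio.get_writer(str(path), format="FFMPEG", fps=fps)
        except Exception as exc:
            raise VideoEncoderUnavailableError(
                "MP4 encoding needs an ffmpeg backend (imageio-ffmpeg); "
                "write a .gif file instead for the built-in fallback"
            ) from exc
        with writer:
            for f in stack:
                writer.append_data(f)
        return path
    raise ValueError(f"unsupported video format {path.suffix!r} (use .gif or .mp4)")


def make_movie(
    dataset: ESMDataset,
    path: Union[str, Path],
    fps: float = 1.0,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> tuple[Path, int]:
    """Render every weekly frame and encode the movie; returns (path, n_frames)."""
    frames = build_week_frames(dataset, bandwidth)
    spec = viz.build_timeline_spec(dataset, bandwidth)
    images = [render_frame(dataset, f, timeline_spec=spec) for f in frames]
    return encode_video(images, fps, path), len(images)


# ---------------------------------------------------------------------------
# Interactive report
# ---------------------------------------------------------------------------

class ReportToggles(BaseModel):
    """Initial state of the report's client-side controls."""

    show_comments: bool = True
    visible_items: Optional[list[str]] = None   # None = all items
    zoom_window: Optional[tuple[dt.date, dt.date]] = None
    show_raw_overlay: bool = False


_REPORT_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>ESM feedback report</title>
<style>
 body {{ font-family: sans-serif; margin: 1.5em; max-width: 1100px; }}
 .panels {{ display: flex; gap: 1em; }}
 canvas {{ border: 1px solid #ccc; }}
 .controls label {{ margin-right: 1em; font-size: 0.9em; }}
 .neg {{ color: #E8638C; }} .pos {{ color: #4C86C6; }}
 .comment {{ background: #FFF8DC; border: 1px solid #ddd; margin: 0.3em 0;
             padding: 0.3em 0.6em; font-size: 0.85em; }}
 details img {{ max-width: 100%; }}
</style>
</head>
<body>
<h1>ESM feedback report</h1>
<p>Smoothed course of the diary items (LOESS, bandwidth {bandwidth}).
Left: negative (symptom-related) items. Right: positive (resilience-related)
items. Use the controls to toggle items, comments, the raw-data overlay, or
to zoom to a period.</p>
<div class="controls" id="itemboxes"></div>
<div class="controls">
 <label><input type="checkbox" id="rawToggle"> raw data overlay</label>
 <label><input type="checkbox" id="commentToggle"> comments</label>
 <label>zoom from <input type="date" id="zoomStart"> to
        <input type="date" id="zoomEnd"></label>
</div>
<div class="panels">
 <div><h3 class="neg">negative</h3><canvas id="negCanvas" width="520" height="300"></canvas></div>
 <div><h3 class="pos">positive</h3><canvas id="posCanvas" width="520" height="300"></canvas></div>
</div>
<div id="comments"></div>
<h2>Week-by-week circle figures</h2>
{weeks_html}
<script>
const DATA = {payload};
function draw() {{
  const zs = Date.parse(document.getElementById('zoomStart').value) || DATA.t_min;
  const ze = Date.parse(document.getElementById('zoomEnd').value) || DATA.t_max;
  const showRaw = document.getElementById('rawToggle').checked;
  for (const pol of ['negative', 'positive']) {{
    const cv = document.getElementById(pol === 'negative' ? 'negCanvas' : 'posCanvas');
    const ctx = cv.getContext('2d');
    ctx.clearRect(0, 0, cv.width, cv.height);
    const X = t => 40 + (t - zs) / (ze - zs) * (cv.width - 50);
    const Y = v => (cv.height - 20) * (1 - v / 100) + 5;
    ctx.strokeStyle = '#888';
    ctx.strokeRect(40, 5, cv.width - 50, cv.height - 25);
    for (const item of DATA.items) {{
      if (item.polarity !== pol) continue;
      const box = document.getElementById('item_' + item.code);
      if (box && !box.checked) continue;
      ctx.strokeStyle = item.color; ctx.lineWidth = 1.5; ctx.beginPath();
      let started = false;
      for (let i = 0; i < item.t.length; i++) {{
        if (item.t[i] < zs || item.t[i] > ze) continue;
        const x = X(item.t[i]), y = Y(item.fit[i]);
        if (!started) {{ ctx.moveTo(x, y); started = true; }} else ctx.lineTo(x, y);
      }}
      ctx.stroke();
      if (showRaw) {{
        ctx.fillStyle = item.color;
        for (let i = 0; i < item.raw_t.length; i++) {{
          if (item.raw_t[i] < zs || item.raw_t[i] > ze) continue;
          ctx.fillRect(X(item.raw_t[i]), Y(item.raw_v[i]), 2, 2);
        }}
      }}
    }}
  }}
  const cdiv = document.getElementById('comments');
  const showC = document.getElementById('commentToggle').checked;
  cdiv.innerHTML = '';
  if (showC) {{
    for (const c of DATA.comments) {{
      if (Date.parse(c.t) < zs || Date.parse(c.t) > ze) continue;
      const d = document.createElement('div');
      d.className = 'comment';
      d.textContent = c.t + ' — ' + c.text;
      cdiv.appendChild(d);
    }}
  }}
}}
const boxes = document.getElementById('itemboxes');
for (const item of DATA.items) {{
  const lab = document.createElement('label');
  lab.className = item.polarity === 'negative' ? 'neg' : 'pos';
  const cb = document.createElement('input');
  cb.type = 'checkbox'; cb.id = 'item_' + item.code; cb.checked = true;
  cb.addEventListener('change', draw);
  lab.appendChild(cb); lab.appendChild(document.createTextNode(item.code));
  boxes.appendChild(lab);
}}
document.getElementById('rawToggle').checked = DATA.show_raw;
document.getElementById('commentToggle').checked = DATA.show_comments;
if (DATA.zoom) {{
  document.getElementById('zoomStart').value = DATA.zoom[0];
  document.getElementById('zoomEnd').value = DATA.zoom[1];
}}
for (const id of ['rawToggle', 'commentToggle', 'zoomStart', 'zoomEnd'])
  document.getElementById(id).addEventListener('change', draw);
draw();
</script>
</body>
</html>
"""


def build_report(
    dataset: ESMDataset,
    toggles: Optional[ReportToggles] = None,
    path: Union[str, Path] = "report.html",
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> Path:
    """Write the self-contained interactive HTML feedback report.

    The curves embedded in the report are computed by the stats module (the
    same LOESS path as the static timeline); week grids are embedded as
    base64 PNG data URIs, so the file needs no server or network access.
    ``toggles.show_comments=False`` omits comment text from the document
    entirely; ``visible_items`` restricts which curves are embedded.
    """
    toggles = toggles or ReportToggles()
    if toggles.visible_items is not None:
        unknown = [c for c in toggles.visible_items if c not in dataset.questionnaire]
        if unknown:
            raise ValueError(f"visible_items not in questionnaire: {unknown}")
    spec = viz.build_timeline_spec(dataset, bandwidth, items=toggles.visible_items)

    items_payload = []
    for polarity, curves in (("negative", spec.negative_curves),
                             ("positive", spec.positive_curves)):
        shades = viz._shades(viz.COLORS[polarity], max(len(curves), 1))
        for curve, rgb in zip(curves, shades):
            raw_t, raw_v = spec.raw_series[curve.item_code]
            color = "#%02x%02x%02x" % tuple(int(255 * c) for c in rgb)
            to_ms = lambda arr: [int(t) for t in
                                 np.asarray(arr, dtype="datetime64[ms]").astype("int64")]
            items_payload.append({
                "code": curve.item_code,
                "polarity": polarity,
                "color": color,
                "t": to_ms(curve.grid_times),
                "fit": [round(float(v), 4) for v in curve.fitted],
                "raw_t": to_ms(raw_t),
                "raw_v": [float(v) for v in raw_v],
            })

    comments = []
    if toggles.show_comments:
        comments = [
            {"t": r.scheduled_time.strftime("%Y-%m-%d %H:%M"), "text": r.comment}
            for r in dataset.records if r.comment
        ]

    weeks_html = []
    for week_start in viz.study_week_starts(dataset):
        png = viz.render_week(dataset, week_start)
        b64 = base64.b64encode(png).decode("ascii")
        iso = week_start.isocalendar()
        weeks_html.append(
            f"<details><summary>week {iso.week}, {iso.year} "
            f"(from {week_start})</summary>"
            f'<img src="data:image/png;base64,{b64}" '
            f'alt="week {iso.week}"></details>'
        )

    t_lo = dt.datetime.combine(dataset.study_start, dt.time.min)
    t_hi = dt.datetime.combine(dataset.study_end, dt.time.max)
    payload = {
        "items": items_payload,
        "comments": comments,
        "t_min": int(np.datetime64(t_lo, "ms").astype("int64")),
        "t_max": int(np.datetime64(t_hi, "ms").astype("int64")),
        "show_raw": toggles.show_raw_overlay,
        "show_comments": toggles.show_comments,
        "zoom": [str(toggles.zoom_window[0]), str(toggles.zoom_window[1])]
        if toggles.zoom_window else None,
    }

    path = Path(path)
    path.write_text(_REPORT_TEMPLATE.format(
        bandwidth=bandwidth,
        payload=json.dumps(payload),
        weeks_html="\n".join(weeks_html),
    ), encoding="utf-8")
    return path
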