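"""Macro + micro together: the weekly movie and the interactive report.

Each movie frame shows the full-study smoothed timeline with a blue overlay
on one week (macro) above that week's circle-figure grid (micro).  The
report is one self-contained HTML file with client-side toggles: items on/
off, comments on/off, raw-data overlay, and a zoom window.
"""

import datetime as dt
from pathlib import Path

import esmview as ev

out = Path("scratch/examples")
out.mkdir(parents=True, exist_ok=True)

dataset = ev.simulate_dataset(ev.default_config(
    seed=7, study_start=dt.date(2017, 3, 6), study_end=dt.date(2017, 4, 30)))

path, n_frames = ev.make_movie(dataset, out / "movie.gif", fps=1.0)
print(f"wrote {path}: {n_frames} frames (one per study week) at 1 frame/s")

report = ev.build_report(
    dataset,
    ev.ReportToggles(show_comments=True, show_raw_overlay=False),
    out / "report.html",
)
size_kb = report.stat().st_size // 1024
print(f"wrote {report} ({size_kb} kB, fully self-contained — open in any browser)")
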