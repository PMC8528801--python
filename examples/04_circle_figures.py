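"""The micro view: one prompt's circle figure, the legend, and a week grid.

Every answer from a single beep in one glyph: slider items as ring nodes
(fill = score/100, pink negative left, blue positive right), context and
events as centre badges, the free-text comment as a text box.  A week grid
stacks 21 of these (3 slots x 7 weekdays) so good and bad days jump out.
"""

import datetime as dt
from pathlib import Path

import esmview as ev

out = Path("scratch/examples")
out.mkdir(parents=True, exist_ok=True)

dataset = ev.simulate_dataset(ev.default_config(
    seed=7, study_start=dt.date(2017, 3, 6), study_end=dt.date(2017, 4, 2)))

record = next(r for r in dataset.records if r.answered and r.comment)
spec = ev.build_circle_spec(record, dataset.questionnaire)
filled = {n.item_code: round(n.fill_fraction, 2) for n in spec.nodes if not n.missing}
print(f"prompt {record.scheduled_time:%Y-%m-%d %H:%M} ({record.slot})")
print(f"node fill fractions (= score/100): {filled}")
print(f"centre badges: {[b.kind + ':' + b.text for b in spec.badges]}")
print(f"comment: {record.comment!r}")

(out / "circle.png").write_bytes(ev.render_circle(spec))
(out / "legend.png").write_bytes(ev.render_legend(dataset.questionnaire))
(out / "week.png").write_bytes(ev.render_week(dataset, dt.date(2017, 3, 13)))
pages = ev.make_poster(dataset, out / "poster.pdf")
print(f"wrote circle.png, legend.png, week.png and poster.pdf ({pages} pages)")
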