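"""Quick overview of item variation: Tukey boxplot summaries.

Five-number summaries with 1.5 x IQR whisker fences per item, ordered on
median within the negative (symptom) and positive (resilience) groups —
the at-a-glance check of where the subject usually sits on each item.
"""

import datetime as dt
from pathlib import Path

import esmview as ev
from esmview import stats, viz

out = Path("scratch/examples")
out.mkdir(parents=True, exist_ok=True)

dataset = ev.simulate_dataset(ev.default_config(
    seed=7, study_start=dt.date(2017, 3, 6), study_end=dt.date(2017, 5, 28)))
frame = dataset.values_frame()

summaries = {}
for code in viz.ring_item_codes(dataset.questionnaire):
    summaries[code] = stats.boxplot_summary(frame[code].dropna().values, code)

polarity = {c: dataset.questionnaire.item(c).polarity for c in summaries}
order = stats.order_items_by_median(list(summaries.values()), polarity)

print(f"{'item':<6} {'pol':<9} {'n':>4} {'median':>7} {'q1':>6} {'q3':>6} {'outliers':>8}")
for code in order:
    s = summaries[code]
    print(f"{code:<6} {polarity[code]:<9} {s.n:>4} {s.median:>7.1f} "
          f"{s.q1:>6.1f} {s.q3:>6.1f} {len(s.outliers):>8}")

png = out / "boxplots.png"
png.write_bytes(ev.render_boxplots(dataset))
print(f"\nwrote {png}; medians rise left-to-right within each colour group,")
print("so the leftmost pink item is the least-endorsed symptom.")
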