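"""Do the visual peaks correspond to the built-in relapses?

The year-long default study contains two episodes in which negative items
rise and positive items fall.  flag_episodes smooths the negative composite
and flags sustained excursions above median + 2 x robust sd — a descriptive
stand-in for spotting relapse periods by eye in the timeline.
"""

import esmview as ev

config = ev.default_config(seed=7, default_sd=10.0)
dataset = ev.simulate_dataset(config)

print("true episodes (simulator ground truth):")
for e in config.episodes:
    print(f"  {e.start_date} .. {e.end_date}  (negative +{e.negative_shift:g}, "
          f"positive -{e.positive_shift:g})")

windows = ev.flag_episodes(dataset)
print("flagged windows (smoothed negative composite above threshold):")
for w in windows:
    hits = [e for e in config.episodes if w.overlaps(e.start_date, e.end_date)]
    tag = "matches a true episode" if hits else "FALSE ALARM"
    print(f"  {w.start} .. {w.end}  -> {tag}")
print(f"{len(windows)} window(s) flagged for {len(config.episodes)} true episodes.")
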