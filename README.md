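# esmview

Dynamic visualization of **single-subject experience-sampling (ESM/EMA)
time series** for descriptive clinical feedback.

In an ESM study a participant — here modelled on a year-long self-monitoring
protocol in obsessive–compulsive disorder — answers a short questionnaire on
their phone several times a day at fixed beeps. The resulting intensive
longitudinal dataset (23 mixed-type items × 3 prompts/day × 52 weeks) is too
rich for means and bar charts: summary feedback hides the dynamics, and
inferential time-series models (VAR networks) are hard to interpret and
fragile at these sample sizes. `esmview` takes the opposite route and gives
the *raw data* back to patient and therapist in layered visual form:

- **Boxplots** per item — Tukey five-number summaries, whiskers at the most
  extreme data point within 1.5 × IQR of the hinges, ordered on median,
  coloured by polarity (pink = symptom-related "negative" items, blue =
  resilience-related "positive" items).
- **Smoothed timeline** — per item *i*, a LOESS fit
  ŷ_i(t) = local degree-1 WLS over the ⌈α·n⌉ nearest prompts with tricube
  weights w = (1 − (d/d_max)³)³, default span α = 0.2, time measured in days.
- **Circle figure** — one glyph per prompt: slider items as ring nodes with
  fill fraction v/100 (negative arc left, positive arc right), context and
  events as centre badges (sleep "S" shaded green by quality, cancelled
  appointment "c", safe-contact count, shaded pleasant/unpleasant event
  marks), free-text comments as a text box. Week grids (3 slots × 7
  weekdays) and a paginated all-responses poster stack these over time.
- **Movie & report** — per-week frames pairing the timeline (blue overlay on
  the week) with that week's grid, encoded as GIF/MP4; plus a single-file
  interactive HTML report with client-side toggles (items, comments, raw
  overlay, zoom).
- **Missingness is first-class** — unanswered prompts are materialized as
  explicit records, drawn as "no response" glyphs and grey axis spans, and a
  `MISSING` value is kept distinct from a score of 0 or a "no".
- **Episode flagging** — a descriptive detector for relapse-like periods:
  flag maximal windows where the LOESS-smoothed negative composite exceeds
  median + k·(1.4826·MAD), k = 2, for ≥ 7 days.

A seeded **simulator** generates realistic studies (AR(1) latent dynamics,
relapse episodes with linear ramps, compliance gaps, events, comments) so
every stage is testable without patient data.

## Worked example

`python examples/05_episode_flagging.py` simulates the default year-long
study (two built-in relapse episodes, σ = 10 so shifts are ≥ 3σ) and asks
whether the flagged peaks correspond to the ground truth:

```
true episodes (simulator ground truth):
  2017-04-10 .. 2017-05-07  (negative +30, positive -20)
  2017-09-18 .. 2017-12-24  (negative +35, positive -25)
flagged windows (smoothed negative composite above threshold):
  2017-04-13 .. 2017-05-09  -> matches a true episode
  2017-09-19 .. 2017-12-23  -> matches a true episode
2 window(s) flagged for 2 true episodes.
```

Both sustained elevations of the symptom items are recovered within a few
days of their true onsets, with no false alarms. The other scripts in
`examples/` walk through simulation and validation, the boxplot overview,
timeline smoothing (including the over-smoothing caveat), circle figures,
and the movie/report builders, each printing what it computes.

The same pipeline is scriptable from the shell:

```bash
esmview simulate --seed 1 --weeks 8 --out d.csv
esmview validate d.csv
esmview timeline d.csv --out timeline.png --bandwidth 0.2
esmview week d.csv --start 2017-03-06 --out week.png
esmview movie d.csv --out movie.gif --fps 1
esmview report d.csv --out report.html
```

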