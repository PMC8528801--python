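# Methods

This note records the models, conventions and numerical choices behind
`esmview`, in the spirit of a statistical package's methods appendix.

## Data model

A study is a `Questionnaire` (ordered items), a `PromptSchedule` and one
`PromptRecord` per scheduled prompt. Items carry a *polarity* (positive /
negative / neutral / event), a *response kind* (0–100 slider, yes/no,
bounded count, free text) and optional *conditionality* (e.g. sleep quality
is only asked after "slept = yes"). The packaged default questionnaire has
23 items: 9 negative symptom items, 9 positive resilience items (including
the 0–4 safe-contact count and the conditional sleep-quality slider), 2
neutral context items, and 3 event items (occurrence plus pleasant /
unpleasant intensities, which may co-occur).

Conventions, chosen where the protocol itself is silent:

- **Missingness.** `MISSING` is a sentinel distinct from 0 and from "no".
  Unanswered prompts are materialized as explicit records at read time (they
  are never stored in the CSV), so downstream code always sees the full
  prompt lattice. Renderers default to the grey-means-zero-or-missing
  convention with a legend caveat; an opt-in hatch disambiguates.
- **Time.** Timestamps are timezone-naive wall-clock times; DST is ignored
  because prompts are nominal clock times. Weeks are ISO weeks starting
  Monday. A prompt's slot (morning/afternoon/evening) is the nearest of the
  three daily times, ties to the earlier; this requires exactly 3 daily
  times because the week grid has 3 rows.
- **Duplicates.** One record per (date, slot); a duplicate submission keeps
  the first (the delivery link deactivates after 60 min, so later rows are
  anomalies) and the validator flags any survivors.
- **Serialization.** Canonical format is RFC-4180 CSV, wide orientation
  (one row per answered prompt — the circle figure's unit of display); a
  long orientation is supported and row-order insensitive. Yes/no is written
  as `yes`/`no`, never 0/1, to avoid collision with counts. Validation
  problems are *findings*, not exceptions; only structural damage (unknown
  item code, unparseable timestamp) raises.

## Synthetic studies

The generator's defaults emulate a 52-week, three-beeps-a-day protocol
(prompts 09:00/15:00/21:00; 15-min instruction window, 30-min reminder,
60-min link expiry) with:

- **Latent dynamics.** Per item, x_t = μ_i + s_i(t) + e_t with stationary
  AR(1) noise e_t = φ·e_{t−1} + ε, ε ~ N(0, σ_i√(1−φ²)), so the marginal sd
  is σ_i at every lag. Defaults φ = 0.4, σ = 15, negative means ≈ 15–30 and
  positive means ≈ 45–60: the subject scores clearly higher on resilience
  items, rarely above 80, with floor pile-up at 0 on symptom items after
  clipping. AR(1) is the minimal structure that produces the smooth
  multi-week trends a LOESS timeline is designed to show; these defaults are
  qualitative emulation, not claims about any real patient.
- **Observation.** Sliders observe round(clip(x, 0, 100)) — clipping before
  rounding keeps the boundary pile-up. Yes/no items draw from
  P(yes) = logistic((x − 50)/15); counts bin the clipped latent into
  likert_max + 1 equal-width bins. Conditional children are generated only
  when the parent condition holds; each event kind occurs independently with
  `event_prob` and then carries a slider-like intensity.
- **Episodes.** A relapse-like `EpisodeSpec` adds `negative_shift` to
  negative means and subtracts `positive_shift` from positive means, with
  linear on/off ramps (`ramp_days`) for the gradual build-up and ebb of a
  real setback. The default year contains two: a four-week episode peaking
  late April and a three-month episode building from late September into
  December.
- **Missingness & texture.** Prompts are unanswered with probability
  1 − compliance (default 0.9) and always inside block-missing windows
  (default: two weeks in mid-May); answered prompts get a templated
  free-text comment with probability 0.15.

Everything derives from one integer seed. What the simulator does *not*
emulate: cross-item lagged dependence (no VAR structure), time-of-day
cycles, reactivity/drift in response style, and informative missingness
(gaps are independent of symptom level). Tests passing on synthetic data
therefore certify the pipeline's mechanics and the detector's behaviour
under the stated conditions, not clinical validity on real diaries.

## Descriptive statistics

- **Boxplots.** Quartiles by linear interpolation between order statistics
  (the common statistical-software default); whiskers are the most extreme
  *data points* within 1.5 × IQR of the hinges; everything beyond is an
  outlier. Edge case: in tiny samples where every point above a hinge is an
  outlier, the interpolated q3 can exceed the whisker — the standard
  definition is kept rather than clamping. Ordering is by median within
  polarity group, ascending by default (exposed as an option, since the
  display convention could be read either way), ties alphabetical.
- **LOESS.** The classical definition: at each grid point, degree-1
  weighted least squares over the k = ⌈α·n⌉ nearest observations by time
  distance, tricube weights, **no robustness iterations**; default span
  α = 0.2; evaluation grid defaults to the observation times. Time distance
  is in days, so same-day prompts at 09:00 and 21:00 are 0.5 day apart.
  Degenerate windows (zero time spread or all-zero weights) fall back to the
  (weighted) mean. Fewer than 3 non-missing points is an error. Equidistant
  ties at the window boundary are harmless: boundary points have tricube
  weight 0, so the fit does not depend on which of them enters the window.
- **Composites.** Per prompt, the mean of the available slider items of one
  polarity; missing if none are available. No reweighting for missing items.
- **Episode flagging.** Smooth the negative composite at the default span,
  then flag maximal runs above median + k·(1.4826·MAD) of the smoothed
  series lasting ≥ `min_days`. Median/MAD rather than mean/sd so that the
  episodes themselves do not inflate the threshold. Defaults k = 2,
  min_days = 7: a week-long sustained elevation two robust sd above the
  typical level. This is a descriptive aid mirroring what a clinician does
  by eye on the timeline, not a change-point model.

## Figures

- **Circle glyph.** Ring nodes are the always-asked positive/negative
  sliders (15 in the default questionnaire); conditional intensity sliders
  (sleep quality, event intensities) fold into their centre badges so that
  every scored value appears exactly once. Negative arc on the left half,
  positive on the right, both starting at 12 o'clock, evenly spaced in
  questionnaire order (the exact per-item angles are a package convention).
  Node fill is bottom-up, fraction v/100. Unanswered prompts render an
  explicit dashed "no response" placeholder, not an all-grey circle, to
  reduce grey ambiguity inside week grids. Colours (pink #E8638C, blue
  #4C86C6, green ramp for sleep) are nameable hues, all overridable.
- **Determinism.** All rendering uses the Agg backend with fixed sizes and
  fonts; identical specs yield byte-identical PNGs (asserted in tests).
- **Timeline.** Two panels sharing the y-axis (0–100): negative items left,
  positive right, per-item shade ramps of the polarity hue. Gaps of ≥ 3
  consecutive unanswered prompts (a full day) are marked as grey spans; an
  optional raw-point overlay addresses the over-smoothing caveat.
- **Poster / movie / report.** The poster stacks week grids, 4 per page
  (⌈n_weeks/4⌉ pages). Movie frames pair the full-study timeline (blue
  overlay on one week) with that week's grid; GIF is the default encoder
  because it needs no external binary, MP4 is attempted via an ffmpeg
  backend and fails with an actionable message naming the GIF fallback.
  Default playback 1 frame (week) per second, exposed as `--fps`. The
  report is a single HTML file: curves come from the same LOESS code path
  as the static timeline and are embedded as JSON; week grids as base64
  PNGs; toggles (item visibility, comments, raw overlay, zoom) are ~100
  lines of vanilla JavaScript drawing on a canvas — a deliberately
  dependency-free replacement for a live server app. Zoom redraws curves
  client-side from the embedded data; axis ticks are fixed labels.

## Problem sizes used in the checked examples

The test suite exercises 2–8-week simulated studies for rendering and I/O,
a full 52-week study for autocorrelation and episode recovery, 1000 random
inputs for the boxplot oracle, and 50 seeded year-long studies (σ = 10, two
≥ 3σ episodes) for the precision/recall suite; the acceptance script uses
the same sizes. These sizes make the whole suite run in about a minute
while keeping every Monte-Carlo margin wide.

## Known limitations

- Polarity assignment for a new questionnaire is a clinical judgement; the
  packaged assignment is a sensible default and fully overridable in the
  schema config.
- Badge layout supports the packaged item roles; a questionnaire with a
  different context/event structure needs a custom `badge_roles` mapping.
- The episode detector assumes elevations of the *negative* composite;
  pure loss-of-positive episodes register only through the composite's
  negative items.
- Timelines with many items (≈ 10+ per panel) become hard to read; the
  report's item toggles are the intended remedy.
- `slot_of` and the week grid are hard-wired to 3 prompts/day; other
  schedules are rejected rather than mis-rendered.
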