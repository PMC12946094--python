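# Methods

This note records the model, the parameters that matter, and the design
choices made where the design was genuinely open.

## The analysis model

The pipeline treats activity→glucose coupling purely *directionally*: it
never estimates the magnitude of a glucose excursion, only whether the
trend after an instant is consistent with the presence of non-standard
physical activity (PA) before it. All quantities are finite differences of
windowed summaries, so the only modelling commitments are:

* **Windowing.** Both streams are reduced to windows of width
  t ∈ {20, 40, 60} min summarised by the in-window standard deviation.
  Windows are half-open `(start, end]` and labelled by their right edge —
  the window covering 10:00:15–10:20:00 is reported at 10:20:00 — because
  an epoch stamped at time τ summarises the sensing interval ending at τ.
  The std is the sample (n−1) flavour; a `ddof=0` switch exists for
  sensitivity analysis. A window left with a single epoch after cleaning
  has an undefined sample std and is excluded at the merge, which also
  drops any window present on only one side.
* **Gradient basis.** The glucose quantity differenced into gradients is
  the window's *level* (last in-window reading) by default, with the
  windowed *std* available behind `basis="std"`. The level basis is the
  default because the method's one canonical worked number
  (7.0 → 6.5 mmol/L over 20 min ⇒ −0.025 mmol/L/min) differences
  concentration; reproducing that number fixes the default. Activity is
  always differenced on the windowed std.
* **Personal baseline.** "Non-standard" PA is a strictly-greater-than
  comparison of the window's activity std against the mean over *all*
  daytime windows of the participant's record. Strict inequality makes
  ties standard (conservative: fewer positives). The whole-record scope
  reflects that the reference is a *habitual* level pooled over the 5–8
  recorded days; a per-day baseline can be had by slicing the input.
  An `activity_gradient` basis is provided as an alternative.
* **Eligibility and the dead zone.** An instant x is evaluated under H1
  iff g_prev < −ε and under H2 iff g_prev > +ε; |g_prev| ≤ ε is evaluated
  under neither, so the hypotheses are disjoint by construction. The same
  ε bounds the "same" change category: d = g_prev − g_post (H1) or
  g_post − g_prev (H2), with increase for d > ε, decrease for d < −ε.
  Default ε = 0.005 mmol/L/min — one CGM quantisation step (0.1 mmol/L)
  spread over a 20 min window. Instants slide window-by-window; every
  eligible instant yields exactly one event.
* **PA attribution.** The PA category at instant x is that of the window
  *ending* at x — the activity of the immediately preceding interval, the
  causal direction the hypotheses posit.

Degenerate inputs are handled explicitly: metrics with a zero denominator
are reported as NaN (undefined), never coerced to 0; days with fewer than
two windows yield no gradients; pairs spanning a gap, a day boundary or the
night (outside 06:00–23:59) are skipped and counted in the logs.

## Exact nonparametric tests

Both consistency tests enumerate their exact null distributions rather than
delegating to a statistics library, so that the small-sample results
(n = 8 participants) are reproducible bit-for-bit:

* Wilcoxon signed-rank: zero differences dropped, mid-ranks on |d|,
  W = min(W⁺, W⁻); the null of W⁺ is built by dynamic programming over the
  2ⁿ sign patterns (ranks doubled to stay integral under ties); two-sided
  p = 2·P(W⁺ ≤ W) capped at 1. Rank-biserial r = (W⁺ − W⁻)/(W⁺ + W⁻).
  Exact up to n = 25.
* Mann–Whitney: U = max(U₁, U₂); for group sizes ≤ 10 the exact two-sided
  p enumerates all C(m+n, m) labelings of the observed pooled mid-ranks;
  larger samples fall back to a tie-corrected, continuity-corrected normal
  approximation (reported as such).

A cross-check against `scipy.stats` (exact methods, tie-free inputs) is a
test, not the implementation.

## The synthetic-data generator

The generator defines the study conditions under which the pipeline is
exercised. Per participant it simulates full days (default 5) of:

* **Baseline activity** — counts per 15 s epoch from a gamma–Poisson
  (negative-binomial-like) mixture, mean 15 counts/epoch, dispersion 0.5
  (variance μ + αμ²): non-negative and right-skewed, as wrist actigraphy
  counts are. No distributional description of real counts is available to
  fit against; these are structural, not estimated, values.
* **Bouts** — scheduled excess activity (counts/epoch above baseline) with
  a deterministic within-bout modulation (epochs alternate 0.5×/1.5× the
  intensity, mean 1×). Real bouts fluctuate epoch-to-epoch; the modulation
  keeps the windowed std strictly positive wherever a bout is present even
  in noise-free runs, so PA categorisation remains well defined there.
* **Glucose** — Euler-integrated at the 5 min CGM tick:
  slope = −`decline_per_count` × (scheduled bout excess, delayed by
  `response_lag_minutes` = 20) + intervention effects, plus N(0, σ) process
  noise per step (σ = `glucose_noise_sd` = 0.03 mmol/L per 5 min step).
  The lag is a pure delay, the simplest mechanism consistent with activity
  affecting glucose roughly 15–20 min after onset. The forcing uses the
  *scheduled* excess, not the noisy realised counts, so that with no bouts
  and zero glucose noise the trace is exactly constant — the property the
  recovery tests rely on. Glucose is clipped to [2, 22] mmol/L (logged).
* **Interventions** — carbohydrate intake or insulin suspension as additive
  slope terms, the behavioural confounders that blunt expected declines and
  generate false positives.
* **Sleep** — epochs outside 06:00–23:59 (and inside any configured sleep
  blocks) are labelled REST-S so the cleaning stage exercises its
  exclusion path.

The default daily schedule is three extended bouts (09:40/180,
12:40/260, 17:40/150 counts-per-epoch excess, 120 min each) and three
carbohydrate "meals" whose effects exactly balance the bout-induced
declines, making the noise-free trajectory day-periodic within ≈6–10
mmol/L. Bout starts and durations sit on the 20 min grid so the lagged
declines align with the finest analysis windows; the midday and evening
bouts begin during meal rises so rising-glucose (H2) instants occur. The
default noise level leaves short-window gradient noise (≈0.003 mmol/L/min)
below the ε dead zone most of the time, which is the regime in which a
gradient method is meaningful at all: the 20 min event stream is dominated
by forced declines, with a realistic minority of noise-driven events.
`decline_per_count` = 1×10⁻⁴ mmol/L·min⁻¹ per excess count puts a
260-count bout at ≈0.026 mmol/L/min — a 2–3 mmol/L decline over two hours.

Ground truth is derived from the *noise-free* twin of the same trajectory:
for every instant that survives the pipeline's own window-survival rules,
the expected PA category (from the bout schedule), gradients, change
category and outcome are recorded. On zero-noise data the pipeline
reproduces these labels exactly (tested at all three widths); under noise
they are the generative expectation, not a guarantee.

### What the generator does not emulate

* Sensor dropout, compression artefacts, calibration drift, or CGM
  quantisation; timestamps are perfectly gridded.
* Meal-absorption or insulin kinetics — interventions are boxcar slope
  terms, and the activity effect switches off sharply at bout-end + lag.
  The sharp offset matters: at widths wider than the 20 min lag, the
  deceleration at the end of a decline falls inside a window whose PA is
  still non-standard, producing structural false positives at 40/60 min
  that real data (where post-activity effects decay slowly) would not show
  to the same degree. Synthetic aggregate accuracy pooled across widths
  (≈0.68) therefore understates the 20 min figure (≈0.89), and the 40/60
  min synthetic results should be read as a stress test of the method's
  window-alignment sensitivity, not as its expected field performance.
* Between-participant heterogeneity beyond the seed: all synthetic
  participants share the schedule, differing only in noise realisations.

Consequently, passing tests demonstrate correctness of the pipeline's
mechanics and its recovery of a known generative signal — not clinical
performance on real cohorts.

## Problem sizes

Tests and the acceptance script run 1–2 day single-participant streams for
unit-level checks, an 8-participant × 5-day run for the consistency
statistics, and a 50-participant × 5-day run at 20 min for stochastic
recovery; these sizes give stable statistics while keeping the whole suite
in the tens of seconds on one CPU.

## Known limitations

* Whether the production analysis differenced glucose levels or windowed
  stds is configurable but not resolvable from first principles; the level
  basis is the default (see above), and conclusions that depend on the
  choice should be checked under both.
* The ε operationalising "same" is a construct of this implementation; the
  underlying classification grids do not quantify it.
* The trailing (causal) baseline variant — habitual PA estimated only from
  data *before* each instant — is not implemented; the whole-record mean
  is used.
* DST transitions and time-zone changes are out of scope; timestamps are
  naive local time, and off-grid jumps are only warned about.
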