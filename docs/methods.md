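# Methods

This note documents the models, rules and design decisions behind
cohortviz: what each pipeline stage computes, the tunable parameters and
their defaults, what the synthetic cohort generator does and does not
emulate, and the numerical conventions.

## Data model

Input is the flat-file subset of the HICDEP exchange layout: one RFC 4180
CSV per table with a header row, all patient-level tables sharing one
subject identifier column (default `patient`). Dates must be ISO 8601
`YYYY-MM-DD`; any other dialect is an error rather than a guess, because
silently coercing, say, `15/03/2011` hides data-preparation bugs that
corrupt follow-up time. Empty cells and the literal `NA` are missing.
Unknown columns are carried through untouched so spec expressions can
reference site-specific extensions. Subjects appearing in longitudinal or
event tables but not in `basic` are retained with a warning — the
alternative (dropping) would silently change denominators.

## Spec sheets and the predicate language

Each plot class is configured by a two-column CSV (`name,specification`).
Omitted or blank names take the documented defaults; unknown names warn
rather than fail so a spec written for a newer version still runs.
Key defaults: follow-up horizon `maxtime` = 730 days; death-attribution
window `long2eventwindow` = 360 days; start-date selection `first`;
transform `identity`; bubble period `year`; minimum bubble denominator
`minnum` = 10; event-axis upper limit 1.4 × the highest final group rate;
longitudinal limits the 0.5th–99.5th percentiles; ~5 "pretty" axis breaks
on the 1/2/5 ladder; group labels `Group <value>`.

Subsets and indicators are expressions over columns. The original
deployment of this style of tool evaluated raw R code from the spec file;
executing arbitrary config-supplied code is unsafe and ties the tool to one
host language, so cohortviz instead defines a closed mini-language:
comparisons, `in (…)` membership, `missing(col)`, `and/or/not`, numeric,
quoted-text and ISO-date literals. The R spellings that appear in field
spec sheets translate mechanically (`table$col` → `col`, `&`→`and`,
`!is.na(x)`→`not missing(x)`, `%in%`→`in`, `c(…)` lists) and the parser
accepts `&`, `|`, `!`, `%in%`, `table$col` directly as aliases. Evaluation
is three-valued (Kleene): comparisons against missing cells are missing,
and subsetting treats a missing result as false, so
`cd4_v > 0 and not missing(cd4_v)` behaves exactly like its R counterpart.
Column types are inferred per column (dates, else numbers, else text);
comparisons across incomparable types evaluate to missing rather than
raising mid-scan.

## Derived variables

* **Day arithmetic.** Day = exact calendar-day difference; day 0 is the
  anchor (ART start) date.
* **Follow-up truncation.** Subjects whose end date falls after `maxtime`
  are administratively censored at `maxtime` (event flag dropped), the
  standard product-limit truncation; excluding them would bias early
  survival.
* **Death attribution.** A death gets an X marker at the value of the
  latest observation no more than `long2eventwindow` days (inclusive)
  before the event; deaths with no attributable value still enter the
  Kaplan-Meier pane. The boundary is inclusive because the window is
  conventionally quoted as "within 12 months".
* **Baseline values.** The observation closest to an anchor date within an
  asymmetric eligibility window, default 180 days before / 30 days after;
  ties at equal distance resolve to the earlier observation. The window is
  configurable because no single convention dominates across cohorts.
* **Periods.** `year`/`quarter`/`month` labels (`2011`, `2011-Q1`,
  `2011-03`) are zero-padded so lexicographic order is chronological order.
* **Country-year aggregation.** Denominator = rows with a non-missing
  indicator; cells with empty denominators are omitted rather than emitted
  as 0/0.

## Statistical primitives

* **Kaplan-Meier.** `S(t) = ∏_{t_i ≤ t} (1 − d_i/n_i)` over distinct event
  times; at tied event/censoring times events precede censorings in the
  risk-set accounting (the universal convention). No confidence bands —
  uncertainty display is out of scope for these animations.
* **LOESS.** Tricube-weighted local polynomial regression over the
  `⌈span·n⌉` nearest neighbors, defaults span 0.75 and degree 1. Degree 1
  is the default because the right edge of follow-up is sparse and local
  quadratics overshoot there; both are overridable. The local design matrix
  is centered at the grid point, so the fitted value is the intercept and
  the fit is exact on polynomials of the fitted degree (a property the test
  suite asserts to machine precision). Curves are fit once over the whole
  span and only revealed per frame, so trends never jitter as frames
  advance.
* **Kernel density.** Gaussian kernels, Silverman bandwidth
  `0.9·min(sd, IQR/1.34)·n^{−1/5}`. Margins with fewer than two distinct
  values are skipped for that frame rather than drawn degenerate.
* **Margin density construction.** The "current distribution" at frame day
  *t* takes, per subject still under follow-up at *t*, the last observed
  value at or before *t* no older than `long2eventwindow` days. The recency
  restriction keeps the terminal-frame density interpretable as the
  end-of-window marker distribution instead of mixing in years-stale
  values; this construction is a documented package choice.

## Rendering rules

* **Frame schedule.** Frames run 0..`maxtime` by `frame_step` (default 1
  day), with the terminal frame always included so the final image shows
  the complete data: 731 frames at step 1, 74 at step 10 for the default
  730-day window.
* **Fixed axes.** All axis limits, ticks and legends are computed before
  frame 0 and never change between frames; bubble axes are fixed to [0, 1]
  because cross-frame comparability is the point of the animation.
* **Degenerate limits** widen by ±5% of the value (±1 around zero).
* **Ticks** are labelled on the original measurement scale even when the
  axis is transformed (sqrt/log/log10); explicit tick values outside the
  limits are dropped.
* **Bubbles** encode count by area, not radius; a trail's shades
  interpolate linearly in HLS lightness from 0.75 (current period, drawn
  topmost) down to 0.35 (oldest), so luminance decreases strictly with age.
  Periods where every group falls below `minnum` still produce an (empty)
  frame to keep the time axis honest.
* **Choropleths** bin percentages into width-10 bins covering the observed
  range (half-open except the last), shaded light-to-dark on a single red
  hue; values with max ≤ 1 are auto-detected as proportions, overridable by
  the spec's `varscale`. The region viewport is the bounding box (plus 5%
  margin) of countries with data in *any* period, so it is identical in
  every frame. Equirectangular projection only — adequate for choropleth
  reading and dependency-free. Data codes with no boundary polygon are
  listed in the run report, never dropped silently.
* **Determinism.** Rendering uses the Agg canvas directly with fixed DPI;
  two runs on the same inputs produce byte-identical PNGs and viewers,
  which the acceptance script verifies.

## Synthetic cohort generator

`simulate_cohort` emulates the structure of a multi-country treatment
cohort: subjects enrolled uniformly within calendar years at 6 sites
(matching the toy boundary file's ISO-3 codes), AIDS stratum with
probability 0.35, lognormal baseline CD4 (median 280 cells/µL non-AIDS, 90
AIDS, σ = 0.8), ART start 0–30 days after enrollment, exponential death
times (5.5 × 10⁻⁵/day non-AIDS, 1.75 × 10⁻⁴/day AIDS — roughly 4% vs 12%
two-year mortality), exponential censoring (4 × 10⁻⁴/day) plus an
administrative cut at 1100 days, square-root-scale linear CD4 recovery
(0.9 resp. 1.2 per 100 days, Gaussian noise SD 1.8) observed at ~90-day
visits, and a −1.5 percentage-point/year trend in the probability of
presenting with CD4 < 200. CD4 values are rounded to integers and floored
at 1 for domain realism.

What it does **not** emulate: loss-to-follow-up that depends on health
state, site-level effect heterogeneity, measurement batch effects,
non-linear recovery plateaus, or any real cohort's actual distributions.
Passing tests therefore demonstrate that the pipeline's *rules and
estimators* are correct under a known generating process, not that any
epidemiological finding generalizes.

Problem sizes used by the test and acceptance runs are deliberately
moderate — 150–250 subjects for end-to-end renders (with frame step 73 for
the panel), 1,000–2,000 subjects for estimator-consistency checks, 1,000
randomized small instances for the product-limit oracle sweep — sizes at
which every asserted tolerance is comfortably identifiable.

## Known limitations

* Single-event survival only; no competing risks, no confidence intervals,
  no log-rank tests.
* The expression language has no arithmetic or user functions by design;
  derived columns belong in upstream data preparation or the `derive`
  helpers.
* No video encoding: the PNG sequences are encoder-ready and the HTML
  viewer provides interactivity without further tooling.
* Choropleth boundaries are an input, not bundled worldwide data; the
  shipped six-country GeoJSON is synthetic and for tests/examples only.
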