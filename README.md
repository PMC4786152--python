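# cohortviz

Animated, configuration-driven visualization of HIV cohort data.

Cohort collaborations exchange patient-level HIV data as HICDEP-style
relational tables (HIV Cohort Data Exchange Protocol): `basic` demographics,
`lab_cd4` laboratory series, `art` treatment episodes, `follow` vital-status
follow-up, all keyed by a shared subject identifier. cohortviz reads that
flat-file subset plus a small CSV "spec sheet" per plot class and renders
three classes of animated graphics as PNG frame sequences with a
self-contained HTML scrubber:

1. **Longitudinal / event-probability panels** — a scatter of a longitudinal
   marker (e.g. CD4+ count) against days since cART initiation, revealed one
   day per frame, with per-group LOESS trend curves, right-margin density
   curves of the current marker distribution, X markers at deceased
   subjects' last attributable value, and a linked pane of Kaplan-Meier
   cumulative probability of death stratified by a patient class (e.g. AIDS
   at ART start).
2. **Bubble plots** — one frame per calendar period (month/quarter/year of
   enrollment), one bubble per group at the observed proportions of two
   binary indicators, bubble *area* proportional to the number enrolled;
   either with per-group 2×2 mosaic (marginal allocation) panels, or with
   per-group trails of prior periods that darken with age.
3. **Temporal choropleths** — per-country, per-year proportions shaded on a
   sequential red palette in 10-percentage-point bins, as a world context
   map and a cropped region map with identical fills.

It is aimed at cohort-network analysts who want animation-ready,
reproducible descriptive graphics without writing plotting code: all inputs
and parameters live in editable CSV spec sheets.

## Statistical core

- **Kaplan-Meier product-limit estimator.** With distinct event times
  `t_1 < t_2 < …`, `d_i` deaths and `n_i` subjects at risk at `t_i`,
  `S(t) = ∏_{t_i ≤ t} (1 − d_i / n_i)`; the event pane plots `1 − S(t)`.
  At tied death/censoring times, censored subjects remain at risk for the
  deaths at that time. Subjects followed past the configured horizon
  (`maxtime`, default 730 days) are administratively censored there.
- **LOESS.** For each grid point, a weighted least-squares polynomial
  (degree 1 or 2) over the `⌈span·n⌉` nearest neighbors with tricube
  weights `w = (1 − (d/d_max)³)³`, fit once over the whole time span and
  only *revealed* frame by frame.
- **Kernel density.** Gaussian kernels with Silverman's rule-of-thumb
  bandwidth `0.9·min(sd, IQR/1.34)·n^{−1/5}` for the margin densities.
- **Grouped proportions.** Per (group, period) 2×2 joint counts of the two
  indicators; rows with either indicator missing are excluded from the
  denominator, and cells with fewer than `minnum` (default 10) subjects are
  suppressed.

Subset and indicator definitions in the spec sheets use a small, safe
expression language (`cd4_v > 0 and not missing(cd4_v)`,
`aids_cl_y in (0,1)`, `cd4_v_cmp < 200`); R-flavoured spellings such as
`table$col`, `&`, `!`, `%in%` and `c(0,25,100)` are accepted aliases.

Because real multi-network cohort data are not redistributable, the package
includes a deterministic synthetic cohort generator
(`cohortviz.synthetic`) with known ground truth — exponential survival per
stratum, square-root-scale CD4 recovery, a calendar trend in late
presentation — used by the test suite and the bundled example data.

## Worked example

The repository ships a 200-subject simulated cohort (`examples/data/`,
3 sites, enrollment 2008–2011, seed 20160310) and the three spec sheets
under `examples/input/`.

```sh
cohortviz panel1 --data examples/data --spec examples/input/panel1_specs.csv \
    --out output --frame-step 10
```

prints

```
plot class : panel1
frames     : 74
viewer     : output/panel1_viewer.html
note       : subjects plotted: 200
note       : groups: 0, 1
warnings   : 0
```

74 frames = days 0, 10, …, 730 of the two-year follow-up window (the
terminal frame is always included). Open `output/panel1_viewer.html` to
scrub or play the animation: dots accumulate as the cohort is followed
forward, the AIDS stratum (group 1) starts at lower CD4 and shows a higher
cumulative probability of death in the bottom pane. Likewise:

```sh
cohortviz bubbles --data examples/data --spec examples/input/panel2_specs.csv --out output
cohortviz bubbles --data examples/data --spec examples/input/panel2_specs.csv --out output --trail
cohortviz simulate --out mydata --seed 7 --n 500   # fresh synthetic cohort
```

For the maps, build a country-year table (columns
`iso3,year,numerator,denominator,proportion`; see
`cohortviz.derive.aggregate_country_year`) and point at any ISO-3-keyed
GeoJSON boundary file — a six-country toy file ships at
`src/cohortviz/data/toy_countries.geojson`:

```sh
cohortviz maps --table country.csv --spec examples/input/map1_specs.csv \
    --boundaries src/cohortviz/data/toy_countries.geojson --out output
```

The frame sequences under `output/scroll_images/` are encoder-ready; e.g.
`ffmpeg -framerate 25 -i output/scroll_images/panel_%04d.png panel1.mp4`.

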