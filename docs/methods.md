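# Methods

This note documents the models in `malisorghum`, the choices behind them,
and what the synthetic-data pipeline can and cannot show. Everything stated
here is computed by the package's own code and checked by its test suite;
no empirical claims beyond that are made.

## Phenology

Development is driven by thermal time. Daily thermal time is computed on
the mean of the daily extremes with a broken-linear response: zero at or
below a base temperature, rising linearly to the optimum, declining
linearly to zero at the maximum. Cardinal temperatures default to
11 / 30 / 42 °C — conventional values for sorghum; the source trials
behind the cultivar coefficients do not constrain them, so they are fields
of `CultivarParams` and can be overridden.

The stage machine runs sowing → emergence → end of juvenile phase →
panicle initiation → flag leaf → flowering → start of grain fill →
maturity → ripe. Phase targets (all °Cd):

| phase | target | CSM63E | CSM335 |
|---|---|---|---|
| sowing → emergence | `tt_sow_to_emergence` | 60 | 60 |
| emergence → end juvenile | `tt_sow_to_endjuv − tt_sow_to_emergence` | 390 | 390 |
| end juvenile → panicle initiation | photoperiod response (below) | 50–302 | 50–502 |
| initiation → flag leaf | `(MaxLNo − leaves emerged at initiation) × phyllochron` | variable | variable |
| flag leaf → flowering | `tt_flag_to_flower` | 170 | 170 |
| flowering → start grain fill | `tt_flower_to_start_grain` | 80 | 80 |
| flowering → maturity | `tt_flower_to_maturity` | 484 | 518 |
| maturity → ripe | `tt_maturity_to_ripe` | 1 | 1 |

Thermal time in excess of a phase target carries into the next phase, so
the °Cd attributed between any two transitions equals the parameter
exactly even though transitions land on whole days; transition records
carry the exact cumulative-°Cd crossing points.

**Photoperiod response.** The end-juvenile → initiation duration is a
triple broken-linear function of photoperiod (day length extended to a
solar depression of 2.2°): a 50 °Cd base below *PPcrit1* = 11.5 h, a rise
of *PPslope* °Cd per hour between the critical photoperiods, a plateau
above *PPcrit2* = 13.5 h. The photoperiod that drives the phase is the
*running mean* over the phase so far, re-evaluated daily — the phase
target therefore drifts as day length changes, which is what compresses
flowering dates across a wide sowing window. The slope can be
re-estimated from trial data with `PhotoperiodSlopeRegression` /
`fit_ppslope` (ordinary least squares on observations strictly inside the
sensitive range; the design is rejected as unidentifiable with fewer than
two distinct in-range photoperiods).

**Basic vegetative duration.** The lumped sowing → end-juvenile duration
is not reported with the cultivar coefficients. It is set to 450 °Cd so
that June-sown crops at ~12.5 °N flower in the September window that
photoperiod-sensitive Malian sorghum is selected for, with main-stem leaf
numbers around 23 (CSM63E) and 27 (CSM335). This single gap-filling
calibration anchors the whole seasonal geometry (flowering relative to
the rain cessation); it was fixed before the downstream analyses and is
configurable per cultivar.

**Sowing rule.** Soil water is reset to 20% fractional available water at
the start of the sowing window (1 June). The crop is sown on the first
window day whose trailing 7-day rainfall reaches 20 mm with at least
10 mm of stored plant-available water (bare-soil water balance stepped
daily through the window), and is force-sown on 15 July otherwise.

## Canopy

Individual leaf area follows a bell-shaped function of leaf rank
(`Y = Y0·exp(a(X−X0)² + b(X−X0)³)`); the largest-leaf area is linear in
total leaf number (`Y0 = MaxLNo·aMaxSlope + aMaxIntercept`, scaled by the
cultivar's largest-leaf multiplier, read here as the conversion from the
main-culm regression to effective per-plant area). The published source
for this approach fits *X0*, *a*, *b* as functions of leaf number but the
coefficients are not reproduced anywhere accessible, so this package uses
configurable defaults chosen to give realistic unimodal profiles:
`X0 = 0.66·MaxLNo`, `a = −0.009 − 0.2/MaxLNo`, `b = 0.0006`. **These three
forms are package defaults, not fitted values** — anyone with leaf-level
data should refit them.

Total leaf number is `embryo_leaves + TT(emergence→initiation) /
plastochron` (rounded, ties up; plastochron 34 °Cd); leaves *emerge* from
one visible leaf at emergence at one per phyllochron (40 °Cd). Before
initiation fixes the final number, the profile is rebuilt daily from the
projected final leaf number implied by the current phase-mean photoperiod;
the projection converges to the realised profile at initiation and keeps
the largest-leaf regression inside its positive domain.

LAI is the summed area of emerged leaves × plant density. The daily
*increment* of this ceiling is realised scaled by the previous day's
supply/demand ratio, and expansion lost to drought is not recovered —
leaf expansion is the most drought-sensitive process in the canon this
model family follows, and without this feedback early-season drought
would cost almost no yield. After flowering, LAI senesces at 0.05% per
°Cd, ×3 when S/D < 0.3.

## Soil water

A layered bucket: per-layer lower limit (LL), drained upper limit (DUL)
and saturation; water above DUL drains to the next layer at a drainage
coefficient of 0.5 d⁻¹ (below-profile drainage is lost); all rain
infiltrates (no runoff — the sites are flat cultivated fields; a known
limitation). Soil evaporation acts on the top layer only with a two-stage
model (6 mm energy-limited after each ≥4 mm wetting, then a
3.5·√t falling rate). Root water supply is `Σ kl·(stored − LL·thickness)`
over rooted layers (kl = 0.07 d⁻¹ everywhere, the standard sorghum value),
with the deepest rooted layer prorated by penetration; the root front
advances 25 mm d⁻¹ from sowing, stops at flowering, and is capped at the
profile depth. Within a daily step the order is infiltration/drainage →
transpiration uptake → soil evaporation, which guarantees that uptake
sized from the morning supply can never overdraw a layer. The balance
closes to ≤10⁻⁹ mm by construction (property-tested).

Two presets reproduce the study soils: `low_swhc` (62 mm over 101 cm,
6 uniform layers) and `high_swhc` (156 mm over 120 cm, 7 layers), with
uniform (DUL−LL) per layer because only profile totals are reported. The
20% reset is filled top-down (surface layers to DUL first); uniform-
fraction filling is the plausible alternative and would slightly lower
early-season supply.

## Growth, stress, and yield

Potential biomass gain is RUE × intercepted radiation
(`RUE = 1.25 g MJ⁻¹`, extinction k = 0.4). Transpiration demand converts
that gain through the vapour pressure deficit and a transpiration-
efficiency coefficient of 9 Pa (`demand = gain·VPD/TE`; VPD estimated as
0.75 of the saturation-vapour-pressure span between the daily extremes).
The daily stress index is `S/D = min(1, supply/demand)`, defined as 1
when demand is zero; supply shortfalls scale both biomass gain and leaf
expansion. Note the operation yields exactly 0 when the rooted zone is at
the lower limit, so daily values live in [0, 1]; the clustered interval
means are strictly positive.

Grain number is the biomass gained within ±100 °Cd of flowering divided
by the dry mass per seed, finalised when the crop reaches flowering
+100 °Cd (grain growth starts then; the 20 °Cd offset from the nominal
start of grain fill is negligible and resolves the circularity of needing
the full window before filling starts). Daily grain growth is the minimum
of the sink (`maxGFRate` in **mg grain⁻¹ °Cd⁻¹** — the only unit scale
that puts potential yields in t ha⁻¹ — × grain number × daily °Cd) and
the source (the day's assimilate plus what remains of a reserve equal to
20% of stem biomass at the start of fill, stem taken as half the
vegetative biomass since organs are not tracked). Grain never exceeds
total biomass.

## Synthetic weather

The generator emulates the monsoonal climate per isohyet zone, not any
particular station year. Per season it draws a wet-window onset
(zone means at day-of-year 178/170/163/156 from the driest to the wettest
zone, sd 12 d — onset is late and variable in the north) and cessation
(253/268/281/291, sd 5 d — the end of the rains is much less variable and
comes earlier in the north; the north–south season-length gradient is
what generates the terminal-drought gradient). Inside the window, wet/dry
days follow a first-order Markov chain (P(wet|dry) = 0.33,
P(wet|wet) = 0.70, ≈55% wet days); wet-day amounts are gamma (shape 0.9)
with a mild mid-season intensity hump, scaled so the season's *expected*
total equals the site's target annual rainfall; ~2% of rain falls as rare
out-of-season showers. Temperatures and radiation are sinusoidal annual
cycles with Gaussian noise inside the regional ranges; wet days are 2 °C
cooler and receive 20% less radiation. The calendar is a fixed 365 days.

What the generator does **not** emulate: multi-year persistence (droughts
clustered across years), spatial correlation between sites, intra-storm
structure, and real interannual temperature trends. Pipeline results on
synthetic weather therefore demonstrate that the *machinery* reproduces
the qualitative structure of the study region — the three stress
archetypes, the soil/cultivar/zone ordering of stress frequencies, the
scenario yield ordering — not station-accurate frequencies.

## Envirotyping

Each completed run is reduced to the means of daily S/D over eight
100 °Cd intervals anchored at flowering (−400…−100 and 100…400; the
flowering day joins the first post-flowering interval; there is no "0"
interval). Runs with less than 400 °Cd of record on either side of
flowering are excluded and reported with reasons. Trajectories from all
runs are clustered jointly in raw S/D space (Euclidean distance, no
standardisation — the coordinates already share the (0, 1] scale) with
either k-means (25 k-means++ restarts, fixed seed) or PAM (BUILD + SWAP
k-medoids, implemented in-package). Clusters are ordered canonically by
descending centroid mean so numbering is permutation-stable, and with
k = 3 they are labelled: centroid mean ≥ 0.95 everywhere → *no stress*
(exactly one must qualify, otherwise a labelling-ambiguity error tells
the caller to reconsider k); of the rest, the centroid whose S/D first
drops below 0.9 earliest → *early pre-flowering stress*, the other →
*flowering stress* (ties broken by the lower pre-flowering mean).

Season weights are `max seasons over isohyets / (total seasons × seasons
in the isohyet)`, read so that each isohyet's seasons carry equal total
weight — the property the weighting exists to provide, and the one the
tests assert. Frequency tables are weighted percentages per isohyet ×
soil × cultivar (rows sum to 100); yield risk curves are weighted
empirical CDFs.

## Problem sizes and determinism

The bundled study ensemble used by the tests and the demo configuration
is 8 sites (two per isohyet zone, with the stations' published mean
annual rainfalls) × 20 seasons × 2 soils × 2 cultivars = 640 runs, which
clusters cleanly and runs in seconds; the full historical design
(459 site-years × 2 × 2 = 1836 runs) is enumerated by the run manifest
and runs the same way given more seasons. All stochastic components
(weather, clustering restarts, calibration noise) are seeded; site
streams are decorrelated with a CRC-based site/year hash so results are
reproducible across processes, and re-running a pipeline config produces
byte-identical outputs.

## Known limitations

- No nitrogen/phosphorus limitation (fertiliser treated as non-limiting),
  no tillering, no waterlogging, no pests/diseases, no lodging or plant
  height.
- The leaf-profile shape coefficients (*X0*, *a*, *b* vs leaf number) are
  package defaults, not fitted to Malian data.
- One cultivar × soil × weather realisation per run; no within-site
  spatial variability.
- Highly photoperiod-sensitive, very long-cycle material (e.g., Guinean
  late landraces) is outside the calibrated range of the canopy model.
- Absolute yields are indicative only; orderings and frequencies are the
  supported outputs.
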