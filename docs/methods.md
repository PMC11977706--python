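# Methods

## The accounting model

The package treats nutrient management as four nested mass-balance systems
per county and year: Cropping ⊂ Animal-crop ⊂ Food ⊂ Ecosystem. Each
system is assigned a set of input flows and productive-output flows from a
closed vocabulary of twenty flow kinds (fertilizer, manure pathways,
fixation, deposition, harvest, feed/food trade, animal products, waste
streams, urban inputs). For every (unit, year, nutrient, system) cell the
engine computes

* inputs *I* = Σ mapped input flows,
* productive outputs *O* = Σ mapped output flows,
* surplus *S* = *I* − *O* (conserved exactly: *I* − *O* − *S* ≡ 0),
* efficiency *E* = *O* / *I* (undefined sentinel when *I* = 0; values above
  1 flagged as soil mining).

Watershed values aggregate counties by summing flows; efficiency is always
recomputed from summed flows, never averaged. Period values (e.g.
"1985" = 1985–1989) average flows first and take ratios afterwards, which
keeps the duality *E* + *S*/*I* = 1 on period cells; the alternative (mean
of yearly ratios) differs whenever flows vary and is deliberately not used.

### The default system mapping

Published watershed tables pin only system totals, not the per-flow lists,
so the flow-kind mapping is configuration with a documented default:

| system | inputs | productive outputs |
|---|---|---|
| Cropping | mineral fertilizer, applied manure, applied biosolids, fixation, deposition | crop harvest |
| Animal-crop | mineral fertilizer, fixation, deposition, feed imports | crop harvest + animal products |
| Food | Animal-crop inputs + food imports | crop harvest + animal products + food imports − processing/retail waste |
| Ecosystem | Food inputs + urban fertilizer + urban deposition/fixation | food exports |

Moving downstream, recycled flows become internal (manure and biosolids
recycling inside the Animal-crop system, locally fed crops inside the Food
system). The Food system's productive output — food reaching consumers
plus exports — is only expressible as *supply minus waste*, so output
coefficients are signed and `food_import` legitimately appears on both
sides of the Food system. Consumed food stays in the landscape (it returns
as human waste), hence the Ecosystem's only productive output is exported
food. With this structure the adjacent-system surplus jumps are
interpretable: Food adds exactly the processing/retail waste, the Ecosystem
adds urban inputs plus consumed food.

Whether exported feed grain belongs in the Animal-crop productive output is
not decidable from the published totals; the default counts the whole
harvest and is labelled an assumption (override via `SystemMapping`).

## The watershed fixture

`table1_fixture()` is a single-unit table whose budgets under the default
mapping equal the published watershed summary cells exactly (32 inputs and
outputs, two nutrients × two periods × four systems). The printed summary
rounds an unrounded database, so a few printed surplus/efficiency cells
differ by one unit from their own input−output difference (e.g. 1985 N
Food: 593 − 315 = 278 vs a printed 279); the fixture therefore stores only
inputs/outputs per flow kind and all derived cells are recomputed, with a
±1 printed-unit tolerance in the tests.

Cells the summary does not pin down were back-solved from the published
watershed fertilizer shares (62% for N in both periods; 58% → 46% for P),
recyclable-waste totals (217 → 210 Gg N, 35 → 32 Gg P), and 2019
fertilizer demand (137 Gg N, 23 Gg P); the remaining freedom (e.g. the
fixation/deposition split) is fixed at field-plausible magnitudes. Fixture
covariates back-solve the published surplus rates (41 kg N ha⁻¹ yr⁻¹ on
2.512 Mha cropland in 1985; 4.2 kg N ha⁻¹ yr⁻¹ on 24.7 Mha land).

## The synthetic cohort generator

`generate(SyntheticConfig())` emulates the *structure* the analysis
assumes — not any real county's values:

* **Heterogeneity.** County land shares are uniform draws normalized to a
  watershed total (24.7 Mha); cropland fractions are uniform on 1–35% and
  additionally divided by (1 + relative population density), so urbanized
  counties carry little cropland. Livestock and population densities are
  log-normal (σ = 0.8 and 1.2), right-skewed to produce the hot-spot
  counties seen in real cohorts; county totals are normalized to watershed
  totals (2.5 Mha cropland, 2.0 M livestock units, 13.5 M people at the
  first year, growing 0.8%/yr).
* **Flows.** Per-hectare rates (N fertilizer 55 kg/ha; P fertilizer
  12 kg/ha declining 1.5%/yr), per-livestock-unit feed intake and excretion
  with fixed manure splits (applied / pasture / unrecycled), and per-capita
  consumption driving retail waste, human-waste loads (split across
  municipal/industrial WWTP, CSO, septic) and urban inputs. Processing
  waste scales with local production entering the food system, retail waste
  with consumption — P processing-heavy, reflecting the large inedible-
  fraction P losses in animal-product processing. All of these are free
  parameters at Chesapeake-like magnitudes, documented here precisely
  because they are choices, not published values.
* **Crop harvest** is efficiency-driven: county NUE = base (0.68) + trend
  (0.0023/yr for N, 0.0077/yr for P, reproducing the published 68→76% and
  68→95% efficiency paths) + a county-level jitter, times cropping inputs.
* **Trade closure.** Feed imports cover the demand local harvest cannot
  (at most 35% of harvest, at most 60% of demand); food imports/exports
  close production + imports = consumption + waste + exports, plus a 15%
  two-way cross-haul so both flows are always positive.
* **Noise and seeding.** Multiplicative log-normal noise (CV 5%, mean 1) on
  the primary flows; derived flows inherit it so closure stays exact. One
  root seed; county substreams come from `SeedSequence(seed, spawn_key=i)`,
  so enlarging the cohort appends counties without reshuffling existing
  draws.
* **Trend targeting.** `target_n_surplus_trend` (Gg/yr) rescales harvests
  per year so the watershed Cropping N surplus follows a linear trend
  anchored at the cohort's own mean — used by the parameter-recovery tests
  (slope recovered within ±20% over 10 seeds).

What the generator does **not** emulate: real spatial autocorrelation,
policy shocks (e.g. recession-driven fertilizer dips), inter-county manure
transport, and any county-level marginal distribution of the real cohort
(no distributional targets exist at that scale). Passing tests therefore
demonstrate correctness of the accounting and the qualitative orderings,
not county-scale realism.

## Calibration

`calibrate(table, targets)` solves one scale factor per (nutrient, flow
kind, period window) so that period-averaged watershed inputs and outputs
equal the target cells exactly, walking the mapping structure: harvest from
the Cropping output, animal products from the Animal-crop/Cropping output
difference, feed imports from the input increments, processing waste from
the Food-output residual, and so on. Optional targets pin watershed
fertilizer demand and the recyclable-waste total (scaling unrecycled manure
and human-waste loads jointly). Factors are constant inside a window,
linearly interpolated between window centers, and held outside; county
heterogeneity is preserved up to scaling. Infeasible cells (a positive
target on a zero generated flow, or a negative required scale) raise a
`CalibrationError` naming the cell. Calibration is idempotent and degree-1
homogeneous (doubling all targets doubles all watershed budgets).

## Numerical and procedural conventions

* Report rounding is half-away-from-zero to integer Gg and percent
  (`round_half_away`); raw unrounded values are always emitted alongside.
* Undefined ratios (0 inputs, 0 areas, 0/0 offsets) are NaN sentinels, never
  infinities; a positive recyclable total against zero fertilizer demand is
  the one infinite-offset sentinel.
* Strict inequalities throughout the comparison metrics ("less than half",
  "higher than", boundary exceedance, source classification); ties count
  against the metric. Largest-change ties break toward the most upstream
  system.
* N:P ratios are computed only when both surpluses are positive; invalid
  ratios carry a reason code and are excluded pairwise from trend counts,
  and "unchanged" (exact equality) counts toward neither direction.
  Watershed ratios are computed from full sums by default; a
  `positive_only_aggregation` mode sums only positive county surpluses —
  the two modes diverge strongly once P soil mining is widespread, and the
  published 2019 watershed ratios are consistent only with county-level
  positive filtering, so both modes are provided.
* Share bins are left-closed right-open with a closed final bin; an
  optional open-ended bin (≥100%) accommodates soil-mining efficiencies.
  The Kruskal–Wallis test uses midranks with tie correction and the
  chi-square approximation (k − 1 df); no exact small-sample tables.
* Missing county-year flows are treated as 0 with a warning; missing
  covariates warn (error in strict mode). The flow vocabulary is closed:
  unknown kinds are schema errors at read time.

## Problem sizes in the test suite

The acceptance checks run the full 197-county, 35-year cohort once
(qualitative orderings, source-county majority), ten such cohorts for trend
recovery, and 100 small cohorts (≤10 counties, 1 year) against brute-force
enumeration oracles; the conservation property suite uses 50 random small
configurations. These sizes are the package's own choice of a
representative yet quick regression surface.

## Known limitations

* Surplus is *potential* loss; no transport, retention or delivery to
  receiving waters is modelled, and no legacy-store dynamics.
* The recyclable-waste estimate is theoretical: recovery multipliers
  default to 1.0 and no logistics or manureshed matching is attempted.
* The default system mapping is an assumption where the published record is
  silent; analyses sensitive to the Animal-crop output definition should
  supply their own `SystemMapping`.
* Calibration currently supports the default mapping only.
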