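# Methods

`escost` couples an ecological post-processing chain for dynamic-vegetation-
model (DGVM) output with an economic valuation of the resulting ecosystem-
service (ES) indicator changes. This note describes the models and
procedures the package implements, the assumptions behind them, and what the
synthetic data generator does and does not emulate.

## Ecological indicators

### Biomization

DGVM output arrives as per-cell, per-year abundances (leaf area index, LAI)
of plant functional types (PFTs): tropical broadleaf evergreen (TrBE),
tropical broadleaf raingreen (TrBR), temperate broadleaf evergreen (TeBE),
temperate needleleaf evergreen (TeNE), C4 and C3 grasses. Each cell-year is
mapped to one of eight biomes by an ordered rule table
(`escost.biomes.BiomeScheme`), evaluated top to bottom with a catch-all
default, so classification is total and deterministic.

The default thresholds are: forest at summed woody LAI ≥ 2.5, savanna at
≥ 0.5, grassland where grass LAI exceeds woody LAI, barren otherwise.
Forests split by the dominant woody PFT. One biome is diagnosed rather than
simulated: tropical needleleaf (pine–oak) forest has no PFT of its own, so
it is identified by TeBE dominance combined with strongly seasonal
precipitation — the coefficient of variation of monthly precipitation above
0.8. The plain TeBE-dominant rule below it then captures aseasonal
temperate evergreen forest. All thresholds, the rule order and the PFT
roster are editable; `escost scheme --out scheme.yaml` dumps the default
table and `BiomeScheme.from_yaml` loads a modified one. The shipped
defaults are declared conventions of this package, not fitted values.

### Biome stability

The habitat-service indicator is biome stability: the percentage of
future-period years (2071–2100) whose classified biome equals the cell's
reference biome,

    stability_i = 100 * (# years with biome_{i,t} = biome_ref,i) / n .

The reference biome is the *modal* biome of the reference period
(1985–2014): biomes are categorical, so a mean is undefined; the mode is the
only order-free deterministic choice. Ties break toward the biome whose
rule appears earlier in the scheme.

### CO2 sequestration

The climate-regulation indicator is period-mean net ecosystem exchange
(NEE). Raw NEE is in kgC/m²/yr under the atmospheric sign convention
(negative = net uptake). Conversion to the reporting unit flips the sign
and applies ×10 (kgC/m² → tC/ha) and the carbon→CO2 mass ratio, fixed at
the practice-oriented rounded constant 3.67 (`escost.indicators.CO2_PER_C`;
deliberately not 44.01/12.011 ≈ 3.664). Sequestration is therefore positive
for uptake, and ΔCO2 = future mean − reference mean is negative where the
sink weakens.

## Economic valuation

Costs are net-present-value differences between the historical and future
period, computed per cell and per service under four variants:
{global, national prices} × {2%/yr discounting, none}.

### Habitat (benefit transfer)

A single per-hectare habitat service value (HSV) is derived from a table of
ES valuation records (service, biome, $/ha/yr):

1. **Cleaning** (`clean_records`), in order: rows with missing fields;
   exact duplicates (first kept); climate-regulation rows (valued separately
   through the carbon price); provisioning-service rows (food, raw
   materials, water, medicinal resources — products of managed rather than
   natural forest); finally values outside the inclusive [5%, 95%] quantile
   band of the remaining values. Quantiles use linear interpolation (NumPy
   default); on 100 distinct values exactly the 5th–94th order statistics
   survive. Each stage's drop count is reported. Note that a quantile trim
   is not idempotent on continuous data — re-cleaning a cleaned set will
   trim another ~10% at the band edges; the categorical stages (missing,
   duplicates, excluded services) do become no-ops after one pass.
2. **Aggregation** (`habitat_baseline`): per biome group, per-service means
   are summed (total-economic-value logic); the baseline is the across-biome
   mean, times a single user-supplied inflation factor to 2015 (default 1
   for synthetic runs).
3. **Discounting**: with rate d the baseline is prolongated to the
   historical central year 1999, `HSV_hist = HSV_2015 * (1+d)^16`, and
   discounted to the future central year 2085,
   `HSV_fut = HSV_2015 / (1+d)^70`. The two operations are exact inverses
   over equal spans.

The per-cell habitat cost is
`factor * (HSV_hist * 1 − HSV_fut * stability/100)`: the historical habitat
indicator is 1 by construction (the reference biome trivially matches its
own period's mode). With d > 0, `HSV_hist > HSV_fut` guarantees a strictly
positive cost at every stability level — discounting alone creates costs
across the entire study area.

### Climate regulation (social cost of carbon)

The social cost of carbon (SCC, $/tCO2) rises over time (damages of an
emitted tonne accumulate) and falls with the discount rate. From a table
indexed by (year, SSP, rate, damage function), the package averages across
damage functions and takes: discounted variant — year 2015 at 2% for the
historical period and year 2085 at 2% for the future; undiscounted
variant — year 2085 at 0%, held constant for both periods. The per-cell
cost is `factor * (SCC_hist * seq_ref − SCC_fut * seq_fut)`.

### Price levels and flooring

National prices scale each country's costs by GDP per capita relative to
the world average; global prices use factor 1 everywhere. Reported "costs"
are the positive part of the raw NPV difference; cells with ES gains
contribute 0 to totals, while the signed surfaces are retained for net
analyses and for hot-spot filtering.

## Aggregation

* **Bivariate map classes** at breaks of 50% stability and 0 t/ha/yr ΔCO2
  partition the grid into four quadrants; boundary cells count as stable /
  non-declining (the breaks themselves are conventions, the assignment of
  exact-boundary cells a documented tie-break).
* **Economic hot spots** are cells where both raw costs are strictly
  positive; their summed cost is binned into classes with a default top
  class above 2500 $/ha/yr, reporting area and average cost per class.
* **Country summaries** multiply per-cell floored costs by the constant
  cell area, total them per country, express totals as % of national GDP,
  and report affected-area fractions relative to the country's forest cells
  (cells whose reference biome is one of the five forest biomes) plus
  quantiles of the per-cell cost distribution.

## Synthetic data generator

The generator replaces two inputs that cannot be shipped: LPJ-GUESS-style
gridded output and the economic source tables.

* **Landscape**: an abstract 100×100 lattice (no projection; constant cell
  area, default 100 ha) with nine contiguous country blocks labelled after
  the Central American roster (BZ, CO, CR, SV, GT, HN, MX, NI, PA).
  Reference biomes form spatially coherent patches (rank-transformed
  smoothed Gaussian noise cut at prescribed proportions, forest-dominated).
  Each biome has a PFT archetype whose multiplicative ±10% LAI noise and
  ±0.05 seasonality noise never cross the classification thresholds, so the
  classifier recovers the intended biome exactly. Reference-period biomes
  are constant per cell; each future cell-year flips to a uniformly drawn
  different biome with per-cell probability p (i.i.d. Bernoulli), making
  per-cell stability exactly Binomial(n, 1−p)/n. Real biome flips are
  temporally autocorrelated (a shifted biome tends to stay shifted); the
  i.i.d. choice trades that realism for analytically known statistics and
  is the main caveat when reading test results onto real DGVM output.
  Ground truth records the *realized* flip fractions and realized NEE
  period means, so parameter-recovery tests are exact rather than
  statistical.
* **Scenarios**: four presets emulate two GCMs × two SSPs. Mild (SSP126)
  presets use low flip rates (~85% of area above 50% stability) with
  negative NEE trends over ~60% of the area; strong (SSP370) presets flip
  more (~79% stable) but reduce uptake over only ~30% (the
  CO2-fertilization analogue), with larger extremes. NEE trends span about
  ±2 t CO2/ha/yr; interannual NEE noise is 0.02 kgC/m²/yr. NEE is
  independent of the flip realization — the generator makes no attempt to
  couple productivity to biome shifts.
* **Valuation records**: a log-normal body (median 180 $/ha/yr, σ = 1.5 on
  the log scale — right-skewed, and yielding a benefit-transfer baseline
  near 2700 $/ha/yr) with injected exact duplicates, missing-field rows,
  excluded-service rows, and extreme outliers in both tails (10⁻⁴–10⁻¹ and
  10⁶–2.25×10¹⁰ $/ha/yr, split evenly so each tail stays within the 5% the
  quantile trim removes). Injection row sets are disjoint and returned as
  ground truth.
* **SCC table**: multiplicative model
  `base(ssp) * 1.015^(year−2015) * exp(−90·rate) * m(df)`, strictly
  increasing in year and decreasing in rate per damage function; 5-yearly
  1985+ years, SSPs 1–5, rates 0–3%.
* **Countries**: 2020-era GDP-per-capita magnitudes jittered ±5%, with the
  world average carried explicitly so price factors are self-contained.

All randomness derives from one root seed through named substreams
(`SeedSequence([seed, crc32(name)])`), so the landscape realization is
identical across valuation variants and every output is reproducible from
the manifest's seed and config hash.

## Numerical choices and degenerate inputs

* Dominant-PFT ties resolve to roster order, identically on the scalar and
  vectorised classification paths; modal-biome ties resolve to rule order.
* The ordering `stability ≥ 50` / `Δ ≥ 0` puts boundary cells on the
  stable/non-declining side.
* Stability truth is stored as the mean of non-flip indicators (not
  1 − flip mean) so recovery comparisons are bit-exact.
* Empty series, non-finite NEE, negative discount rates, flip rates outside
  [0, 1], unknown PFTs or countries, and record tables that empty out after
  exclusion all raise `ValueError`; pipeline stages wrap failures in a
  stage-named `PipelineError`.
* Gridded I/O uses NetCDF3 (SciPy backend) and long-format CSV; integer
  biome rasters round-trip bit-exactly, and both encodings of a landscape
  yield identical indicators.

## Problem sizes

Default runs use a 100×100 grid, 30 + 30 years and 4 scenarios × 4
variants; the full sweep completes in a few seconds, and the test suite
exercises the same sizes where a statistical claim needs 10,000 cells.

## Limitations

* The landscape has no geodesy: no projection, coastlines, or real country
  geometry; cell area is a constant parameter.
* Biome flips are i.i.d. in time and uniform over target biomes; NEE is
  decoupled from composition.
* The valuation, SCC and country tables are statistical emulations with the
  documented qualitative structure, not data; absolute cost levels from
  synthetic runs are therefore only meaningful relative to one another
  (between variants and scenarios), not as real-world estimates.
* One inflation factor stands in for currency correction; there is no
  original SCC modelling and no econometric estimation of ES values.
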