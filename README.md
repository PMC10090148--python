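# escost

Economic costs of declining biome stability and weakening carbon sinks,
computed from dynamic-vegetation-model output.

Climate change can shift biomes and weaken the CO2 sink of tropical
forests. Both matter economically: stable biomes underpin habitat services
(a bundle of regulating, cultural and supporting ecosystem services), and
net CO2 uptake is climate regulation that can be priced with the social
cost of carbon. `escost` turns gridded vegetation-model output (plant-
functional-type composition and net ecosystem exchange per cell and year)
into monetary cost estimates of projected ecosystem-service declines. It is
aimed at ecosystem-service and climate-impact modellers who post-process
DGVM simulations (e.g. LPJ-GUESS-style output) and want reproducible,
testable economics on top.

The chain, per climate scenario:

1. **Biomization** — an ordered, editable rule table maps each cell-year's
   PFT abundances (plus precipitation seasonality) to one of eight biomes,
   including a diagnosed tropical needleleaf (pine–oak) class.
2. **Indicators** — biome stability
   `stability_i = 100 · Σ_t [biome_{i,t} ≡ biome_ref,i] / n`
   over the future period (2071–2100) against the reference-period modal
   biome (1985–2014); and CO2 sequestration, the period-mean NEE converted
   by `−NEE · 10 · 3.67` to t CO2/ha/yr (uptake positive).
3. **Valuation** — habitat: a benefit-transfer baseline HSV (cleaned,
   biome-grouped record averages), prolongated/discounted as
   `HSV·(1+d)^16` and `HSV/(1+d)^70` for the historical/future central
   years; climate regulation: social-cost-of-carbon prices for 2015/2085.
   Costs are NPV differences, per cell, under four variants:
   {global, national prices} × {2%, no discounting}.
4. **Aggregation** — bivariate stability × ΔCO2 map classes at the 50%/0
   breaks, economic hot spots (both services losing), cost-class summaries,
   and country totals with GDP fractions.

A synthetic-data module generates every input — landscapes with known
ground truth, valuation records with injected defects, SCC and country
tables — so the whole pipeline is testable without any downloads. See
`docs/methods.md` for the full model description and its limitations.

## Worked example

```python
from escost.io import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=1))   # 100×100 grid, 4 scenarios × 4 variants

print(f"habitat service value (2015): {result.hsv_2015:.1f} $/ha/yr")
b = result.bivariate_fractions["GFDL-SSP126"]
print(f"stable area (GFDL-SSP126): "
      f"{100*(b['stable_declining_co2']+b['stable_increasing_co2']):.1f}%")
vr = result.variant_results[("GFDL-SSP126", "global-d0")]
print(f"habitat cost:  {vr.region.habitat_cost_total/1e6:.1f} M$/yr")
print(f"climate cost:  {vr.region.climate_cost_total/1e6:.1f} M$/yr")
print(f"hot-spot area: {100*vr.region.hotspot_area_fraction:.1f}%")
print(vr.country_table[["country", "total_cost_usd_yr", "cost_pct_gdp"]]
      .sort_values("cost_pct_gdp", ascending=False).head(3).to_string(index=False))
```

prints

```
habitat service value (2015): 2291.9 $/ha/yr
stable area (GFDL-SSP126): 84.9%
habitat cost:  558.4 M$/yr
climate cost:  103.3 M$/yr
hot-spot area: 53.0%
country  total_cost_usd_yr  cost_pct_gdp
     BZ       2.286025e+07      1.265709
     NI       1.194907e+08      0.939478
     HN       6.602922e+07      0.284323
```

Reading this: the cleaned benefit-transfer records give a habitat service
value of ~2 292 $/ha/yr; under the mild scenario 84.9 % of the area keeps
its biome in more than half of the future years; with global prices and no
discounting the synthetic region loses ~558 M$/yr of habitat services and
~103 M$/yr of climate regulation, with both services declining together on
53 % of the area; and relative to GDP the poorest economies (here Belize
and Nicaragua) are hit hardest.

The same run is available from the shell:

```sh
escost run --seed 1 --out run1        # writes CSVs + manifest.json
escost report --run-dir run1          # prints the regional summary
escost synth landscape --seed 1 --out land.nc
escost scheme --out scheme.yaml       # editable biomization table
```

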