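# parkshed

Do parks actually see less disturbance than the landscapes around them?
`parkshed` compares three decades of stand-replacing forest disturbance —
wildfire and harvest — inside parks and protected areas (PPAs) against
matched samples of their immediate surroundings, the *greater park
ecosystems* (GPEs), and against whole ecozones. It is aimed at landscape
ecologists and conservation analysts working with Landsat-style per-pixel
disturbance products (event year + agent class) and protected-area polygons.

## Method

For each eligible PPA (land area ≥ 100 ha, strict IUCN class Ia/Ib/II/IV,
protected for ≥ 10 years):

1. **GPE delineation.** A square search window grows outward from the
   footprint one pixel ring at a time (Chebyshev distance), collecting
   pixels that are not water, agriculture, or any protected area, until a
   candidate region of exactly **2 × |footprint|** pixels is assembled; an
   equal-area sample of **|footprint|** pixels is then drawn uniformly
   without replacement.
2. **Rates.** For unit *u* with land-pixel set *P(u)* over its protection
   period of *n* years (inclusive; 1985–2015 ⇒ *n* = 31, truncated to the
   establishment year when later),

   rate(u, agent) = 100 · |{p ∈ P(u) : event(p) = agent, year(p) in window}| / |P(u)| / n  [%/yr]

   The same period applies to a PPA and its GPE. Ecozone rates use all land
   pixels of the zone over the full window.
3. **Comparison layer.** Per ecozone, two-sided paired t-tests of PPA vs
   GPE rates (α = 0.05); Pearson *r* between PPA and GPE rates per agent;
   the relative difference 100·(PPA_D − GPE_D)/((PPA_D + GPE_D)/2) ∈
   [−200, 200]; the fraction of units with > 0.1 %/yr disturbed; means by
   integer-degree latitude bin and a 55° N split.

A first-class synthetic-scenario generator produces landscapes with the
structure this analysis assumes — fires as contiguous patches that ignore
protection boundaries and intensify northward, harvest patches strictly
excluded from protection and intensifying southward — so the full pipeline
is testable without any data download. Real disturbance rasters (GeoTIFF)
and PPA/ecozone polygons (GeoJSON) feed the identical code path.

## Worked example

```sh
python examples/compare_fire_harvest.py
```

```
analyzed units: 46
fire     mean PPA 0.530  mean GPE 0.543 %/yr  t=  -0.34  p=7.36e-01  r=0.748
harvest  mean PPA 0.000  mean GPE 0.384 %/yr  t=  -9.23  p=6.02e-12  r=0.000
mean burn rate below 55N: 0.382 %/yr, at/above 55N: 0.856 %/yr
GPE units with harvest >0.1%/yr: 83%
PPA units with harvest >0.1%/yr: 0%
```

Fire rates inside and beside protection are statistically indistinguishable
(p = 0.74) and strongly correlated (r = 0.75) — fire does not respect the
boundary. Harvest is significantly higher in the neighbourhoods
(0.38 %/yr vs 0.00, p ≈ 6e-12) with no correlation — harvest stops at the
boundary. Burn rates roughly double north of 55° N, where the scenario's
fire intensity gradient peaks. `examples/delineate_neighbourhood.py` and
`examples/disturbance_rates.py` walk the delineation geometry and the rate
arithmetic on small inputs.

## Command line

```sh
parkshed run-all --config cfg.yaml --out run1 --seed 7
parkshed simulate|delineate|rates|compare ...   # stage-by-stage
```

Outputs are flat CSV (rates, comparisons, correlations, latitude
summaries, GPE manifest), GeoTIFF rasters, GeoJSON vectors, and a JSON run
manifest; re-running an identical config reproduces the CSVs byte for byte.

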