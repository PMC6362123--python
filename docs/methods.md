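# Methods

## The comparison problem

A protected area's disturbance history only means something relative to a
counterfactual: what would have burned or been cut on that land had it not
been protected. `parkshed` operationalizes the counterfactual as the
*greater park ecosystem* (GPE) — an equal-area random pixel sample drawn
from the closest available unprotected, non-water, non-agricultural land
around each park. Because the control is immediately adjacent, it shares
the park's climate, latitude and fire regime; what differs is protection.

## GPE delineation

The search window is square: ring *d* contains the pixels whose minimum
Chebyshev distance to the footprint equals *d*. Rings are accumulated
(excluding water, agriculture, the target's own footprint and all other
protected areas) until the cumulative count reaches 2 × |footprint|; the
final, overshooting ring is trimmed by seeded uniform sampling without
replacement so the candidate hits the 2× target exactly. The equal-area
sample is then drawn uniformly without replacement from the candidate.
Implementation uses an exact chessboard distance transform
(`scipy.ndimage.distance_transform_cdt`); the test suite checks it against
a brute-force distance-sort oracle on random landscapes.

Design choices where the procedure was genuinely open:

* **Window shape** — Chebyshev rings (a square window grown one pixel per
  iteration). Any isotropic window satisfies the same contracts; square is
  the natural raster search window and exactly ring-decomposable.
* **Overshoot** — trimmed to exactly 2×, preserving the stated area target;
  accepting overshoot would bias candidate size upward for small units.
* **Unreachable targets** — growth is capped at `max_radius_px`
  (default 3333 px, i.e. 100 km at 30 m). Units whose candidate is smaller
  than their footprint are excluded from paired analyses and reported;
  incomplete-but-sufficient candidates are retained with a warning.
* **Sampling without replacement** — an exact-count equal-area sample;
  replacement would break the equal-area property.

## Rates

rate = 100 × disturbed / land / n_years, with the year count inclusive
(1985–2015 = 31 years; both endpoint years can carry events). Units
established after the window start are assessed from their establishment
year, and the identical truncated window applies to their GPE, so pairs
stay comparable. The 100 ha eligibility threshold is applied on exact area
(pixel count × pixel area ≥ 10⁶ m²), not a rounded pixel count. Ecozone
membership follows the area-weighted centroid of the land footprint
(centroids exactly on a boundary go to the lexicographically smallest zone
id); ecozone-level rates pool all land pixels of the zone over the full
window with no tenure truncation.

## Comparison layer

Per-ecozone two-sided paired t-tests at α = 0.05 on per-unit rate pairs
(d = PPA − GPE). Differences with zero variance — including an exact
constant shift, detected up to float rounding at 10⁻¹² of the data scale —
yield an undefined result that claims no significance. No multiplicity
correction is applied across ecozones by default, matching per-zone
reporting at a fixed α; `holm_adjust` is available and off by default.
Pearson *r* is undefined for a constant vector; the pipeline-level summary
reports r = 0 with a `defined = False` flag in that case, since "no
measurable linear association" is the informative summary when, e.g.,
harvest never occurs inside protection. The relative difference
100·(PPA_D − GPE_D)/mean(PPA_D, GPE_D) is clamped to its exact bounds
[−200, 200] against float rounding and undefined when both rates are zero.
Latitude bins round unit centroid latitude half-away-from-zero to the
nearest degree; the 55° N split counts units exactly at the threshold as
"above"; split means pool PPA and GPE units.

## Synthetic scenarios

The generator emulates the statistical structure the analysis assumes, not
fire physics: ignitions are Poisson-seeded per year with per-row intensity
linear in latitude, and each grows into a contiguous patch by stochastic
4-neighbour region growth with geometric size (configurable mean). Fire
spreads across protection boundaries and stops only at water/agriculture;
harvest additionally never enters any protected footprint. Each pixel keeps
its first event (fire wins where both agents reach a pixel in the same
run order). Water/agriculture masks are contiguous blobs hitting requested
fractions within ±20 %. One master seed drives named substreams per
purpose, year, and unit, so scenarios are bit-reproducible and adding a
unit does not perturb unrelated draws.

The two canonical scenarios (`parkshed.scenarios`) fix the study
conditions:

* **Fire-correlation scenario** — 200 units on a 500×500 grid, fire only,
  0.02 → 2 %/yr of land burned annually from 45° N to 62° N. Unit areas
  (80–600 px) are large relative to the mean patch (6 px) so each unit
  integrates many independent events and the latitude gradient dominates
  between-unit variance; boundary-crossing fires then make PPA and GPE burn
  rates strongly correlated (r ≈ 0.85).
* **Harvest-contrast scenario** — 50 units on a 250×250 grid with both
  agents: fire 0.1 → 1 %/yr northward, harvest 0.8 → 0 %/yr southward and
  excluded from protection. GPE harvest significantly exceeds PPA harvest
  (which is structurally zero) while fire stays uncontrasted and
  correlated.

Both use 100 m pixels so that footprints of a few hundred pixels span
realistic park areas (80–600 ha) around the 100 ha eligibility threshold
at desk scale; `ScenarioConfig` defaults to 30 m for product-resolution
work. Grid sizes and the 30 acceptance-script replicates are the package's
own scale choices for quick, single-CPU runs.

What the synthetic landscapes do **not** emulate: fuel and weather-driven
fire shapes and size distributions, spatial autocorrelation of harvest
scheduling (cut-block adjacency rules), multi-year disturbance (a pixel
disturbed twice), insect and other non-stand-replacing agents, and real
coastline/terrain geometry. Passing structural tests therefore shows the
pipeline recovers boundary-related contrasts when present — not that any
particular real landscape exhibits them.

## Numerical conventions and degenerate inputs

Pixel-in-polygon uses the pixel-center rule with boundary counted inside —
the single rasterization convention for protected areas and ecozones
alike. Rasters are single-band GeoTIFFs (int16 year, uint8 agent codes
0/1/2 = none/fire/harvest) carrying ModelPixelScale/ModelTiepoint
georeferencing; inputs must be pre-aligned (no reprojection). Ingestion
coerces pixels violating the agent⇔year consistency rule to no-event with
a logged count. Empty pixel sets raise undefined-rate errors rather than
returning NaN; empty candidate regions yield empty samples and exclusion
downstream. All CSV outputs have fixed column order and are byte-identical
across reruns of the same config.

## Known limitations

Paired t-tests on rate data are used as specified even though rates are
bounded and zero-inflated; the permutation cross-check in the tests guards
the calibration only at small n. GPE candidate regions of different units
may overlap each other (only protected footprints are mutually excluded),
so units packed densely share surroundings and their rates are not fully
independent. Ecozone assignment by centroid puts a boundary-straddling
unit wholly into one zone. Real-data mode expects single-event-per-pixel
products; products with repeat disturbance must be reduced upstream.
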