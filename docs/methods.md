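# Methods

## Model and assumptions

`baar` stratifies remaining forest into two near-term deforestation-risk
classes by buffering historical deforestation patches, then uses the
stratification to distribute a jurisdictional FREL to nested projects. The
model's assumptions, in decreasing order of importance:

1. **Past loss predicts future loss.** All predictive signal comes from
   the location and size of calibration-period deforestation patches; no
   covariates (roads, rivers, population) enter the model.
2. **Risk scales with patch size.** A patch of area *aₚ* is buffered by
   `r_high(aₚ, m) = √((aₚ·m + aₚ)/π) − √(aₚ/π)` — the ring width that
   would multiply the patch's equivalent circle by *m*. For non-circular
   patches the ring area is not exactly `m·aₚ` and no correction is
   applied: the equivalent-circle radius is applied to the actual
   footprint. Overlapping buffers are unioned, so the aggregate high-risk
   multiple is below `m` at landscape scale.
3. **Two strata suffice.** The buffer union, clipped to eligible forest,
   is high risk; the rest is low risk. The deforested footprints are not
   forest and belong to neither stratum.
4. **The FREL is taken as given.** Allocation redistributes it spatially;
   it never alters the total.

## Pipeline and parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| minimum contiguous forest | 5,000 | ha | eligibility filter on the benchmark forest |
| minimum patch size | 0.18 | ha | drops sub-two-pixel (30 m) noise patches |
| connectivity | 8 | — | patch adjacency; a diagonal pixel pair is one patch |
| area multiple m | sweep 1–120 | — | buffer size dial; one map per m |
| calibration / validation | 10 / 4 | yr | period split (2000–2010 / 2010–2014 pattern) |
| NDC target | caller-supplied | % | enters MPE only |
| FREL | caller-supplied | tCO₂e/yr | total to distribute |
| high:low split | 90:10 | % | policy share of FREL per stratum |

Year windows are half-open `(start, end]`, so the calibration and
validation periods share their boundary year without double counting. The
patch-size filter keeps patches with area ≥ 0.18 ha, so a two-pixel patch
passes; with the default 8-connectivity that includes a diagonal pair.
Both the threshold's strictness and the connectivity are arguments.

**Buffer geometry.** The canonical mode (`mode="vector"`) polygonises each
patch's pixel footprint and selects forest cells whose centre lies within
exact Euclidean distance `r_high` of the polygon (`shapely.dwithin`). A
pure-raster mode measures centre-to-centre distances with a Euclidean
distance transform; it is cheaper, biased slightly low (about half a pixel
of the footprint's extent is lost), and non-canonical. On a single
near-circular patch both modes reproduce the closed-form ring area
`π(R+r)² − πR² = m·aₚ` to under 2% at 5 m pixels; the vector mode carries
a small positive bias (the pixel staircase bulges outside the inscribed
circle) of roughly +3% at 10 m pixels for a 200 m-radius patch, shrinking
with pixel size. Buffers running past the grid edge are clipped; edge
effects are accepted and logged.

**Metrics.** Predictive power, precision and the aggregate multiple are
exact cell-count ratios. The MPE denominator is the *scaled* predictive
power: the published formulation prints plain PP, but its worked values
(21/1.645 → 12.8%, 21/1.95 → 10.8%) are only consistent with PPs, and the
two coincide when the periods are equal — so PPs is used throughout. The
efficiency column has no published formula; it is reconstructed as
`PP × Pr` (as fractions), which matches the published table to within the
rounding of its inputs, and is labelled "reconstructed" here for that
reason. Map selection takes the median-MPE candidate among those with
MPE < 100%; an even candidate count uses the lower-middle rank and exact
MPE ties break toward the smaller m. The published selection is not
uniquely recoverable from the published table under any fixed median
convention, so the rule also accepts a caller-supplied callable.

**Allocation.** Within each stratum the density is uniform per hectare
(`d_s = split_s · FREL / A_s`) — the minimal assumption given that only
the split and the carbon weighting are specified. Carbon weighting is
applied per stratum and per forest type as
`d_{s,t} = d_s · stock_t / stock̄_s` with `stock̄_s` the area-weighted mean
stock of the stratum, which preserves each stratum total exactly (no
double counting against the jurisdictional FREL). Weighting the strata
independently rather than jointly is a design choice; the alternative
would let high-risk allocation leak into low-risk strata through a shared
mean. The PAA is derived by centre-containment rasterization of the
project polygon intersected with cells continuously forested for the 10
years before the project start; since the history model is monotone (no
regrowth), this equals "not lost by the start year", and the history must
reach 10 years back or the derivation refuses. The sensitivity summary
reports the relative standard deviation as population SD / mean × 100 so
that two scenarios of 90 and 110 give exactly 10%.

## Synthetic landscapes

The generator emulates the structural features the method relies on:

- a patchy but largely connected forest benchmark (thresholded smoothed
  Gaussian noise);
- calibration patches grown at random seeds with log-normal sizes
  (median 8 ha, σ_log 0.8) and uniform year tags;
- validation loss drawn per remaining-forest cell with probability
  ∝ `exp(−d/λ)` (d = distance to the nearest calibration patch,
  λ = 300 m default), scaled to a 3% expected loss fraction — loss
  clustered on the frontier, which is exactly the regime where buffering
  past loss should beat an area-proportional null;
- Voronoi forest-type zones with Congo-basin-style stocks
  (747/409/245 tCO₂e/ha) and rectangular projects on forest.

Defaults use a 200 × 200 grid of 1-ha cells with the 10/4-year period
split. A single seeded `numpy.random.default_rng` (PCG64) stream drives
placement, sizes and draws in fixed order, so one seed fixes every output
bit-exactly across platforms.

What the generator does **not** emulate: roads or other access drivers,
regrowth, spatially autocorrelated multi-year frontier progression (each
validation cell is drawn independently), mixed-pixel boundaries, or map
classification error. Tests passing on these landscapes therefore
demonstrate the pipeline's accounting and its behaviour under the
clustered-loss assumption — not predictive skill on real activity data.

## Numerical choices and degenerate inputs

- Areas are exact cell counts × `pixel_size²/10⁴`; the high/low partition
  of eligible forest is exact by construction, never approximate.
- Exponential frontier weights are computed relative to the minimum
  candidate distance before scaling, so tiny decay lengths degrade to
  adjacent-cell loss instead of underflowing to no loss.
- An empty patch set yields a valid all-low-risk map; an empty PAA yields
  a zero baseline with a warning; an empty stratum with a nonzero split,
  zero validation loss, a zero-area high stratum, or a zero mean stock are
  errors, not NaNs.
- Grids must share geometry exactly (shape, origin, pixel, CRS);
  mismatches raise rather than resample. Geographic (degree) CRS
  identifiers are refused via a small deny-list (EPSG:4326 family,
  `longlat`/`degree` markers); arbitrary projected CRS ids beyond that
  list are trusted, not validated — a deliberate limitation in the absence
  of a full CRS database.
- Rasters travel as ESRI ASCII grids with a JSON sidecar (CRS id, integer
  nodata); categorical values are never interpolated.

## Problem sizes

The test suite and the acceptance script run on 80–340² grids (toy
fixture, ring-geometry checks at 5 m pixels, and 120² frontier landscapes
over 20 seeds), sizes at which the vector buffer path and the exhaustive
test oracles are comfortably exact; the pipeline itself is O(patches ×
buffer window) and handles larger grids by windowed per-patch work.

## Known limitations

- Two risk strata only; no probabilistic risk surface.
- Single-stage allocation (FREL → projects); multi-stage subnational
  tiers are out of scope.
- No uncertainty discounts, reversal buffers or planned-deforestation
  adjustments.
- The vector buffer cost grows with patch perimeter; continental rasters
  would need tiling that is deliberately not implemented.
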