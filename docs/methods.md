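# Methods

## Model

`dasycrop` implements capped, population-weighted dasymetric
disaggregation: an administrative unit's crop total is spread over its
pixels proportionally to rural population, under a per-pixel capacity
cap. The underlying assumptions are the ones that make rural population
a defensible single covariate for a subsistence root crop: the crop is
grown near the people who eat it, its density responds linearly to
rural population up to a physical ceiling, and dense urban populations
do not farm. No cropland mask, suitability index or multi-covariate
fusion is used — that is a deliberate scope boundary, not an oversight
(see Limitations).

The pipeline for one quantity kind (production in tonnes, or harvested
area in hectares — two fully independent runs):

1. urban masking of the population grid;
2. rasterisation of admin polygons to per-pixel unit membership;
3. zonal rural-population sums;
4. proportional standardisation of raw census values to national
   reference totals;
5. per-capita rates;
6. neighbour/group imputation of missing rates;
7. per-unit linear allocation plus capped redistribution;
8. optional bounding-box gap fill.

Everything downstream of the synthetic generator is deterministic.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `urban_threshold` | 5,000 | people/pixel | strictly-above cutoff for urban masking; a pixel exactly at the cutoff is rural |
| `cap_harvested_area` | 50 | ha/pixel | half of a ~100 ha pixel can be under the crop |
| `cap_production` | 1,000 | t/pixel | follows from the 50 ha cap and the yield ceiling |
| `implied_max_yield` | 20 | t/ha | must equal `cap_production / cap_harvested_area`; enforced through the cap ratio, never as a joint per-pixel constraint |
| `convergence_tol` | 1e-9 | native units | max tolerated cap violation / residual for feasible units |
| `infeasible_policy` | `cap-and-report` | — | units whose total exceeds `n_pixels × cap` have every receiving pixel set to the cap and the leftover surfaced as `residual`; `error` raises instead |
| `zero_population_policy` | `uniform-spread` | — | all-urban units with a positive total are spread evenly over their pixels (still capped); `leave-unallocated` reports the whole total as residual |
| gap-fill `constant_rate` | 0.02 | quantity/person | per-capita rate written into no-unit pixels inside declared bounding boxes |

Every pixel is treated as "approximately 1 km²" regardless of latitude;
no equal-area correction is applied to the caps or the mask threshold.

## Numerical choices

**Pixel membership** is decided by containment of the pixel centre, so
the grid is partitioned unambiguously and zonal sums conserve mass; a
centre exactly on a shared polygon boundary belongs to no interior and
falls outside (in practice rectangles in fixtures are snapped to pixel
edges so this does not arise). "All touched" rasterisation was rejected
because it double-counts boundary pixels.

**Capped redistribution** is formulated as an order-independent fixed
point: pixels above the cap are fixed at the cap and the deducted
excess is re-spread over the still-uncapped pixels proportionally to
population, repeatedly. Each pass caps at least one new pixel, so at
most `n` passes run. The fixed point is the water-filling solution
`x_i = min(cap, λ·pop_i)` with λ set by conservation, which is how the
test-suite oracle computes it independently (bisection on λ).
Proportional-to-population redistribution weights were chosen for
consistency with the linear allocation model; an equal-split
alternative would break the monotonicity guarantee (a higher-population
pixel never receives less).

**Standardisation order.** Country raw sums include only units with
data; missing units receive none of the national total at the scaling
stage and are handled afterwards as imputed per-capita rates. The
alternative — imputing raw values first and scaling everything
together — would make imputed mass count against the national total;
here imputed mass is always *additional* and reported, so the choice is
visible in the outputs either way.

**Imputation** donor order: explicit unit-group map (the hook for
agro-ecological-zone style groupings chosen by expert judgement), then
same-country adjacency (positive-length shared boundary; corner contact
does not count), then the country mean as a last resort. "Average" is
the unweighted arithmetic mean of per-capita rates, not a
population-weighted mean, because the quantity being borrowed is the
rate itself. Donors are always original rates — imputed values never
cascade. The gap-fill constant is user input with 0.02 as the
documented default; the rule by which such a constant should be derived
from neighbouring pixels is left to the user.

**Degenerate inputs.** Zero-rate or zero-total units allocate zeros;
positive totals over zero rural population follow
`zero_population_policy`; units covering no pixel centre are logged and
their total reported as residual; nodata population pixels count as 0
people in zonal sums but stay nodata in written rasters.

## Synthetic generator

`synthetic.make_landscape` emulates the *shape* of the real inputs: a
lognormal rural background (mean 50 people/pixel, σ = 1 — a plausible
rural density for the region at ~1 km), Gaussian urban hotspots peaking
at 8,000 people/pixel so the 5,000 cutoff genuinely bites, a
rectangular unit partition (chosen over Voronoi for exactly
reproducible adjacency), and per-unit true rates drawn uniformly from
FAO-scale per-capita magnitudes (production 0.05–0.5 t/person —
continental cassava output over rural population is ≈0.2 t/person —
and harvested area 0.005–0.05 ha/person). Census values are the zonal
truth sums times one jitter factor per country (0.8–1.25), so
standardisation has real work to do while within-country proportions —
and hence exact truth recovery — are preserved; a per-unit jitter would
deliberately break recovery and is not what the generator models.
`missing_fraction` blanks units at random without ever emptying a
country.

What it does **not** emulate: real geography (coastlines, enclaves,
sliver polygons), LandScan's weighting artefacts, spatially correlated
census error, or cross-country boundary misalignment beyond the
bbox-fill hook. Passing tests therefore demonstrate the *algorithmic*
contracts (conservation, caps, recovery, imputation bounds) — not that
the proxy assumption holds for any real crop.

Default problem sizes (40×40 grid, 2 countries × 4 units) keep every
test and the acceptance script in seconds while still exercising
hotspots, capping and imputation; the algorithms are linear in pixel
count and have been run on much larger grids without issue.

## Limitations

- Single-covariate allocation: regions where cultural preference,
  poverty or market access decouple the crop from rural population are
  systematically mis-allocated; national-resolution censuses produce
  flat, variance-underestimating surfaces.
- Inputs must share one geographic grid; there is no reprojection,
  resampling or equal-area pixel correction.
- Production and harvested area are independent layers; the 20 t/ha
  ceiling holds per pixel only through the cap ratio, and the two
  layers' cap events need not coincide.
- Shapefile input is not supported; admin layers are GeoJSON.
- Imputation strategies are per-run, not per-unit; reproducing
  hand-curated per-unit donor choices requires the unit-group map.
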