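# dasycrop

Population-weighted dasymetric disaggregation of administrative crop
statistics onto a ~1 km grid.

Agricultural censuses in much of sub-Saharan Africa report crop
production (tonnes) and harvested area (hectares) only per province or
district, from scattered census years. For crops like cassava — grown
by smallholders, intercropped, and effectively invisible to satellite
classification — the distribution of the *rural population* is the best
available proxy for where the crop actually is. `dasycrop` turns zonal
census totals plus a gridded population surface into per-pixel crop
density layers, with known conservation and capacity guarantees, and
ships a synthetic landscape generator so the whole pipeline is testable
without any proprietary data.

## Method

For each administrative unit and quantity kind, with national
reference-year (2014-style) totals:

1. **Urban mask.** Pixels with population density strictly above
   5,000 inhabitants per ~1 km² pixel are deemed non-farming and get
   weight 0; the rest is the *rural population*.
2. **Standardisation.** Raw unit values are rescaled so each country
   sums to its national reference total:
   `adjusted_u = raw_u / Σ_country raw × national_total`.
3. **Per-capita rate.** `rate_u = adjusted_u / rural_pop_u`, the linear
   allocation coefficient (t/person or ha/person).
4. **Allocation.** Each pixel receives `rate_u × pixel_population`,
   subject to per-pixel capacity caps — at most half a pixel under the
   crop (50 ha) and a 20 t/ha yield ceiling, hence at most 1,000 t of
   production per pixel. Where linear allocation overshoots, the excess
   is deducted and redistributed over the unit's uncapped pixels in
   proportion to population until no pixel exceeds the cap
   (water-filling); the unit total is conserved whenever it fits under
   `n_pixels × cap`.
5. **Missing data.** Units without census values get the unweighted
   mean rate of same-country adjacent units (or of a user-declared unit
   group), logged per unit with its donors. Pixels covered by no
   polygon (misaligned national boundaries) can be gap-filled inside
   declared bounding boxes at a constant per-capita rate (default
   0.02).

## Worked example

Saturated-unit water-filling (`examples/01_capped_water_filling.py`):
a town of 1,000 people and nine villages of 100 share 8,000 t.

```
per-capita rate:    4.2105 t/person
linear allocation:  [4210.5  421.1  421.1  421.1  421.1  421.1  421.1  421.1  421.1  421.1]
after water-fill:   [1000.   777.8  777.8  777.8  777.8  777.8  777.8  777.8  777.8  777.8]
iterations=1  residual=0.00e+00  total=8000.0 (conserved)
```

The town pixel is clipped at the 1,000 t/pixel cap and the deducted
3,210 t moves to the village pixels; the unit total is unchanged.

End to end on a synthetic two-country landscape
(`examples/04_end_to_end_synthetic.py`, seed 1, one district blanked):

```
C0: reference    39424.1 t, allocated    65596.9 t
C1: reference    16134.5 t, allocated    16134.5 t
max pixel value: 1000.0 t (never above the 1,000 t/pixel cap)
```

C1's census is complete, so its allocation equals the national
reference exactly. C0 has an imputed district whose neighbour-mean rate
× population sits on top of the scaled total — imputed mass is always
additional and always reported.

The other examples cover standardisation/per-capita rates and the
imputation log. A `dasycrop` CLI (`simulate`, `disaggregate`,
`validate`) wraps the same library for shell use:

```bash
dasycrop simulate --seed 3 --out data/
dasycrop disaggregate --population data/population.tif --units data/units.geojson \
    --census data/census.csv --totals data/totals.csv --kind production --out out/
dasycrop validate --grid out/production_grid.tif --report out/production_report.csv --cap 1000
```

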