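"""Synthetic landscapes with known ground truth for testing the pipeline.

Emulates the shape of the real inputs without any external data: a
population surface with a diffuse lognormal rural background and dense
Gaussian urban hotspots (exceeding the urban mask threshold), a
rectangular admin-unit partition per country, per-unit per-capita rates
drawn from FAO-scale ranges, and census tables whose country sums are
jittered away from the national reference totals so the standardisation
step has real work to do.  Truth grids record the exact per-pixel
allocation implied by the drawn rates, so every pipeline stage can be
checked against a known answer.

All randomness flows from one seeded generator; a fixed seed reproduces
the landscape bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from shapely.geometry import box

from .allocate import AllocationConfig, allocate_linear, redistribute_capped
from .errors import ParameterError
from .grid import (
    AdminLayer,
    AdminUnit,
    GridSpec,
    PopulationGrid,
    UnitIdGrid,
    mask_urban,
    rasterize_admin,
    zonal_population,
)
from .standardize import HARVESTED_AREA, PRODUCTION, CensusRecord, NationalTotal

#: Default per-capita rate ranges, quantity per rural person per year.
#: Production ~0.2 t/person is the continental-scale cassava magnitude
#: (~150 Mt over ~700 M people); harvested area is an order of magnitude
#: smaller in its own units (ha/person).
DEFAULT_RATE_RANGES: Mapping[str, Tuple[float, float]] = {
    PRODUCTION: (0.05, 0.5),
    HARVESTED_AREA: (0.005, 0.05),
}


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the generator; defaults give a small but non-trivial world."""

    seed: int = 0
    n_countries: int = 2
    units_per_country: int = 4
    n_rows: int = 40
    n_cols: int = 40
    origin_lon: float = 30.0
    origin_lat: float = 2.0
    cell_size: float = 30.0
    rural_density_mean: float = 50.0      # people / pixel
    rural_sigma: float = 1.0              # lognormal shape
    n_urban_hotspots: int = 2
    hotspot_peak: float = 8_000.0         # people / pixel, above the mask cutoff
    hotspot_width: float = 1.5            # Gaussian sigma, pixels
    urban_threshold: float = 5_000.0
    true_rate_ranges: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATE_RANGES))
    missing_fraction: float = 0.0
    census_scale_jitter: Tuple[float, float] = (0.8, 1.25)

    def __post_init__(self) -> None:
        if not (0 <= self.missing_fraction < 1):
            raise ParameterError("missing_fraction must be in [0, 1)")
        if self.hotspot_peak <= self.urban_threshold:
            raise ParameterError(
                "hotspot_peak must exceed urban_threshold to exercise masking"
            )
        if self.n_countries < 1 or self.units_per_country < 1:
            raise ParameterError("need at least one country and one unit")
        if self.n_cols < self.n_countries or self.n_rows < self.units_per_country:
            raise ParameterError("grid too small for the requested units")

    @property
    def spec(self) -> GridSpec:
        return GridSpec(self.origin_lon, self.origin_lat,
                        self.n_rows, self.n_cols, self.cell_size)


@dataclass
class Landscape:
    """A generated world: inputs plus the per-pixel truth."""

    params: SyntheticParams
    population: PopulationGrid
    layer: AdminLayer
    zones: UnitIdGrid
    true_rates: Dict[Tuple[str, str], float]   # (unit_id, kind) -> rate
    truth: Dict[str, np.ndarray]               # kind -> per-pixel allocation (NaN outside)
    reference_totals: List[NationalTotal]      # true country sums

    def truth_country_sum(self, country: str, kind: str) -> float:
        mask = np.zeros(self.population.spec.shape, dtype=bool)
        for u in self.layer:
            if u.country == country:
                rr, cc = self.zones.pixels_of(u.unit_id)
                mask[rr, cc] = True
        return float(np.nansum(self.truth[kind][mask]))


def _rect_partition(params: SyntheticParams) -> AdminLayer:
    """Countries as vertical strips, units as horizontal bands per strip.

    Rectangle edges sit on pixel boundaries so centre containment is
    unambiguous and adjacency fixtures are exactly reproducible.
    """
    spec = params.spec
    d = spec.cell_deg
    col_edges = np.linspace(0, spec.n_cols, params.n_countries + 1).round().astype(int)
    row_edges = np.linspace(0, spec.n_rows, params.units_per_country + 1).round().astype(int)
    units = []
    for ci in range(params.n_countries):
        country = f"C{ci}"
        for ui in range(params.units_per_country):
            x0 = spec.origin_lon + col_edges[ci] * d
            x1 = spec.origin_lon + col_edges[ci + 1] * d
            y0 = spec.origin_lat - row_edges[ui + 1] * d
            y1 = spec.origin_lat - row_edges[ui] * d
            units.append(AdminUnit(
                unit_id=f"{country}_U{ui}", country=country, level=1,
                geometry=box(x0, y0, x1, y1)))
    return AdminLayer(units)


def make_landscape(
    params: SyntheticParams,
    rng: Optional[np.random.Generator] = None,
    config: Optional[AllocationConfig] = None,
) -> Landscape:
    """Generate population, admin units and the capped per-pixel truth."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    config = config or AllocationConfig(urban_threshold=params.urban_threshold)
    spec = params.spec

    # lognormal rural background with mean rural_density_mean people/pixel
    mu = np.log(params.rural_density_mean) - params.rural_sigma**2 / 2
    pop = rng.lognormal(mu, params.rural_sigma, size=spec.shape)

    # Gaussian urban hotspots poking above the mask threshold
    rr, cc = np.mgrid[0:spec.n_rows, 0:spec.n_cols]
    for _ in range(params.n_urban_hotspots):
        r0 = rng.uniform(2, spec.n_rows - 2)
        c0 = rng.uniform(2, spec.n_cols - 2)
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        pop += params.hotspot_peak * np.exp(-d2 / (2 * params.hotspot_width**2))

    population = PopulationGrid(spec, pop)
    layer = _rect_partition(params)
    zones = rasterize_admin(layer, spec)
    rural = mask_urban(population, params.urban_threshold)
    rural_vals = rural.filled(0.0)

    true_rates: Dict[Tuple[str, str], float] = {}
    truth: Dict[str, np.ndarray] = {}
    for kind in (PRODUCTION, HARVESTED_AREA):
        lo, hi = params.true_rate_ranges[kind]
        grid = np.full(spec.shape, np.nan)
        cap = config.cap_for(kind)
        for unit in layer:
            rate = float(rng.uniform(lo, hi))
            true_rates[(unit.unit_id, kind)] = rate
            pr, pc = zones.pixels_of(unit.unit_id)
            lin = allocate_linear(rate, rural_vals[pr, pc])
            capped, _, _ = redistribute_capped(lin, rural_vals[pr, pc], cap,
                                               config.convergence_tol)
            grid[pr, pc] = capped
        truth[kind] = grid

    totals = []
    countries = layer.countries()
    for kind in (PRODUCTION, HARVESTED_AREA):
        for country in countries:
            s = 0.0
            for u in layer:
                if u.country == country:
                    pr, pc = zones.pixels_of(u.unit_id)
                    s += float(np.nansum(truth[kind][pr, pc]))
            totals.append(NationalTotal(country, kind, s))

    return Landscape(params=params, population=population, layer=layer,
                     zones=zones, true_rates=true_rates, truth=truth,
                     reference_totals=totals)


def make_census(
    landscape: Landscape,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[CensusRecord], List[NationalTotal]]:
    """Derive census tables from the truth grids.

    Raw unit values are the zonal sums of the truth scaled by one jitter
    factor per country (so standardisation is non-trivial but preserves
    within-country proportions); reference totals are the exact country
    sums of the truth.  ``missing_fraction`` of units is blanked at
    random per quantity kind, never blanking every unit of a country.
    """
    params = landscape.params
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    lo, hi = params.census_scale_jitter
    jitter = {c: float(rng.uniform(lo, hi)) for c in landscape.layer.countries()}

    records: List[CensusRecord] = []
    for kind in (PRODUCTION, HARVESTED_AREA):
        unit_ids = landscape.layer.unit_ids
        n_missing = int(round(params.missing_fraction * len(unit_ids)))
        missing: set = set()
        if n_missing:
            # keep at least one unit with data per country
            protected = {}
            for u in landscape.layer:
                protected.setdefault(u.country, u.unit_id)
            eligible = [u for u in unit_ids if u not in protected.values()]
            chosen = rng.choice(len(eligible), size=min(n_missing, len(eligible)),
                                replace=False)
            missing = {eligible[i] for i in chosen}
        for unit in landscape.layer:
            pr, pc = landscape.zones.pixels_of(unit.unit_id)
            true_sum = float(np.nansum(landscape.truth[kind][pr, pc]))
            value = None if unit.unit_id in missing else true_sum * jitter[unit.country]
            year = int(rng.integers(1999, 2014))
            records.append(CensusRecord(unit.unit_id, unit.country, kind,
                                        value, census_year=year,
                                        source="synthetic"))
    return records, list(landscape.reference_totals)


def simulate(params: SyntheticParams) -> Tuple[Landscape, List[CensusRecord], List[NationalTotal]]:
    """One-call generator: landscape plus census, single seeded stream."""
    rng = np.random.default_rng(params.seed)
    landscape = make_landscape(params, rng)
    records, totals = make_census(landscape, rng)
    return landscape, records, totals
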