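"""Capped per-capita allocation of unit totals to pixels.

Within each admin unit the quantity is spread linearly over rural
population: pixel allocation = per-capita rate x pixel population.  Two
physical caps bound each ~1 km pixel: at most half of it can be under
the crop (50 ha of harvested area) and yields do not exceed 20 t/ha,
hence at most 1,000 t of production.  Where linear allocation overshoots
a cap, the excess is deducted and redistributed among the unit's
still-uncapped pixels in proportion to their population, repeatedly,
until no pixel exceeds the cap — a water-filling fixed point.  The unit
total is conserved whenever it fits under pixel-count x cap; otherwise
the unit is infeasible and the unallocatable residual is reported, never
silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InfeasibleUnitError, ParameterError
from .grid import (
    AdminLayer,
    GridSpec,
    PopulationGrid,
    UnitIdGrid,
    mask_urban,
    rasterize_admin,
    zonal_population,
)
from .impute import Adjacency, BBoxFill, UnitGroupMap, adjacency, fill_bbox_gaps, impute_all
from .standardize import (
    HARVESTED_AREA,
    PRODUCTION,
    RATE_MISSING,
    RATE_OK,
    RATE_UNDEFINED,
    AdjustedRecord,
    CensusRecord,
    NationalTotal,
    PerCapitaRate,
    per_capita_rates,
    standardize_to_national,
)

logger = logging.getLogger(__name__)

# Per-pixel capacity defaults: half a ~100 ha pixel under the crop, and a
# 20 t/ha yield ceiling, so at most 1,000 t of production per pixel.
DEFAULT_CAP_HARVESTED_AREA = 50.0     # hectares / pixel
DEFAULT_CAP_PRODUCTION = 1_000.0      # tonnes / pixel
DEFAULT_MAX_YIELD = 20.0              # tonnes / hectare


@dataclass(frozen=True)
class AllocationConfig:
    """Thresholds, caps and degenerate-case policies for a run.

    ``implied_max_yield`` must equal ``cap_production /
    cap_harvested_area``; the yield bound is enforced through the cap
    ratio, not as a joint per-pixel constraint.
    """

    urban_threshold: float = 5_000.0
    cap_harvested_area: float = DEFAULT_CAP_HARVESTED_AREA
    cap_production: float = DEFAULT_CAP_PRODUCTION
    implied_max_yield: float = DEFAULT_MAX_YIELD
    convergence_tol: float = 1e-9
    infeasible_policy: str = "cap-and-report"     # or "error"
    zero_population_policy: str = "uniform-spread"  # or "leave-unallocated"

    def __post_init__(self) -> None:
        if self.cap_harvested_area <= 0 or self.cap_production <= 0:
            raise ParameterError("caps must be > 0")
        if self.urban_threshold <= 0:
            raise ParameterError("urban_threshold must be > 0")
        expected = self.implied_max_yield * self.cap_harvested_area
        if not np.isclose(self.cap_production, expected, rtol=1e-12):
            raise ParameterError(
                f"cap_production ({self.cap_production}) must equal "
                f"implied_max_yield x cap_harvested_area ({expected})"
            )
        if self.infeasible_policy not in ("cap-and-report", "error"):
            raise ParameterError(f"unknown infeasible_policy {self.infeasible_policy!r}")
        if self.zero_population_policy not in ("uniform-spread", "leave-unallocated"):
            raise ParameterError(
                f"unknown zero_population_policy {self.zero_population_policy!r}"
            )

    def cap_for(self, quantity_kind: str) -> float:
        if quantity_kind == PRODUCTION:
            return self.cap_production
        if quantity_kind == HARVESTED_AREA:
            return self.cap_harvested_area
        raise ParameterError(f"unknown quantity_kind {quantity_kind!r}")


@dataclass
class AllocationGrid:
    """Per-pixel allocated quantity; NaN outside all units."""

    spec: GridSpec
    values: np.ndarray
    quantity_kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.spec.shape:
            raise ParameterError("values shape does not match grid spec")

    def total(self) -> float:
        return float(np.nansum(self.values))


@dataclass
class UnitAllocation:
    """Per-unit diagnostics emitted by the driver."""

    unit_id: str
    country: str
    adjusted_value: Optional[float]
    zonal_pop: float
    rate: Optional[float]
    imputed: bool
    n_pixels: int
    n_capped: int
    iterations: int
    residual: float
    status: str  # ok | infeasible | zero-population | no-pixels


@dataclass
class DisaggregationResult:
    """Everything one run produces for one quantity kind."""

    grid: AllocationGrid
    report: pd.DataFrame
    imputation_log: pd.DataFrame
    bbox_added_mass: float = 0.0


def allocate_linear(rate: float, pixel_pops: Sequence[float]) -> np.ndarray:
    """Linear per-capita allocation: out[i] = rate * pops[i]."""
    if rate < 0:
        raise ParameterError(f"rate must be >= 0, got {rate}")
    pops = np.asarray(pixel_pops, dtype=np.float64)
    if pops.size and pops.min() < 0:
        raise ParameterError("pixel populations must be >= 0")
    return rate * pops


def redistribute_capped(
    alloc: Sequence[float],
    pixel_pops: Sequence[float],
    cap: float,
    tol: float = 1e-9,
    infeasible_policy: str = "cap-and-report",
) -> Tuple[np.ndarray, int, float]:
    """Clip allocations at ``cap`` and re-spread the excess (water-filling).

    Iteratively fixes above-cap pixels at the cap and redistributes the
    deducted excess among still-uncapped pixels proportionally to their
    population, until the worst violation is within ``tol``.  Each
    iteration caps at least one new pixel, so at most n iterations run.
    The fixed point is order-independent.

    Returns ``(allocation, iterations, residual)``.  When the total
    exceeds populated-pixel-count x cap the unit is infeasible: under
    the default policy every populated pixel is set to the cap and the
    leftover mass is returned as the residual; under ``"error"`` an
    :class:`InfeasibleUnitError` is raised.
    """
    if cap <= 0:
        raise ParameterError(f"cap must be > 0, got {cap}")
    out = np.asarray(alloc, dtype=np.float64).copy()
    pops = np.asarray(pixel_pops, dtype=np.float64)
    if out.shape != pops.shape:
        raise ParameterError("alloc and pixel_pops must have the same shape")
    total = float(out.sum())
    receiving = out > 0  # pixels that took part in the linear allocation
    capacity = float(receiving.sum()) * cap
    if total > capacity + tol:
        if infeasible_policy == "error":
            raise InfeasibleUnitError(
                f"total {total} exceeds capacity {capacity} ({receiving.sum()} pixels x cap {cap})"
            )
        out = np.where(receiving, cap, 0.0)
        return out, 0, total - capacity

    capped = np.zeros(out.shape, dtype=bool)
    iterations = 0
    while True:
        over = ~capped & (out > cap + tol)
        if not over.any():
            break
        capped |= over
        iterations += 1
        remaining = total - cap * capped.sum()
        free = ~capped & receiving
        wsum = float(pops[free].sum())
        out[capped] = cap
        out[~capped] = 0.0
        if wsum > 0:
            out[free] = remaining * pops[free] / wsum
        elif remaining > tol:
            # every receiving pixel capped; feasibility bound makes this dust
            break
    residual = max(0.0, total - float(out.sum()))
    return out, iterations, residual


def _allocate_unit(
    rate_rec: PerCapitaRate,
    adjusted: Optional[float],
    pops: np.ndarray,
    cap: float,
    config: AllocationConfig,
) -> Tuple[np.ndarray, UnitAllocation]:
    """Allocate one unit's total over its pixels, honouring policies."""
    n_pixels = int(pops.size)
    tol = config.convergence_tol
    base = UnitAllocation(
        unit_id=rate_rec.unit_id,
        country=rate_rec.country,
        adjusted_value=adjusted,
        zonal_pop=float(pops.sum()),
        rate=rate_rec.rate,
        imputed=rate_rec.imputed,
        n_pixels=n_pixels,
        n_capped=0,
        iterations=0,
        residual=0.0,
        status="ok",
    )
    if n_pixels == 0:
        base.status = "no-pixels"
        if adjusted:
            base.residual = adjusted
            logger.warning("unit %r covers no pixel; %g unallocated",
                           rate_rec.unit_id, adjusted)
        return np.zeros(0), base

    if rate_rec.status == RATE_UNDEFINED or (pops.sum() == 0 and (adjusted or 0) > 0):
        base.status = "zero-population"
        logger.warning("unit %r has zero rural population but total %g; policy %s",
                       rate_rec.unit_id, adjusted, config.zero_population_policy)
        if config.zero_population_policy == "leave-unallocated":
            base.residual = adjusted or 0.0
            return np.zeros(n_pixels), base
        # uniform spread: every pixel equally, still capped
        flat = np.full(n_pixels, adjusted / n_pixels)
        out, iters, residual = redistribute_capped(
            flat, np.ones(n_pixels), cap, tol, config.infeasible_policy)
        base.iterations = iters
        base.residual = residual
        base.n_capped = int(np.sum(out >= cap - tol))
        return out, base

    rate = rate_rec.rate or 0.0
    lin = allocate_linear(rate, pops)
    out, iters, residual = redistribute_capped(
        lin, pops, cap, tol, config.infeasible_policy)
    base.iterations = iters
    base.residual = residual
    base.n_capped = int(np.sum(out >= cap - tol)) if out.size else 0
    if residual > tol:
        base.status = "infeasible"
        logger.warning("unit %r infeasible: residual %g above capacity",
                       rate_rec.unit_id, residual)
    return out, base


def disaggregate(
    pop: PopulationGrid,
    layer: AdminLayer,
    census: Iterable[CensusRecord],
    totals: Iterable[NationalTotal],
    quantity_kind: str = PRODUCTION,
    groups: Optional[UnitGroupMap] = None,
    bbox_fills: Optional[Iterable[BBoxFill]] = None,
    config: Optional[AllocationConfig] = None,
) -> DisaggregationResult:
    """End-to-end disaggregation of one quantity kind onto the grid.

    Pipeline: urban mask -> rasterise units -> zonal rural population ->
    standardise census to national totals -> per-capita rates -> impute
    missing rates from neighbours -> per-unit linear allocation + capped
    redistribution -> optional bbox gap fill.  Units present in the
    layer but absent from the census are treated as missing records and
    imputed.  The whole pipeline is deterministic.
    """
    config = config or AllocationConfig()
    census = [c for c in census if c.quantity_kind == quantity_kind]

    rural = mask_urban(pop, config.urban_threshold)
    zones = rasterize_admin(layer, pop.spec)
    zonal = zonal_population(rural, zones)

    # units in the layer with no census record count as missing
    have = {c.unit_id for c in census}
    for u in layer:
        if u.unit_id not in have:
            census.append(CensusRecord(u.unit_id, u.country, quantity_kind, None))
    unknown = [c.unit_id for c in census if c.unit_id not in layer]
    if unknown:
        logger.warning("census units absent from layer, skipped: %s", unknown)
        census = [c for c in census if c.unit_id in layer]

    adjusted = standardize_to_national(census, totals)
    rates = per_capita_rates(adjusted, zonal)

    needs_imputation = any(r.status == RATE_MISSING for r in rates)
    adj: Adjacency = adjacency(layer) if needs_imputation else {}
    rates, imp_log = impute_all(rates, adj, groups)

    adj_by_id: Dict[str, AdjustedRecord] = {a.unit_id: a for a in adjusted}
    rate_by_id: Dict[str, PerCapitaRate] = {r.unit_id: r for r in rates}

    cap = config.cap_for(quantity_kind)
    values = np.full(pop.spec.shape, np.nan)
    rural_vals = rural.filled(0.0)
    rows: List[UnitAllocation] = []
    for unit in layer:
        rr, cc = zones.pixels_of(unit.unit_id)
        pops = rural_vals[rr, cc]
        rate_rec = rate_by_id[unit.unit_id]
        arec = adj_by_id[unit.unit_id]
        adjusted_value = arec.adjusted_value
        if adjusted_value is None and rate_rec.status == RATE_OK:
            # imputed rate: the unit total is rate x rural population
            adjusted_value = rate_rec.rate * float(pops.sum())
        alloc, row = _allocate_unit(rate_rec, adjusted_value, pops, cap, config)
        values[rr, cc] = alloc
        rows.append(row)

    added = 0.0
    if bbox_fills:
        values, added = fill_bbox_gaps(values, bbox_fills, rural)

    report_columns = ["unit_id", "country", "adjusted_value", "zonal_pop",
                      "rate", "imputed", "n_pixels", "n_capped", "iterations",
                      "residual", "status"]
    report = pd.DataFrame([vars(r) for r in rows], columns=report_columns)
    ref_by_country = {t.country: t.reference_value for t in totals
                      if t.quantity_kind == quantity_kind}
    raw_by_id = {c.unit_id: c for c in census}
    report["quantity_kind"] = quantity_kind
    report["raw_value"] = [getattr(raw_by_id.get(u), "raw_value", None)
                           for u in report["unit_id"]]
    report["census_year"] = [getattr(raw_by_id.get(u), "census_year", 0)
                             for u in report["unit_id"]]
    report["source"] = [getattr(raw_by_id.get(u), "source", "")
                        for u in report["unit_id"]]
    report["admin_level"] = [layer[u].level for u in report["unit_id"]]
    report["country_raw_sum"] = [adj_by_id[u].country_raw_sum
                                 for u in report["unit_id"]]
    report["national_reference"] = [ref_by_country.get(c, np.nan)
                                    for c in report["country"]]

    imp_df = pd.DataFrame(
        [{"unit_id": e.unit_id, "quantity_kind": e.quantity_kind,
          "donors": ";".join(e.donors), "function": e.function,
          "rate": e.rate, "strategy": e.strategy}
         for e in imp_log],
        columns=["unit_id", "quantity_kind", "donors", "function",
                 "rate", "strategy"],
    )
    grid = AllocationGrid(pop.spec, values, quantity_kind)
    return DisaggregationResult(grid=grid, report=report,
                                imputation_log=imp_df, bbox_added_mass=added)
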