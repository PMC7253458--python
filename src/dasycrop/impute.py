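"""Missing-data imputation for per-capita rates and boundary gap filling.

Units without census data still grow the crop; their per-capita rate is
borrowed from neighbours.  The donor preference order is

1. an explicit unit-group map (the user's hook for agro-ecological-zone
   style groupings chosen by expert judgement) — mean over the unit's
   group, excluding itself;
2. the unweighted mean over same-country units sharing a boundary of
   positive length with the unit;
3. fallback: the mean over all same-country units with data.

A unit with no donor anywhere in its country is an error.  Every
imputation is logged with its donor list and function ("mean").

Separately, slivers of pixels covered by no admin polygon (misaligned
national boundaries) can be gap-filled inside user-declared bounding
boxes with a constant per-capita rate (0.02 in the source study) times
the pixel's rural population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
from shapely.strtree import STRtree

from .errors import ParameterError, UnimputableUnitError
from .grid import AdminLayer, PopulationGrid
from .standardize import RATE_OK, PerCapitaRate

logger = logging.getLogger(__name__)

#: Default gap-fill per-capita rate (quantity per person), applied to both
#: production and harvested area.
DEFAULT_GAPFILL_RATE = 0.02

Adjacency = Dict[str, Set[str]]
UnitGroupMap = Mapping[str, str]


@dataclass(frozen=True)
class BBoxFill:
    """A bounding box (degrees) to gap-fill at a constant per-capita rate."""

    min_lon: float
    min_lat: float
    max_lon: float
    max_lat: float
    constant_rate: float = DEFAULT_GAPFILL_RATE

    def __post_init__(self) -> None:
        if not (self.min_lon < self.max_lon and self.min_lat < self.max_lat):
            raise ParameterError("bbox must satisfy min < max on both axes")
        if self.constant_rate < 0:
            raise ParameterError("constant_rate must be >= 0")


@dataclass(frozen=True)
class ImputationLogEntry:
    """One imputed unit: donors used and the combining function."""

    unit_id: str
    quantity_kind: str
    donors: Tuple[str, ...]
    function: str
    rate: float
    strategy: str  # "group" | "adjacent" | "country-mean"


def adjacency(layer: AdminLayer, min_shared_length: float = 1e-12) -> Adjacency:
    """Neighbour sets: same-country units sharing a positive-length boundary.

    Point-touching (corner contact) does not count.  The relation is
    symmetric and irreflexive; isolated units get empty sets.
    """
    out: Adjacency = {u.unit_id: set() for u in layer}
    geoms = [u.geometry for u in layer.units]
    if not geoms:
        return out
    tree = STRtree(geoms)
    pairs = tree.query(np.array(geoms, dtype=object), predicate="intersects")
    for i, j in zip(*pairs):
        if i >= j:
            continue
        a, b = layer.units[int(i)], layer.units[int(j)]
        if a.country != b.country:
            continue
        shared = a.geometry.intersection(b.geometry)
        if shared.length > min_shared_length:
            out[a.unit_id].add(b.unit_id)
            out[b.unit_id].add(a.unit_id)
    return out


def _mean_over(donors: List[PerCapitaRate]) -> float:
    return float(np.mean([d.rate for d in donors]))


def impute_missing_rate(
    unit_id: str,
    rates: Iterable[PerCapitaRate],
    adj: Adjacency,
    groups: Optional[UnitGroupMap] = None,
) -> Tuple[PerCapitaRate, ImputationLogEntry]:
    """Fill one unit's missing rate from its donors.

    Returns the imputed rate (flagged) and a log entry mirroring the
    per-unit provenance a reviewer needs: donor ids and the function.
    """
    rates = list(rates)
    target = next((r for r in rates if r.unit_id == unit_id), None)
    if target is None:
        raise ParameterError(f"unit {unit_id!r} not found among rates")
    if target.status == RATE_OK:
        raise ParameterError(f"unit {unit_id!r} already has a rate; nothing to impute")

    same_kind = [r for r in rates
                 if r.quantity_kind == target.quantity_kind and r.status == RATE_OK]
    by_id = {r.unit_id: r for r in same_kind}

    donors: List[PerCapitaRate] = []
    strategy = ""
    if groups and unit_id in groups:
        label = groups[unit_id]
        donors = [by_id[u] for u, g in groups.items()
                  if g == label and u != unit_id and u in by_id]
        strategy = "group"
    if not donors:
        neighbours = adj.get(unit_id, set())
        donors = [by_id[u] for u in sorted(neighbours)
                  if u in by_id and by_id[u].country == target.country]
        strategy = "adjacent"
    if not donors:
        donors = [r for r in same_kind if r.country == target.country]
        strategy = "country-mean"
    if not donors:
        raise UnimputableUnitError(
            f"unit {unit_id!r} ({target.quantity_kind}): no donor with data "
            f"in country {target.country!r}"
        )

    value = _mean_over(donors)
    entry = ImputationLogEntry(
        unit_id=unit_id,
        quantity_kind=target.quantity_kind,
        donors=tuple(sorted(d.unit_id for d in donors)),
        function="mean",
        rate=value,
        strategy=strategy,
    )
    logger.info("imputed rate for %r from %d donors (%s): %g",
                unit_id, len(donors), strategy, value)
    imputed = PerCapitaRate(unit_id, target.country, target.quantity_kind,
                            value, status=RATE_OK, imputed=True)
    return imputed, entry


def impute_all(
    rates: Iterable[PerCapitaRate],
    adj: Adjacency,
    groups: Optional[UnitGroupMap] = None,
) -> Tuple[List[PerCapitaRate], List[ImputationLogEntry]]:
    """Impute every missing rate; non-missing rates pass through untouched.

    Donors are always original (non-imputed) rates: imputed values never
    cascade into other units' means.
    """
    rates = list(rates)
    out: List[PerCapitaRate] = []
    log: List[ImputationLogEntry] = []
    for r in rates:
        if r.status == "missing":
            imputed, entry = impute_missing_rate(r.unit_id, rates, adj, groups)
            out.append(imputed)
            log.append(entry)
        else:
            out.append(r)
    return out, log


def fill_bbox_gaps(
    values: np.ndarray,
    fills: Iterable[BBoxFill],
    pop: PopulationGrid,
) -> Tuple[np.ndarray, float]:
    """Fill no-unit (NaN) pixels inside declared bboxes.

    Each NaN pixel whose centre lies in a bbox and whose rural
    population is positive receives ``constant_rate * population``; all
    other pixels are untouched.  Returns the filled array and the total
    mass added (this mass is on top of any national total, so country
    conservation is intentionally relaxed where fills apply).  A bbox
    that misses the grid entirely is a warning and a no-op.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape != pop.spec.shape:
        raise ParameterError("values shape does not match population grid spec")
    out = values.copy()
    popv = pop.filled(0.0)
    added = 0.0
    for f in fills:
        mask = pop.spec.bbox_mask(f.min_lon, f.min_lat, f.max_lon, f.max_lat)
        if not mask.any():
            logger.warning("bbox %s is outside the grid extent; skipped", f)
            continue
        target = mask & np.isnan(out) & (popv > 0)
        out[target] = f.constant_rate * popv[target]
        added += float(out[target].sum())
    return out, added
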