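"""Georeferenced grid model: population rasters, admin polygons, zonal sums.

The pipeline operates on a single fixed grid of ~30 arc-second (~1 km)
square cells in geographic coordinates.  All rasters taking part in one
run must share an identical :class:`GridSpec`; no reprojection or
resampling is performed.  Missing pixels are carried as NaN in memory and
as the spec's ``nodata`` sentinel on disk.

Polygon membership of a pixel is decided by containment of the pixel
*centre*, which yields an unambiguous partition of the grid: every pixel
belongs to exactly one admin unit or to none ("outside").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .errors import AlignmentError, OverlapError, ParameterError

logger = logging.getLogger(__name__)

#: Default urban-density cutoff, people per ~1 km pixel.  Pixels strictly
#: above this density are considered urban and excluded from allocation.
DEFAULT_URBAN_THRESHOLD = 5_000.0

#: Sentinel label for pixels whose centre falls inside no admin unit.
OUTSIDE = -1

ZonalPopulation = Dict[str, float]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up geographic grid.

    Parameters
    ----------
    origin_lon, origin_lat
        Longitude/latitude of the grid's upper-left *corner*, in degrees.
    n_rows, n_cols
        Grid shape; rows increase southwards.
    cell_size
        Square cell edge in arc-seconds (default 30, ~1 km at the equator).
    nodata
        Sentinel written to disk for missing pixels.
    """

    origin_lon: float
    origin_lat: float
    n_rows: int
    n_cols: int
    cell_size: float = 30.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ParameterError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ParameterError(
                f"grid shape must be at least 1x1, got {self.n_rows}x{self.n_cols}"
            )

    @property
    def cell_deg(self) -> float:
        """Cell edge in degrees."""
        return self.cell_size / 3600.0

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def pixel_centres(self) -> Tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols) at pixel centres."""
        d = self.cell_deg
        lons = self.origin_lon + (np.arange(self.n_cols) + 0.5) * d
        lats = self.origin_lat - (np.arange(self.n_rows) + 0.5) * d
        return np.meshgrid(lons, lats)

    def bbox_mask(self, min_lon: float, min_lat: float,
                  max_lon: float, max_lat: float) -> np.ndarray:
        """Boolean mask of pixels whose centre lies in the closed bbox."""
        lon, lat = self.pixel_centres()
        return (lon >= min_lon) & (lon <= max_lon) & (lat >= min_lat) & (lat <= max_lat)


@dataclass
class PopulationGrid:
    """Per-pixel people counts on a :class:`GridSpec` grid.

    ``values`` is float64 with NaN marking nodata; all finite values are
    non-negative.
    """

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.spec.shape:
            raise ParameterError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ParameterError("population values must be non-negative")

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Values with nodata replaced by ``fill``."""
        return np.where(np.isfinite(self.values), self.values, fill)

    def total(self) -> float:
        """Total population, counting nodata pixels as 0 people."""
        return float(np.nansum(self.values))


@dataclass
class AdminUnit:
    """One administrative unit: id, country, hierarchy level, footprint."""

    unit_id: str
    country: str
    level: int
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if self.geometry is None or self.geometry.is_empty:
            raise ParameterError(f"unit {self.unit_id!r}: empty geometry")
        if not self.geometry.is_valid:
            raise ParameterError(f"unit {self.unit_id!r}: invalid geometry")


class AdminLayer:
    """A collection of admin units with unique ids.

    Units of the same country must not overlap in area (pairwise
    intersection area below ``overlap_tol``); the layer is the zonal
    frame of the whole run, so overlaps would double-allocate.
    """

    def __init__(self, units: Iterable[AdminUnit], overlap_tol: float = 1e-9):
        self.units: List[AdminUnit] = list(units)
        seen: Dict[str, AdminUnit] = {}
        for u in self.units:
            if u.unit_id in seen:
                raise ParameterError(f"duplicate unit_id {u.unit_id!r} in layer")
            seen[u.unit_id] = u
        self._by_id = seen
        self._check_overlaps(overlap_tol)

    def _check_overlaps(self, tol: float) -> None:
        geoms = [u.geometry for u in self.units]
        if not geoms:
            return
        tree = STRtree(geoms)
        pairs = tree.query(np.array(geoms, dtype=object), predicate="intersects")
        for i, j in zip(*pairs):
            if i >= j:
                continue
            a, b = self.units[int(i)], self.units[int(j)]
            if a.country != b.country:
                continue
            inter = a.geometry.intersection(b.geometry)
            if inter.area > tol:
                raise OverlapError(
                    f"units {a.unit_id!r} and {b.unit_id!r} overlap "
                    f"(area {inter.area:.3g})"
                )

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    def __getitem__(self, unit_id: str) -> AdminUnit:
        return self._by_id[unit_id]

    def __contains__(self, unit_id: str) -> bool:
        return unit_id in self._by_id

    @property
    def unit_ids(self) -> List[str]:
        return [u.unit_id for u in self.units]

    def countries(self) -> List[str]:
        return sorted({u.country for u in self.units})


@dataclass
class UnitIdGrid:
    """Per-pixel admin-unit membership.

    ``labels`` holds the index of each pixel's unit in ``unit_ids``, or
    :data:`OUTSIDE` (-1) where the pixel centre lies in no unit.
    """

    spec: GridSpec
    labels: np.ndarray
    unit_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != self.spec.shape:
            raise ParameterError("labels shape does not match grid spec")

    def pixels_of(self, unit_id: str) -> Tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the pixels belonging to ``unit_id``."""
        idx = self.unit_ids.index(unit_id)
        return np.nonzero(self.labels == idx)

    def outside_mask(self) -> np.ndarray:
        return self.labels == OUTSIDE


def mask_urban(pop: PopulationGrid,
               threshold: float = DEFAULT_URBAN_THRESHOLD) -> PopulationGrid:
    """Zero out densely populated (urban) pixels.

    Pixels with population *strictly greater* than ``threshold`` people
    per pixel are set to 0 — kept in the grid at zero weight so outputs
    stay full-extent — reflecting the assumption that dense urban
    populations do not farm.  Pixels exactly at the threshold are rural.
    nodata pixels are preserved as nodata.
    """
    if threshold <= 0:
        raise ParameterError(f"urban threshold must be > 0, got {threshold}")
    vals = pop.values.copy()
    with np.errstate(invalid="ignore"):
        vals[vals > threshold] = 0.0
    return PopulationGrid(pop.spec, vals)


def rasterize_admin(layer: AdminLayer, spec: GridSpec) -> UnitIdGrid:
    """Assign every pixel to the unit containing its centre.

    Deterministic for a fixed layer.  Pixels whose centre lies in no
    polygon (including centres exactly on a shared boundary, which no
    polygon's interior contains) are labelled outside.  Two units
    claiming the same centre raise :class:`OverlapError`; units covering
    no pixel centre are logged.
    """
    lon, lat = spec.pixel_centres()
    points = shapely.points(lon.ravel(), lat.ravel())
    labels = np.full(points.shape, OUTSIDE, dtype=np.int32)
    tree = STRtree(points)
    for ui, unit in enumerate(layer):
        hit = tree.query(unit.geometry, predicate="contains")
        clash = hit[labels[hit] != OUTSIDE]
        if clash.size:
            other = layer.units[int(labels[clash[0]])]
            raise OverlapError(
                f"pixel centre claimed by both {other.unit_id!r} "
                f"and {unit.unit_id!r}"
            )
        labels[hit] = ui
        if hit.size == 0:
            logger.warning(
                "unit %r covers no pixel centre; it will receive no allocation",
                unit.unit_id,
            )
    return UnitIdGrid(spec, labels.reshape(spec.shape), tuple(layer.unit_ids))


def zonal_population(rural: PopulationGrid, zones: UnitIdGrid) -> ZonalPopulation:
    """Sum (post-mask) population per admin unit.

    nodata pixels contribute 0 people; units with no pixels get sum 0.
    """
    if rural.spec != zones.spec:
        raise AlignmentError("population grid and unit-id grid specs differ")
    vals = rural.filled(0.0).ravel()
    labels = zones.labels.ravel()
    inside = labels != OUTSIDE
    sums = np.bincount(labels[inside], weights=vals[inside],
                       minlength=len(zones.unit_ids))
    return {uid: float(s) for uid, s in zip(zones.unit_ids, sums)}
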