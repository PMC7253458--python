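"""Standardisation of raw admin census values to national reference totals.

Administrative crop censuses are taken in scattered years, so a
country's unit values rarely sum to the FAO national estimate for the
reference year (2014).  Each unit's raw value is therefore rescaled
proportionally,

    adjusted = raw / country_raw_sum * national_reference,

so that the country sum of adjusted values equals the national total
exactly.  Dividing the adjusted value by the unit's rural population
gives the per-capita rate that drives the linear pixel allocation.

Production (tonnes) and harvested area (hectares) are processed as two
independent passes over the same machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .errors import MissingTotalError, ParameterError, UnscalableCountryError
from .grid import ZonalPopulation

PRODUCTION = "production"
HARVESTED_AREA = "harvested_area"
QUANTITY_KINDS = (PRODUCTION, HARVESTED_AREA)

#: Relative / absolute tolerance for conservation checks, native units.
CONSERVATION_RTOL = 1e-9
CONSERVATION_ATOL = 1e-6


def _check_kind(kind: str) -> None:
    if kind not in QUANTITY_KINDS:
        raise ParameterError(f"unknown quantity_kind {kind!r}")


@dataclass(frozen=True)
class CensusRecord:
    """One raw admin-unit statistic; ``raw_value`` None means missing."""

    unit_id: str
    country: str
    quantity_kind: str
    raw_value: Optional[float]
    census_year: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        _check_kind(self.quantity_kind)
        if self.raw_value is not None and self.raw_value < 0:
            raise ParameterError(
                f"unit {self.unit_id!r}: raw_value must be >= 0, got {self.raw_value}"
            )

    @property
    def missing(self) -> bool:
        return self.raw_value is None


@dataclass(frozen=True)
class NationalTotal:
    """National reference-year estimate (FAO-style), one per country/kind."""

    country: str
    quantity_kind: str
    reference_value: float
    reference_year: int = 2014

    def __post_init__(self) -> None:
        _check_kind(self.quantity_kind)
        if self.reference_value < 0:
            raise ParameterError(
                f"country {self.country!r}: reference_value must be >= 0"
            )


@dataclass(frozen=True)
class AdjustedRecord:
    """Unit value rescaled to the national reference year; None if missing."""

    unit_id: str
    country: str
    quantity_kind: str
    adjusted_value: Optional[float]
    raw_value: Optional[float] = None
    country_raw_sum: float = float("nan")
    reference_value: float = float("nan")

    @property
    def missing(self) -> bool:
        return self.adjusted_value is None


# Rate status values
RATE_OK = "ok"
RATE_MISSING = "missing"          # no census value; candidate for imputation
RATE_UNDEFINED = "undefined"      # positive total over zero rural population


@dataclass(frozen=True)
class PerCapitaRate:
    """Adjusted quantity per rural person for one unit.

    ``status`` is ``"ok"`` for a finite rate, ``"missing"`` when the
    census value was absent (the imputation stage fills these), and
    ``"undefined"`` when a positive total meets zero rural population
    (the allocator's zero-population policy decides what happens).
    """

    unit_id: str
    country: str
    quantity_kind: str
    rate: Optional[float]
    status: str = RATE_OK
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.status == RATE_OK:
            if self.rate is None or not math.isfinite(self.rate) or self.rate < 0:
                raise ParameterError(
                    f"unit {self.unit_id!r}: ok rate must be finite and >= 0"
                )


def country_raw_sums(
    records: Iterable[CensusRecord],
) -> Dict[Tuple[str, str], float]:
    """Sum of non-missing raw values per (country, quantity_kind)."""
    sums: Dict[Tuple[str, str], float] = {}
    for r in records:
        key = (r.country, r.quantity_kind)
        sums.setdefault(key, 0.0)
        if not r.missing:
            sums[key] += r.raw_value
    return sums


def standardize_to_national(
    records: Iterable[CensusRecord],
    totals: Iterable[NationalTotal],
) -> List[AdjustedRecord]:
    """Rescale raw unit values so country sums match national totals.

    Country raw sums are computed over non-missing records only; missing
    records pass through still missing and receive a per-capita rate by
    imputation later.  Raises :class:`MissingTotalError` if a record's
    country has no reference total of the matching kind, and
    :class:`UnscalableCountryError` when a country's raw sum is zero but
    its reference value is positive (no basis for proportions).
    """
    records = list(records)
    seen: set = set()
    for r in records:
        key = (r.unit_id, r.quantity_kind)
        if key in seen:
            raise ParameterError(
                f"duplicate census record for unit {r.unit_id!r}, "
                f"kind {r.quantity_kind!r}"
            )
        seen.add(key)

    ref: Dict[Tuple[str, str], float] = {
        (t.country, t.quantity_kind): t.reference_value for t in totals
    }
    sums = country_raw_sums(records)

    out: List[AdjustedRecord] = []
    for r in records:
        key = (r.country, r.quantity_kind)
        if key not in ref:
            raise MissingTotalError(
                f"no national total for country {r.country!r}, "
                f"kind {r.quantity_kind!r}"
            )
        reference = ref[key]
        raw_sum = sums[key]
        if r.missing:
            adjusted = None
        else:
            if raw_sum == 0:
                if reference > 0:
                    raise UnscalableCountryError(
                        f"country {r.country!r} ({r.quantity_kind}): raw sum is 0 "
                        f"but national total is {reference}"
                    )
                adjusted = 0.0
            else:
                adjusted = r.raw_value / raw_sum * reference
        out.append(
            AdjustedRecord(
                unit_id=r.unit_id,
                country=r.country,
                quantity_kind=r.quantity_kind,
                adjusted_value=adjusted,
                raw_value=r.raw_value,
                country_raw_sum=raw_sum,
                reference_value=reference,
            )
        )
    return out


def per_capita_rates(
    adjusted: Iterable[AdjustedRecord],
    zonal: ZonalPopulation,
) -> List[PerCapitaRate]:
    """Divide adjusted unit totals by rural population sums.

    Every record's unit must appear in ``zonal``.  Units with adjusted
    value 0 get rate 0 regardless of population; a positive value over
    zero population yields the ``"undefined"`` sentinel rather than
    infinity; missing records yield ``"missing"`` rates for the imputer.
    """
    out: List[PerCapitaRate] = []
    for a in adjusted:
        if a.unit_id not in zonal:
            raise ParameterError(
                f"unit {a.unit_id!r} has no zonal population entry"
            )
        pop = zonal[a.unit_id]
        if a.missing:
            out.append(PerCapitaRate(a.unit_id, a.country, a.quantity_kind,
                                     None, status=RATE_MISSING))
        elif a.adjusted_value == 0:
            out.append(PerCapitaRate(a.unit_id, a.country, a.quantity_kind, 0.0))
        elif pop == 0:
            out.append(PerCapitaRate(a.unit_id, a.country, a.quantity_kind,
                                     None, status=RATE_UNDEFINED))
        else:
            out.append(PerCapitaRate(a.unit_id, a.country, a.quantity_kind,
                                     a.adjusted_value / pop))
    return out
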