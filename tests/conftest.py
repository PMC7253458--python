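"""Shared fixtures and independent oracles.

The water-filling oracle solves the capped-allocation fixed point in
closed form by bisection on the multiplier lambda, with per-pixel value
min(cap, lambda * pop) summing to the unit total.  It shares no code
with the iterative implementation it checks.
"""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import box

from dasycrop import AdminLayer, AdminUnit, GridSpec, PopulationGrid


def waterfill_oracle(alloc, pops, cap, tol=1e-12):
    """Closed-form capped allocation via bisection on the multiplier.

    Pixels that received nothing in the linear allocation stay at zero;
    for the rest, x_i = min(cap, lam * pop_i) with lam chosen so the
    values sum to the unit total.  If the total exceeds the receiving
    pixels' capacity, every receiving pixel sits at the cap.
    """
    alloc = np.asarray(alloc, dtype=float)
    pops = np.asarray(pops, dtype=float)
    total = float(alloc.sum())
    receiving = alloc > 0
    if total == 0:
        return np.zeros_like(alloc)
    capacity = receiving.sum() * cap
    if total >= capacity:
        return np.where(receiving, cap, 0.0)

    def placed(lam):
        return float(np.minimum(cap, lam * pops[receiving]).sum())

    lo, hi = 0.0, 1.0
    while placed(hi) < total:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if placed(mid) < total:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    lam = 0.5 * (lo + hi)
    out = np.zeros_like(alloc)
    out[receiving] = np.minimum(cap, lam * pops[receiving])
    return out


@pytest.fixture
def small_spec():
    """A 4x4 grid of 30 arc-second cells with its UL corner at (30E, 2N)."""
    return GridSpec(origin_lon=30.0, origin_lat=2.0, n_rows=4, n_cols=4)


def rect_for_pixels(spec: GridSpec, row0, row1, col0, col1):
    """Axis-aligned box covering pixel rows [row0, row1) x cols [col0, col1)."""
    d = spec.cell_deg
    return box(spec.origin_lon + col0 * d, spec.origin_lat - row1 * d,
               spec.origin_lon + col1 * d, spec.origin_lat - row0 * d)


@pytest.fixture
def two_unit_layer(small_spec):
    """Two abutting rectangles splitting the 4x4 grid into left/right halves."""
    return AdminLayer([
        AdminUnit("L", "C0", 1, rect_for_pixels(small_spec, 0, 4, 0, 2)),
        AdminUnit("R", "C0", 1, rect_for_pixels(small_spec, 0, 4, 2, 4)),
    ])


@pytest.fixture
def chain_layer(small_spec):
    """Three units stacked as horizontal bands: A (rows 0-1), B (row 2),
    C (row 3).  A-B and B-C share edges; A and C do not touch."""
    return AdminLayer([
        AdminUnit("A", "C0", 1, rect_for_pixels(small_spec, 0, 2, 0, 4)),
        AdminUnit("B", "C0", 1, rect_for_pixels(small_spec, 2, 3, 0, 4)),
        AdminUnit("C", "C0", 1, rect_for_pixels(small_spec, 3, 4, 0, 4)),
    ])


@pytest.fixture
def uniform_pop(small_spec):
    """10 people in every pixel of the small grid."""
    return PopulationGrid(small_spec, np.full(small_spec.shape, 10.0))
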