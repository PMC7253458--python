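"""Linear allocation, capped water-filling, and the end-to-end driver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dasycrop import (
    AdminLayer,
    AdminUnit,
    AllocationConfig,
    CensusRecord,
    InfeasibleUnitError,
    NationalTotal,
    ParameterError,
    PopulationGrid,
    allocate_linear,
    disaggregate,
    rasterize_admin,
    redistribute_capped,
)
from dasycrop.standardize import PRODUCTION

from conftest import rect_for_pixels, waterfill_oracle


class TestAllocateLinear:
    def test_direct_multiplication(self):
        np.testing.assert_allclose(allocate_linear(0.2, [10, 0, 90]), [2, 0, 18])

    def test_zero_rate_gives_zeros(self):
        assert (allocate_linear(0.0, [5, 5]) == 0).all()

    def test_mass_is_rate_times_population(self):
        rng = np.random.default_rng(2)
        pops = rng.uniform(0, 500, 40)
        out = allocate_linear(1.7, pops)
        assert out.sum() == pytest.approx(1.7 * pops.sum(), rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            allocate_linear(-0.1, [1, 2])


class TestRedistributeCapped:
    def test_one_iteration_hand_example(self):
        """Excess 46 off the big pixel splits evenly over the equal pair."""
        out, iters, residual = redistribute_capped([12, 12, 96], [10, 10, 80], 50)
        np.testing.assert_allclose(out, [35, 35, 50])
        assert iters == 1
        assert residual == pytest.approx(0.0, abs=1e-9)

    def test_feasible_input_unchanged_zero_iterations(self):
        alloc = np.array([10.0, 20.0, 30.0])
        out, iters, residual = redistribute_capped(alloc, [1, 2, 3], 50)
        np.testing.assert_array_equal(out, alloc)
        assert iters == 0 and residual == 0

    def test_infeasible_unit_capped_with_residual(self):
        """200 over 3 pixels of capacity 150: all at cap, 50 left over."""
        out, _, residual = redistribute_capped([70, 70, 60], [1, 1, 1], 50)
        np.testing.assert_allclose(out, [50, 50, 50])
        assert residual == pytest.approx(50.0)

    def test_infeasible_error_policy(self):
        with pytest.raises(InfeasibleUnitError):
            redistribute_capped([70, 70, 60], [1, 1, 1], 50,
                                infeasible_policy="error")

    def test_nonpositive_cap_rejected(self):
        with pytest.raises(ParameterError):
            redistribute_capped([1.0], [1.0], 0.0)

    def test_idempotent_on_feasible_output(self):
        rng = np.random.default_rng(4)
        pops = rng.uniform(1, 100, 8)
        alloc = allocate_linear(2.0, pops)
        once, _, _ = redistribute_capped(alloc, pops, 60)
        twice, iters, _ = redistribute_capped(once, pops, 60)
        np.testing.assert_allclose(twice, once, atol=1e-9)
        assert iters == 0

    def test_equal_populations_closed_form(self):
        """With equal pixel populations everyone gets min(cap, total/n)."""
        for total, n, cap in [(400, 8, 75), (100, 4, 50), (900, 3, 200)]:
            pops = np.full(n, 10.0)
            out, _, residual = redistribute_capped(
                allocate_linear(total / (10.0 * n), pops), pops, cap)
            expected = min(cap, total / n)
            np.testing.assert_allclose(out, expected, rtol=1e-9)

    def test_monotone_in_population(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            pops = rng.uniform(0, 200, 10)
            rate = rng.uniform(0.1, 3.0)
            out, _, _ = redistribute_capped(allocate_linear(rate, pops), pops, 80)
            order = np.argsort(pops)
            assert (np.diff(out[order]) >= -1e-9).all()

    def test_cap_compliance_random(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            n = rng.integers(1, 15)
            pops = rng.uniform(0, 500, n)
            rate = rng.uniform(0, 5)
            cap = rng.uniform(10, 300)
            out, iters, _ = redistribute_capped(allocate_linear(rate, pops), pops, cap)
            assert out.max(initial=0.0) <= cap + 1e-9
            assert iters <= n

    def test_matches_bisection_oracle(self):
        """1,000 random small units agree with the closed-form water level."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 13))
            pops = rng.uniform(0, 300, n)
            pops[rng.random(n) < 0.2] = 0.0  # some empty pixels
            rate = float(rng.uniform(0, 4))
            cap = float(rng.uniform(5, 250))
            alloc = allocate_linear(rate, pops)
            got, _, residual = redistribute_capped(alloc, pops, cap, tol=1e-12)
            want = waterfill_oracle(alloc, pops, cap)
            np.testing.assert_allclose(got, want, atol=1e-8)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        pops=st.lists(st.floats(0.0, 1e3), min_size=1, max_size=12),
        rate=st.floats(0.0, 10.0),
        cap=st.floats(1.0, 500.0),
    )
    def test_conserves_or_reports_residual(self, pops, rate, cap):
        """Placed mass plus residual always equals the linear total."""
        pops = np.asarray(pops)
        alloc = allocate_linear(rate, pops)
        out, _, residual = redistribute_capped(alloc, pops, cap, tol=1e-12)
        assert out.sum() + residual == pytest.approx(alloc.sum(), abs=1e-6, rel=1e-9)
        assert out.max(initial=0.0) <= cap + 1e-9


class TestAllocationConfig:
    def test_defaults_are_internally_consistent(self):
        cfg = AllocationConfig()
        assert cfg.cap_production == cfg.implied_max_yield * cfg.cap_harvested_area

    def test_inconsistent_yield_rejected(self):
        with pytest.raises(ParameterError):
            AllocationConfig(cap_production=900.0)

    def test_cap_for_kind(self):
        cfg = AllocationConfig()
        assert cfg.cap_for("production") == 1000.0
        assert cfg.cap_for("harvested_area") == 50.0


def _chain_inputs(small_spec, chain_layer):
    """Uniform 10 people/pixel; A raw 80, C raw 160, B missing; ref 240."""
    pop = PopulationGrid(small_spec, np.full(small_spec.shape, 10.0))
    census = [
        CensusRecord("A", "C0", PRODUCTION, 80.0),
        CensusRecord("C", "C0", PRODUCTION, 160.0),
    ]
    totals = [NationalTotal("C0", PRODUCTION, 240.0)]
    return pop, census, totals


class TestDisaggregate:
    def test_country_conservation_two_countries(self, small_spec):
        layer = AdminLayer([
            AdminUnit("a0", "C0", 1, rect_for_pixels(small_spec, 0, 2, 0, 2)),
            AdminUnit("a1", "C0", 1, rect_for_pixels(small_spec, 2, 4, 0, 2)),
            AdminUnit("b0", "C1", 1, rect_for_pixels(small_spec, 0, 2, 2, 4)),
            AdminUnit("b1", "C1", 1, rect_for_pixels(small_spec, 2, 4, 2, 4)),
        ])
        rng = np.random.default_rng(8)
        pop = PopulationGrid(small_spec, rng.uniform(5, 50, small_spec.shape))
        census = [CensusRecord("a0", "C0", PRODUCTION, 120.0),
                  CensusRecord("a1", "C0", PRODUCTION, 30.0),
                  CensusRecord("b0", "C1", PRODUCTION, 77.0),
                  CensusRecord("b1", "C1", PRODUCTION, 11.0)]
        totals = [NationalTotal("C0", PRODUCTION, 600.0),
                  NationalTotal("C1", PRODUCTION, 250.0)]
        res = disaggregate(pop, layer, census, totals)
        zones = rasterize_admin(layer, small_spec)
        for country, ref in [("C0", 600.0), ("C1", 250.0)]:
            mask = np.zeros(small_spec.shape, bool)
            for u in layer:
                if u.country == country:
                    rr, cc = zones.pixels_of(u.unit_id)
                    mask[rr, cc] = True
            assert np.nansum(res.grid.values[mask]) == pytest.approx(ref, rel=1e-9)

    def test_missing_unit_receives_imputed_rate_times_population(
            self, small_spec, chain_layer):
        """Hand composition on the A-B-C chain: B gets mean(rate_A, rate_C)."""
        pop, census, totals = _chain_inputs(small_spec, chain_layer)
        res = disaggregate(pop, chain_layer, census, totals)
        # A: 80 people, adjusted 80 -> rate 1.0; C: 40 people, adjusted 160 -> rate 4.0
        # B imputed: mean(1.0, 4.0) = 2.5; each of B's 4 pixels gets 2.5 x 10 = 25
        b_row = res.report.set_index("unit_id").loc["B"]
        assert b_row["imputed"]
        assert b_row["rate"] == pytest.approx(2.5)
        zones = rasterize_admin(chain_layer, small_spec)
        rr, cc = zones.pixels_of("B")
        np.testing.assert_allclose(res.grid.values[rr, cc], 25.0, rtol=1e-12)
        log = res.imputation_log
        assert list(log["unit_id"]) == ["B"]
        assert log.iloc[0]["donors"] == "A;C"
        assert log.iloc[0]["function"] == "mean"

    def test_all_urban_unit_uniform_spread(self, small_spec, chain_layer):
        vals = np.full(small_spec.shape, 10.0)
        vals[2, :] = 6000.0  # unit B's only row is all urban
        pop = PopulationGrid(small_spec, vals)
        census = [CensusRecord("A", "C0", PRODUCTION, 80.0),
                  CensusRecord("B", "C0", PRODUCTION, 40.0),
                  CensusRecord("C", "C0", PRODUCTION, 120.0)]
        totals = [NationalTotal("C0", PRODUCTION, 240.0)]
        res = disaggregate(pop, chain_layer, census, totals)
        b_row = res.report.set_index("unit_id").loc["B"]
        assert b_row["status"] == "zero-population"
        zones = rasterize_admin(chain_layer, small_spec)
        rr, cc = zones.pixels_of("B")
        np.testing.assert_allclose(res.grid.values[rr, cc], 40.0 / 4, rtol=1e-12)

    def test_all_urban_unit_leave_unallocated(self, small_spec, chain_layer):
        vals = np.full(small_spec.shape, 10.0)
        vals[2, :] = 6000.0
        pop = PopulationGrid(small_spec, vals)
        census = [CensusRecord("A", "C0", PRODUCTION, 80.0),
                  CensusRecord("B", "C0", PRODUCTION, 40.0),
                  CensusRecord("C", "C0", PRODUCTION, 120.0)]
        totals = [NationalTotal("C0", PRODUCTION, 240.0)]
        cfg = AllocationConfig(zero_population_policy="leave-unallocated")
        res = disaggregate(pop, chain_layer, census, totals, config=cfg)
        b_row = res.report.set_index("unit_id").loc["B"]
        assert b_row["residual"] == pytest.approx(40.0)
        zones = rasterize_admin(chain_layer, small_spec)
        rr, cc = zones.pixels_of("B")
        assert (res.grid.values[rr, cc] == 0).all()

    def test_urban_pixels_get_zero_allocation(self, small_spec, chain_layer):
        vals = np.full(small_spec.shape, 10.0)
        vals[0, 0] = 7000.0  # one urban pixel inside unit A
        pop = PopulationGrid(small_spec, vals)
        census = [CensusRecord("A", "C0", PRODUCTION, 80.0),
                  CensusRecord("B", "C0", PRODUCTION, 40.0),
                  CensusRecord("C", "C0", PRODUCTION, 120.0)]
        totals = [NationalTotal("C0", PRODUCTION, 240.0)]
        res = disaggregate(pop, chain_layer, census, totals)
        assert res.grid.values[0, 0] == 0.0
        assert np.nansum(res.grid.values) == pytest.approx(240.0, rel=1e-9)
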