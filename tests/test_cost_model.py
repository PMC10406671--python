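"""Unit tests for the closed-form coverage cost model."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aednet import (
    AIRBORNE_DEFAULTS,
    STATIONARY_DEFAULTS,
    DeliveryModeParams,
    InfeasibleScenarioError,
    Mode,
    Scenario,
    UnitCostBreakdown,
    annualize_unit_cost,
    ceil_to_next_integer,
    cost_per_km2,
    hex_catchment_area,
    operational_radius,
    total_annual_cost,
    units_required,
)
from aednet.cost_model import round_half_up

from reference_tables import AREA_KM2, FULL_TABLE


class TestCeiling:
    @pytest.mark.parametrize("value, expected", [
        (3930 / hex_catchment_area(0.1), 151_266),  # 151,265.65... rounds up
        (9.0, 9),
        (0.001, 1),
        (0.0, 0),
        (568.5, 569),
    ])
    def test_values(self, value, expected):
        assert ceil_to_next_integer(value) == expected

    @pytest.mark.parametrize("bad", [-1, -0.5, float("nan"), float("inf"), "3", None])
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(ValueError):
            ceil_to_next_integer(bad)

    @given(st.floats(min_value=0, max_value=1e12))
    @settings(max_examples=200, derandomize=True)
    def test_is_mathematical_ceiling(self, v):
        c = ceil_to_next_integer(v)
        assert c - 1 < v <= c


class TestOperationalRadius:
    def test_stationary_halves_the_travel_budget(self):
        r = operational_radius(STATIONARY_DEFAULTS, 3)
        assert r == pytest.approx(0.1)

    def test_airborne_one_way(self):
        assert operational_radius(AIRBORNE_DEFAULTS, 4) == pytest.approx(3.0)

    def test_zero_travel_budget_is_infeasible(self):
        with pytest.raises(InfeasibleScenarioError):
            operational_radius(STATIONARY_DEFAULTS, 1)

    def test_below_access_time_is_infeasible(self):
        with pytest.raises(InfeasibleScenarioError):
            operational_radius(AIRBORNE_DEFAULTS, 0.5)


class TestHexCatchment:
    @pytest.mark.parametrize("r, expected, tol", [
        (2.0, 10.39, 5e-3),
        (0.35, 0.318, 5e-4),
        (1.0, 2.598076, 1e-6),
    ])
    def test_reference_values(self, r, expected, tol):
        assert hex_catchment_area(r) == pytest.approx(expected, abs=tol)

    def test_nonpositive_radius_rejected(self):
        for r in (0.0, -1.0):
            with pytest.raises(ValueError):
                hex_catchment_area(r)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=100, derandomize=True)
    def test_agrees_with_shoelace_polygon_area(self, r):
        """Analytic area equals the shoelace area of the explicit hexagon."""
        angles = np.deg2rad(np.arange(6) * 60.0)
        x, y = r * np.cos(angles), r * np.sin(angles)
        shoelace = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert hex_catchment_area(r) == pytest.approx(shoelace, rel=1e-9)

    def test_every_hexagon_point_within_circumradius(self):
        """Monte-Carlo geometry oracle: the hexagon fits in its circle."""
        import shapely
        from shapely.geometry import Polygon

        r = 1.7
        angles = np.deg2rad(np.arange(6) * 60.0)
        hexagon = Polygon(zip(r * np.cos(angles), r * np.sin(angles)))
        rng = np.random.default_rng(20240601)
        pts = rng.uniform(-r, r, size=(100_000, 2))
        inside = shapely.contains_xy(hexagon, pts[:, 0], pts[:, 1])
        dist = np.hypot(pts[:, 0], pts[:, 1])
        assert np.all(dist[inside] <= r + 1e-12)
        # and the hexagon is a strict subset: some in-circle points fall outside
        assert np.any((dist <= r) & ~inside)


def _params(mode, k=None):
    base = STATIONARY_DEFAULTS if mode == "stationary" else AIRBORNE_DEFAULTS
    return base if k is None else replace(base, unit_cost_eur_per_year=float(k))


class TestFullReferenceTable:
    """The complete sweep: every radius, catchment, count and cost."""

    @pytest.mark.parametrize(
        "area_label, mode, d, radius, catchment, dp, units, costs",
        FULL_TABLE,
        ids=[f"{r[0]}-{r[1]}-d{r[2]}" for r in FULL_TABLE],
    )
    def test_row(self, area_label, mode, d, radius, catchment, dp, units, costs):
        params = _params(mode)
        x = AREA_KM2[area_label]
        r = operational_radius(params, d)
        assert r == pytest.approx(radius, abs=1e-12)
        # printed catchments are truncated; allow one unit in the last digit
        assert abs(hex_catchment_area(r) - catchment) < 10.0**-dp
        assert units_required(Scenario(params, d, x)) == units
        for k, total in costs.items():
            sc = Scenario(_params(mode, k), d, x)
            got = total_annual_cost(sc)
            assert got == total
            assert float(got).is_integer()


class TestUnitsAndCosts:
    def test_airborne_redundancy_order_of_operations(self):
        """Inner ceiling (locations), then x1.5, then outer ceiling (units)."""
        sc = Scenario(AIRBORNE_DEFAULTS, 3, 3930.0)
        inner = ceil_to_next_integer(3930.0 / hex_catchment_area(2.0))
        assert inner == 379
        assert units_required(sc) == math.ceil(inner * 1.5) == 569

    def test_exact_redundancy_multiple_is_fixed_point(self):
        # 6 locations x 1.5 = 9 exactly: outer ceiling must not add a unit
        sc = Scenario(AIRBORNE_DEFAULTS, 8, 680.4)
        assert units_required(sc) == 9

    def test_area_exactly_one_catchment_needs_one_unit(self):
        a = hex_catchment_area(operational_radius(STATIONARY_DEFAULTS, 5))
        assert units_required(Scenario(STATIONARY_DEFAULTS, 5, a)) == 1

    @given(
        d=st.floats(min_value=1.5, max_value=20),
        x=st.floats(min_value=0.1, max_value=1e5),
        redundancy=st.floats(min_value=1.0, max_value=3.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_redundancy_bound(self, d, x, redundancy):
        """units / inner-ceiling lies in [rho, rho + 1/inner)."""
        params = replace(AIRBORNE_DEFAULTS, redundancy_factor=redundancy)
        inner = ceil_to_next_integer(
            x / hex_catchment_area(operational_radius(params, d)))
        n = units_required(Scenario(params, d, x))
        assert redundancy <= n / inner < redundancy + 1.0 / inner

    @pytest.mark.parametrize("mode, x", [("stationary", 3930.0), ("airborne", 3930.0),
                                         ("stationary", 680.4), ("airborne", 680.4)])
    def test_monotone_in_response_time(self, mode, x):
        params = _params(mode)
        units = [units_required(Scenario(params, d, x)) for d in range(3, 9)]
        costs = [total_annual_cost(Scenario(params, d, x)) for d in range(3, 9)]
        assert units == sorted(units, reverse=True)
        assert costs == sorted(costs, reverse=True)


class TestCostPerKm2:
    @pytest.mark.parametrize("mode, d, k, expected", [
        ("stationary", 3, 170, 6543.30),
        ("airborne", 3, 32_248, 3103.07),
        ("stationary", 6, 170, 1046.93),
        ("airborne", 6, 32_248, 496.49),
    ])
    def test_reference_values(self, mode, d, k, expected):
        got = cost_per_km2(_params(mode, k), d)
        assert round_half_up(got, 2) == pytest.approx(expected, abs=1e-9)

    def test_independent_of_area(self):
        """Density cost uses one unit's catchment only — no ceilings."""
        got = cost_per_km2(AIRBORNE_DEFAULTS, 4)
        assert got == pytest.approx(32_248 / hex_catchment_area(3.0), rel=1e-12)


class TestUnitCostAnnualization:
    @pytest.mark.parametrize("acq, life, cons, expected", [
        (127_500, 4, 0, 31_875),
        (5000, 1, 0, 5000),
        (1_700, 10, 0, 170),
        (127_500, 4, 363, 32_238),   # drone + mid-cost AED + charging
    ])
    def test_straight_line(self, acq, life, cons, expected):
        bd = UnitCostBreakdown(acq, life, cons)
        assert annualize_unit_cost(bd) == pytest.approx(expected)

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(ValueError):
            UnitCostBreakdown(1000, 0)


class TestValidation:
    def test_scenario_requires_positive_area(self):
        with pytest.raises(ValueError):
            Scenario(STATIONARY_DEFAULTS, 5, -10.0)

    def test_scenario_requires_feasible_response(self):
        with pytest.raises(InfeasibleScenarioError):
            Scenario(STATIONARY_DEFAULTS, 1.0, 100.0)

    @pytest.mark.parametrize("kwargs", [
        dict(access_time_min=-1), dict(speed_km_per_min=0),
        dict(unit_cost_eur_per_year=0), dict(redundancy_factor=0.5),
    ])
    def test_params_invariants(self, kwargs):
        base = dict(mode=Mode.STATIONARY, access_time_min=1.0,
                    speed_km_per_min=0.1, unit_cost_eur_per_year=170.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            DeliveryModeParams(**base)
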