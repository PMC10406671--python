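"""Closed-form cost model for AED network coverage.

A region is tiled with regular hexagons (a Christaller comb) around AED
service points.  Each point serves the hexagon inscribed in the circle of
its *operational radius* — the distance coverable within the response-time
budget.  Stationary AEDs are retrieved on foot, so the outward and return
legs halve the radius; drone-delivered ("airborne") AEDs fly one way.
Total annual cost is the unit count (a ceiling, since partial devices do
not exist) times the annual unit cost; airborne units are over-provisioned
by a redundancy factor to buffer technical failures and weather downtime.

All distances are km, times minutes, speeds km/min, costs EUR per year.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "Mode",
    "DeliveryModeParams",
    "Scenario",
    "CoverageResult",
    "UnitCostBreakdown",
    "InfeasibleScenarioError",
    "ceil_to_next_integer",
    "operational_radius",
    "hex_catchment_area",
    "units_required",
    "total_annual_cost",
    "cost_per_km2",
    "coverage_result",
    "annualize_unit_cost",
    "STATIONARY_DEFAULTS",
    "AIRBORNE_DEFAULTS",
]

#: sin(60 degrees) — the hexagon shape factor in A = 3 r^2 sin(60).
SIN60 = math.sin(math.radians(60.0))


class Mode(str, enum.Enum):
    """AED delivery mode."""

    STATIONARY = "stationary"
    AIRBORNE = "airborne"


class InfeasibleScenarioError(ValueError):
    """Raised when the response budget leaves no travel time (d <= access time)."""


@dataclass(frozen=True)
class DeliveryModeParams:
    """Physics and economics of one delivery mode.

    Parameters
    ----------
    mode
        Stationary (walk-and-retrieve) or airborne (drone delivery).
    access_time_min
        Fixed overhead in minutes: time to locate/unlock a stationary AED,
        or take-off plus landing time for a drone.
    speed_km_per_min
        Travel speed. Brisk walking is about 0.1 km/min; the reference
        drone averages 1 km/min (60 km/h) including manoeuvres.
    unit_cost_eur_per_year
        Annualised cost of owning and operating one unit.
    redundancy_factor
        Over-provisioning multiplier (1.0 = none). Airborne networks use
        1.5 to keep service available despite crashes, faults and weather.
    """

    mode: Mode
    access_time_min: float
    speed_km_per_min: float
    unit_cost_eur_per_year: float
    redundancy_factor: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        if not (self.access_time_min >= 0 and math.isfinite(self.access_time_min)):
            raise ValueError(f"access_time_min must be >= 0, got {self.access_time_min}")
        if not self.speed_km_per_min > 0:
            raise ValueError(f"speed_km_per_min must be > 0, got {self.speed_km_per_min}")
        if not self.unit_cost_eur_per_year > 0:
            raise ValueError(
                f"unit_cost_eur_per_year must be > 0, got {self.unit_cost_eur_per_year}"
            )
        if not self.redundancy_factor >= 1:
            raise ValueError(f"redundancy_factor must be >= 1, got {self.redundancy_factor}")


#: Reference stationary-mode parameters (cheapest device).
STATIONARY_DEFAULTS = DeliveryModeParams(
    mode=Mode.STATIONARY,
    access_time_min=1.0,
    speed_km_per_min=0.1,
    unit_cost_eur_per_year=170.0,
    redundancy_factor=1.0,
)

#: Reference airborne-mode parameters (base drone-system cost).
AIRBORNE_DEFAULTS = DeliveryModeParams(
    mode=Mode.AIRBORNE,
    access_time_min=1.0,
    speed_km_per_min=1.0,
    unit_cost_eur_per_year=32_248.0,
    redundancy_factor=1.5,
)


@dataclass(frozen=True)
class Scenario:
    """One model cell: a delivery mode covering an area within a response time."""

    params: DeliveryModeParams
    response_time_min: float
    area_km2: float

    def __post_init__(self) -> None:
        if not self.area_km2 > 0:
            raise ValueError(f"area_km2 must be > 0, got {self.area_km2}")
        if not self.response_time_min > self.params.access_time_min:
            raise InfeasibleScenarioError(
                f"response time {self.response_time_min} min leaves no travel "
                f"budget (access time {self.params.access_time_min} min)"
            )


@dataclass(frozen=True)
class CoverageResult:
    """Derived coverage quantities for a scenario."""

    radius_km: float
    catchment_km2: float
    units_required: int
    total_cost_eur_per_year: float
    cost_per_km2_eur: float


@dataclass(frozen=True)
class UnitCostBreakdown:
    """Annualisation of one unit's cost by straight-line depreciation.

    ``annual_unit_cost_eur = acquisition_eur / lifetime_years +
    annual_consumables_eur``.  Consumables (electrodes, battery, drone
    charging) are carried here for transparency even though they are small
    enough to be irrelevant for network-level decisions.
    """

    acquisition_eur: float
    lifetime_years: float
    annual_consumables_eur: float = 0.0

    def __post_init__(self) -> None:
        if not self.lifetime_years > 0:
            raise ValueError(f"lifetime_years must be > 0, got {self.lifetime_years}")
        if self.acquisition_eur < 0 or self.annual_consumables_eur < 0:
            raise ValueError("costs must be nonnegative")


def ceil_to_next_integer(value: float) -> int:
    """Mathematical ceiling of a finite nonnegative number.

    Exact integers are fixed points (``9.0 -> 9``); any positive fraction
    rounds up (``0.001 -> 1``). Negative or non-finite input raises
    :class:`ValueError`.
    """
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ValueError(f"expected a real number, got {value!r}")
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"expected a finite nonnegative number, got {value!r}")
    return math.ceil(value)


def operational_radius(params: DeliveryModeParams, response_time_min: float) -> float:
    """Maximum service distance in km within the response budget.

    Stationary: ``(d - a) * b / 2`` — the responder walks out and back, so
    only half the travel budget buys distance.  Airborne: ``(d - a) * b`` —
    the drone flies one way; the access time covers take-off and landing.
    """
    budget = response_time_min - params.access_time_min
    if budget <= 0:
        raise InfeasibleScenarioError(
            f"response time {response_time_min} min <= access time "
            f"{params.access_time_min} min: coverage radius would be <= 0"
        )
    r = budget * params.speed_km_per_min
    if params.mode is Mode.STATIONARY:
        r /= 2.0
    return r


def hex_catchment_area(radius_km: float) -> float:
    """Area (km²) of the regular hexagon inscribed in a circle of given radius.

    ``A = 3 r² sin(60°)`` = (3√3/2) r².  The hexagon, not the circle, is the
    catchment: hexagons tile the plane without gaps or overlap.
    """
    if not radius_km > 0:
        raise ValueError(f"radius_km must be > 0, got {radius_km}")
    return 3.0 * radius_km * radius_km * SIN60


def units_required(scenario: Scenario) -> int:
    """Number of AED units needed to cover the scenario area.

    Stationary: ``ceil(x / A)``.  Airborne: ``ceil(ceil(x / A) * redundancy)``
    — the inner ceiling counts locations, the outer applies the redundancy
    provisioning to whole units.
    """
    r = operational_radius(scenario.params, scenario.response_time_min)
    area_per_unit = hex_catchment_area(r)
    n_locations = ceil_to_next_integer(scenario.area_km2 / area_per_unit)
    if scenario.params.mode is Mode.AIRBORNE:
        return ceil_to_next_integer(n_locations * scenario.params.redundancy_factor)
    return n_locations


def total_annual_cost(scenario: Scenario) -> float:
    """Annual network cost: unit count times annual unit cost.

    Exact (integer arithmetic) whenever the unit cost is an integer.
    """
    n = units_required(scenario)
    k = scenario.params.unit_cost_eur_per_year
    if float(k).is_integer():
        return float(n * int(k))
    return n * k


def cost_per_km2(params: DeliveryModeParams, response_time_min: float) -> float:
    """Annual cost per km² of coverage, independent of the total area.

    Unit cost divided by one unit's hexagonal catchment — no ceiling, no
    redundancy.  This is the marginal density cost of the network and the
    natural scale-free efficiency comparison between modes.
    """
    area = hex_catchment_area(operational_radius(params, response_time_min))
    return params.unit_cost_eur_per_year / area


def coverage_result(scenario: Scenario) -> CoverageResult:
    """All derived quantities of a scenario in one pass."""
    r = operational_radius(scenario.params, scenario.response_time_min)
    return CoverageResult(
        radius_km=r,
        catchment_km2=hex_catchment_area(r),
        units_required=units_required(scenario),
        total_cost_eur_per_year=total_annual_cost(scenario),
        cost_per_km2_eur=cost_per_km2(scenario.params, scenario.response_time_min),
    )


def annualize_unit_cost(breakdown: UnitCostBreakdown) -> float:
    """Annual unit cost under straight-line depreciation plus consumables."""
    return breakdown.acquisition_eur / breakdown.lifetime_years + breakdown.annual_consumables_eur


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero — the convention used for printed currency."""
    factor = 10.0**ndigits
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)
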