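"""Indifference-threshold sensitivity analysis.

For each response time and area, solves for the unit cost of one delivery
mode at which its total annual cost exactly equals the other mode's total.
Because total cost is linear in unit cost at a fixed unit count, the
indifference cost is the competing mode's total divided by this mode's
unit count — solved in closed form, no root finding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .cost_model import (
    DeliveryModeParams,
    Mode,
    Scenario,
    round_half_up,
    total_annual_cost,
    units_required,
)
from .scenario_engine import ScenarioGrid

__all__ = [
    "IndifferencePoint",
    "indifference_stationary_unit_cost",
    "indifference_airborne_unit_cost",
    "run_sensitivity_table",
]


@dataclass(frozen=True)
class IndifferencePoint:
    """One solved indifference threshold.

    ``fixed_mode`` holds its printed unit cost; ``solved_unit_cost`` is the
    unit cost the *other* mode would need for both networks to cost the
    same per year.
    """

    area_label: str
    area_km2: float
    response_time_min: float
    fixed_mode: Mode
    fixed_unit_cost: float
    solved_mode: Mode
    solved_unit_cost: float


def indifference_stationary_unit_cost(
    response_time_min: float,
    area_km2: float,
    airborne_params: DeliveryModeParams,
    stationary_params: DeliveryModeParams,
) -> float:
    """Stationary unit cost that equates totals with the airborne network.

    Returns ``K_airborne / N_stationary`` (unrounded): the airborne total
    annual cost spread over the stationary unit count.  If real stationary
    devices cost more than this threshold, the airborne network wins.
    """
    k_air_total = total_annual_cost(Scenario(airborne_params, response_time_min, area_km2))
    n_stat = units_required(Scenario(stationary_params, response_time_min, area_km2))
    return k_air_total / n_stat


def indifference_airborne_unit_cost(
    response_time_min: float,
    area_km2: float,
    stationary_params: DeliveryModeParams,
    airborne_params: DeliveryModeParams,
) -> float:
    """Airborne unit cost that equates totals with the stationary network.

    Returns ``K_stationary / N_airborne`` (unrounded), with the airborne
    unit count including redundancy.  Below this threshold the airborne
    network is cheaper.
    """
    k_stat_total = total_annual_cost(Scenario(stationary_params, response_time_min, area_km2))
    n_air = units_required(Scenario(airborne_params, response_time_min, area_km2))
    return k_stat_total / n_air


def run_sensitivity_table(grid: ScenarioGrid) -> pd.DataFrame:
    """Solve every indifference point of the grid.

    For each (area, response time): each airborne unit-cost level fixed in
    turn solving for the stationary threshold, and each stationary level
    fixed solving for the airborne threshold.  With the default grid that
    is 6 response times x 2 areas x (3 + 3) = 72 points.

    Solved costs are reported rounded half-up to 2 decimals in the
    ``solved_unit_cost_eur`` column; ``solved_unit_cost_exact`` keeps full
    precision for downstream comparisons.
    """
    rows = []
    for area_label, area_km2 in grid.areas_km2:
        for d in grid.response_times_min:
            for k_m in sorted(grid.airborne_unit_costs):
                air = replace(grid.airborne_params, unit_cost_eur_per_year=k_m)
                solved = indifference_stationary_unit_cost(
                    d, area_km2, air, grid.stationary_params)
                rows.append(_row(area_label, area_km2, d,
                                 Mode.AIRBORNE, k_m, Mode.STATIONARY, solved))
            for k_s in sorted(grid.stationary_unit_costs):
                stat = replace(grid.stationary_params, unit_cost_eur_per_year=k_s)
                solved = indifference_airborne_unit_cost(
                    d, area_km2, stat, grid.airborne_params)
                rows.append(_row(area_label, area_km2, d,
                                 Mode.STATIONARY, k_s, Mode.AIRBORNE, solved))
    return pd.DataFrame(rows)


def _row(area_label, area_km2, d, fixed_mode, fixed_k, solved_mode, solved):
    return {
        "area_label": area_label,
        "area_km2": area_km2,
        "response_time_min": d,
        "fixed_mode": fixed_mode.value,
        "fixed_unit_cost_eur": fixed_k,
        "solved_mode": solved_mode.value,
        "solved_unit_cost_eur": round_half_up(solved, 2),
        "solved_unit_cost_exact": solved,
    }
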