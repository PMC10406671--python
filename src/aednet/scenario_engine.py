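"""Scenario sweeps over area, response time, unit cost and delivery mode.

Builds the full results table of the study design: two coverage areas
(whole district vs cardiac-arrest hot spots), integer response times from
3 to 8 minutes, and three unit-cost levels per mode, all evaluated with
the closed-form cost model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .cost_model import (
    AIRBORNE_DEFAULTS,
    STATIONARY_DEFAULTS,
    DeliveryModeParams,
    InfeasibleScenarioError,
    Mode,
    Scenario,
    coverage_result,
)

__all__ = ["ScenarioGrid", "run_grid", "summarize_ranges", "compare_modes",
           "RESULT_COLUMNS", "DEFAULT_AREAS"]

#: (label, km²) pairs of the reference study region: the full rural district
#: and the aggregate area of its OHCA hot spots.
DEFAULT_AREAS: tuple[tuple[str, float], ...] = (
    ("full_area", 3930.0),
    ("hot_spots", 680.4),
)

RESULT_COLUMNS = [
    "area_label", "area_km2", "mode", "response_time_min",
    "radius_km", "catchment_km2", "units", "unit_cost_eur", "total_cost_eur",
]


@dataclass(frozen=True)
class ScenarioGrid:
    """Cartesian scenario design: areas x response times x unit costs x modes.

    Defaults reproduce the reference study inputs: areas 3930 and 680.4 km²,
    response times 3–8 min, stationary unit costs {170, 263, 405} EUR/yr and
    airborne {32,248; 45,000; 55,000} EUR/yr.
    """

    areas_km2: tuple[tuple[str, float], ...] = DEFAULT_AREAS
    response_times_min: tuple[float, ...] = (3, 4, 5, 6, 7, 8)
    stationary_unit_costs: tuple[float, ...] = (170.0, 263.0, 405.0)
    airborne_unit_costs: tuple[float, ...] = (32_248.0, 45_000.0, 55_000.0)
    stationary_params: DeliveryModeParams = STATIONARY_DEFAULTS
    airborne_params: DeliveryModeParams = AIRBORNE_DEFAULTS

    def __post_init__(self) -> None:
        for name in ("areas_km2", "response_times_min",
                     "stationary_unit_costs", "airborne_unit_costs"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        for label, area in self.areas_km2:
            if not area > 0:
                raise ValueError(f"area {label!r} must be positive, got {area}")


def run_grid(grid: ScenarioGrid) -> pd.DataFrame:
    """Evaluate every grid cell and return the long-form results table.

    One row per (area, response time, mode, unit cost); deterministic and
    ordered by (area, d ascending, mode, unit cost ascending) so CSV output
    is diffable.  An infeasible cell aborts with an error naming it.
    """
    rows = []
    mode_specs = [
        (grid.stationary_params, grid.stationary_unit_costs),
        (grid.airborne_params, grid.airborne_unit_costs),
    ]
    for area_label, area_km2 in grid.areas_km2:
        for d in grid.response_times_min:
            for base_params, unit_costs in mode_specs:
                for k in sorted(unit_costs):
                    params = replace(base_params, unit_cost_eur_per_year=k)
                    try:
                        res = coverage_result(Scenario(params, d, area_km2))
                    except InfeasibleScenarioError as exc:
                        raise InfeasibleScenarioError(
                            f"infeasible cell (area={area_label}, mode="
                            f"{params.mode.value}, d={d}): {exc}"
                        ) from exc
                    rows.append({
                        "area_label": area_label,
                        "area_km2": area_km2,
                        "mode": params.mode.value,
                        "response_time_min": d,
                        "radius_km": res.radius_km,
                        "catchment_km2": res.catchment_km2,
                        "units": res.units_required,
                        "unit_cost_eur": k,
                        "total_cost_eur": res.total_cost_eur_per_year,
                    })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def summarize_ranges(table: pd.DataFrame) -> pd.DataFrame:
    """Min/max unit counts and total costs per (area, mode) stratum."""
    if table.empty:
        raise ValueError("results table is empty")
    grouped = table.groupby(["area_label", "mode"], sort=True)
    out = grouped.agg(
        units_min=("units", "min"),
        units_max=("units", "max"),
        total_cost_min_eur=("total_cost_eur", "min"),
        total_cost_max_eur=("total_cost_eur", "max"),
    ).reset_index()
    return out


def compare_modes(table: pd.DataFrame) -> pd.DataFrame:
    """Cost-dominance report: which mode is cheaper per (area, d, k_s, k_m).

    Enumerates the full cross of stationary and airborne unit-cost levels
    at each (area, response time), flagging the cheaper mode and tagging
    the rank-matched diagonal (lowest vs lowest, and so on), which is the
    natural like-for-like comparison.
    """
    modes = set(table["mode"])
    if {"stationary", "airborne"} - modes:
        raise ValueError(f"table must contain both modes, has {sorted(modes)}")
    stat = table[table["mode"] == "stationary"]
    air = table[table["mode"] == "airborne"]
    rows = []
    keys = ["area_label", "response_time_min"]
    for (area, d), s_block in stat.groupby(keys, sort=False):
        a_block = air[(air["area_label"] == area) & (air["response_time_min"] == d)]
        s_costs = sorted(s_block["unit_cost_eur"].unique())
        a_costs = sorted(a_block["unit_cost_eur"].unique())
        for i, ks in enumerate(s_costs):
            for j, km in enumerate(a_costs):
                cs = float(s_block.loc[s_block["unit_cost_eur"] == ks, "total_cost_eur"].iloc[0])
                cm = float(a_block.loc[a_block["unit_cost_eur"] == km, "total_cost_eur"].iloc[0])
                if cm < cs:
                    cheaper = "airborne"
                elif cs < cm:
                    cheaper = "stationary"
                else:
                    cheaper = "tie"
                rows.append({
                    "area_label": area,
                    "response_time_min": d,
                    "stationary_unit_cost_eur": ks,
                    "airborne_unit_cost_eur": km,
                    "stationary_total_eur": cs,
                    "airborne_total_eur": cm,
                    "cheaper_mode": cheaper,
                    "rank_matched": i == j,
                })
    return pd.DataFrame(rows)
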