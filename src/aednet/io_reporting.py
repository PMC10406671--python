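"""Configuration, serialization and figures for the AED network pipeline.

Ties the cost model, scenario sweeps, sensitivity analysis and synthetic
event generator into a reproducible run: a YAML config (defaults = the
reference study inputs), CSV/GeoJSON outputs with a run manifest, and the
two standard figures (interval-fixed cost step curves and cost-per-km²
versus response time).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cost_model import (
    AIRBORNE_DEFAULTS,
    STATIONARY_DEFAULTS,
    DeliveryModeParams,
)
from .ohca_synthetic import (
    DEFAULT_CLUSTER_SPEC,
    DEFAULT_HOTSPOT_THRESHOLD,
    ClusterSpec,
    HotSpotSummary,
    OHCAEventSet,
    StudyRegion,
)
from .scenario_engine import DEFAULT_AREAS, ScenarioGrid

logger = logging.getLogger("aednet")

__all__ = [
    "RunConfig", "load_config", "write_results", "plot_cost_curves",
    "events_to_geojson", "hotspots_to_geojson",
]

#: Response times shorter than this are flagged as clinically unrealistic
#: (deployment and dispatch overheads make sub-3-minute delivery infeasible).
MIN_REALISTIC_RESPONSE_MIN = 3.0


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; defaults are the reference study inputs."""

    grid: ScenarioGrid = field(default_factory=ScenarioGrid)
    region: StudyRegion = field(default_factory=StudyRegion)
    n_events: int = 555
    window_days: int = 730
    cluster_spec: ClusterSpec = DEFAULT_CLUSTER_SPEC
    cell_size_km: float = 1.0
    hotspot_threshold: int = DEFAULT_HOTSPOT_THRESHOLD
    seed: int = 0
    outdir: str = "aednet_output"
    report_precision: int = 2


_MODE_KEYS = {"access_time_min", "speed_km_per_min", "speed_km_per_h",
              "unit_cost_eur_per_year", "redundancy_factor"}
_TOP_KEYS = {"areas", "response_times", "unit_costs", "stationary", "airborne",
             "region", "n_events", "window_days", "cluster_spec", "cell_size_km",
             "hotspot_threshold", "seed", "outdir", "report_precision"}


def _mode_params(base: DeliveryModeParams, raw: dict, name: str) -> DeliveryModeParams:
    unknown = set(raw) - _MODE_KEYS
    if unknown:
        raise ValueError(f"unknown keys under {name!r}: {sorted(unknown)}")
    raw = dict(raw)
    if "speed_km_per_h" in raw:  # convert at load; internal unit is km/min
        raw["speed_km_per_min"] = raw.pop("speed_km_per_h") / 60.0
    return replace(base, **raw)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; with no file, return study defaults.

    Unknown keys are rejected with an error naming them.  A response time
    below 3 minutes triggers a warning (unrealistic for real deployments);
    one not exceeding the access time is a hard error raised downstream.
    """
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    stat = _mode_params(STATIONARY_DEFAULTS, data.get("stationary", {}), "stationary")
    air = _mode_params(AIRBORNE_DEFAULTS, data.get("airborne", {}), "airborne")

    kcfg = data.get("unit_costs", {})
    unknown = set(kcfg) - {"stationary", "airborne"}
    if unknown:
        raise ValueError(f"unknown keys under 'unit_costs': {sorted(unknown)}")

    areas = tuple((str(lbl), float(a)) for lbl, a in data.get("areas", DEFAULT_AREAS))
    d_list = tuple(data.get("response_times", (3, 4, 5, 6, 7, 8)))
    for d in d_list:
        if d < MIN_REALISTIC_RESPONSE_MIN:
            warnings.warn(
                f"response time {d} min is below {MIN_REALISTIC_RESPONSE_MIN} min, "
                "which is unlikely to be operationally feasible",
                UserWarning, stacklevel=2)
        if d <= stat.access_time_min or d <= air.access_time_min:
            raise ValueError(
                f"response time {d} min does not exceed the access time; "
                "coverage radius would be <= 0")

    grid = ScenarioGrid(
        areas_km2=areas,
        response_times_min=d_list,
        stationary_unit_costs=tuple(kcfg.get("stationary", (170.0, 263.0, 405.0))),
        airborne_unit_costs=tuple(kcfg.get("airborne", (32_248.0, 45_000.0, 55_000.0))),
        stationary_params=stat,
        airborne_params=air,
    )

    region_cfg = data.get("region", {})
    unknown = set(region_cfg) - {"width_km", "height_km"}
    if unknown:
        raise ValueError(f"unknown keys under 'region': {sorted(unknown)}")
    region = StudyRegion(**region_cfg)

    cs_cfg = data.get("cluster_spec", {})
    unknown = set(cs_cfg) - {"n_clusters", "sigma_km", "background_fraction"}
    if unknown:
        raise ValueError(f"unknown keys under 'cluster_spec': {sorted(unknown)}")
    cluster = replace(DEFAULT_CLUSTER_SPEC, **cs_cfg) if cs_cfg else DEFAULT_CLUSTER_SPEC

    return RunConfig(
        grid=grid,
        region=region,
        n_events=int(data.get("n_events", 555)),
        window_days=int(data.get("window_days", 730)),
        cluster_spec=cluster,
        cell_size_km=float(data.get("cell_size_km", 1.0)),
        hotspot_threshold=int(data.get("hotspot_threshold", DEFAULT_HOTSPOT_THRESHOLD)),
        seed=int(data.get("seed", 0)),
        outdir=str(data.get("outdir", "aednet_output")),
        report_precision=int(data.get("report_precision", 2)),
    )


def events_to_geojson(events: OHCAEventSet) -> dict:
    """Events as a GeoJSON FeatureCollection of Points (local planar km)."""
    return {
        "type": "FeatureCollection",
        "properties": {
            "coordinate_system": "local planar Cartesian, units km (no CRS)",
            "window_days": events.window_days,
        },
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [round(float(x), 6), round(float(y), 6)]},
                "properties": {"day_index": int(t)},
            }
            for x, y, t in zip(events.x_km, events.y_km, events.day_index)
        ],
    }


def hotspots_to_geojson(summary: HotSpotSummary) -> dict:
    """Hot-spot cells as a GeoJSON FeatureCollection of square Polygons."""
    c = summary.cell_size_km
    feats = []
    for ix, iy in summary.hotspot_cells:
        x0, y0 = ix * c, iy * c
        ring = [[x0, y0], [x0 + c, y0], [x0 + c, y0 + c], [x0, y0 + c], [x0, y0]]
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"count": int(summary.cell_counts[ix, iy])},
        })
    return {
        "type": "FeatureCollection",
        "properties": {
            "coordinate_system": "local planar Cartesian, units km (no CRS)",
            "cell_size_km": c,
            "hotspot_area_km2": summary.hotspot_area_km2,
            "events_covered": summary.events_covered,
            "coverage_fraction": summary.coverage_fraction,
        },
        "features": feats,
    }


def write_results(
    outdir: str | Path,
    config: RunConfig,
    scenarios: pd.DataFrame,
    sensitivity: pd.DataFrame,
    ranges: pd.DataFrame,
    events: OHCAEventSet | None = None,
    hotspots: HotSpotSummary | None = None,
) -> dict:
    """Write CSVs, GeoJSON layers and a run manifest; return the manifest.

    Output is locale-independent (decimal points, no thousands separators,
    no currency symbols — the manifest records ``currency: EUR``).  Nothing
    is written if any input table is empty.
    """
    for name, tbl in (("scenarios", scenarios), ("sensitivity", sensitivity),
                      ("ranges", ranges)):
        if tbl is None or tbl.empty:
            raise ValueError(f"{name} table is empty; nothing written")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False)
        written.append(name)

    _csv(scenarios, "scenarios.csv")
    _csv(sensitivity, "sensitivity.csv")
    _csv(ranges, "range_summary.csv")
    if events is not None:
        ev = pd.DataFrame({"x_km": events.x_km, "y_km": events.y_km,
                           "day_index": events.day_index})
        _csv(ev, "events.csv")
        (out / "events.geojson").write_text(
            json.dumps(events_to_geojson(events), indent=1))
        written.append("events.geojson")
    if hotspots is not None:
        (out / "hotspots.geojson").write_text(
            json.dumps(hotspots_to_geojson(hotspots), indent=1))
        written.append("hotspots.geojson")

    manifest = {
        "package": "aednet",
        "version": __version__,
        "currency": "EUR",
        "seed": config.seed,
        "config": _config_dict(config),
        "files": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("wrote %d files to %s", len(written) + 1, out)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["grid"]["stationary_params"]["mode"] = config.grid.stationary_params.mode.value
    d["grid"]["airborne_params"]["mode"] = config.grid.airborne_params.mode.value
    return d


def plot_cost_curves(
    scenarios: pd.DataFrame,
    outdir: str | Path,
    max_area_km2: float | None = None,
) -> list[Path]:
    """Render the two standard figures; return the written paths.

    1. Annual total cost versus covered area for each mode at the lowest
       unit-cost level and each response time — the ceiling on unit counts
       makes these step ("interval-fixed") curves.
    2. Cost per km² versus response time for both modes, which is
       independent of the covered area.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    from .cost_model import Mode, Scenario, cost_per_km2, total_annual_cost

    if scenarios.empty:
        raise ValueError("empty results table")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    # reconstruct per-mode params at the lowest unit-cost level
    mode_params = {}
    for mode, base in (("stationary", STATIONARY_DEFAULTS), ("airborne", AIRBORNE_DEFAULTS)):
        block = scenarios[scenarios["mode"] == mode]
        if block.empty:
            continue
        k = block["unit_cost_eur"].min()
        mode_params[mode] = replace(base, unit_cost_eur_per_year=k)

    if max_area_km2 is None:
        max_area_km2 = float(scenarios["area_km2"].max())
    d_values = sorted(scenarios["response_time_min"].unique())
    areas = np.linspace(max_area_km2 / 400.0, max_area_km2, 400)

    fig, axes = plt.subplots(1, len(mode_params), figsize=(11, 4.5), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, (mode, params) in zip(axes, mode_params.items()):
        for d in d_values:
            costs = [total_annual_cost(Scenario(params, d, a)) for a in areas]
            ax.step(areas, costs, where="post", label=f"d = {d:g} min")
        ax.set_title(f"{mode} (unit cost {params.unit_cost_eur_per_year:,.0f} EUR/yr)")
        ax.set_xlabel("covered area [km²]")
        ax.legend(fontsize=8)
    axes[0].set_ylabel("total annual cost [EUR/yr]")
    fig.suptitle("Interval-fixed annual network cost vs covered area")
    fig.tight_layout()
    p = out / "cost_vs_area.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    for mode, params in mode_params.items():
        dens = [cost_per_km2(params, d) for d in d_values]
        ax.plot(d_values, dens, marker="o", label=mode)
    ax.set_xlabel("response time d [min]")
    ax.set_ylabel("cost per km² [EUR/yr/km²]")
    ax.set_yscale("log")
    ax.set_title("Coverage cost density vs response time")
    ax.legend()
    fig.tight_layout()
    p = out / "cost_per_km2.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
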