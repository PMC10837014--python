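"""Composed analyses built from the stage modules.

`simulated_environment_analysis` runs the full environmental-variability
study on synthetic weather: enumerate the (site, year, planting date) grid,
attach a constant-family window index to every cell, partition the index
variance among site / year / planting date (overall and within site), and
summarize per-site index distributions.  Site coordinates are synthetic
stand-ins chosen so latitude ordering matches the real testing regions
(high-latitude temperate sites vs a near-tropical site).
"""

from __future__ import annotations

import logging

import numpy as np

from .env_simulation import (
    SimEnvironment,
    build_env_grid,
    partition_variance,
    rice_design,
    site_distributions,
    sorghum_design,
)
from .enviro_index import window_index
from .synthetic_data import simulate_weather

logger = logging.getLogger(__name__)

__all__ = ["simulated_environment_analysis", "DESIGNS"]

# synthetic stand-in coordinates: temperate vs tropical testing regions
DESIGNS = {
    "sorghum": {
        "plans": sorghum_design,
        "latitudes": {"IA": 42.0, "KS": 39.1, "PRS": 18.0, "PRW": 18.0},
        "weather_sites": {"IA": 42.0, "KS": 39.1, "PR": 18.0},
        "site_to_weather": {"IA": "IA", "KS": "KS", "PRS": "PR", "PRW": "PR"},
        "family": "PTT",
        "window": (18, 43),
        "merge": None,
    },
    "rice": {
        "plans": rice_design,
        "latitudes": {"ISA": 39.1, "TS": 36.0, "FU": 34.5,
                      "ISI": 24.3, "TH": 23.5, "HA": 22.0},
        "weather_sites": {"ISA": 39.1, "TS": 36.0, "FU": 34.5,
                          "ISI": 24.3, "TH": 23.5, "HA": 22.0},
        "site_to_weather": {s: s for s in ("ISA", "TS", "FU", "ISI", "TH", "HA")},
        "family": "GDD",
        "window": (9, 50),
        "merge": {"FU": "TS+FU", "TS": "TS+FU", "TH": "TH+HA", "HA": "TH+HA"},
    },
}


def simulated_environment_analysis(design: str = "sorghum", seed: int = 0) -> dict:
    """Grid -> index -> variance shares -> site distributions, on synthetic weather.

    The same index family and window is applied to every simulated
    environment (constant-index assumption, logged below).
    """
    cfg = DESIGNS[design]
    plans = cfg["plans"]()
    envs: list[SimEnvironment] = build_env_grid(plans)
    years = sorted({y for p in plans for y in p.years})
    weathers = simulate_weather(cfg["weather_sites"], years, seed=seed)
    family, (start, end) = cfg["family"], cfg["window"]
    logger.info("constant-index assumption: %s window %d-%d applied to all "
                "%d simulated environments", family, start, end, len(envs))
    for env in envs:
        w = weathers[cfg["site_to_weather"][env.site]]
        env.index_value = window_index(w, env.planting_date, start, end,
                                       family).value

    values = np.array([e.index_value for e in envs])
    factors = {
        "site": np.array([e.site for e in envs]),
        "year": np.array([e.year for e in envs]),
        "planting_date": np.array([
            (e.planting_date - e.planting_date.replace(month=1, day=1)).days
            for e in envs]),
    }
    overall = partition_variance(values, factors, ["site", "year", "planting_date"])

    within = {}
    for site in sorted({e.site for e in envs}):
        m = factors["site"] == site
        within[site] = partition_variance(
            values[m], {"year": factors["year"][m],
                        "planting_date": factors["planting_date"][m]},
            ["year", "planting_date"])
    # population-level within-site share: pool the sites' centred values
    pooled_vals, pooled_factors = [], {"year": [], "planting_date": [], "site": []}
    for site in within:
        m = factors["site"] == site
        pooled_vals.append(values[m] - values[m].mean())
        pooled_factors["year"].append(factors["year"][m])
        pooled_factors["planting_date"].append(factors["planting_date"][m])
        pooled_factors["site"].append(np.array([site] * int(m.sum())))
    within_pooled = partition_variance(
        np.concatenate(pooled_vals),
        {"site_year": np.array([f"{s}_{y}" for s, y in zip(
            np.concatenate(pooled_factors["site"]),
            np.concatenate(pooled_factors["year"]))]),
         "planting_date": np.concatenate(pooled_factors["planting_date"])},
        ["site_year", "planting_date"])

    return {
        "environments": envs,
        "partition": overall,
        "within_site": within,
        "within_site_pooled": within_pooled,
        "distributions": site_distributions(envs, merge=cfg["merge"]),
        "family": family,
        "window": (start, end),
    }
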