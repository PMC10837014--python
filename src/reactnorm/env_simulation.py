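"""Simulated multi-environment grids and environmental-variability analysis.

A simulated "environment" is one (site, year, planting date) cell; the full
grid enumerates every planting day inside each site's window for each year.
Attaching an environmental-index value (same family and window for every
cell — an explicit constant-index assumption) lets the index variance be
partitioned among site, year and planting date, and per-site index
distributions be compared to judge which testing sites sample a wide
environmental range.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)

__all__ = [
    "SitePlan",
    "SimEnvironment",
    "VariancePartition",
    "build_env_grid",
    "partition_variance",
    "site_distributions",
    "sorghum_design",
    "rice_design",
]


@dataclass
class SitePlan:
    """A site (or site-season set) with its years and planting-date window.

    The window is given as "MM-DD" strings; an end before the start rolls
    into the next calendar year (winter plantings).
    """

    site: str
    years: list[int]
    window_start: str
    window_end: str

    def dates(self, year: int) -> list[dt.date]:
        sm, sd = (int(p) for p in self.window_start.split("-"))
        em, ed = (int(p) for p in self.window_end.split("-"))
        start = dt.date(year, sm, sd)
        end = dt.date(year + 1, em, ed) if (em, ed) < (sm, sd) else dt.date(year, em, ed)
        if end < start:
            raise InvalidArgumentError(f"window end {end} before start {start}")
        return [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]


@dataclass
class SimEnvironment:
    site: str
    year: int
    planting_date: dt.date
    index_value: float | None = None


@dataclass
class VariancePartition:
    factor_names: list[str]
    percents: np.ndarray
    residual_percent: float


def build_env_grid(site_plans: list[SitePlan]) -> list[SimEnvironment]:
    """Full Cartesian enumeration: every site-plan x year x daily planting date."""
    out = []
    for plan in sorted(site_plans, key=lambda p: p.site):
        if not plan.years:
            raise InvalidArgumentError(f"site {plan.site} has no years")
        for year in sorted(plan.years):
            for d in plan.dates(year):
                out.append(SimEnvironment(site=plan.site, year=year, planting_date=d))
    return out


def sorghum_design(years: range | list[int] = range(2010, 2017)) -> list[SitePlan]:
    """Three summer site-sets (IA, KS, PR) plus a PR winter set, 51-day windows."""
    years = list(years)
    return [
        SitePlan("IA", years, "05-21", "07-10"),
        SitePlan("KS", years, "05-21", "07-10"),
        SitePlan("PRS", years, "05-21", "07-10"),
        SitePlan("PRW", years, "12-01", "01-20"),
    ]


def rice_design(years: range | list[int] = range(2007, 2010)) -> list[SitePlan]:
    """Six sites, 93-day spring windows (30 March - 30 June)."""
    years = list(years)
    return [SitePlan(s, years, "03-30", "06-30")
            for s in ("TS", "FU", "ISI", "ISA", "HA", "TH")]


def _dummies(labels: np.ndarray) -> np.ndarray:
    levels, codes = np.unique(labels, return_inverse=True)
    return np.eye(len(levels))[codes]


def partition_variance(
    values: np.ndarray,
    factors: dict[str, np.ndarray],
    order: list[str] | None = None,
) -> VariancePartition:
    """Sequential (Type-I) decomposition of the index variance by factor.

    Factors enter as categorical main effects in the given order; each
    factor's percent is its incremental reduction in residual sum of squares
    over the total centred sum of squares.  With a balanced grid the order
    does not matter.  Single-level factors contribute 0 with a warning;
    confounded factors keep whatever incremental SS the least-squares fit
    assigns them.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise InvalidArgumentError("need >=2 environments")
    if order is None:
        order = list(factors)
    for name in order:
        if len(np.asarray(factors[name])) != n:
            raise InvalidArgumentError(f"factor {name} length mismatch")
    tss = float(np.sum((values - values.mean()) ** 2))
    if tss == 0:
        return VariancePartition(list(order), np.zeros(len(order)), 0.0)

    X = np.ones((n, 1))
    rss_prev = tss
    percents = []
    for name in order:
        labels = np.asarray(factors[name])
        if len(np.unique(labels)) < 2:
            logger.warning("factor %s has a single level; contributes 0", name)
            percents.append(0.0)
            continue
        X = np.hstack([X, _dummies(labels)])
        coef, *_ = np.linalg.lstsq(X, values, rcond=None)
        rss = float(np.sum((values - X @ coef) ** 2))
        percents.append(max(rss_prev - rss, 0.0) / tss * 100.0)
        rss_prev = rss
    return VariancePartition(list(order), np.array(percents),
                             residual_percent=rss_prev / tss * 100.0)


def site_distributions(
    envs: list[SimEnvironment],
    merge: dict[str, str] | None = None,
    grid_points: int = 256,
) -> dict[str, dict]:
    """Per-site summary of index values: moments plus a KDE on a common grid.

    ``merge`` maps site ids to group labels (e.g. TS and FU pooled); sites
    with <2 values or zero spread get point statistics only, flagged
    degenerate.
    """
    merge = merge or {}
    by_site: dict[str, list[float]] = {}
    for env in envs:
        if env.index_value is None:
            raise InvalidArgumentError("environments lack index values")
        by_site.setdefault(merge.get(env.site, env.site), []).append(env.index_value)
    all_vals = np.concatenate([np.asarray(v) for v in by_site.values()])
    lo, hi = all_vals.min(), all_vals.max()
    pad = 0.05 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, grid_points)

    out = {}
    for site, vals in sorted(by_site.items()):
        v = np.asarray(vals, dtype=float)
        summary = {
            "n": len(v), "min": float(v.min()), "max": float(v.max()),
            "mean": float(v.mean()), "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            "grid": grid, "density": None, "degenerate": False,
        }
        if len(v) < 2 or summary["sd"] == 0.0:
            summary["degenerate"] = True
            logger.warning("site %s has a degenerate index distribution", site)
        else:
            summary["density"] = gaussian_kde(v)(grid)
        out[site] = summary
    return out
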