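"""CSV readers/writers for every table the pipeline consumes or produces.

Schemas (all CSV, UTF-8, ISO-8601 dates):

* phenotypes, wide: first column ``genotype``, one column per environment,
  empty or "NA" cells missing;
* phenotypes, long: columns genotype, environment, replicate, value —
  replicates are averaged into line means;
* markers: first column ``genotype``, one column per marker, codes in
  {-1, 0, 1} (or {0, 1, 2} with ``coding="012"``), empty/"NA" missing;
* weather: columns site, date, T2M_MAX, T2M_MIN, optional DAY_LENGTH, plus
  a site-metadata table with site, latitude, longitude.

Readers validate rather than coerce: malformed cells raise SchemaError with
coordinates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .enviro_index import DailyWeather
from .errors import DataError, SchemaError
from .genomic_prediction import CVResult, MarkerMatrix
from .reaction_norm import PhenotypeMatrix, ReactionNormSet
from .subset_consistency import ConsistencyResult, CurveFit

logger = logging.getLogger(__name__)

__all__ = [
    "read_phenotypes", "write_phenotypes", "read_markers", "write_markers",
    "read_weather", "write_weather", "write_reaction_norms",
    "write_consistency", "write_curve_fit", "write_cv_results",
    "RunConfig",
]

_NA = {"", "NA", "NaN", "nan"}


def _numeric(frame: pd.DataFrame, context: str) -> np.ndarray:
    out = np.full(frame.shape, np.nan)
    for j, col in enumerate(frame.columns):
        for i, raw in enumerate(frame[col]):
            s = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
            if s in _NA:
                continue
            try:
                out[i, j] = float(s)
            except ValueError:
                raise SchemaError(
                    f"{context}: non-numeric cell at row {i + 2}, column {col!r}: {raw!r}")
    return out


def read_phenotypes(path: str | Path, layout: str = "wide") -> PhenotypeMatrix:
    """Read a genotype x environment line-mean table (wide or long layout)."""
    path = Path(path)
    if layout == "wide":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if df.shape[1] < 3:
            raise SchemaError(f"{path}: wide layout needs a genotype column and >=2 environments")
        geno = df.iloc[:, 0].tolist()
        if len(set(geno)) != len(geno):
            raise SchemaError(f"{path}: duplicate genotype ids")
        env = list(df.columns[1:])
        values = _numeric(df.iloc[:, 1:], str(path))
        empty = np.all(np.isnan(values), axis=0)
        if empty.any():
            raise DataError(f"{path}: environments with no data: "
                            f"{[e for e, b in zip(env, empty) if b]}")
        return PhenotypeMatrix(geno, env, values)
    if layout == "long":
        df = pd.read_csv(path)
        needed = {"genotype", "environment", "value"}
        if not needed <= set(df.columns):
            raise SchemaError(f"{path}: long layout needs columns {sorted(needed)}")
        if not np.issubdtype(df["value"].dtype, np.number):
            bad = df.index[pd.to_numeric(df["value"], errors="coerce").isna()
                           & df["value"].notna()]
            raise SchemaError(f"{path}: non-numeric value cells at rows {list(bad + 2)[:5]}")
        means = df.groupby(["genotype", "environment"])["value"].mean().unstack()
        return PhenotypeMatrix(list(means.index.astype(str)),
                               list(means.columns.astype(str)),
                               means.to_numpy())
    raise SchemaError(f"unknown layout {layout!r}")


def write_phenotypes(pheno: PhenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(pheno.values, index=pheno.genotype_ids,
                      columns=pheno.environment_ids)
    df.index.name = "genotype"
    df.to_csv(path)


def read_markers(path: str | Path, coding: str = "-101") -> MarkerMatrix:
    """Read a genotype x marker code table; ``coding="012"`` recodes to -1/0/+1."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: needs a genotype column and >=1 marker")
    geno = df.iloc[:, 0].tolist()
    codes = _numeric(df.iloc[:, 1:], str(path))
    if coding == "012":
        codes = codes - 1.0
    elif coding != "-101":
        raise SchemaError(f"unknown marker coding {coding!r}")
    return MarkerMatrix(geno, list(df.columns[1:]), codes)


def write_markers(markers: MarkerMatrix, path: str | Path) -> None:
    df = pd.DataFrame(markers.codes, index=markers.genotype_ids,
                      columns=markers.marker_ids)
    df.index.name = "genotype"
    df.to_csv(path)


def read_weather(weather_path: str | Path, sites_path: str | Path) -> dict[str, DailyWeather]:
    """Read a NASA-POWER-like daily weather table plus site coordinates."""
    wx = pd.read_csv(weather_path, parse_dates=["date"])
    needed = {"site", "date", "T2M_MAX", "T2M_MIN"}
    if not needed <= set(wx.columns):
        raise SchemaError(f"{weather_path}: needs columns {sorted(needed)}")
    meta = pd.read_csv(sites_path).set_index("site")
    out = {}
    for site, grp in wx.groupby("site"):
        if site not in meta.index:
            raise SchemaError(f"{sites_path}: no coordinates for site {site!r}")
        frame = pd.DataFrame({"tmax": grp["T2M_MAX"].to_numpy(),
                              "tmin": grp["T2M_MIN"].to_numpy()},
                             index=pd.DatetimeIndex(grp["date"]))
        if "DAY_LENGTH" in grp.columns:
            frame["day_length"] = grp["DAY_LENGTH"].to_numpy()
        out[site] = DailyWeather(site=site, latitude=float(meta.loc[site, "latitude"]),
                                 longitude=float(meta.loc[site, "longitude"]),
                                 frame=frame.sort_index())
    return out


def write_weather(weathers: dict[str, DailyWeather], weather_path: str | Path,
                  sites_path: str | Path) -> None:
    rows = []
    for site, w in sorted(weathers.items()):
        df = w.frame.reset_index(names="date")
        df.insert(0, "site", site)
        df = df.rename(columns={"tmax": "T2M_MAX", "tmin": "T2M_MIN",
                                "day_length": "DAY_LENGTH"})
        rows.append(df)
    pd.concat(rows).to_csv(weather_path, index=False)
    pd.DataFrame([{"site": s, "latitude": w.latitude, "longitude": w.longitude}
                  for s, w in sorted(weathers.items())]).to_csv(sites_path, index=False)


def write_reaction_norms(norms: ReactionNormSet, path: str | Path) -> None:
    pd.DataFrame({"genotype": norms.genotype_ids, "intercept": norms.intercepts,
                  "slope": norms.slopes, "n_env_used": norms.n_env_used,
                  "method": norms.method}).to_csv(path, index=False)


def write_consistency(results: list[ConsistencyResult], path: str | Path) -> None:
    """Tidy CSV: one row per subset with membership, range and correlations."""
    pd.DataFrame([{
        "k": r.subset.k,
        "members": ";".join(r.subset.members),
        "env_mean_range": r.subset.env_mean_range,
        "range_fraction": r.subset.range_fraction,
        "corr_slope": r.corr_slope,
        "corr_intercept": r.corr_intercept,
        "n_genotypes": r.n_genotypes,
        "error": r.error or "",
    } for r in results]).to_csv(path, index=False)


def write_curve_fit(fit: CurveFit, path: str | Path) -> None:
    payload = {"model": fit.model, "a": fit.a, "b": fit.b, "rss": fit.rss,
               "smoothing_parameter": fit.smoothing_parameter,
               "x_grid": np.asarray(fit.x_grid).tolist(),
               "fitted": np.asarray(fit.fitted).tolist()}
    Path(path).write_text(json.dumps(payload, indent=2))


def write_cv_results(results: list[CVResult], path: str | Path) -> None:
    pd.DataFrame([{
        "scenario": r.scenario, "parameter": r.parameter,
        "members": ";".join(r.subset.members), "k": r.subset.k,
        "n_folds": r.n_folds, "seed": r.seed, "accuracy": r.accuracy,
        "n_genotypes": r.n_genotypes,
    } for r in results]).to_csv(path, index=False)


@dataclasses.dataclass
class RunConfig:
    """Run-level configuration, serialized next to outputs for provenance."""

    seed: int = 0
    trait: str = "flowering_time"
    trait_units: str = "GDD"
    gdd_base: float = 10.0
    gdd_ceiling: float = 37.8
    index_family: str = "PTT"
    index_window: tuple[int, int] = (18, 43)
    cv_folds: int = 10
    subset_k_min: int = 2
    subset_k_max: int | None = None
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        if "index_window" in raw:
            raw["index_window"] = tuple(raw["index_window"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["index_window"] = list(d["index_window"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
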