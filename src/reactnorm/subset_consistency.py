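"""Exhaustive environment-subset analysis of reaction-norm consistency.

Every subset of the tested environments is re-analysed on its own
environmental-mean gradient, and the resulting slopes/intercepts are
correlated (Pearson) against the whole-set estimates.  The key design
variable is the subset's environmental mean range, expressed as a fraction
of the whole-set range; summary curves (a cube-root power law and per-size
smoothing splines) describe how consistency grows with that range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.interpolate import BSpline, make_smoothing_spline

from .errors import InvalidArgumentError
from .reaction_norm import (
    PhenotypeMatrix,
    ReactionNormSet,
    compute_environment_means,
    fit_joint_regression,
    two_env_parameters,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EnvironmentSubset",
    "ConsistencyResult",
    "CurveFit",
    "enumerate_subsets",
    "consistency_scan",
    "fit_cube_root",
    "fit_smoothing_spline",
]


@dataclass
class EnvironmentSubset:
    """A subset of environments with its range on the whole-set I scale."""

    members: tuple[str, ...]
    k: int
    env_mean_range: float | None = None
    range_fraction: float | None = None


@dataclass
class ConsistencyResult:
    subset: EnvironmentSubset
    corr_slope: float
    corr_intercept: float
    n_genotypes: int
    error: str | None = None


@dataclass
class CurveFit:
    """A fitted summary curve: cube-root power law or smoothing spline."""

    model: str
    a: float | None
    b: float | None
    x_grid: np.ndarray
    fitted: np.ndarray
    rss: float
    smoothing_parameter: float | None = None
    predict: object | None = None


def enumerate_subsets(n_env: int, k_min: int, k_max: int,
                      env_ids: list[str] | None = None) -> list[EnvironmentSubset]:
    """All environment subsets of size k_min..k_max in lexicographic order."""
    if k_min < 2:
        raise InvalidArgumentError("k_min must be >= 2")
    if not (k_min <= k_max <= n_env):
        raise InvalidArgumentError("require 2 <= k_min <= k_max <= n_env")
    if env_ids is None:
        env_ids = [str(j) for j in range(n_env)]
    if len(env_ids) != n_env:
        raise InvalidArgumentError("env_ids length must equal n_env")
    out = []
    for k in range(k_min, k_max + 1):
        for combo in combinations(env_ids, k):
            out.append(EnvironmentSubset(members=tuple(combo), k=k))
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def consistency_scan(
    pheno: PhenotypeMatrix, k_min: int = 2, k_max: int | None = None
) -> list[ConsistencyResult]:
    """Correlate subset-estimated parameters against whole-set estimates.

    For each subset the environmental means are recomputed within the subset
    (two-environment subsets use the averaging/difference rule).  Ranges are
    measured on the whole-set I scale so they are comparable across subsets.
    Estimation failures are recorded on the result, not raised.
    """
    n_env = pheno.n_environments
    if k_max is None:
        k_max = n_env - 1
    I_whole = compute_environment_means(pheno)
    whole = fit_joint_regression(pheno, I_whole)
    whole_pos = {g: i for i, g in enumerate(whole.genotype_ids)}
    I_by_env = dict(zip(I_whole.environment_ids, I_whole.centered))
    whole_range = float(np.ptp(I_whole.centered))

    results = []
    for subset in enumerate_subsets(n_env, k_min, k_max, pheno.environment_ids):
        ivals = np.array([I_by_env[e] for e in subset.members])
        subset.env_mean_range = float(np.ptp(ivals))
        subset.range_fraction = subset.env_mean_range / whole_range
        try:
            if subset.k == 2:
                est = two_env_parameters(pheno, list(subset.members))
            else:
                I_sub = compute_environment_means(pheno, list(subset.members))
                est = fit_joint_regression(pheno, I_sub)
        except Exception as exc:  # tagged, scan continues
            logger.warning("subset %s failed: %s", subset.members, exc)
            results.append(ConsistencyResult(subset, np.nan, np.nan, 0, str(exc)))
            continue
        common = [i for i, g in enumerate(est.genotype_ids) if g in whole_pos]
        wi = [whole_pos[est.genotype_ids[i]] for i in common]
        results.append(ConsistencyResult(
            subset=subset,
            corr_slope=_pearson(est.slopes[common], whole.slopes[wi]),
            corr_intercept=_pearson(est.intercepts[common], whole.intercepts[wi]),
            n_genotypes=len(common),
        ))
    return results


def fit_cube_root(x: np.ndarray, y: np.ndarray) -> CurveFit:
    """Least squares of y on x^(-1/3) with intercept: y = a + b*x^(-1/3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0):
        raise InvalidArgumentError("cube-root fit requires all x > 0")
    if len(np.unique(x)) < 2:
        raise InvalidArgumentError("need >=2 distinct x values")
    X = np.column_stack([np.ones_like(x), x ** (-1.0 / 3.0)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    a, b = float(coef[0]), float(coef[1])
    return CurveFit(
        model="cube_root", a=a, b=b, x_grid=x, fitted=fitted,
        rss=float(np.sum((y - fitted) ** 2)),
        predict=lambda xn, a=a, b=b: a + b * np.asarray(xn, dtype=float) ** (-1.0 / 3.0),
    )


def _gcv_spline(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                lams: np.ndarray) -> tuple[BSpline, float]:
    """Pick the penalty by generalized cross-validation over a log grid.

    The smoother is linear in y, so its trace is recovered by smoothing the
    unit vectors; GCV(lam) = (RSS/n) / (1 - tr(S)/n)^2.
    """
    n = len(x)
    best = (np.inf, None, None)
    eye = np.eye(n)
    for lam in lams:
        spl = make_smoothing_spline(x, y, w=w, lam=lam)
        fitted = spl(x)
        rss = float(np.sum(w * (y - fitted) ** 2))
        tr = sum(make_smoothing_spline(x, eye[j], w=w, lam=lam)(x[j]) for j in range(n))
        denom = (1.0 - tr / n) ** 2
        score = (rss / n) / denom if denom > 0 else np.inf
        if score < best[0]:
            best = (score, spl, lam)
    return best[1], best[2]


def fit_smoothing_spline(
    x: np.ndarray,
    y: np.ndarray,
    group: np.ndarray | None = None,
    x_grid: np.ndarray | None = None,
    lam: float | None = None,
) -> dict[object, CurveFit]:
    """One GCV-smoothed spline of y on x per group (e.g. per environment count).

    Duplicate x within a group are collapsed to their mean with proportional
    weight.  Groups with <4 distinct x fall back to a straight line; groups
    with <2 points are skipped with a warning.  ``lam`` forces a fixed
    penalty instead of the GCV choice.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if group is None:
        group = np.zeros(len(x), dtype=int)
    group = np.asarray(group)
    fits: dict[object, CurveFit] = {}
    for g in np.unique(group):
        m = group == g
        xs, ys = x[m], y[m]
        ux, inv = np.unique(xs, return_inverse=True)
        if len(ux) < 2:
            logger.warning("group %s has <2 distinct x points; skipped", g)
            continue
        uy = np.bincount(inv, weights=ys) / np.bincount(inv)
        w = np.bincount(inv).astype(float)
        grid = np.linspace(ux[0], ux[-1], 100) if x_grid is None else np.asarray(x_grid)
        if len(ux) < 4:
            logger.info("group %s has <4 distinct x points; linear fallback", g)
            coef = np.polyfit(ux, uy, 1, w=np.sqrt(w))
            fitted = np.polyval(coef, grid)
            rss = float(np.sum(w * (uy - np.polyval(coef, ux)) ** 2))
            fits[g] = CurveFit("linear", a=float(coef[1]), b=float(coef[0]),
                               x_grid=grid, fitted=fitted, rss=rss,
                               predict=lambda xn, c=coef: np.polyval(c, xn))
            continue
        if lam is None:
            spl, lam_used = _gcv_spline(ux, uy, w, np.logspace(-6, 4, 21))
        else:
            spl, lam_used = make_smoothing_spline(ux, uy, w=w, lam=lam), lam
        fitted_u = spl(ux)
        fits[g] = CurveFit(
            model="spline", a=None, b=None, x_grid=grid, fitted=spl(grid),
            rss=float(np.sum(w * (uy - fitted_u) ** 2)),
            smoothing_parameter=float(lam_used), predict=spl,
        )
    return fits
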