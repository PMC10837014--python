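"""Joint-regression (Finlay-Wilkinson) estimation of reaction norms.

Each genotype's phenotype across environments is modelled as a line in the
environmental mean: ``Y_ij = mu_i + beta_i * I_j + delta_ij`` where ``I_j``
is the mean of all genotypes in environment *j*, centred by the grand mean
so that ``mu_i`` is the intercept (genotypic value) and ``beta_i`` the slope
(plasticity).  Two-environment designs cannot support a regression; there
the intercept is the average of the two values and the slope the difference
standardised by the spread of the environmental means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, InvalidArgumentError, SingularDesignError

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeMatrix",
    "EnvironmentMeanVector",
    "ReactionNormSet",
    "compute_environment_means",
    "fit_joint_regression",
    "two_env_parameters",
]


@dataclass
class PhenotypeMatrix:
    """Genotype x environment table of line means.

    ``values`` has shape (n_genotypes, n_environments); missing cells are NaN.
    """

    genotype_ids: list[str]
    environment_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_g, n_e = self.values.shape
        if len(self.genotype_ids) != n_g or len(self.environment_ids) != n_e:
            raise InvalidArgumentError("id lists do not match the value matrix shape")
        if len(set(self.genotype_ids)) != n_g:
            raise InvalidArgumentError("genotype ids are not unique")
        if len(set(self.environment_ids)) != n_e:
            raise InvalidArgumentError("environment ids are not unique")
        if n_g < 2 or n_e < 2:
            raise InvalidArgumentError("need at least 2 genotypes and 2 environments")
        n_obs = np.sum(~np.isnan(self.values), axis=1)
        if np.any(n_obs < 2):
            bad = [g for g, n in zip(self.genotype_ids, n_obs) if n < 2]
            raise DataError(f"genotypes with <2 observed environments: {bad}")

    @property
    def n_genotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_environments(self) -> int:
        return self.values.shape[1]

    def env_indices(self, env_subset: list[str]) -> np.ndarray:
        missing = [e for e in env_subset if e not in self.environment_ids]
        if missing:
            raise InvalidArgumentError(f"unknown environments: {missing}")
        pos = {e: j for j, e in enumerate(self.environment_ids)}
        return np.array([pos[e] for e in env_subset], dtype=int)


@dataclass
class EnvironmentMeanVector:
    """Per-environment population means; ``centered`` are the I_j values."""

    environment_ids: list[str]
    raw_means: np.ndarray
    grand_mean: float
    centered: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.raw_means = np.asarray(self.raw_means, dtype=float)
        self.centered = self.raw_means - self.grand_mean


@dataclass
class ReactionNormSet:
    """Per-genotype intercepts and slopes with regression residuals.

    ``residuals`` has one row per genotype, one column per environment used in
    the fit (NaN where the phenotype was missing).  ``method`` is "ols" for
    joint regression or "two_env" for the two-environment rule.
    """

    genotype_ids: list[str]
    environment_ids: list[str]
    intercepts: np.ndarray
    slopes: np.ndarray
    residuals: np.ndarray
    n_env_used: np.ndarray
    method: str


def compute_environment_means(
    pheno: PhenotypeMatrix, env_subset: list[str] | None = None
) -> EnvironmentMeanVector:
    """Environment means over genotypes, centred by the unweighted grand mean.

    Each environment's raw mean averages genotypes with non-missing values;
    the grand mean is the unweighted mean of the subset's raw means, so the
    centred values (the I_j gradient) sum to zero.
    """
    if env_subset is None:
        env_subset = list(pheno.environment_ids)
    if len(env_subset) == 0:
        raise InvalidArgumentError("environment subset is empty")
    idx = pheno.env_indices(env_subset)
    sub = pheno.values[:, idx]
    n_obs = np.sum(~np.isnan(sub), axis=0)
    if np.any(n_obs == 0):
        bad = [env_subset[j] for j in np.flatnonzero(n_obs == 0)]
        raise DataError(f"environments with no observed genotypes: {bad}")
    raw = np.nanmean(sub, axis=0)
    grand = float(np.mean(raw))
    return EnvironmentMeanVector(list(env_subset), raw, grand)


def fit_joint_regression(
    pheno: PhenotypeMatrix, I: EnvironmentMeanVector
) -> ReactionNormSet:
    """Per-genotype OLS of phenotype on the centred environmental mean.

    Requires >=3 environments; genotypes are fitted on their non-missing
    environments only and dropped (with a warning) below 3 usable values.
    """
    if len(I.environment_ids) < 3:
        raise InvalidArgumentError(
            "joint regression needs >=3 environments; use two_env_parameters for pairs"
        )
    x_all = I.centered
    if np.ptp(x_all) == 0:
        raise SingularDesignError("all environmental means identical")
    idx = pheno.env_indices(I.environment_ids)
    Y = pheno.values[:, idx]

    n_g, n_e = Y.shape
    obs = ~np.isnan(Y)
    n_used = obs.sum(axis=1)
    keep = n_used >= 3
    if not np.all(keep):
        dropped = [g for g, k in zip(pheno.genotype_ids, keep) if not k]
        logger.warning("dropping %d genotypes with <3 observed environments: %s",
                       len(dropped), dropped)

    intercepts = np.full(n_g, np.nan)
    slopes = np.full(n_g, np.nan)
    resid = np.full_like(Y, np.nan)

    complete = keep & (n_used == n_e)
    if np.any(complete):
        # vectorised closed form for the common complete-data case
        xc = x_all - x_all.mean()
        sxx = float(xc @ xc)
        Yc = Y[complete]
        b = (Yc @ xc) / sxx
        a = Yc.mean(axis=1) - b * x_all.mean()
        slopes[complete] = b
        intercepts[complete] = a
        resid[complete] = Yc - (a[:, None] + np.outer(b, x_all))
    for i in np.flatnonzero(keep & ~complete):
        m = obs[i]
        x = x_all[m]
        if np.ptp(x) == 0:
            logger.warning("genotype %s observed only at identical I values; dropped",
                           pheno.genotype_ids[i])
            keep[i] = False
            continue
        y = Y[i, m]
        b, a = np.polyfit(x, y, 1)
        slopes[i], intercepts[i] = b, a
        resid[i, m] = y - (a + b * x)

    ok = keep
    return ReactionNormSet(
        genotype_ids=[g for g, k in zip(pheno.genotype_ids, ok) if k],
        environment_ids=list(I.environment_ids),
        intercepts=intercepts[ok],
        slopes=slopes[ok],
        residuals=resid[ok],
        n_env_used=n_used[ok],
        method="ols",
    )


def two_env_parameters(
    pheno: PhenotypeMatrix,
    env_pair: list[str],
    I: EnvironmentMeanVector | None = None,
) -> ReactionNormSet:
    """Intercepts and slopes from exactly two environments.

    Intercept is the average of the two line means; slope is their difference
    divided by the spread of the environmental means, with the pair ordered so
    the higher-mean environment comes second.  Genotypes missing either value
    are excluded.
    """
    if len(env_pair) != 2:
        raise InvalidArgumentError("env_pair must contain exactly 2 environments")
    if I is None:
        I = compute_environment_means(pheno, env_pair)
    else:
        if list(I.environment_ids) != list(env_pair):
            raise InvalidArgumentError("I does not match env_pair")
    order = np.argsort(I.centered, kind="stable")
    ids = [env_pair[j] for j in order]
    i_lo, i_hi = I.centered[order]
    if i_hi == i_lo:
        raise SingularDesignError(f"environments {ids} have identical means")

    idx = pheno.env_indices(ids)
    Y = pheno.values[:, idx]
    obs = ~np.isnan(Y).any(axis=1)
    if not np.all(obs):
        excluded = [g for g, k in zip(pheno.genotype_ids, obs) if not k]
        logger.warning("two_env_parameters excluding %d genotypes with missing values: %s",
                       len(excluded), excluded)
    Yo = Y[obs]
    intercepts = Yo.mean(axis=1)
    slopes = (Yo[:, 1] - Yo[:, 0]) / (i_hi - i_lo)
    fitted_lo = intercepts + slopes * i_lo
    fitted_hi = intercepts + slopes * i_hi
    resid = np.column_stack([Yo[:, 0] - fitted_lo, Yo[:, 1] - fitted_hi])
    return ReactionNormSet(
        genotype_ids=[g for g, k in zip(pheno.genotype_ids, obs) if k],
        environment_ids=ids,
        intercepts=intercepts,
        slopes=slopes,
        residuals=resid,
        n_env_used=np.full(int(obs.sum()), 2),
        method="two_env",
    )
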