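"""Ridge-regression BLUP of reaction-norm parameters from genome-wide markers.

The model is ``y = 1*m + Z*u + e`` with marker effects ``u ~ N(0, s2_u I)``
and residuals ``e ~ N(0, s2_e I)``.  The variance ratio ``lambda = s2_e/s2_u``
is estimated by restricted maximum likelihood: the genotype-relationship
kernel ``Z Z'`` is eigendecomposed once in the space orthogonal to the
intercept, after which the restricted likelihood is a cheap one-dimensional
function of lambda, profiled on a coarse log grid and refined by
golden-section search.  At the optimum the effects are the usual ridge
solution, so prediction is ``mean + codes . effects``.

Cross-validation follows two scenarios: "within" scores held-out predictions
against parameters estimated from the same environment subset, "whole"
against parameters estimated from the full set of environments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import golden

from .errors import (
    DegenerateDesignError,
    InvalidArgumentError,
    SchemaError,
)
from .reaction_norm import (
    PhenotypeMatrix,
    compute_environment_means,
    fit_joint_regression,
    two_env_parameters,
)
from .subset_consistency import EnvironmentSubset

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMatrix",
    "BlupModel",
    "CVResult",
    "fit_ridge_blup",
    "predict",
    "cross_validate",
    "reml_neg_loglik",
]


@dataclass
class MarkerMatrix:
    """Numeric biallelic marker codes: -1 / 0 / +1 per genotype x marker.

    Missing codes are NaN and are mean-imputed per marker at fit time.
    """

    genotype_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.genotype_ids), len(self.marker_ids)):
            raise InvalidArgumentError("codes shape does not match id lists")
        finite = self.codes[~np.isnan(self.codes)]
        if finite.size and not np.all(np.isin(finite, (-1.0, 0.0, 1.0))):
            raise InvalidArgumentError("marker codes must be in {-1, 0, +1} or missing")

    def imputed(self) -> np.ndarray:
        """Codes with missing entries replaced by the marker's mean code."""
        Z = self.codes.copy()
        if np.isnan(Z).any():
            col_mean = np.nanmean(Z, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            nan_r, nan_c = np.where(np.isnan(Z))
            Z[nan_r, nan_c] = col_mean[nan_c]
        return Z

    def subset(self, rows: np.ndarray) -> "MarkerMatrix":
        return MarkerMatrix([self.genotype_ids[i] for i in rows],
                            list(self.marker_ids), self.codes[rows])


@dataclass
class BlupModel:
    mean: float
    effects: np.ndarray
    marker_ids: list[str]
    lam: float
    reml_loglik: float
    sigma2_u: float
    sigma2_e: float


def _projected_eigen(Z: np.ndarray, y: np.ndarray):
    """Eigendecomposition of the marker kernel orthogonal to the intercept."""
    n = len(y)
    K = Z @ Z.T
    T = np.linalg.qr(np.hstack([np.ones((n, 1)), np.eye(n)[:, : n - 1]]))[0][:, 1:]
    M = T.T @ K @ T
    theta, U = np.linalg.eigh(M)
    theta = np.clip(theta, 0.0, None)
    eta = U.T @ (T.T @ y)
    return K, theta, eta


def reml_neg_loglik(markers: MarkerMatrix, y: np.ndarray, lam: float) -> float:
    """Eigen-based restricted negative log-likelihood at a fixed variance ratio.

    Up to an additive constant in lam:
    0.5 * [(n-1) log(y' P y) + log|K + lam I| + log|1' (K + lam I)^-1 1|].
    """
    y = np.asarray(y, dtype=float)
    _, theta, eta = _projected_eigen(markers.imputed(), y)
    return _reml_profile(theta, eta * eta)(np.log10(lam))


def _reml_profile(theta: np.ndarray, eta2: np.ndarray):
    """Restricted log-likelihood of log10(lambda), up to an additive constant."""
    m = len(theta)

    def nll(log10_lam: float) -> float:
        lam = 10.0 ** log10_lam
        d = theta + lam
        s = float(np.sum(eta2 / d))
        if s <= 0:  # y in the span of the intercept: flat likelihood
            return 0.0
        return 0.5 * (m * np.log(s) + float(np.sum(np.log(d))))

    return nll


def fit_ridge_blup(markers: MarkerMatrix, y: np.ndarray) -> BlupModel:
    """REML ridge-BLUP of marker effects for a per-genotype target.

    lambda is profiled on a 25-point grid over log10 lambda in [-6, 6] and
    refined by golden-section search between the neighbours of the grid
    optimum; ties resolve toward more shrinkage.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise InvalidArgumentError("y contains non-finite values")
    n = len(y)
    if n != len(markers.genotype_ids):
        raise InvalidArgumentError("y length does not match genotype count")
    if n < 3:
        raise InvalidArgumentError("need >=3 genotypes")
    Z = markers.imputed()
    if np.allclose(Z, Z[0], atol=0.0):
        raise DegenerateDesignError("all genotypes have identical marker codes")

    K, theta, eta = _projected_eigen(Z, y)
    nll = _reml_profile(theta, eta * eta)

    grid = np.linspace(-6.0, 6.0, 25)
    vals = np.array([nll(g) for g in grid])
    best = int(np.flatnonzero(vals == vals.min())[-1])  # ties -> larger lambda
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if best in (0, len(grid) - 1):
        log_lam = grid[best]
    else:
        try:
            log_lam = float(golden(nll, brack=(lo, grid[best], hi)))
        except ValueError:  # flat bracket: keep the grid optimum
            log_lam = grid[best]
    lam = 10.0 ** float(np.clip(log_lam, -6.0, 6.0))

    H = K + lam * np.eye(n)
    Hinv_y = np.linalg.solve(H, y)
    Hinv_1 = np.linalg.solve(H, np.ones(n))
    mean = float(np.ones(n) @ Hinv_y / (np.ones(n) @ Hinv_1))
    resid = y - mean
    u = Z.T @ np.linalg.solve(H, resid)

    m = n - 1
    s = float(np.sum(eta * eta / (theta + lam)))
    sigma2_u = s / m if s > 0 else 0.0
    return BlupModel(
        mean=mean, effects=u, marker_ids=list(markers.marker_ids), lam=lam,
        reml_loglik=-nll(np.log10(lam)), sigma2_u=sigma2_u,
        sigma2_e=lam * sigma2_u,
    )


def predict(model: BlupModel, markers_new: MarkerMatrix) -> np.ndarray:
    """Predicted target for new genotypes: mean + codes . effects."""
    if list(markers_new.marker_ids) != list(model.marker_ids):
        missing = [m for m in model.marker_ids if m not in markers_new.marker_ids]
        raise SchemaError(f"marker ids do not match training set; missing: {missing}")
    return model.mean + markers_new.imputed() @ model.effects


def _estimate_parameters(pheno: PhenotypeMatrix, env_ids: list[str]):
    if len(env_ids) == 2:
        return two_env_parameters(pheno, env_ids)
    I = compute_environment_means(pheno, env_ids)
    return fit_joint_regression(pheno, I)


@dataclass
class CVResult:
    scenario: str
    parameter: str
    subset: EnvironmentSubset
    n_folds: int
    seed: int
    accuracy: float
    n_genotypes: int


def cross_validate(
    markers: MarkerMatrix,
    pheno: PhenotypeMatrix,
    subset: EnvironmentSubset | list[str],
    scenario: str = "within",
    parameter: str = "slope",
    n_folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Seeded k-fold CV accuracy of ridge-BLUP for one plasticity parameter.

    Genotypes are shuffled by the seed and split into contiguous folds; each
    fold's model is trained on subset-estimated parameters of the remaining
    genotypes.  Accuracy is the mean over folds of the Pearson correlation
    between that fold's predictions and its reference values
    (subset-estimated for scenario "within", whole-set-estimated for
    scenario "whole").  Per-fold correlation is used rather than pooling all
    out-of-fold predictions into one correlation: pooled predictions carry
    each fold's training mean, which is anti-correlated with the held-out
    values, biasing the pooled correlation noticeably below zero when the
    genetic signal is weak.
    """
    if scenario not in ("within", "whole"):
        raise InvalidArgumentError(f"unknown scenario {scenario!r}")
    if parameter not in ("slope", "intercept"):
        raise InvalidArgumentError(f"unknown parameter {parameter!r}")
    env_ids = list(subset.members) if isinstance(subset, EnvironmentSubset) else list(subset)
    sub_est = _estimate_parameters(pheno, env_ids)
    train_vals = {g: v for g, v in zip(
        sub_est.genotype_ids,
        sub_est.slopes if parameter == "slope" else sub_est.intercepts)}
    if scenario == "whole":
        whole = _estimate_parameters(pheno, list(pheno.environment_ids))
        ref_vals = {g: v for g, v in zip(
            whole.genotype_ids,
            whole.slopes if parameter == "slope" else whole.intercepts)}
    else:
        ref_vals = train_vals

    usable = np.array([i for i, g in enumerate(markers.genotype_ids)
                       if g in train_vals and g in ref_vals])
    n_dropped = len(markers.genotype_ids) - len(usable)
    if n_dropped:
        logger.info("cross_validate dropping %d genotypes without estimates", n_dropped)
    if not (2 <= n_folds <= len(usable)):
        raise InvalidArgumentError("n_folds must be in [2, n_genotypes]")

    rng = np.random.default_rng(seed)
    order = rng.permutation(usable)
    folds = np.array_split(order, n_folds)
    if min(len(f) for f in folds) < 2:
        raise InvalidArgumentError("a fold has <2 genotypes; reduce n_folds")

    fold_corrs = []
    for fold in folds:
        train = np.setdiff1d(order, fold)
        y_train = np.array([train_vals[markers.genotype_ids[i]] for i in train])
        model = fit_ridge_blup(markers.subset(train), y_train)
        p = predict(model, markers.subset(fold))
        r = np.array([ref_vals[markers.genotype_ids[i]] for i in fold])
        if np.std(p) == 0 or np.std(r) == 0:
            logger.warning("fold with zero variance skipped in accuracy")
            continue
        fold_corrs.append(float(np.corrcoef(p, r)[0, 1]))
    acc = float(np.mean(fold_corrs)) if fold_corrs else np.nan
    sub_obj = subset if isinstance(subset, EnvironmentSubset) else EnvironmentSubset(
        members=tuple(env_ids), k=len(env_ids))
    return CVResult(scenario=scenario, parameter=parameter, subset=sub_obj,
                    n_folds=n_folds, seed=seed, accuracy=acc,
                    n_genotypes=len(usable))
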