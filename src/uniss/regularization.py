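"""Elastic-net fits for a single trait, exposing the nonzero support.

The downstream selection-probability machinery only consumes the *support*
(which genetic coefficients are nonzero) of an elastic-net fit at a fixed
penalty level, for either a Gaussian (quantitative trait) or a binomial
(binary trait) loss, optionally with unpenalized covariates such as
population-cluster indicators.

The objective is parameterized in the normalized convention used by modern
path solvers: mean loss plus ``lam * (alpha * L1 + (1 - alpha)/2 * L2)``.
This is a monotone reparameterization of the unnormalized "sum of squares
plus lam * (alpha L1 + (1-alpha) L2)" form, so supports at matched path
positions are identical; only the numeric lambda scale differs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from uniss import _solver
from uniss.simdata import GenotypeMatrix

__all__ = ["ElasticNetSpec", "FitResult", "lambda_path", "fit_support", "standardize_columns"]

Family = Literal["gaussian", "binomial"]


class DegenerateResponseError(ValueError):
    """Raised for constant (or otherwise unusable) response vectors."""


@dataclass(frozen=True)
class ElasticNetSpec:
    """Solver and path settings.

    alpha
        Lasso/ridge mixing proportion; the default 0.1 leans on the ridge
        side, appropriate for the strong inter-variant correlation of
        genotype panels.
    n_lambda, lambda_min_ratio
        Length and depth of the geometric penalty path from ``lambda_max``
        (smallest penalty with an empty support) downwards.
    """

    alpha: float = 0.1
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    standardize: bool = True
    max_iter: int = 100_000
    tol: float = 1e-7

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be at least 2")
        if not (0.0 < self.lambda_min_ratio < 1.0):
            raise ValueError("lambda_min_ratio must lie in (0, 1)")


@dataclass
class FitResult:
    """Support of the penalized genetic coefficients at one penalty level."""

    support: np.ndarray  # bool, length p (genetic variants only)
    lambda_used: float
    trait_family: Family
    n_nonzero: int

    def __post_init__(self) -> None:
        if self.n_nonzero != int(self.support.sum()):
            raise ValueError("n_nonzero inconsistent with support")


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, GenotypeMatrix):
        return X.values
    return np.asarray(X)


def standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center columns and scale them to unit 1/n-variance.

    Zero-variance columns are mapped to all-zero columns (scale reported as
    0), which removes them from the fit without reindexing; their
    coefficients can only be zero.
    """
    X = np.asarray(X, dtype=np.float64)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / scale
    Xs[:, sd == 0.0] = 0.0
    return np.asfortranarray(Xs), mean, np.where(sd > 0, sd, 0.0)


def _validate_response(y: np.ndarray, family: Family) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64).ravel()
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    if np.ptp(y) == 0.0:
        raise DegenerateResponseError("response is constant")
    if family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial response must be coded 0/1")
    return y


def _null_linear_predictor(
    Xc_std: Optional[np.ndarray], y: np.ndarray, family: Family, spec: ElasticNetSpec
) -> np.ndarray:
    """Fitted values of the covariate-only (or intercept-only) model."""
    n = y.shape[0]
    if family == "gaussian":
        if Xc_std is None:
            return np.full(n, y.mean())
        design = np.column_stack([np.ones(n), Xc_std])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return design @ coef
    if Xc_std is None:
        return np.full(n, y.mean())
    pf = np.zeros(Xc_std.shape[1])
    beta, b0, _ = _solver.enet_binomial_cd(
        np.asfortranarray(Xc_std), y, 1.0, spec.alpha, pf, spec.tol, spec.max_iter
    )
    eta = b0 + Xc_std @ beta
    return 1.0 / (1.0 + np.exp(-eta))


def lambda_max(
    X,
    y: np.ndarray,
    family: Family = "gaussian",
    spec: ElasticNetSpec = ElasticNetSpec(),
    covariates: Optional[np.ndarray] = None,
) -> float:
    """Smallest penalty at which every penalized coefficient is zero.

    Derived from the KKT conditions at beta = 0 (after the covariate-only
    fit): ``lambda_max = max_j |<x_j, y - null_fit>| / (n * alpha)``.
    """
    if spec.alpha == 0.0:
        raise ValueError("lambda_max is undefined for alpha = 0 (pure ridge)")
    Xm = _as_matrix(X)
    y = _validate_response(y, family)
    Xs, _, _ = standardize_columns(Xm) if spec.standardize else (np.asfortranarray(Xm, dtype=np.float64), None, None)
    Xc_std = None
    if covariates is not None:
        Xc_std, _, _ = standardize_columns(covariates)
    fitted = _null_linear_predictor(Xc_std, y, family, spec)
    grad = Xs.T @ (y - fitted) / y.shape[0]
    lam = float(np.max(np.abs(grad))) / spec.alpha
    if lam <= 0.0:
        raise DegenerateResponseError("response carries no signal against any variant")
    # tiny inflation so the boundary tie |gradient| == threshold resolves to
    # the empty support regardless of summation order
    return lam * (1.0 + 1e-10)


def lambda_path(
    X,
    y: np.ndarray,
    family: Family = "gaussian",
    spec: ElasticNetSpec = ElasticNetSpec(),
    covariates: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Strictly decreasing geometric grid of ``n_lambda`` penalty values.

    Runs from ``lambda_max`` down to ``lambda_max * lambda_min_ratio``,
    log-equispaced, matching the conventional regularization path.
    """
    lmax = lambda_max(X, y, family, spec, covariates)
    return np.geomspace(lmax, lmax * spec.lambda_min_ratio, num=spec.n_lambda)


def fit_support(
    X,
    y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    family: Family = "gaussian",
    lam: float = 1.0,
    spec: ElasticNetSpec = ElasticNetSpec(),
) -> FitResult:
    """Fit the elastic net at one penalty and report the genetic support.

    The intercept and any covariates are never penalized and never counted
    in the support.  Genotype columns are standardized before fitting (the
    support is reported in the original column order).
    """
    Xm = _as_matrix(X)
    y = _validate_response(y, family)
    if not np.isfinite(Xm).all():
        raise ValueError("design matrix contains non-finite values")
    if lam <= 0.0:
        raise ValueError("lam must be positive")
    n, p = Xm.shape
    if spec.standardize:
        Xs, _, _ = standardize_columns(Xm)
    else:
        Xs = np.asfortranarray(Xm, dtype=np.float64)
    n_cov = 0
    if covariates is not None:
        Xc = np.asarray(covariates, dtype=np.float64)
        if Xc.ndim == 1:
            Xc = Xc[:, None]
        Xc_std, _, sd = standardize_columns(Xc)
        if (sd == 0.0).any():
            raise ValueError("constant covariate column (absorbed by the intercept)")
        n_cov = Xc_std.shape[1]
        Xs = np.asfortranarray(np.column_stack([Xc_std, Xs]))
    pf = np.concatenate([np.zeros(n_cov), np.ones(p)])

    beta = _fit_standardized(Xs, y, family, lam, spec.alpha, pf, spec.tol, spec.max_iter)
    support = beta[n_cov:] != 0.0
    return FitResult(
        support=support,
        lambda_used=float(lam),
        trait_family=family,
        n_nonzero=int(support.sum()),
    )


def _fit_standardized(Xs, y, family, lam, alpha, pf, tol, max_iter) -> np.ndarray:
    """Low-level dispatch used by the bootstrap loop (no re-validation).

    The Gaussian response is standardized internally (path-solver
    convention) with the penalty rescaled to match, which makes supports at
    matched path positions exactly invariant to rescaling y.
    """
    if family == "gaussian":
        yc = y - y.mean()
        sdy = yc.std()
        if sdy == 0.0:
            raise DegenerateResponseError("response is constant")
        beta, passes = _solver.enet_gaussian_cd(Xs, yc / sdy, lam / sdy, alpha, pf, tol, max_iter)
    elif family == "binomial":
        beta, _b0, passes = _solver.enet_binomial_cd(Xs, y, lam, alpha, pf, tol, max_iter)
    else:
        raise ValueError(f"unknown family {family!r}")
    if passes >= max_iter:
        raise RuntimeError(
            f"coordinate descent did not converge within {max_iter} sweeps "
            f"(family={family}, lam={lam:g})"
        )
    return beta
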