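"""Reliability estimation from pairwise covariances.

Under the reflective factor model ``X_i = lambda_i * eta + eps_i`` with a
standard-normal latent, mutually independent errors and unit-variance
indicators, the loading lambda_i is the indicator's reliability and the
off-diagonal covariances satisfy ``Cov(X_i, X_j) = lambda_i * lambda_j``.
The d loadings are estimated by solving the unbiased estimating equations

    sum_{j != i} lambda_j (C_ij - lambda_i lambda_j) = 0,   i = 1..d,

where C_ij is the divisor-N sample covariance.  Two solvers are provided:
a damped Newton iteration on log-lambda ("root") and the equivalent
quasi-Poisson log-link regression of the d(d-1) covariance vector on item
membership indicators ("quasi-poisson").  Both give the same point
estimates.

The per-subject moment vector V_k behind these equations, and its mean
Jacobian in lambda, are exposed for the plug-in variance correction of the
reliability-dependent structural test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .data_model import IndicatorMatrix, ValidationError

__all__ = [
    "CovarianceSet",
    "ReliabilityEstimate",
    "IdentificationError",
    "EstimationError",
    "ConvergenceError",
    "pairwise_covariances",
    "reliability_moment_vector",
    "reliability_moment_rows",
    "estimate_reliabilities",
    "solve_from_covariances",
    "reliability_jacobian",
    "closed_form_d3",
]


class IdentificationError(ValidationError):
    """Fewer than 3 indicators: the loading system is underidentified."""


class EstimationError(ValueError):
    """A covariance configuration incompatible with positive loadings."""


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, residual: float | None = None):
        super().__init__(msg)
        self.residual = residual


@dataclass(frozen=True)
class CovarianceSet:
    """d x d matrix of pairwise divisor-N covariances; diagonal is unused."""

    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValidationError("covariance set must be square")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValidationError("covariance set must be symmetric")
        off = C[~np.eye(C.shape[0], dtype=bool)]
        if not np.isfinite(off).all():
            raise ValidationError("non-finite off-diagonal covariance")
        object.__setattr__(self, "C", C)

    @property
    def d(self) -> int:
        return self.C.shape[0]


@dataclass(frozen=True)
class ReliabilityEstimate:
    lambda_: np.ndarray
    log_lambda: np.ndarray
    converged: bool
    solver: str
    n_used: int

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambda_, dtype=float)
        if np.any(lam <= 0):
            raise ValidationError("reliabilities must be strictly positive")
        if not np.allclose(lam, np.exp(self.log_lambda), rtol=1e-10):
            raise ValidationError("lambda and log_lambda disagree")
        object.__setattr__(self, "lambda_", lam)
        object.__setattr__(self, "log_lambda", np.asarray(self.log_lambda, float))

    @property
    def d(self) -> int:
        return self.lambda_.shape[0]


def pairwise_covariances(X: IndicatorMatrix) -> CovarianceSet:
    """All pairwise sample covariances C_ij with divisor N."""
    return CovarianceSet(np.cov(X.values, rowvar=False, bias=True))


def closed_form_d3(C: np.ndarray) -> np.ndarray:
    """Spearman-type closed form for d=3: lambda_1 = sqrt(C12*C13/C23) etc."""
    C = np.asarray(C, float)
    return np.array(
        [
            np.sqrt(C[0, 1] * C[0, 2] / C[1, 2]),
            np.sqrt(C[0, 1] * C[1, 2] / C[0, 2]),
            np.sqrt(C[0, 2] * C[1, 2] / C[0, 1]),
        ]
    )


def reliability_moment_vector(
    x_row: np.ndarray, xbar: np.ndarray, lam: np.ndarray
) -> np.ndarray:
    """Per-subject estimating-function vector V_k.

    V_ik = sum_{j != i} lambda_j [ (x_i - xbar_i)(x_j - xbar_j) - lambda_i lambda_j ].
    Its sample average vanishes at the estimating-equation solution.
    """
    return reliability_moment_rows(np.asarray(x_row, float)[None, :], xbar, lam)[0]


def reliability_moment_rows(
    X_values: np.ndarray, xbar: np.ndarray, lam: np.ndarray
) -> np.ndarray:
    """N x d matrix of V_k rows, vectorized over subjects."""
    lam = np.asarray(lam, float)
    if np.any(lam <= 0):
        raise ValueError("lambda must be strictly positive")
    Xc = np.atleast_2d(np.asarray(X_values, float)) - np.asarray(xbar, float)
    d = lam.shape[0]
    # V_ik = sum_{j!=i} lam_j * xc_i * xc_j  -  lam_i * sum_{j!=i} lam_j^2
    s1 = Xc @ lam  # sum_j lam_j xc_j per subject
    cross = Xc * (s1[:, None] - Xc * lam[None, :])
    const = lam * (np.sum(lam**2) - lam**2)
    return cross - const[None, :]


def reliability_jacobian(X: IndicatorMatrix, lam: np.ndarray) -> np.ndarray:
    """Mean Jacobian (1/N) sum_k dV_k/dlambda, analytic.

    Off-diagonal (i, m != i): C_im - 2 lambda_i lambda_m.
    Diagonal (i, i): -sum_{j != i} lambda_j^2.
    """
    lam = np.asarray(lam, float)
    C = np.cov(X.values, rowvar=False, bias=True)
    J = C - 2.0 * np.outer(lam, lam)
    np.fill_diagonal(J, -(np.sum(lam**2) - lam**2))
    return J


def _residual(lam: np.ndarray, C: np.ndarray) -> np.ndarray:
    """g_i = sum_{j != i} lam_j (C_ij - lam_i lam_j)."""
    M = C - np.outer(lam, lam)
    np.fill_diagonal(M, 0.0)
    return M @ lam


def _jacobian_g(lam: np.ndarray, C: np.ndarray) -> np.ndarray:
    J = C - 2.0 * np.outer(lam, lam)
    np.fill_diagonal(J, -(np.sum(lam**2) - lam**2))
    return J


def _init_log_lambda(C: np.ndarray) -> np.ndarray:
    """Initialize at the median of Spearman-type closed forms.

    For each item s, every pair (i, j) of other items gives the estimate
    sqrt(C_si C_sj / C_ij); the median over pairs is exact at rank-1 input
    and robust otherwise.  The weighted estimating equations have spurious
    roots far from the rank-1 cone, so starting close matters.
    """
    d = C.shape[0]
    init = np.empty(d)
    for s in range(d):
        others = [i for i in range(d) if i != s]
        vals = [
            C[s, i] * C[s, j] / C[i, j]
            for k, i in enumerate(others)
            for j in others[k + 1 :]
            if C[i, j] > 0
        ]
        vals = [v for v in vals if v > 0]
        init[s] = np.median(vals) if vals else 1e-3
    return 0.5 * np.log(np.maximum(init, 1e-6))


def _solve_root(C: np.ndarray, tol: float = 1e-10, max_iter: int = 200):
    """Damped Newton on log-lambda (positivity enforced by parameterization)."""
    Lam = _init_log_lambda(C)
    lam = np.exp(Lam)
    res = _residual(lam, C)
    for _ in range(max_iter):
        if np.abs(res).max() < tol:
            return lam, True, float(np.abs(res).max())
        # d g / d Lam = (d g / d lam) * diag(lam)
        J = _jacobian_g(lam, C) * lam[None, :]
        try:
            step = np.linalg.solve(J, -res)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -res, rcond=None)[0]
        t = 1.0
        norm0 = np.abs(res).max()
        while t > 1e-8:
            lam_new = np.exp(Lam + t * step)
            res_new = _residual(lam_new, C)
            if np.abs(res_new).max() < norm0:
                break
            t /= 2.0
        Lam = Lam + t * step
        lam = np.exp(Lam)
        res = _residual(lam, C)
    return lam, bool(np.abs(res).max() < tol), float(np.abs(res).max())


def _solve_quasi_poisson(C: np.ndarray):
    """Log-link regression of the d(d-1) covariance vector on item membership.

    Working model: log E(C_ij) = Lambda_i + Lambda_j, without intercept;
    both (i,j) and (j,i) entries enter, treated as mutually independent
    and homoscedastic.  The homoscedastic (constant-variance) working
    assumption makes the quasi-likelihood score for Lambda_s exactly
    sum_{j != s} lambda_j (C_sj - lambda_s lambda_j) = 0, so the
    exponentiated coefficients solve the same estimating equations as the
    root solver for any covariance set.  (A variance-proportional-to-mean
    working model would instead drop the lambda_j weight and only agree
    at exactly rank-1 input.)
    """
    d = C.shape[0]
    rows, cols, y = [], [], []
    for i in range(d):
        for j in range(d):
            if i != j:
                rows.append(i)
                cols.append(j)
                y.append(C[i, j])
    y = np.asarray(y)
    design = np.zeros((len(y), d))
    design[np.arange(len(y)), rows] = 1.0
    design[np.arange(len(y)), cols] = 1.0
    model = sm.GLM(
        y, design, family=sm.families.Gaussian(link=sm.families.links.Log())
    )
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # an exactly rank-1 covariance set fits with zero deviance, which
        # statsmodels flags as perfect separation; harmless here
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(maxiter=1000, tol=1e-14)
        except ValueError:
            # IRLS can stumble on a poor first step; quasi-Newton fallback
            fit = model.fit(method="lbfgs", maxiter=2000)
    lam = np.exp(fit.params)
    res = float(np.abs(_residual(lam, C)).max())
    return lam, res < 1e-8, res


def solve_from_covariances(
    cov: CovarianceSet, solver: str = "root", n_used: int = 0
) -> ReliabilityEstimate:
    """Solve the estimating equations given a covariance set."""
    C = cov.C
    d = cov.d
    if d < 3:
        raise IdentificationError(
            f"reliability estimation needs d >= 3 indicators, got d={d}"
        )
    off = ~np.eye(d, dtype=bool)
    if np.any(C[off] <= 0):
        i, j = np.argwhere((C <= 0) & off)[0]
        raise EstimationError(
            f"non-positive pairwise covariance C[{i + 1},{j + 1}]={C[i, j]:.4g}; "
            "reverse-code indicators first"
        )
    if solver == "root":
        lam, converged, res = _solve_root(C)
    elif solver == "quasi-poisson":
        lam, converged, res = _solve_quasi_poisson(C)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    if not converged and res > 1e-6:
        raise ConvergenceError(
            f"reliability solver {solver!r} failed; final residual {res:.3g}",
            residual=res,
        )
    return ReliabilityEstimate(
        lambda_=lam,
        log_lambda=np.log(lam),
        converged=converged,
        solver=solver,
        n_used=n_used,
    )


def estimate_reliabilities(
    X: IndicatorMatrix, solver: str = "root"
) -> ReliabilityEstimate:
    """Estimate loadings from the data's pairwise covariances."""
    return solve_from_covariances(pairwise_covariances(X), solver=solver, n_used=X.n)
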