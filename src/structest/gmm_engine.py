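"""Distance-metric GMM machinery shared by both structural tests.

Given per-subject moment vectors U_k(theta) whose population mean is zero
under the null, the distance-metric statistic

    T = N * Ubar(theta)' Sigma^{-1} Ubar(theta),   minimized over theta,

is asymptotically chi-square with (moments - parameters) degrees of
freedom, where Sigma is the empirical covariance of the U_k.  This module
implements the empirical weight matrix (with an eigenvalue-truncated
pseudo-inverse for structurally singular directions), the quadratic-form
minimizer, and chi-square inference.  One-step weighting: Sigma is
evaluated once at initial consistent estimates and held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MomentSpec",
    "WeightMatrix",
    "TestResult",
    "DegenerateMomentsError",
    "GmmConvergenceError",
    "empirical_weight",
    "minimize_distance_metric",
    "chi_square_pvalue",
]


class DegenerateMomentsError(ValueError):
    """All moment vectors are identically zero."""


class GmmConvergenceError(RuntimeError):
    def __init__(self, msg: str, best_value: float, grad_norm: float):
        super().__init__(msg)
        self.best_value = best_value
        self.grad_norm = grad_norm


@dataclass(frozen=True)
class MomentSpec:
    """Moment condition system for one test.

    ``mean_moment(theta)`` returns the m-vector Ubar(theta) averaged over
    subjects; ``mean_jacobian(theta)`` its m x q derivative.  Both are
    typically built from per-level sufficient statistics so each optimizer
    step costs O(m*q), independent of N.  ``u_rows(theta)`` materializes
    the N x m per-subject moments (used to build the weight matrix).
    """

    dim_moments: int
    dim_params: int
    mean_moment: Callable[[np.ndarray], np.ndarray]
    mean_jacobian: Optional[Callable[[np.ndarray], np.ndarray]] = None
    u_rows: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.dim_moments <= self.dim_params:
            warnings.warn(
                "m <= q: the minimized statistic is degenerate (no "
                "overidentifying restrictions)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class WeightMatrix:
    sigma: np.ndarray
    inverse: np.ndarray
    rank: int
    ridge_used: bool = False


@dataclass(frozen=True)
class TestResult:
    """Outcome of a structural test: statistic, df, p-value, nuisance fit."""

    statistic: float
    df: int
    p_value: float
    params: dict
    converged: bool
    n_used: int
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            return v

        return {
            "statistic": float(self.statistic),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "params": _clean(self.params),
            "converged": bool(self.converged),
            "n_used": int(self.n_used),
            "diagnostics": _clean(self.diagnostics),
        }


def empirical_weight(
    U_rows: np.ndarray,
    expected_rank_deficiency: int = 0,
    rtol: float = 1e-10,
) -> WeightMatrix:
    """Empirical covariance of the moment rows and its (pseudo-)inverse.

    Sigma = (1/N) sum_k (U_k - Ubar)(U_k - Ubar)'.  The inverse is formed by
    eigendecomposition, truncating eigenvalues below ``rtol`` times the
    largest.  If the rank falls short of m by more than the structurally
    expected deficiency, a small ridge is added and flagged.
    """
    U = np.asarray(U_rows, float)
    n, m = U.shape
    if n <= m:
        warnings.warn(f"N={n} <= m={m}: weight matrix may be unstable", stacklevel=2)
    if not U.any():
        raise DegenerateMomentsError("all moment vectors are zero")
    Uc = U - U.mean(axis=0)
    sigma = (Uc.T @ Uc) / n
    sigma = 0.5 * (sigma + sigma.T)

    evals, evecs = np.linalg.eigh(sigma)
    cutoff = rtol * max(evals.max(), np.finfo(float).tiny)
    keep = evals > cutoff
    rank = int(keep.sum())
    ridge_used = False
    if m - rank > expected_rank_deficiency:
        eps = 1e-8 * np.trace(sigma) / m
        sigma = sigma + eps * np.eye(m)
        ridge_used = True
        evals, evecs = np.linalg.eigh(sigma)
        keep = evals > rtol * evals.max()
        rank = int(keep.sum())
    inv = (evecs[:, keep] / evals[keep]) @ evecs[:, keep].T
    return WeightMatrix(sigma=sigma, inverse=inv, rank=rank, ridge_used=ridge_used)


def _objective(spec: MomentSpec, W: np.ndarray, n: int, free_mask: np.ndarray,
               full0: np.ndarray):
    def embed(theta_free: np.ndarray) -> np.ndarray:
        full = full0.copy()
        full[free_mask] = theta_free
        return full

    def fun(theta_free: np.ndarray) -> float:
        u = spec.mean_moment(embed(theta_free))
        return float(n * u @ W @ u)

    def grad(theta_free: np.ndarray) -> np.ndarray:
        full = embed(theta_free)
        u = spec.mean_moment(full)
        J = spec.mean_jacobian(full)
        return (2.0 * n) * (J.T @ (W @ u))[free_mask]

    return fun, (grad if spec.mean_jacobian is not None else None), embed


def minimize_distance_metric(
    spec: MomentSpec,
    weight: WeightMatrix,
    init: np.ndarray,
    n: int,
    free_mask: Optional[np.ndarray] = None,
    seed: int = 0,
    grad_tol: float = 1e-6,
    n_restarts: int = 5,
) -> tuple[np.ndarray, float, dict]:
    """Minimize N * Ubar' Sigma^{-1} Ubar over the free parameters.

    ``free_mask`` marks which coordinates of ``init`` vary (all, by
    default); frozen coordinates implement normalization conventions.
    Quasi-Newton (BFGS) with the analytic Jacobian when available; if the
    first solve ends with a large gradient, up to ``n_restarts`` perturbed
    restarts are tried and the smallest value kept.
    """
    init = np.asarray(init, float)
    if free_mask is None:
        free_mask = np.ones(init.shape, bool)
    fun, grad, embed = _objective(spec, weight.inverse, n, free_mask, init)

    def solve(x0):
        return optimize.minimize(
            fun, x0, jac=grad, method="BFGS",
            options={"gtol": 1e-8, "maxiter": 500},
        )

    x0 = init[free_mask]
    best = solve(x0)
    rng = np.random.default_rng(seed)
    tries = 0
    gnorm = float(np.linalg.norm(best.jac)) if best.jac is not None else np.inf
    while gnorm > grad_tol and tries < n_restarts:
        tries += 1
        scale = 0.1 * (1.0 + np.abs(x0))
        cand = solve(x0 + scale * rng.standard_normal(x0.shape))
        if cand.fun < best.fun:
            best = cand
        gnorm = float(np.linalg.norm(best.jac)) if best.jac is not None else np.inf

    if not np.isfinite(best.fun):
        raise GmmConvergenceError(
            "distance-metric minimization failed", best.fun, gnorm
        )
    diagnostics = {
        "iterations": int(best.nit),
        "gradient_norm": gnorm,
        "restarts": tries,
        "weight_rank": weight.rank,
        "ridge_used": weight.ridge_used,
    }
    return embed(best.x), max(float(best.fun), 0.0), diagnostics


def chi_square_pvalue(statistic: float, df: int) -> float:
    """Upper-tail chi-square probability."""
    if statistic < 0:
        raise ValueError(f"statistic must be nonnegative, got {statistic}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(stats.chi2.sf(statistic, df))
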