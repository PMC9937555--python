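"""Reliability-free structural test (T1).

The structural interpretation implies that the (p-1) x d matrix of
group-mean contrasts E(X_i|Z=z) - E(X_i|Z=1) has rank one:

    E(X_i | Z=z) = gamma_i + alpha_i * beta_z,   beta_1 = 0,

for some parameters alpha_i (proportional to the loadings) and beta_z
(proportional to the latent-scale group contrast).  No reliability
estimates are needed, but Z must have at least p=3 levels for the
restriction to bind.  The GMM distance-metric statistic T1 over the d*p
moments I(Z_k=w)(X_ik - gamma_i - alpha_i beta_w) is chi-square with
(d-1)(p-2) df under the null.

Only the products alpha_i * beta_w are identified (alpha/tau, beta*tau
describe the same model), so one alpha coordinate is frozen during
optimization; the statistic does not depend on the convention.
"""

from __future__ import annotations

import warnings

import numpy as np
from dataclasses import dataclass

from .data_model import (
    GroupingVariable,
    IndicatorMatrix,
    ValidationError,
    group_means,
)
from .gmm_engine import (
    MomentSpec,
    TestResult,
    chi_square_pvalue,
    empirical_weight,
    minimize_distance_metric,
)

__all__ = ["T1Params", "u_vector_t1", "run_test_t1", "build_composite_z"]


@dataclass(frozen=True)
class T1Params:
    """Rank-1 contrast model parameters; ``beta`` excludes the fixed beta_1=0."""

    gamma: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    normalization: str = "alpha_max"

    def __post_init__(self) -> None:
        for name in ("gamma", "alpha", "beta"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not all(
            np.isfinite(getattr(self, name)).all()
            for name in ("gamma", "alpha", "beta")
        ):
            raise ValidationError("non-finite T1 parameters")

    @property
    def beta_full(self) -> np.ndarray:
        return np.concatenate(([0.0], self.beta))


def u_vector_t1(x_row: np.ndarray, z: int, params: T1Params) -> np.ndarray:
    """Single-subject moment vector, length d*p, laid out level-major.

    Element (w, i) is I(z=w) (x_i - gamma_i - alpha_i beta_w).
    """
    d = params.gamma.shape[0]
    beta_full = params.beta_full
    p = beta_full.shape[0]
    out = np.zeros(p * d)
    resid = np.asarray(x_row, float) - params.gamma - params.alpha * beta_full[z - 1]
    out[(z - 1) * d : z * d] = resid
    return out


def _u_rows_t1(
    X: IndicatorMatrix, Z: GroupingVariable,
    gamma: np.ndarray, alpha: np.ndarray, beta_full: np.ndarray,
) -> np.ndarray:
    H = Z.indicator_columns()
    fitted = gamma[None, :] + np.outer(beta_full[Z.codes - 1], alpha)
    resid = X.values - fitted
    return (H[:, :, None] * resid[:, None, :]).reshape(X.n, Z.p * X.d)


def _initial_values(gm_means: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """gamma from the reference level; (alpha, beta) from the leading
    singular triplet of the contrast matrix."""
    gamma0 = gm_means[0].copy()
    D = gm_means[1:] - gm_means[0]  # (p-1) x d
    u_, s_, vt = np.linalg.svd(D, full_matrices=False)
    alpha0 = vt[0] * s_[0]
    beta0 = u_[:, 0]
    # sign convention: make the largest-|alpha| coordinate positive
    j = int(np.argmax(np.abs(alpha0)))
    if alpha0[j] < 0:
        alpha0, beta0 = -alpha0, -beta0
    return gamma0, alpha0, beta0


def run_test_t1(
    X: IndicatorMatrix,
    Z: GroupingVariable,
    normalization: str = "alpha_max",
    seed: int = 0,
) -> TestResult:
    """Run the reliability-free rank-1 structural test.

    ``normalization`` fixes the alpha/beta scale during optimization:
    ``"alpha_max"`` freezes the alpha coordinate of largest initial
    magnitude, ``"beta2"`` freezes beta_2.  The statistic is invariant to
    this choice.
    """
    if X.n != Z.n:
        raise ValidationError("X and Z length mismatch")
    if Z.p < 3:
        raise ValidationError(
            f"T1 requires Z with at least 3 levels (got p={Z.p}); "
            "with p=2 use the reliability-dependent test T0"
        )
    d, p, n = X.d, Z.p, X.n
    gm = group_means(X, Z)
    gamma0, alpha0, beta0 = _initial_values(gm.means)
    if np.abs(gm.contrasts()).max() < 1e-12:
        warnings.warn(
            "all group-mean contrasts are ~0; the rank-1 restriction is "
            "uninformative and the statistic will be near 0",
            stacklevel=2,
        )

    # theta = (gamma_1..d, alpha_1..d, beta_2..p); freeze one coordinate
    init = np.concatenate([gamma0, alpha0, beta0])
    free = np.ones(init.shape, bool)
    if normalization == "alpha_max":
        frozen = d + int(np.argmax(np.abs(alpha0)))
    elif normalization == "beta2":
        frozen = 2 * d
        if abs(init[frozen]) < 1e-8:
            warnings.warn("beta_2 ~ 0: freezing it is ill-conditioned; "
                          "falling back to alpha_max", stacklevel=2)
            frozen = d + int(np.argmax(np.abs(alpha0)))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    free[frozen] = False

    beta_full0 = np.concatenate(([0.0], beta0))
    U0 = _u_rows_t1(X, Z, gamma0, alpha0, beta_full0)
    weight = empirical_weight(U0, expected_rank_deficiency=1)

    w_lev = Z.counts() / n
    m1 = gm.means * w_lev[:, None]

    def unpack(theta):
        return theta[:d], theta[d : 2 * d], np.concatenate(([0.0], theta[2 * d :]))

    def mean_moment(theta: np.ndarray) -> np.ndarray:
        gamma, alpha, beta_full = unpack(theta)
        fitted = gamma[None, :] + np.outer(beta_full, alpha)
        return (m1 - w_lev[:, None] * fitted).ravel()

    def mean_jacobian(theta: np.ndarray) -> np.ndarray:
        _, alpha, beta_full = unpack(theta)
        J = np.zeros((p * d, 2 * d + p - 1))
        for z in range(p):
            blk = slice(z * d, (z + 1) * d)
            J[blk, :d][np.diag_indices(d)] = -w_lev[z]
            J[blk, d : 2 * d][np.diag_indices(d)] = -w_lev[z] * beta_full[z]
            if z >= 1:
                J[blk, 2 * d + z - 1] = -w_lev[z] * alpha
        return J

    spec = MomentSpec(
        dim_moments=p * d,
        dim_params=2 * d + p - 2,  # identified count (one coordinate frozen)
        mean_moment=mean_moment,
        mean_jacobian=mean_jacobian,
    )
    theta, statistic, diagnostics = minimize_distance_metric(
        spec, weight, init, n, free_mask=free, seed=seed
    )
    gamma_hat, alpha_hat, beta_full_hat = unpack(theta)

    df = (d - 1) * (p - 2)
    return TestResult(
        statistic=statistic,
        df=df,
        p_value=chi_square_pvalue(statistic, df),
        params={
            "gamma": gamma_hat,
            "alpha": alpha_hat,
            "beta": beta_full_hat[1:],
            "normalization": normalization,
        },
        converged=diagnostics["gradient_norm"] <= 1e-4,
        n_used=n,
        diagnostics={"test": "t1", **diagnostics},
    )


def build_composite_z(
    Z1: GroupingVariable, Z2: GroupingVariable
) -> GroupingVariable:
    """Cross-classify two grouping variables into one.

    Levels are ordered lexicographically by (Z2, Z1) — the first factor
    varies fastest — so e.g. two binary factors yield codes 1..4 as
    (Z2=1,Z1=1), (Z2=1,Z1=2), (Z2=2,Z1=1), (Z2=2,Z1=2).  Empty cross
    cells are dropped with a warning and the remaining levels recoded.
    """
    if Z1.n != Z2.n:
        raise ValidationError("grouping variables have different lengths")
    raw = (Z2.codes - 1) * Z1.p + Z1.codes  # 1..p1*p2
    present = np.unique(raw)
    if present.size < Z1.p * Z2.p:
        warnings.warn(
            f"{Z1.p * Z2.p - present.size} empty cross-cell(s) dropped",
            stacklevel=2,
        )
    recode = {int(v): i + 1 for i, v in enumerate(present)}
    codes = np.array([recode[int(v)] for v in raw])
    level_map = {}
    for (orig1, c1) in Z1.level_map.items():
        for (orig2, c2) in Z2.level_map.items():
            v = (c2 - 1) * Z1.p + c1
            if v in recode:
                level_map[(orig2, orig1)] = recode[v]
    return GroupingVariable(codes, p=present.size, level_map=level_map)
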