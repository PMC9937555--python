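"""Reliability-dependent structural test (T0).

Under the structural interpretation of the factor model, for any discrete
Z the group-mean contrast of each indicator scaled by its reliability is
the same across indicators.  With reliabilities lambda this is the mean
restriction

    E(X_i | Z=z) = gamma_i + (lambda_i / lambda_1) * beta_z,   beta_1 = 0,

where indicator 1 is a reference with nonzero loading, gamma_i is the
reference-level mean and beta_z the reference indicator's contrast.  The
restriction is tested by the GMM distance-metric statistic T0 built from
the p*d per-subject moments

    U_k[(z,i)] = I(Z_k=z) (X_ik - gamma_i - (lambda_i/lambda_1) beta_z),

chi-square with (d-1)(p-1) df under the null.  When lambda is estimated
from the pairwise covariances, the weight matrix is the empirical
covariance of U_k minus its first-stage projection onto the reliability
moments V_k, which accounts for the plug-in uncertainty.

Internally the fit is parameterized by nu_z = beta_z / lambda_ref (the
contrast on the latent scale), so that E(X_i|Z=z) = gamma_i + lambda_i
nu_z.  The fitted family, the statistic and the variance correction are
then exactly invariant to which indicator plays the reference role; the
reference only enters when reporting beta = lambda_ref * nu.
"""

from __future__ import annotations

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
    WeightMatrix,
    chi_square_pvalue,
    empirical_weight,
    minimize_distance_metric,
)
from .reliability import (
    ReliabilityEstimate,
    estimate_reliabilities,
    reliability_jacobian,
    reliability_moment_rows,
)

__all__ = [
    "T0Params",
    "CorrectionError",
    "u_vector_t0",
    "du_dlambda",
    "corrected_weight_t0",
    "run_test_t0",
]


class CorrectionError(RuntimeError):
    """The first-stage Jacobian is singular; plug-in correction unavailable."""


@dataclass(frozen=True)
class T0Params:
    """Nuisance parameters of the restricted mean model.

    ``gamma[i] = E(X_i | Z=1)``; ``beta[w-2] = E(X_ref | Z=w) - E(X_ref | Z=1)``
    for w = 2..p; ``ref`` is the (0-based) reference indicator.
    """

    gamma: np.ndarray
    beta: np.ndarray
    ref: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma", np.asarray(self.gamma, float))
        object.__setattr__(self, "beta", np.asarray(self.beta, float))
        if not (np.isfinite(self.gamma).all() and np.isfinite(self.beta).all()):
            raise ValidationError("non-finite T0 parameters")

    @property
    def beta_full(self) -> np.ndarray:
        """Length-p contrast vector with the reference level's 0 prepended."""
        return np.concatenate(([0.0], self.beta))


def u_vector_t0(
    x_row: np.ndarray, z: int, params: T0Params, lam: np.ndarray
) -> np.ndarray:
    """Single-subject moment vector, length p*d, laid out z-major.

    Element (z', i) is I(z=z') (x_i - gamma_i - (lambda_i/lambda_ref) beta_z').
    """
    lam = np.asarray(lam, float)
    if lam[params.ref] == 0:
        raise ValidationError("reference reliability must be nonzero")
    d = lam.shape[0]
    beta_full = params.beta_full
    p = beta_full.shape[0]
    ratio = lam / lam[params.ref]
    out = np.zeros(p * d)
    resid = np.asarray(x_row, float) - params.gamma - ratio * beta_full[z - 1]
    out[(z - 1) * d : z * d] = resid
    return out


def du_dlambda(
    x_row: np.ndarray, z: int, params: T0Params, lam: np.ndarray
) -> np.ndarray:
    """Analytic (p*d) x d derivative of the subject moment vector in lambda.

    With (gamma, beta) held fixed, lambda enters only through the ratio
    lambda_i/lambda_ref: rows for the reference indicator are identically
    zero, and for i != ref only the columns i and ref are nonzero.
    """
    lam = np.asarray(lam, float)
    d = lam.shape[0]
    beta_full = params.beta_full
    p = beta_full.shape[0]
    r = params.ref
    out = np.zeros((p * d, d))
    bz = beta_full[z - 1]
    for i in range(d):
        if i == r:
            continue
        row = (z - 1) * d + i
        out[row, i] = -bz / lam[r]
        out[row, r] = bz * lam[i] / lam[r] ** 2
    return out


def _u_rows_t0(
    X: IndicatorMatrix, Z: GroupingVariable, gamma: np.ndarray, nu_full: np.ndarray,
    lam: np.ndarray,
) -> np.ndarray:
    """N x (p*d) moment rows in the (gamma, nu) parameterization."""
    H = Z.indicator_columns()  # N x p
    fitted = gamma[None, :] + np.outer(nu_full[Z.codes - 1], lam)
    resid = X.values - fitted  # N x d
    return (H[:, :, None] * resid[:, None, :]).reshape(X.n, Z.p * X.d)


def corrected_weight_t0(
    U_rows: np.ndarray,
    V_rows: np.ndarray,
    mean_dU_dlambda: np.ndarray,
    mean_dV_dlambda: np.ndarray,
) -> WeightMatrix:
    """Weight matrix accounting for first-stage reliability estimation.

    Sigma is the empirical covariance of the adjusted rows
    ``U_k - A B^{-1} V_k`` with A the mean moment derivative in lambda and
    B the mean reliability-moment Jacobian.
    """
    A = np.asarray(mean_dU_dlambda, float)
    B = np.asarray(mean_dV_dlambda, float)
    cond = np.linalg.cond(B)
    if not np.isfinite(cond) or cond > 1e10:
        raise CorrectionError(
            f"first-stage Jacobian is near-singular (cond={cond:.3g}); "
            "supply lambda as known to use the uncorrected weight"
        )
    adjusted = U_rows - V_rows @ np.linalg.solve(B, A.T)
    return empirical_weight(adjusted)


def _mean_du_dlambda_scale_fixed(
    Z: GroupingVariable, nu_full: np.ndarray, d: int
) -> np.ndarray:
    """Mean dU/dlambda holding (gamma, nu) fixed: -w_z nu_z on the (z,i,i) slots."""
    w = Z.counts() / Z.n
    A = np.zeros((Z.p * d, d))
    for z in range(Z.p):
        A[z * d : (z + 1) * d, :][np.diag_indices(d)] = -w[z] * nu_full[z]
    return A


def run_test_t0(
    X: IndicatorMatrix,
    Z: GroupingVariable,
    lam: ReliabilityEstimate | np.ndarray | None = None,
    solver: str = "root",
    seed: int = 0,
) -> TestResult:
    """Run the reliability-dependent structural test.

    If ``lam`` is omitted, reliabilities are estimated from the pairwise
    covariances (requires d >= 3) and the weight matrix is corrected for
    that first-stage uncertainty; a supplied ``lam`` is treated as known
    and the uncorrected weight is used.
    """
    if X.n != Z.n:
        raise ValidationError("X and Z length mismatch")
    if Z.p < 2:
        raise ValidationError("T0 requires Z with at least 2 levels")

    corrected = lam is None
    if corrected:
        est = estimate_reliabilities(X, solver=solver)
        lam_vec = est.lambda_
    else:
        lam_vec = lam.lambda_ if isinstance(lam, ReliabilityEstimate) else np.asarray(lam, float)
        if lam_vec.shape != (X.d,):
            raise ValidationError("lambda length must equal d")
    ref = int(np.argmax(np.abs(lam_vec)))
    if lam_vec[ref] == 0:
        raise ValidationError("all reliabilities are zero; test undefined")

    d, p, n = X.d, Z.p, X.n
    gm = group_means(X, Z)
    gamma0 = gm.means[0].copy()
    # latent-scale contrasts: least-squares projection of the mean contrasts
    # onto lambda (invariant to the reference-indicator choice)
    contrasts = gm.contrasts()  # (p-1) x d
    nu0 = contrasts @ lam_vec / float(lam_vec @ lam_vec)
    nu_full0 = np.concatenate(([0.0], nu0))

    U0 = _u_rows_t0(X, Z, gamma0, nu_full0, lam_vec)
    if corrected:
        V = reliability_moment_rows(X.values, X.values.mean(axis=0), lam_vec)
        A = _mean_du_dlambda_scale_fixed(Z, nu_full0, d)
        B = reliability_jacobian(X, lam_vec)
        weight = corrected_weight_t0(U0, V, A, B)
    else:
        weight = empirical_weight(U0)

    w_lev = Z.counts() / n
    m1 = gm.means * w_lev[:, None]  # p x d, (1/N) sum_k I(Z=z) X_i

    def mean_moment(theta: np.ndarray) -> np.ndarray:
        gamma = theta[:d]
        nu_full = np.concatenate(([0.0], theta[d:]))
        fitted = gamma[None, :] + np.outer(nu_full, lam_vec)
        return (m1 - w_lev[:, None] * fitted).ravel()

    def mean_jacobian(theta: np.ndarray) -> np.ndarray:
        J = np.zeros((p * d, d + p - 1))
        for z in range(p):
            blk = slice(z * d, (z + 1) * d)
            J[blk, :d][np.diag_indices(d)] = -w_lev[z]
            if z >= 1:
                J[blk, d + z - 1] = -w_lev[z] * lam_vec
        return J

    spec = MomentSpec(
        dim_moments=p * d,
        dim_params=d + p - 1,
        mean_moment=mean_moment,
        mean_jacobian=mean_jacobian,
    )
    init = np.concatenate([gamma0, nu0])
    theta, statistic, diagnostics = minimize_distance_metric(
        spec, weight, init, n, seed=seed
    )
    gamma_hat = theta[:d]
    nu_hat = theta[d:]
    beta_hat = lam_vec[ref] * nu_hat

    df = (d - 1) * (p - 1)
    return TestResult(
        statistic=statistic,
        df=df,
        p_value=chi_square_pvalue(statistic, df),
        params={
            "gamma": gamma_hat,
            "beta": beta_hat,
            "nu": nu_hat,
            "lambda": lam_vec,
            "reference_indicator": ref + 1,
        },
        converged=diagnostics["gradient_norm"] <= 1e-4,
        n_used=n,
        diagnostics={"test": "t0", "corrected": corrected, **diagnostics},
    )
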