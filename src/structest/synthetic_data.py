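"""Synthetic data with the exact structure the structural tests assume.

The generator draws a standard-normal latent eta, mean-zero errors eps_i
with variance 1 - lambda_i^2 (so each indicator X_i = lambda_i eta + eps_i
has population variance 1), and a discrete Z produced from eta alone under
the null — either by thresholding eta at fixed cutpoints or through a
multinomial-logistic mechanism.  Under the alternative, subjects in level
w additionally have indicator i shifted by delta[i, w-1]: Z then carries
direct dependence on the indicators beyond eta, which breaks the
proportionality of group-mean contrasts unless delta happens to be
proportional to lambda.

Errors are normal by default; a scaled-t option (5 df, rescaled to the
target variance) probes robustness to heavy tails.  An exchangeable
error correlation can be switched on to violate the independent-errors
assumption behind the reliability model while keeping the null structure
of Z intact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .data_model import GroupingVariable, IndicatorMatrix, ValidationError

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "default_lambda",
    "generate_null_dataset",
    "generate_alternative_dataset",
]

#: loadings used throughout the simulation studies for d=5
DEFAULT_LAMBDA_5 = (0.8, 0.7, 0.75, 0.65, 0.6)


def default_lambda(d: int) -> np.ndarray:
    """Moderate, unequal loadings: the d=5 defaults, cycled/trimmed for other d."""
    base = np.asarray(DEFAULT_LAMBDA_5)
    return np.resize(base, d)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic data-generating process.

    ``z_cutpoints_or_coefs``: for the ``eta_threshold`` mechanism, the p-1
    strictly increasing cutpoints on the eta scale (default: standard
    normal quantiles giving equal level probabilities); for
    ``eta_logistic``, the p-1 slopes b_w of log odds vs level 1 (linear
    predictor b_w * eta, zero intercepts).
    ``direct_effects``: d x (p-1) matrix of mean shifts applied to
    subjects in levels 2..p — all zero under the null.
    """

    d: int = 5
    N: int = 2000
    lambda_: tuple = DEFAULT_LAMBDA_5
    p: int = 2
    z_mechanism: str = "eta_threshold"
    z_cutpoints_or_coefs: tuple | None = None
    direct_effects: tuple = ()
    error_correlation: float = 0.0
    error_dist: str = "normal"
    seed: int = 0

    def lambda_array(self) -> np.ndarray:
        lam = np.asarray(self.lambda_, float)
        if lam.shape != (self.d,):
            raise ValidationError(f"lambda must have length d={self.d}")
        if np.any(lam**2 >= 1):
            raise ValidationError("need lambda_i^2 < 1 (nonnegative error variance)")
        return lam

    def delta_matrix(self) -> np.ndarray:
        if not len(self.direct_effects):
            return np.zeros((self.d, self.p - 1))
        delta = np.asarray(self.direct_effects, float)
        if delta.shape != (self.d, self.p - 1):
            raise ValidationError(
                f"direct_effects must be d x (p-1) = {self.d} x {self.p - 1}"
            )
        return delta

    def cutpoints(self) -> np.ndarray:
        if self.z_mechanism != "eta_threshold":
            raise ValueError("cutpoints only defined for eta_threshold")
        if self.z_cutpoints_or_coefs is None:
            qs = np.arange(1, self.p) / self.p
            return stats.norm.ppf(qs)
        cp = np.asarray(self.z_cutpoints_or_coefs, float)
        if cp.shape != (self.p - 1,) or np.any(np.diff(cp) <= 0):
            raise ValidationError("cutpoints must be p-1 strictly increasing values")
        return cp

    def logistic_slopes(self) -> np.ndarray:
        if self.z_cutpoints_or_coefs is None:
            return 0.5 * np.arange(1, self.p)
        b = np.asarray(self.z_cutpoints_or_coefs, float)
        if b.shape != (self.p - 1,):
            raise ValidationError("need p-1 logistic slopes")
        return b


@dataclass(frozen=True)
class SyntheticDataset:
    X: IndicatorMatrix
    Z: GroupingVariable
    eta: np.ndarray = field(repr=False)
    truth: GeneratorConfig = None


def _draw_errors(rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    """N x d errors with Var(eps_i) = 1 - lambda_i^2 and exchangeable
    cross-correlation cfg.error_correlation."""
    lam = cfg.lambda_array()
    sd = np.sqrt(1.0 - lam**2)
    rho = cfg.error_correlation
    if not 0.0 <= rho < 1.0:
        raise ValidationError("error_correlation must be in [0, 1)")
    if cfg.error_dist == "normal":
        raw = rng.standard_normal((cfg.N, cfg.d))
    elif cfg.error_dist == "t5":
        raw = rng.standard_t(5, size=(cfg.N, cfg.d)) / np.sqrt(5.0 / 3.0)
    else:
        raise ValidationError(f"unknown error_dist {cfg.error_dist!r}")
    if rho > 0:
        R = np.full((cfg.d, cfg.d), rho)
        np.fill_diagonal(R, 1.0)
        raw = raw @ np.linalg.cholesky(R).T
    return raw * sd[None, :]


def _draw_z(rng: np.random.Generator, eta: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    if cfg.z_mechanism == "eta_threshold":
        return np.digitize(eta, cfg.cutpoints()) + 1
    if cfg.z_mechanism == "eta_logistic":
        b = cfg.logistic_slopes()
        logits = np.concatenate(
            [np.zeros((eta.shape[0], 1)), eta[:, None] * b[None, :]], axis=1
        )
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(eta.shape[0])
        return 1 + (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    raise ValidationError(f"unknown z_mechanism {cfg.z_mechanism!r}")


def _generate(cfg: GeneratorConfig) -> SyntheticDataset:
    lam = cfg.lambda_array()
    delta = cfg.delta_matrix()
    rng = np.random.default_rng(cfg.seed)
    for attempt in range(10):
        eta = rng.standard_normal(cfg.N)
        eps = _draw_errors(rng, cfg)
        X = eta[:, None] * lam[None, :] + eps
        z = _draw_z(rng, eta, cfg)
        counts = np.bincount(z, minlength=cfg.p + 1)[1:]
        if np.all(counts > 0):
            break
        warnings.warn(
            f"empty Z level on attempt {attempt + 1}; regenerating", stacklevel=3
        )
    else:
        raise ValidationError("could not produce all Z levels in 10 attempts")
    # direct dependence of Z on the indicators, as within-level mean shifts
    for w in range(2, cfg.p + 1):
        mask = z == w
        X[mask] += delta[:, w - 2][None, :]
    return SyntheticDataset(
        X=IndicatorMatrix(X),
        Z=GroupingVariable(z, p=cfg.p),
        eta=eta,
        truth=cfg,
    )


def generate_null_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Structural null: Z depends on the indicators only through eta."""
    if np.any(config.delta_matrix() != 0):
        raise ValidationError("null generator requires all direct effects zero")
    return _generate(config)


def generate_alternative_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Direct-dependence alternative: per-level mean shifts on chosen indicators.

    Warns when delta is (column-wise) proportional to lambda, in which
    case the shift mimics a latent-mean difference and the alternative is
    indistinguishable from a null in the group means.
    """
    delta = config.delta_matrix()
    lam = config.lambda_array()
    with np.errstate(invalid="ignore"):
        proj = np.outer(lam, lam @ delta) / float(lam @ lam)
    if np.allclose(delta, proj, atol=1e-12):
        warnings.warn(
            "direct effects proportional to lambda: indistinguishable from "
            "the null in group means",
            stacklevel=2,
        )
    return _generate(config)
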