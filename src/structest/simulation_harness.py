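"""Monte-Carlo calibration and power evaluation for the structural tests.

Each replicate generates a synthetic dataset, runs the standard pipeline
(finite-sample standardization, reverse-coding, reliability estimation
when T0 needs it, test), and records the statistic and p-value.
Per-replicate seeds are derived from the base seed and the replicate
index through a counter-based stream, so results do not depend on
execution order and replicates can be distributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .data_model import auto_reverse_code, standardize
from .gmm_engine import TestResult
from .synthetic_data import GeneratorConfig, generate_alternative_dataset, generate_null_dataset
from .test_t0 import run_test_t0
from .test_t1 import run_test_t1

__all__ = [
    "ScenarioResult",
    "replicate_seed",
    "run_single",
    "collect_statistics",
    "estimate_rejection_rate",
    "ks_calibration",
]


@dataclass(frozen=True)
class ScenarioResult:
    """Rejection-rate estimate for one (config, test, alpha) scenario."""

    test: str
    alpha: float
    reps: int
    n_failed: int
    rejection_rate: float
    ci_low: float
    ci_high: float
    statistics: np.ndarray = field(repr=False)
    p_values: np.ndarray = field(repr=False)
    df: int = 0
    unreliable: bool = False

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "alpha": self.alpha,
            "reps": self.reps,
            "n_failed": self.n_failed,
            "rejection_rate": self.rejection_rate,
            "ci_95": [self.ci_low, self.ci_high],
            "df": self.df,
            "unreliable": self.unreliable,
        }


def replicate_seed(base_seed: int, rep: int) -> int:
    """Deterministic, order-independent per-replicate seed below 2^31."""
    return int(np.random.SeedSequence([base_seed, rep]).generate_state(1)[0] % 2**31)


def run_single(config: GeneratorConfig, test: str, seed: int) -> TestResult:
    """Generate one dataset under ``config`` and run one test on it."""
    cfg = replace(config, seed=seed)
    delta = cfg.delta_matrix()
    data = (
        generate_null_dataset(cfg)
        if not delta.any()
        else generate_alternative_dataset(cfg)
    )
    X = auto_reverse_code(standardize(data.X))
    if test == "t0":
        return run_test_t0(X, data.Z, seed=seed)
    if test == "t1":
        return run_test_t1(X, data.Z, seed=seed)
    raise ValueError(f"unknown test {test!r}")


def collect_statistics(
    config: GeneratorConfig, test: str, reps: int, seed: int
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """(statistics, p_values, df, n_failed) over ``reps`` replicates."""
    stats_, pvals = [], []
    df = 0
    n_failed = 0
    for rep in range(reps):
        try:
            res = run_single(config, test, replicate_seed(seed, rep))
        except Exception:
            n_failed += 1
            continue
        stats_.append(res.statistic)
        pvals.append(res.p_value)
        df = res.df
    return np.asarray(stats_), np.asarray(pvals), df, n_failed


def estimate_rejection_rate(
    config: GeneratorConfig,
    test: str,
    alpha: float = 0.05,
    reps: int = 500,
    seed: int = 0,
) -> ScenarioResult:
    """Monte-Carlo rejection rate with an exact binomial 95% CI.

    Replicates whose fit fails are excluded from the denominator and
    counted; the result is flagged unreliable if more than 5% fail.
    """
    if reps < 100:
        raise ValueError("need at least 100 replicates for a rate estimate")
    statistics, pvals, df, n_failed = collect_statistics(config, test, reps, seed)
    n_ok = pvals.size
    k = int((pvals < alpha).sum())
    ci = stats.binomtest(k, n_ok).proportion_ci(0.95) if n_ok else (np.nan, np.nan)
    return ScenarioResult(
        test=test,
        alpha=alpha,
        reps=n_ok,
        n_failed=n_failed,
        rejection_rate=k / n_ok if n_ok else np.nan,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        statistics=statistics,
        p_values=pvals,
        df=df,
        unreliable=n_failed > 0.05 * reps,
    )


def ks_calibration(
    config: GeneratorConfig, test: str, reps: int = 500, seed: int = 0
) -> float:
    """KS distance between null statistics and the reference chi-square.

    Only meaningful under a null configuration; supplying direct effects
    is a usage error.
    """
    if config.delta_matrix().any():
        raise ValueError("ks_calibration requires a null configuration")
    statistics, _, df, _ = collect_statistics(config, test, reps, seed)
    return float(stats.kstest(statistics, stats.chi2(df).cdf).statistic)
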