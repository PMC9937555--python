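"""Core data containers and preprocessing.

Indicators live in an :class:`IndicatorMatrix` (subjects x items), the
discrete grouping variable in a :class:`GroupingVariable` with levels coded
``1..p`` (reference level 1).  All covariance-type quantities in this
package use the divisor ``N`` (not ``N-1``), matching the ``1/N`` factor in
the reliability estimating equations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("structest")

__all__ = [
    "IndicatorMatrix",
    "GroupingVariable",
    "GroupMeans",
    "DegenerateIndicatorError",
    "ValidationError",
    "load_dataset",
    "standardize",
    "auto_reverse_code",
    "group_means",
]


class ValidationError(ValueError):
    """Input fails a structural requirement (empty level, too few items...)."""


class DegenerateIndicatorError(ValidationError):
    """An indicator column is constant and cannot be standardized."""


@dataclass(frozen=True)
class IndicatorMatrix:
    """N x d matrix of item responses.

    Parameters
    ----------
    values
        Real matrix, one row per subject, one column per indicator.
    indicator_names
        Column labels; defaults to ``x1..xd``.
    standardized
        Whether each column has (divisor-N) sample mean 0 and variance 1.
    flipped
        Indices (0-based) of indicators whose sign was reversed by
        :func:`auto_reverse_code`.
    """

    values: np.ndarray
    indicator_names: tuple[str, ...] = ()
    standardized: bool = False
    flipped: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValidationError("indicator matrix must be 2-dimensional")
        n, d = v.shape
        if d < 2:
            raise ValidationError(f"need at least 2 indicators, got {d}")
        if n <= d:
            raise ValidationError(f"need N > d subjects, got N={n}, d={d}")
        if not np.isfinite(v).all():
            raise ValidationError("indicator matrix contains non-finite entries")
        object.__setattr__(self, "values", v)
        if not self.indicator_names:
            object.__setattr__(
                self, "indicator_names", tuple(f"x{i + 1}" for i in range(d))
            )
        elif len(self.indicator_names) != d:
            raise ValidationError("indicator_names length mismatch")
        if self.standardized:
            mu = v.mean(axis=0)
            var = v.var(axis=0)  # divisor N
            if np.abs(mu).max() >= 1e-10 or np.abs(var - 1).max() >= 1e-8:
                raise ValidationError("standardized flag set but columns are not")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def centered(self) -> np.ndarray:
        """Column-centered values (sample means removed)."""
        return self.values - self.values.mean(axis=0)


@dataclass(frozen=True)
class GroupingVariable:
    """Per-subject discrete Z with ordered levels 1..p; reference level is 1."""

    codes: np.ndarray
    p: int
    level_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.codes, dtype=int)
        if self.p < 2:
            raise ValidationError(f"Z needs at least 2 levels, got p={self.p}")
        present = np.unique(c)
        expected = np.arange(1, self.p + 1)
        if not np.array_equal(present, expected):
            missing = sorted(set(expected) - set(present))
            raise ValidationError(
                f"every level 1..{self.p} must occur; missing codes {missing}"
            )
        object.__setattr__(self, "codes", c)
        if not self.level_map:
            object.__setattr__(self, "level_map", {z: z for z in expected})

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def reference_level(self) -> int:
        return 1

    def counts(self) -> np.ndarray:
        return np.bincount(self.codes, minlength=self.p + 1)[1:]

    def indicator_columns(self) -> np.ndarray:
        """N x p one-hot matrix I(Z_k = z)."""
        return (self.codes[:, None] == np.arange(1, self.p + 1)[None, :]).astype(float)


@dataclass(frozen=True)
class GroupMeans:
    """Within-level indicator means E(X_i | Z=z) and level sizes."""

    means: np.ndarray  # p x d
    counts: np.ndarray  # p

    def __post_init__(self) -> None:
        m = np.asarray(self.means, dtype=float)
        c = np.asarray(self.counts, dtype=int)
        if m.shape[0] != c.shape[0]:
            raise ValidationError("means/counts level mismatch")
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def contrasts(self) -> np.ndarray:
        """(p-1) x d matrix of mean differences vs the reference level 1."""
        return self.means[1:] - self.means[0]


def load_dataset(
    table, indicator_cols, z_col: str
) -> tuple[IndicatorMatrix, GroupingVariable]:
    """Read a subjects-by-items table plus a grouping column.

    ``table`` may be a path to a CSV/TSV file (delimiter sniffed from the
    extension) or a :class:`pandas.DataFrame`.  Rows with any missing
    indicator or missing Z are dropped (complete-case); Z levels are coded
    ``1..p`` in sorted order of their original values.
    """
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        sep = "\t" if str(table).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(table, sep=sep)
    indicator_cols = list(indicator_cols)
    if len(indicator_cols) < 2:
        raise ValidationError("need at least 2 indicator columns")
    missing_cols = [c for c in indicator_cols + [z_col] if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"columns not found: {missing_cols}")

    n_read = len(df)
    sub = df[indicator_cols + [z_col]].dropna()
    n_removed = n_read - len(sub)
    logger.info("read %d rows, retained %d (%d incomplete removed)",
                n_read, len(sub), n_removed)

    levels = sorted(pd.unique(sub[z_col]))
    raw_levels = sorted(pd.unique(df[z_col].dropna()))
    lost = [lv for lv in raw_levels if lv not in levels]
    if lost:
        raise ValidationError(
            f"Z level(s) {lost} have no subjects after complete-case filtering"
        )
    if len(levels) < 2:
        raise ValidationError(
            f"Z column {z_col!r} has {len(levels)} level(s) after filtering; need >= 2"
        )
    level_map = {orig: i + 1 for i, orig in enumerate(levels)}
    codes = sub[z_col].map(level_map).to_numpy(dtype=int)

    X = IndicatorMatrix(
        sub[indicator_cols].to_numpy(dtype=float),
        indicator_names=tuple(indicator_cols),
    )
    Z = GroupingVariable(codes, p=len(levels), level_map=level_map)
    return X, Z


def standardize(X: IndicatorMatrix) -> IndicatorMatrix:
    """Center each indicator and scale to unit divisor-N sample variance."""
    v = X.values
    sd = v.std(axis=0)  # divisor N
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [X.indicator_names[i] for i in bad]
        raise DegenerateIndicatorError(f"constant indicator column(s): {names}")
    out = (v - v.mean(axis=0)) / sd
    return replace(X, values=out, standardized=True)


def auto_reverse_code(X: IndicatorMatrix, max_passes: int = 100) -> IndicatorMatrix:
    """Flip indicator signs until all pairwise covariances are positive.

    A reflective factor model with positive loadings implies a positive
    pairwise covariance matrix; items worded in the opposite direction show
    up as negative covariances and are reverse-coded.  Greedy: repeatedly
    flip the indicator whose mean covariance with the others is most
    negative.  Warns if positivity is unattainable (e.g. pure noise items).
    """
    v = X.values.copy()
    d = X.d
    C = np.cov(v, rowvar=False, bias=True)
    off = ~np.eye(d, dtype=bool)
    signs = np.ones(d)
    for _ in range(max_passes):
        row_mean = np.where(off, C, 0.0).sum(axis=1) / (d - 1)
        worst = int(np.argmin(row_mean))
        if row_mean[worst] >= 0:
            break
        signs[worst] *= -1
        C[worst, :] *= -1
        C[:, worst] *= -1
    if np.any(np.where(off, C, 1.0) <= 0):
        warnings.warn(
            "could not make all pairwise covariances positive by sign flips",
            stacklevel=2,
        )
    flips = frozenset(int(i) for i in np.flatnonzero(signs < 0))
    if not flips:
        return X
    logger.info("reverse-coded indicators: %s",
                [X.indicator_names[i] for i in sorted(flips)])
    return replace(X, values=v * signs, flipped=X.flipped ^ flips)


def group_means(X: IndicatorMatrix, Z: GroupingVariable) -> GroupMeans:
    """Within-level sample means of each indicator."""
    if X.n != Z.n:
        raise ValidationError(f"length mismatch: X has {X.n} rows, Z has {Z.n}")
    H = Z.indicator_columns()  # N x p
    counts = H.sum(axis=0)
    means = (H.T @ X.values) / counts[:, None]
    return GroupMeans(means=means, counts=counts.astype(int))
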