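"""Two-group tests for differences in mean and in dispersion.

The dispersion permutation tests compare a robust or classical spread metric
(SD, MAD, or Gini mean difference) between two groups via the scale-free
two-sided statistic ``T = |log(D1 / D2)|`` under random relabelling, with the
add-one permutation p-value ``p = (1 + #{T* >= T}) / (B + 1)``.  Classical
wrappers (Levene/Brown-Forsythe, ANOVA, Welch t, two-sample KS) share the same
:class:`SampleSet` / :class:`TestResult` surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .exceptions import (
    DataSchemaError,
    DegenerateDataError,
    DesignError,
    ParameterError,
)

__all__ = [
    "SampleSet",
    "TestResult",
    "gini_mean_difference",
    "median_absolute_deviation",
    "permutation_dispersion_test",
    "levene_test",
    "mean_test",
    "ks_two_sample",
    "MAD_NORMAL_CONSISTENCY",
]

# conventional constant making the MAD consistent for the normal SD
MAD_NORMAL_CONSISTENCY = 1.4826


@dataclass
class SampleSet:
    """Numeric values with aligned categorical group labels."""

    values: np.ndarray
    groups: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.values.ndim != 1 or self.values.shape != self.groups.shape:
            raise DataSchemaError("values and groups must be aligned 1-d arrays")
        if not np.all(np.isfinite(self.values)):
            raise DataSchemaError("values must be finite (drop missing on ingest)")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SampleSet":
        for col in ("group", "value"):
            if col not in df.columns:
                raise DataSchemaError(
                    "input table must have columns 'group' and 'value'; "
                    f"got {list(df.columns)}"
                )
        sub = df[["group", "value"]].copy()
        sub["value"] = pd.to_numeric(sub["value"], errors="coerce")
        n_bad = int(sub["value"].isna().sum() + sub["group"].isna().sum())
        if n_bad:
            warnings.warn(f"dropping {n_bad} rows with missing group/value")
            sub = sub.dropna()
        return cls(sub["value"].to_numpy(), sub["group"].to_numpy())

    @classmethod
    def from_csv(cls, path, sep=None) -> "SampleSet":
        if sep is None:  # sniffing trips on single-column files
            with open(path) as fh:
                sep = "\t" if "\t" in fh.readline() else ","
        df = pd.read_csv(path, sep=sep)
        return cls.from_dataframe(df)

    def group_levels(self) -> list:
        return list(pd.unique(self.groups))

    def split(self) -> list[np.ndarray]:
        return [self.values[self.groups == g] for g in self.group_levels()]

    def require_two_groups(self, min_per_group: int = 2) -> tuple[np.ndarray, np.ndarray]:
        parts = self.split()
        if len(parts) != 2:
            raise DesignError(
                f"exactly 2 groups required, found {len(parts)}: {self.group_levels()}"
            )
        for g, part in zip(self.group_levels(), parts):
            if part.size < min_per_group:
                raise DesignError(
                    f"group {g!r} has {part.size} observations (< {min_per_group})"
                )
        return parts[0], parts[1]


@dataclass
class TestResult:
    """Uniform result record for every test in the package."""

    method: str
    statistic: float
    p_value: float
    n_resamples: int | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_record()])


# ---------------------------------------------------------------------------
# dispersion metrics
# ---------------------------------------------------------------------------

def gini_mean_difference(values) -> float:
    """Gini's mean difference: mean |x_i - x_j| over all unordered pairs.

    Computed in O(n log n) via the sorted-order identity
    ``GMD = 2 / (n (n-1)) * sum_i (2 i - n - 1) x_(i)`` (i = 1..n).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ParameterError("gini_mean_difference needs n >= 2")
    n = x.size
    xs = np.sort(x)
    i = np.arange(1, n + 1, dtype=float)
    return float(2.0 * np.sum((2.0 * i - n - 1.0) * xs) / (n * (n - 1.0)))


def median_absolute_deviation(values, scaled: bool = False) -> float:
    """Median absolute deviation from the median (x 1.4826 when ``scaled``)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ParameterError("median_absolute_deviation needs n >= 2")
    mad = float(np.median(np.abs(x - np.median(x))))
    return MAD_NORMAL_CONSISTENCY * mad if scaled else mad


def _metric_rows(x2d: np.ndarray, metric: str) -> np.ndarray:
    """Dispersion metric applied to each row of a 2-d array."""
    if metric == "sd":
        return x2d.std(axis=1, ddof=1)
    if metric == "mad":
        med = np.median(x2d, axis=1, keepdims=True)
        return np.median(np.abs(x2d - med), axis=1)
    if metric == "gini":
        n = x2d.shape[1]
        xs = np.sort(x2d, axis=1)
        w = 2.0 * np.arange(1, n + 1, dtype=float) - n - 1.0
        return 2.0 * (xs @ w) / (n * (n - 1.0))
    raise ParameterError(f"unknown dispersion metric {metric!r}")


def _metric_1d(x: np.ndarray, metric: str) -> float:
    return float(_metric_rows(x[None, :], metric)[0])


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _log_ratio_stat(d1: np.ndarray, d2: np.ndarray, floor: float) -> np.ndarray:
    d1 = np.maximum(d1, floor)
    d2 = np.maximum(d2, floor)
    return np.abs(np.log(d1) - np.log(d2))


def permutation_dispersion_test(
    data: SampleSet,
    metric: str = "sd",
    n_perm: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Two-group permutation test on a dispersion metric.

    Observed statistic ``T = |log(D1/D2)|`` where ``D_g`` is the metric in
    group g; labels are permuted ``n_perm`` times and
    ``p = (1 + #{T* >= T}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    g1, g2 = data.require_two_groups()
    d1, d2 = _metric_1d(g1, metric), _metric_1d(g2, metric)
    if not (np.isfinite(d1) and np.isfinite(d2)):
        raise DegenerateDataError("non-finite dispersion in a group")
    if d1 == 0.0 and d2 == 0.0:
        raise DegenerateDataError("both groups have zero dispersion")
    pooled = np.concatenate([g1, g2])
    # map a zero dispersion to a tiny positive floor so the log stays finite
    floor = 1e-12 * max(pooled.std(ddof=0), np.finfo(float).tiny)
    if d1 == 0.0 or d2 == 0.0:
        warnings.warn(
            "one group has zero dispersion; mapped to a tiny positive value "
            "so the log-ratio statistic stays finite"
        )
    t_obs = float(_log_ratio_stat(np.array([d1]), np.array([d2]), floor)[0])

    n1, n = g1.size, pooled.size
    rng = substream(seed, "perm_dispersion", metric)
    # vectorized label permutations: argsort of uniforms gives random orders
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_vals = pooled[order]
    t_star = _log_ratio_stat(
        _metric_rows(perm_vals[:, :n1], metric),
        _metric_rows(perm_vals[:, n1:], metric),
        floor,
    )
    p = (1.0 + np.count_nonzero(t_star >= t_obs)) / (n_perm + 1.0)
    return TestResult(
        method=f"perm_{metric}",
        statistic=t_obs,
        p_value=float(p),
        n_resamples=n_perm,
        seed=seed,
        extras={"dispersion_1": d1, "dispersion_2": d2},
    )


def levene_test(data: SampleSet, center: str = "median") -> TestResult:
    """Levene (center='mean') / Brown-Forsythe (center='median') test.

    One-way ANOVA F on the absolute deviations from each group's center,
    with (k-1, N-k) degrees of freedom.
    """
    if center not in ("mean", "median"):
        raise ParameterError("center must be 'mean' or 'median'")
    parts = data.split()
    if len(parts) < 2 or any(p.size < 2 for p in parts):
        raise DesignError("levene_test needs >= 2 groups with >= 2 obs each")
    z = [np.abs(p - (p.mean() if center == "mean" else np.median(p))) for p in parts]
    if np.ptp(np.concatenate(z)) == 0.0:
        raise DegenerateDataError("all absolute deviations identical")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.levene(*parts, center=center)
    if not np.isfinite(stat):
        raise DegenerateDataError("degenerate data for Levene's test")
    method = "levene_mean" if center == "mean" else "brown_forsythe"
    return TestResult(method=method, statistic=float(stat), p_value=float(p))


def mean_test(
    data: SampleSet,
    method: str = "welch_t",
    n_perm: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Two-group location test: one-way ANOVA, Welch t, or permutation."""
    if method == "anova":
        parts = data.split()
        if len(parts) < 2:
            raise DesignError("anova needs >= 2 groups")
        stat, p = stats.f_oneway(*parts)
        return TestResult(method="anova", statistic=float(stat), p_value=float(p))
    g1, g2 = data.require_two_groups()
    if method == "welch_t":
        stat, p = stats.ttest_ind(g1, g2, equal_var=False)
        return TestResult(method="welch_t", statistic=float(stat), p_value=float(p))
    if method == "perm_mean":
        if n_perm < 1:
            raise ParameterError("n_perm must be >= 1")
        t_obs = abs(g1.mean() - g2.mean())
        pooled = np.concatenate([g1, g2])
        n1, n = g1.size, pooled.size
        rng = substream(seed, "perm_mean")
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        perm_vals = pooled[order]
        t_star = np.abs(
            perm_vals[:, :n1].mean(axis=1) - perm_vals[:, n1:].mean(axis=1)
        )
        p = (1.0 + np.count_nonzero(t_star >= t_obs)) / (n_perm + 1.0)
        return TestResult(
            method="perm_mean",
            statistic=float(t_obs),
            p_value=float(p),
            n_resamples=n_perm,
            seed=seed,
        )
    raise ParameterError(f"unknown mean test {method!r}")


def ks_two_sample(data: SampleSet, method: str = "auto") -> TestResult:
    """Two-sample Kolmogorov-Smirnov test, ``D = sup |F1 - F2|``.

    ``method`` is passed to scipy ('auto' uses the exact distribution for
    small samples, the asymptotic one otherwise).
    """
    g1, g2 = data.require_two_groups(min_per_group=1)
    res = stats.ks_2samp(g1, g2, method=method)
    return TestResult(
        method="ks",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )
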