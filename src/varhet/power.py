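"""Monte-Carlo power and false-positive-rate engine.

Three study designs mirror the simulation modules of the web tool this
package's methods come from:

* ``two_group``: two unimodal groups, the second derived from the first by a
  mean shift and/or an SD fold-change — powered for mean/dispersion tests;
* ``one_group_bimodality``: a single cohort drawn from a mixture (or from a
  unimodal family under the null) — powered for bimodality tests;
* ``two_group_mixture``: two cohorts drawn from two mixtures, compared by a
  whole-distribution test (KS or the two-group tests).

``estimate_power`` simulates ``n_sim`` datasets per sample size and reports
the rejection proportion with a Wilson interval; with an identity effect the
same number is the false positive rate.  ``empirical_power_subsample``
estimates power non-parametrically by resampling pilot data down/up to the
target sizes, the standard design check when a pilot dataset exists.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .bimodality import (
    BC_UNIFORM_REFERENCE,
    bimodality_coefficient,
    dip_test,
    test_bimodality,
)
from .dispersion import (
    SampleSet,
    ks_two_sample,
    levene_test,
    mean_test,
    permutation_dispersion_test,
)
from .distributions import (
    DistributionSpec,
    EffectSpec,
    MixtureSpec,
    apply_effect,
    sample,
    sample_mixture,
)
from .exceptions import (
    DegenerateDataError,
    DegenerateFitError,
    DesignError,
    ParameterError,
)

__all__ = [
    "PowerDesign",
    "PowerResult",
    "estimate_power",
    "empirical_power_subsample",
    "wilson_interval",
    "TWO_GROUP_TESTS",
    "BIMODALITY_TESTS",
    "DEFAULT_N_GRID",
]

# the sample-size grid used throughout the reference analyses
DEFAULT_N_GRID = (40, 50, 60, 70, 80, 90, 100)

TWO_GROUP_TESTS = (
    "perm_sd",
    "perm_mad",
    "perm_gini",
    "levene_mean",
    "brown_forsythe",
    "anova",
    "welch_t",
    "perm_mean",
    "ks",
)
BIMODALITY_TESTS = (
    "mix_lrt_normal",
    "mix_lrt_weibull",
    "mix_lrt_lognormal",
    "dip",
    "bc",
)


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if not (0 <= k <= n) or n < 1:
        raise ParameterError("need 0 <= k <= n with n >= 1")
    from scipy import stats

    z = stats.norm.ppf(0.5 + level / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lo = 0.0 if k == 0 else max(0.0, center - half)
    hi = 1.0 if k == n else min(1.0, center + half)
    return lo, hi


@dataclass(frozen=True)
class PowerDesign:
    """A complete specification of one power/FPR simulation study."""

    design: str  # two_group | one_group_bimodality | two_group_mixture
    baseline: DistributionSpec | MixtureSpec
    effect: EffectSpec | MixtureSpec | None
    test: str
    n_per_group: tuple = DEFAULT_N_GRID
    alpha: float = 0.05
    n_sim: int = 1000
    seed: int = 0
    test_settings: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.design not in (
            "two_group",
            "one_group_bimodality",
            "two_group_mixture",
        ):
            raise DesignError(f"unknown design {self.design!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError("alpha must be in (0,1)")
        if self.n_sim < 1:
            raise ParameterError("n_sim must be >= 1")
        if any(n < 5 for n in self.n_per_group):
            raise ParameterError("all sample sizes must be >= 5")
        object.__setattr__(self, "n_per_group", tuple(int(n) for n in self.n_per_group))
        # design/test compatibility
        if self.design == "one_group_bimodality":
            if self.test not in BIMODALITY_TESTS:
                raise DesignError(
                    f"{self.test!r} is not a one-group bimodality test"
                )
        else:
            if self.test not in TWO_GROUP_TESTS:
                raise DesignError(f"{self.test!r} is not a two-group test")
        if self.design == "two_group":
            if not isinstance(self.baseline, DistributionSpec):
                raise DesignError("two_group needs a DistributionSpec baseline")
            if self.effect is not None and not isinstance(self.effect, EffectSpec):
                raise DesignError("two_group effect must be an EffectSpec")
        if self.design == "two_group_mixture":
            if self.effect is not None and not isinstance(self.effect, MixtureSpec):
                raise DesignError(
                    "two_group_mixture needs a second MixtureSpec (or None)"
                )

    @property
    def is_null(self) -> bool:
        """True when the simulation runs under the null (reports FPR)."""
        if self.design == "two_group":
            return self.effect is None or self.effect.is_identity
        if self.design == "one_group_bimodality":
            return isinstance(self.baseline, DistributionSpec) or (
                isinstance(self.baseline, MixtureSpec) and self.baseline.k == 1
            )
        return self.effect is None


@dataclass
class PowerResult:
    """Per-sample-size rejection proportions with Wilson 95% intervals."""

    design: str
    test: str
    alpha: float
    seed: int
    rows: pd.DataFrame  # columns: n, n_sim, rejections, power, ci_low, ci_high, mean_runtime_s
    label: str = "power"  # 'power' or 'fpr'

    def to_frame(self) -> pd.DataFrame:
        df = self.rows.copy()
        df.insert(0, "design", self.design)
        df.insert(1, "test", self.test)
        df["alpha"] = self.alpha
        df["seed"] = self.seed
        df["estimate_of"] = self.label
        return df

    def power_at(self, n: int) -> float:
        row = self.rows[self.rows["n"] == n]
        if row.empty:
            raise KeyError(f"no row for n={n}")
        return float(row["power"].iloc[0])


def _run_two_group_test(test, g1, g2, alpha, seed, settings):
    data = SampleSet(
        np.concatenate([g1, g2]),
        np.concatenate([np.zeros(g1.size, int), np.ones(g2.size, int)]),
    )
    n_perm = settings.get("n_perm", 1000)
    if test in ("perm_sd", "perm_mad", "perm_gini"):
        res = permutation_dispersion_test(
            data, metric=test.removeprefix("perm_"), n_perm=n_perm, seed=seed
        )
    elif test == "levene_mean":
        res = levene_test(data, center="mean")
    elif test == "brown_forsythe":
        res = levene_test(data, center="median")
    elif test in ("anova", "welch_t"):
        res = mean_test(data, method=test)
    elif test == "perm_mean":
        res = mean_test(data, method="perm_mean", n_perm=n_perm, seed=seed)
    elif test == "ks":
        res = ks_two_sample(data, method=settings.get("ks_method", "auto"))
    else:  # pragma: no cover - guarded by PowerDesign
        raise DesignError(f"unknown two-group test {test!r}")
    return res.p_value <= alpha


def _run_bimodality_test(test, values, alpha, seed, settings):
    if test == "bc":
        # no p-value: flag when the coefficient exceeds the uniform benchmark
        try:
            return bimodality_coefficient(values) > BC_UNIFORM_REFERENCE
        except DegenerateDataError:
            return False
    if test == "dip":
        res = dip_test(values, n_null=settings.get("n_null", 2000), seed=seed)
        return res.p_value <= alpha
    try:
        summary = test_bimodality(
            values,
            method=test,
            n_boot=settings.get("n_boot", 100),
            seed=seed,
            **{
                k: v
                for k, v in settings.items()
                if k in ("init", "n_restarts", "tol", "max_iter")
            },
        )
    except DegenerateFitError:
        # no usable mixture fit at all: no evidence of bimodality
        return False
    return summary.p_value <= alpha


def _simulate_and_test(design: PowerDesign, n: int, rep: int) -> bool:
    seed_rep = design.seed
    rng = substream(seed_rep, "power", design.design, design.test, n, rep)
    test_seed = int(rng.integers(0, 2**31 - 1))
    if design.design == "two_group":
        g1 = sample(design.baseline, n, rng)
        spec2 = (
            design.baseline
            if design.effect is None
            else apply_effect(design.baseline, design.effect)
        )
        g2 = sample(spec2, n, rng)
        return _run_two_group_test(
            design.test, g1, g2, design.alpha, test_seed, design.test_settings
        )
    if design.design == "one_group_bimodality":
        if isinstance(design.baseline, MixtureSpec):
            values, _ = sample_mixture(design.baseline, n, rng)
        else:
            values = sample(design.baseline, n, rng)
        return _run_bimodality_test(
            design.test, values, design.alpha, test_seed, design.test_settings
        )
    # two_group_mixture
    g1, _ = sample_mixture(design.baseline, n, rng)
    second = design.effect if design.effect is not None else design.baseline
    g2, _ = sample_mixture(second, n, rng)
    return _run_two_group_test(
        design.test, g1, g2, design.alpha, test_seed, design.test_settings
    )


def estimate_power(design: PowerDesign) -> PowerResult:
    """Monte-Carlo power (or FPR, when the design is null) over the n grid.

    Every (n, replicate) pair draws from its own seed substream, so results
    for one sample size are unchanged when more sizes are added.
    """
    records = []
    for n in design.n_per_group:
        t0 = time.perf_counter()
        rejections = 0
        for rep in range(design.n_sim):
            rejections += bool(_simulate_and_test(design, n, rep))
        dt = (time.perf_counter() - t0) / design.n_sim
        lo, hi = wilson_interval(rejections, design.n_sim)
        records.append(
            {
                "n": n,
                "n_sim": design.n_sim,
                "rejections": rejections,
                "power": rejections / design.n_sim,
                "ci_low": lo,
                "ci_high": hi,
                "mean_runtime_s": dt,
            }
        )
    return PowerResult(
        design=design.design,
        test=design.test,
        alpha=design.alpha,
        seed=design.seed,
        rows=pd.DataFrame.from_records(records),
        label="fpr" if design.is_null else "power",
    )


def empirical_power_subsample(
    pilot_values,
    n_targets,
    test: str,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    pilot_groups=None,
    test_settings: dict | None = None,
) -> PowerResult:
    """Power by bootstrapped subsampling of pilot data.

    For each target n, ``n_boot`` with-replacement resamples of size n are
    drawn from the pilot (per group when ``pilot_groups`` is given) and the
    test applied; the rejection fraction estimates power under the pilot's
    empirical distribution with no parametric assumption.
    """
    pilot_values = np.asarray(pilot_values, dtype=float)
    if pilot_values.size == 0:
        raise ParameterError("empty pilot data")
    settings = dict(test_settings or {})
    two_group = test in TWO_GROUP_TESTS
    if two_group:
        if pilot_groups is None:
            raise DesignError(f"{test!r} needs pilot_groups")
        pilot_groups = np.asarray(pilot_groups)
        levels = pd.unique(pilot_groups)
        if levels.size != 2:
            raise DesignError("two-group subsampling needs exactly 2 groups")
        pools = [pilot_values[pilot_groups == g] for g in levels]
    elif test not in BIMODALITY_TESTS:
        raise DesignError(f"unknown test {test!r}")

    records = []
    for n in n_targets:
        t0 = time.perf_counter()
        rejections = 0
        if pilot_values.size < n:
            warnings.warn(
                f"target n={n} exceeds pilot size {pilot_values.size}; "
                "with-replacement resampling still applies"
            )
        for rep in range(n_boot):
            rng = substream(seed, "subsample", test, int(n), rep)
            test_seed = int(rng.integers(0, 2**31 - 1))
            if two_group:
                g1 = rng.choice(pools[0], size=n, replace=True)
                g2 = rng.choice(pools[1], size=n, replace=True)
                rejections += bool(
                    _run_two_group_test(test, g1, g2, alpha, test_seed, settings)
                )
            else:
                values = rng.choice(pilot_values, size=n, replace=True)
                rejections += bool(
                    _run_bimodality_test(test, values, alpha, test_seed, settings)
                )
        dt = (time.perf_counter() - t0) / n_boot
        lo, hi = wilson_interval(rejections, n_boot)
        records.append(
            {
                "n": int(n),
                "n_sim": n_boot,
                "rejections": rejections,
                "power": rejections / n_boot,
                "ci_low": lo,
                "ci_high": hi,
                "mean_runtime_s": dt,
            }
        )
    return PowerResult(
        design="subsample",
        test=test,
        alpha=alpha,
        seed=seed,
        rows=pd.DataFrame.from_records(records),
        label="power",
    )
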