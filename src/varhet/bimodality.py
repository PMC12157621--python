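"""Bimodality detectors: bimodality coefficient, dip test, mixture LRT.

Three complementary ways to ask "is this one population or two":

* the bimodality coefficient (BC), a moment-based index whose uniform
  benchmark is 5/9 — values above it are plausibly bimodal;
* Hartigan's dip test, a shape-free distance from the ECDF to the nearest
  unimodal CDF, calibrated here by Monte-Carlo sampling from the uniform
  (the standard calibration distribution for the dip);
* the parametric-bootstrap mixture LRT (1 vs 2 components) from
  :mod:`varhet.mixtures`, the most powerful option when a family fits.

``test_bimodality`` dispatches over all of them with a uniform result type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._dip import dip_batch_sorted, dip_sorted
from ._rng import substream
from .dispersion import TestResult
from .exceptions import DegenerateDataError, ParameterError
from .mixtures import bootstrap_lrt

__all__ = [
    "BC_UNIFORM_REFERENCE",
    "BimodalitySummary",
    "bimodality_coefficient",
    "dip_statistic",
    "dip_test",
    "test_bimodality",
    "BIMODALITY_METHODS",
]

BC_UNIFORM_REFERENCE = 5.0 / 9.0

BIMODALITY_METHODS = (
    "mix_lrt_normal",
    "mix_lrt_weibull",
    "mix_lrt_lognormal",
    "dip",
    "bc",
)


@dataclass
class BimodalitySummary:
    """Uniform packaging of any bimodality method's outcome."""

    method: str
    statistic: float
    p_value: float | None
    threshold_reference: float | None = None
    n_resamples: int | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "threshold_reference": self.threshold_reference,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
        }


def _validate(values, min_n=4) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < min_n:
        raise ParameterError(f"need a 1-d sample with n >= {min_n}")
    if not np.all(np.isfinite(x)):
        raise ParameterError("values must be finite")
    return x


def bimodality_coefficient(values) -> float:
    """Bimodality coefficient ``(g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3)))``.

    ``g1``/``g2`` are the bias-adjusted sample skewness and excess kurtosis.
    Converges to 5/9 on the uniform and 1/3 on the normal; two symmetric
    point masses drive it to 1.  Affine-invariant.
    """
    x = _validate(values, min_n=4)
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("zero variance: bimodality coefficient undefined")
    n = x.size
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, fisher=True, bias=False)
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def dip_statistic(values) -> float:
    """Hartigan-Hartigan dip: sup-distance from the ECDF to the nearest
    unimodal CDF.  Bounded by [1/(2n), 1/4]; invariant under increasing
    affine transforms."""
    x = _validate(values, min_n=4)
    return float(dip_sorted(np.sort(x)))


def dip_test(values, n_null: int = 2000, seed: int = 0) -> TestResult:
    """Dip test with a Monte-Carlo uniform null.

    ``p = (1 + #{dip(U(0,1)^n) >= dip_obs}) / (n_null + 1)``.  The uniform is
    the canonical least-favourable unimodal null for the dip; the resulting
    test is conservative on lighter-tailed unimodal data such as the normal.
    """
    x = _validate(values, min_n=4)
    if n_null < 1:
        raise ParameterError("n_null must be >= 1")
    d_obs = float(dip_sorted(np.sort(x)))
    rng = substream(seed, "dip_test")
    nulls = np.sort(rng.random((n_null, x.size)), axis=1)
    d_null = dip_batch_sorted(nulls)
    p = (1.0 + np.count_nonzero(d_null >= d_obs)) / (n_null + 1.0)
    return TestResult(
        method="dip",
        statistic=d_obs,
        p_value=float(p),
        n_resamples=n_null,
        seed=seed,
    )


def test_bimodality(
    values,
    method: str = "mix_lrt_normal",
    n_boot: int = 100,
    n_null: int = 2000,
    seed: int = 0,
    **em_settings,
) -> BimodalitySummary:
    """Single dispatch point over every bimodality method.

    ``mix_lrt_{family}`` runs the 1-vs-2 bootstrap LRT (``n_boot``
    resamples); ``dip`` runs the Monte-Carlo dip test (``n_null`` nulls);
    ``bc`` returns the bare coefficient with the 5/9 uniform benchmark and no
    p-value.
    """
    if method not in BIMODALITY_METHODS:
        raise ParameterError(
            f"unknown method {method!r}; expected one of {BIMODALITY_METHODS}"
        )
    if method == "bc":
        return BimodalitySummary(
            method="bc",
            statistic=bimodality_coefficient(values),
            p_value=None,
            threshold_reference=BC_UNIFORM_REFERENCE,
        )
    if method == "dip":
        res = dip_test(values, n_null=n_null, seed=seed)
        return BimodalitySummary(
            method="dip",
            statistic=res.statistic,
            p_value=res.p_value,
            n_resamples=res.n_resamples,
            seed=seed,
        )
    family = method.removeprefix("mix_lrt_")
    res = bootstrap_lrt(values, family, 1, 2, n_boot=n_boot, seed=seed, **em_settings)
    return BimodalitySummary(
        method=method,
        statistic=res.lrt_statistic,
        p_value=res.p_value,
        n_resamples=res.n_boot,
        seed=seed,
        extras={
            "weights_alt": (
                tuple(float(w) for w in res.alt_fit.weights)
                if res.alt_fit is not None
                else None
            ),
            "null_fit": res.null_fit,
            "alt_fit": res.alt_fit,
        },
    )
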