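"""Parametric families, sampling, moments, MLE, and effect parameterization.

Four families are supported — normal, lognormal, Weibull and beta — the usual
candidates for biomedical measurements (symmetric noise, right-skewed
biomarker levels, survival times, and bounded proportions such as methylation
beta-values).  A :class:`DistributionSpec` names a family with its parameters;
an :class:`EffectSpec` turns a baseline group into a comparison group by
shifting the natural-scale mean and rescaling the standard deviation; a
:class:`MixtureSpec` combines same-family components with simplex weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from ._rng import substream
from .exceptions import (
    ConvergenceError,
    DegenerateDataError,
    InfeasibleEffectError,
    ParameterError,
    SupportError,
)

__all__ = [
    "FAMILIES",
    "DistributionSpec",
    "EffectSpec",
    "MixtureSpec",
    "sample",
    "sample_mixture",
    "apply_effect",
    "moments",
    "fit_single",
]

FAMILIES = ("normal", "lognormal", "weibull", "beta")

# parameter names per family, in canonical order
_PARAM_NAMES = {
    "normal": ("mean", "sd"),
    "lognormal": ("meanlog", "sdlog"),
    "weibull": ("shape", "scale"),
    "beta": ("alpha", "beta"),
}
# parameters that must be strictly positive
_POSITIVE = {
    "normal": ("sd",),
    "lognormal": ("sdlog",),
    "weibull": ("shape", "scale"),
    "beta": ("alpha", "beta"),
}


@dataclass(frozen=True)
class DistributionSpec:
    """A parametric family with concrete parameters.

    Parameters are family specific::

        normal:    mean (real),  sd > 0
        lognormal: meanlog (real), sdlog > 0   (parameters of log X)
        weibull:   shape > 0, scale > 0
        beta:      alpha > 0, beta > 0         (support (0, 1))
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        names = _PARAM_NAMES[self.family]
        missing = set(names) - set(self.params)
        extra = set(self.params) - set(names)
        if missing or extra:
            raise ParameterError(
                f"{self.family} expects parameters {names}; "
                f"missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        for name in names:
            value = float(self.params[name])
            if not math.isfinite(value):
                raise ParameterError(f"{self.family}.{name} must be finite")
        for name in _POSITIVE[self.family]:
            if float(self.params[name]) <= 0:
                raise ParameterError(
                    f"{self.family}.{name} must be > 0, got {self.params[name]}"
                )
        # normalize to plain floats (frozen dataclass: go through __dict__)
        object.__setattr__(
            self, "params", {k: float(self.params[k]) for k in names}
        )

    # -- scipy bridge ------------------------------------------------------
    def frozen(self):
        """The equivalent frozen scipy.stats distribution."""
        p = self.params
        if self.family == "normal":
            return stats.norm(loc=p["mean"], scale=p["sd"])
        if self.family == "lognormal":
            return stats.lognorm(s=p["sdlog"], scale=math.exp(p["meanlog"]))
        if self.family == "weibull":
            return stats.weibull_min(c=p["shape"], scale=p["scale"])
        return stats.beta(p["alpha"], p["beta"])

    @property
    def support(self) -> tuple[float, float]:
        if self.family == "normal":
            return (-math.inf, math.inf)
        if self.family == "beta":
            return (0.0, 1.0)
        return (0.0, math.inf)

    def mean(self) -> float:
        return moments(self)[0]

    def sd(self) -> float:
        return math.sqrt(moments(self)[1])

    def to_config(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_config(cls, cfg: dict) -> "DistributionSpec":
        return cls(cfg["family"], dict(cfg["params"]))


@dataclass(frozen=True)
class EffectSpec:
    """Additive mean shift plus multiplicative fold-change on the SD.

    ``(mean_effect=0, variance_effect=1)`` is the identity.  The fold-change
    applies to the standard deviation (so a variance_effect of 2 doubles the
    spread, quadrupling the variance).
    """

    mean_effect: float = 0.0
    variance_effect: float = 1.0

    def __post_init__(self):
        if not math.isfinite(self.mean_effect):
            raise ParameterError("mean_effect must be finite")
        if not (math.isfinite(self.variance_effect) and self.variance_effect > 0):
            raise ParameterError("variance_effect must be finite and > 0")

    @property
    def is_identity(self) -> bool:
        return self.mean_effect == 0.0 and self.variance_effect == 1.0


@dataclass(frozen=True)
class MixtureSpec:
    """Same-family components with simplex weights, sorted by component mean."""

    components: tuple
    weights: tuple

    def __init__(self, components: Sequence[DistributionSpec], weights: Sequence[float]):
        components = tuple(components)
        if len(components) == 0:
            raise ParameterError("mixture needs at least one component")
        families = {c.family for c in components}
        if len(families) != 1:
            raise ParameterError("all mixture components must share a family")
        weights = tuple(float(w) for w in weights)
        if len(weights) != len(components):
            raise ParameterError("weights and components must align")
        if any(w <= 0 for w in weights):
            raise ParameterError("weights must all be > 0")
        if abs(sum(weights) - 1.0) > 1e-12:
            raise ParameterError("weights must sum to 1 within 1e-12")
        order = np.argsort([c.mean() for c in components], kind="stable")
        object.__setattr__(self, "components", tuple(components[i] for i in order))
        object.__setattr__(self, "weights", tuple(weights[i] for i in order))

    @property
    def family(self) -> str:
        return self.components[0].family

    @property
    def k(self) -> int:
        return len(self.components)

    def mean(self) -> float:
        return float(sum(w * c.mean() for w, c in zip(self.weights, self.components)))

    def var(self) -> float:
        m = self.mean()
        return float(
            sum(
                w * (c.sd() ** 2 + (c.mean() - m) ** 2)
                for w, c in zip(self.weights, self.components)
            )
        )

    def to_config(self) -> dict:
        return {
            "weights": list(self.weights),
            "components": [c.to_config() for c in self.components],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "MixtureSpec":
        return cls(
            [DistributionSpec.from_config(c) for c in cfg["components"]],
            cfg["weights"],
        )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample(spec: DistributionSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` values from ``spec``, reproducibly for a given seed."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed)
    p = spec.params
    if spec.family == "normal":
        return rng.normal(p["mean"], p["sd"], size=n)
    if spec.family == "lognormal":
        return np.exp(rng.normal(p["meanlog"], p["sdlog"], size=n))
    if spec.family == "weibull":
        return p["scale"] * rng.weibull(p["shape"], size=n)
    return rng.beta(p["alpha"], p["beta"], size=n)


def sample_mixture(
    spec: MixtureSpec, n: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` values from a mixture; returns ``(values, component labels)``.

    Labels are 0-based indices into ``spec.components`` (sorted by mean).
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed)
    labels = rng.choice(spec.k, size=n, p=np.asarray(spec.weights))
    values = np.empty(n, dtype=float)
    for j, comp in enumerate(spec.components):
        mask = labels == j
        cnt = int(mask.sum())
        if cnt:
            values[mask] = sample(comp, cnt, rng)
    return values, labels


# ---------------------------------------------------------------------------
# moments and the effect-size parameterization
# ---------------------------------------------------------------------------

def moments(spec: DistributionSpec) -> tuple[float, float, float, float]:
    """Closed-form (mean, variance, skewness, excess kurtosis)."""
    m, v, s, k = spec.frozen().stats(moments="mvsk")
    return float(m), float(v), float(s), float(k)


def _weibull_log_cv(shape: float) -> float:
    # log coefficient of variation; depends on the shape only and is
    # strictly decreasing in it.  Log-space keeps tiny shapes from
    # overflowing exp(gammaln).
    t = special.gammaln(1.0 + 2.0 / shape) - 2.0 * special.gammaln(
        1.0 + 1.0 / shape
    )  # log(E[X^2]/E[X]^2)
    if t > 30.0:
        return 0.5 * t  # expm1(t) ~ exp(t)
    return 0.5 * math.log(math.expm1(t))


def _solve_weibull_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    if mean <= 0:
        raise InfeasibleEffectError(
            f"weibull requires a positive mean, requested {mean}"
        )
    if sd <= 0:
        raise InfeasibleEffectError("weibull requires a positive sd")
    lcv = math.log(sd / mean)
    lo, hi = 1e-3, 1e4
    if not (_weibull_log_cv(hi) <= lcv <= _weibull_log_cv(lo)):
        raise InfeasibleEffectError(
            f"weibull cannot realise cv={sd / mean:.4g} "
            f"(shape bracket [{lo},{hi}])"
        )
    shape = optimize.brentq(
        lambda k: _weibull_log_cv(k) - lcv, lo, hi, xtol=1e-12
    )
    scale = mean / math.exp(special.gammaln(1.0 + 1.0 / shape))
    return shape, scale


def apply_effect(spec: DistributionSpec, effect: EffectSpec) -> DistributionSpec:
    """Re-solve family parameters for a shifted mean and rescaled SD.

    The returned spec has natural-scale mean ``mean(spec) + mean_effect`` and
    sd ``sd(spec) * variance_effect``.  Normal is direct; lognormal and beta
    use their closed-form mean/variance inversions; Weibull solves the CV
    equation for the shape with a bracketed root finder.  Requested moments
    outside the family's feasible set raise :class:`InfeasibleEffectError`
    rather than being clipped.
    """
    m0, v0, _, _ = moments(spec)
    target_mean = m0 + effect.mean_effect
    target_sd = math.sqrt(v0) * effect.variance_effect

    if spec.family == "normal":
        return DistributionSpec("normal", {"mean": target_mean, "sd": target_sd})

    if spec.family == "lognormal":
        if target_mean <= 0:
            raise InfeasibleEffectError(
                f"lognormal requires a positive mean, requested {target_mean}"
            )
        sdlog2 = math.log1p((target_sd / target_mean) ** 2)
        if sdlog2 <= 0:
            raise InfeasibleEffectError("lognormal requires a positive sd")
        meanlog = math.log(target_mean) - 0.5 * sdlog2
        return DistributionSpec(
            "lognormal", {"meanlog": meanlog, "sdlog": math.sqrt(sdlog2)}
        )

    if spec.family == "weibull":
        shape, scale = _solve_weibull_from_mean_sd(target_mean, target_sd)
        return DistributionSpec("weibull", {"shape": shape, "scale": scale})

    # beta: mean in (0,1) and var < mean(1-mean)
    m, v = target_mean, target_sd**2
    if not (0.0 < m < 1.0):
        raise InfeasibleEffectError(f"beta mean must lie in (0,1), requested {m}")
    if not (0.0 < v < m * (1.0 - m)):
        raise InfeasibleEffectError(
            f"beta variance must lie in (0, mean(1-mean)) = (0, {m * (1 - m):.4g}), "
            f"requested {v:.4g}"
        )
    nu = m * (1.0 - m) / v - 1.0
    return DistributionSpec("beta", {"alpha": m * nu, "beta": (1.0 - m) * nu})


# ---------------------------------------------------------------------------
# single-component maximum likelihood
# ---------------------------------------------------------------------------

def _check_support(values: np.ndarray, family: str) -> None:
    if family in ("lognormal", "weibull") and np.any(values <= 0):
        raise SupportError(f"{family} requires strictly positive values")
    if family == "beta" and (np.any(values <= 0) or np.any(values >= 1)):
        raise SupportError("beta requires values strictly inside (0, 1)")


def log_likelihood(values: np.ndarray, spec: DistributionSpec) -> float:
    """Total log-likelihood of ``values`` under ``spec``."""
    return float(np.sum(spec.frozen().logpdf(np.asarray(values, dtype=float))))


def weibull_profile_gradient(values: np.ndarray, shape: float) -> float:
    """Profile log-likelihood derivative in the shape (scale profiled out)."""
    x = np.asarray(values, dtype=float)
    lx = np.log(x)
    xk = np.power(x / x.max(), shape)  # normalized to dodge overflow
    return float(np.sum(xk * lx) / np.sum(xk) - 1.0 / shape - lx.mean())


def _fit_weibull(values: np.ndarray) -> tuple[float, float]:
    x = np.asarray(values, dtype=float)
    mean, sd = x.mean(), x.std(ddof=0)
    # moment-based starting value (standard cv**-1.086 approximation)
    k0 = float(np.clip((sd / mean) ** -1.086, 1e-2, 5e2))
    k = k0
    converged = False
    for _ in range(100):  # Newton on the profile shape equation
        g = weibull_profile_gradient(x, k)
        eps = 1e-6 * k
        dg = (weibull_profile_gradient(x, k + eps) - g) / eps
        if dg == 0:
            break
        step = g / dg
        k_new = k - step
        if not (1e-4 < k_new < 1e4):
            break
        if abs(k_new - k) < 1e-12 * k:
            k = k_new
            converged = True
            break
        k = k_new
        if abs(weibull_profile_gradient(x, k)) < 1e-12:
            converged = True
            break
    if not converged:
        # bisection fallback on a wide bracket
        lo, hi = 1e-4, 1e4
        glo, ghi = weibull_profile_gradient(x, lo), weibull_profile_gradient(x, hi)
        if glo * ghi > 0:
            raise ConvergenceError(
                "weibull shape equation has no root in [1e-4, 1e4]",
                last_iterate={"shape": k},
            )
        k = optimize.brentq(lambda s: weibull_profile_gradient(x, s), lo, hi, xtol=1e-12)
    scale = float(np.mean(np.power(x, k)) ** (1.0 / k))
    return float(k), scale


def _fit_beta(values: np.ndarray) -> tuple[float, float]:
    x = np.asarray(values, dtype=float)
    n = x.size
    mlx, ml1x = np.log(x).mean(), np.log1p(-x).mean()
    # method-of-moments start
    m, v = x.mean(), x.var(ddof=0)
    v = min(v, m * (1 - m) * 0.999)
    nu = m * (1 - m) / v - 1.0
    theta = np.array([max(m * nu, 1e-3), max((1 - m) * nu, 1e-3)])

    def grad(t):
        a, b = t
        psum = special.digamma(a + b)
        return n * np.array(
            [psum - special.digamma(a) + mlx, psum - special.digamma(b) + ml1x]
        )

    def hess(t):
        a, b = t
        tsum = special.polygamma(1, a + b)
        return n * np.array(
            [
                [tsum - special.polygamma(1, a), tsum],
                [tsum, tsum - special.polygamma(1, b)],
            ]
        )

    for _ in range(200):  # Newton with step halving to stay positive
        g = grad(theta)
        if np.max(np.abs(g)) < 1e-10 * n:
            return float(theta[0]), float(theta[1])
        try:
            step = np.linalg.solve(hess(theta), g)
        except np.linalg.LinAlgError:
            break
        scale_f = 1.0
        while np.any(theta - scale_f * step <= 0) and scale_f > 1e-8:
            scale_f /= 2.0
        theta = theta - scale_f * step
    # robust fallback
    res = optimize.minimize(
        lambda t: -float(
            np.sum(stats.beta.logpdf(x, np.exp(t[0]), np.exp(t[1])))
        ),
        np.log(np.maximum(theta, 1e-3)),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    if not res.success:
        raise ConvergenceError(
            "beta MLE failed to converge", last_iterate={"log_params": res.x}
        )
    return float(np.exp(res.x[0])), float(np.exp(res.x[1]))


def fit_single(values, family: str) -> DistributionSpec:
    """Maximum-likelihood fit of one component of ``family`` to ``values``.

    Normal and lognormal are closed form; Weibull uses Newton on the profile
    shape equation with a bisection fallback; beta uses Newton on the digamma
    score equations from a method-of-moments start.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 5:
        raise ParameterError("fit_single needs a 1-d sample with n >= 5")
    if not np.all(np.isfinite(x)):
        raise SupportError("values must be finite")
    _check_support(x, family)
    if np.ptp(x) == 0.0:
        raise DegenerateDataError(
            f"all values identical; {family} MLE is degenerate (zero spread)"
        )
    if family == "normal":
        return DistributionSpec(
            "normal", {"mean": float(x.mean()), "sd": float(x.std(ddof=0))}
        )
    if family == "lognormal":
        lx = np.log(x)
        return DistributionSpec(
            "lognormal",
            {"meanlog": float(lx.mean()), "sdlog": float(lx.std(ddof=0))},
        )
    if family == "weibull":
        shape, scale = _fit_weibull(x)
        return DistributionSpec("weibull", {"shape": shape, "scale": scale})
    if family == "beta":
        a, b = _fit_beta(x)
        return DistributionSpec("beta", {"alpha": a, "beta": b})
    raise ParameterError(f"unknown family {family!r}")
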