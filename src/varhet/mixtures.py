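"""Finite-mixture EM and the parametric-bootstrap likelihood-ratio test.

``em_fit`` fits a K-component mixture (normal, lognormal, or Weibull) by EM
with quantile (or k-means) initialization and multiple restarts;
``bootstrap_lrt`` compares K0 vs K1 components by refitting both models on
data simulated from the fitted null — the standard parametric-bootstrap LRT
for mixture order selection.

Lognormal mixtures are fitted as Gaussian mixtures of the logs (an exact
reparameterization: weights and posteriors coincide, log-likelihoods differ
by the fixed Jacobian sum(log x), and component parameters map by exp/log).

The EM inner loops live in :mod:`varhet._emkern` and are JIT-compiled;
bootstrap replicates are fitted in batches so large Monte-Carlo studies stay
tractable without changing any single fit's result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from . import _emkern
from ._rng import substream
from .dispersion import TestResult  # shared result record  # noqa: F401
from .distributions import DistributionSpec, _check_support
from .exceptions import (
    DegenerateFitError,
    ParameterError,
    SupportError,
)

__all__ = [
    "MixtureFit",
    "BootstrapLRTResult",
    "em_fit",
    "bootstrap_lrt",
    "classify_modes",
    "bic",
]

_LOG_2PI = math.log(2.0 * math.pi)
_SD_FLOOR_REL = 1e-6  # spread floor, relative to the sample SD


@dataclass
class MixtureFit:
    """A fitted K-component mixture, components sorted by ascending mean.

    For lognormal fits the ordering key is the component meanlog (the
    Gaussian order on logs), so the lognormal/normal-on-logs equivalence is
    exact.
    """

    family: str
    k: int
    weights: np.ndarray
    components: tuple
    log_likelihood: float
    posteriors: np.ndarray
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray
    n_obs: int

    def to_record(self) -> dict:
        rec = {
            "family": self.family,
            "k": self.k,
            "log_likelihood": self.log_likelihood,
            "bic": bic(self),
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        for j, (w, c) in enumerate(zip(self.weights, self.components), start=1):
            rec[f"weight_{j}"] = float(w)
            for name, val in c.params.items():
                rec[f"{name}_{j}"] = val
        return rec


@dataclass
class BootstrapLRTResult:
    """Result of the K0-vs-K1 parametric-bootstrap likelihood-ratio test.

    ``alt_fit`` is None in the rare case where every K1 restart collapsed
    even after escalation; the alternative then degenerates to the null on
    this dataset and the test reports LRT = 0, p = 1.
    """

    lrt_statistic: float
    p_value: float
    n_boot: int
    null_fit: MixtureFit
    alt_fit: MixtureFit
    seed: int

    def to_test_result(self, family: str) -> TestResult:
        return TestResult(
            method=f"mix_lrt_{family}",
            statistic=self.lrt_statistic,
            p_value=self.p_value,
            n_resamples=self.n_boot,
            seed=self.seed,
            extras={
                "k0": self.null_fit.k,
                "k1": self.alt_fit.k if self.alt_fit is not None else None,
                "weights_alt": (
                    tuple(float(w) for w in self.alt_fit.weights)
                    if self.alt_fit is not None
                    else None
                ),
            },
        )


# ---------------------------------------------------------------------------
# numpy E-step (for final posteriors/loglik at given parameters)
# ---------------------------------------------------------------------------

def _log_weibull_pdf(x, lx, shape, scale):
    lscale = np.log(scale)
    t = shape * (lx - lscale)
    return np.log(shape) - lscale + (shape - 1.0) * (lx - lscale) - np.exp(
        np.minimum(t, 700.0)
    )


def _e_step(x, family, w, a, b):
    """Log-likelihood and responsibilities of one dataset at fixed params."""
    xc = x[:, None]
    if family == "normal":
        lp = -0.5 * ((xc - a) / b) ** 2 - np.log(b) - 0.5 * _LOG_2PI
    else:
        lp = _log_weibull_pdf(xc, np.log(xc), a, b)
    lp = lp + np.log(w)
    m = lp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(lp - m).sum(axis=1))
    return float(lse.sum()), np.exp(lp - lse[:, None])


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _block_stats(xs_sorted, K):
    """Per-block mean/sd/weight of a (B, n) row-sorted array, K blocks."""
    B, n = xs_sorted.shape
    edges = np.linspace(0, n, K + 1).astype(int)
    mu = np.empty((B, K))
    sd = np.empty((B, K))
    w = np.empty((B, K))
    for j in range(K):
        blk = xs_sorted[:, edges[j] : edges[j + 1]]
        mu[:, j] = blk.mean(axis=1)
        sd[:, j] = blk.std(axis=1)
        w[:, j] = blk.shape[1] / n
    return w, mu, sd


def _lloyd_1d(xs_sorted, centers, n_iter=25):
    """Plain 1-d k-means refinement of sorted data from given centers."""
    for _ in range(n_iter):
        d = np.abs(xs_sorted[:, :, None] - centers[:, None, :])
        lab = d.argmin(axis=2)
        for j in range(centers.shape[1]):
            mask = lab == j
            cnt = mask.sum(axis=1)
            tot = np.where(mask, xs_sorted, 0.0).sum(axis=1)
            upd = cnt > 0
            centers[upd, j] = tot[upd] / cnt[upd]
    return np.sort(centers, axis=1), lab


def _init_batch(X, family, K, init, restart, rng):
    """Initial (w, a, b) for every row of X; restart 0 is deterministic."""
    B, n = X.shape
    xs = np.sort(X, axis=1)
    if restart == 0:
        w, mu, sd = _block_stats(xs, K)
        if init == "kmeans" and K > 1:
            centers, lab = _lloyd_1d(xs, mu.copy())
            mu = centers
            for j in range(K):
                mask = lab == j
                cnt = np.maximum(mask.sum(axis=1), 1)
                w[:, j] = mask.sum(axis=1) / n
                mean_j = np.where(mask, xs, 0.0).sum(axis=1) / cnt
                var_j = np.where(mask, (xs - mean_j[:, None]) ** 2, 0.0).sum(
                    axis=1
                ) / cnt
                sd[:, j] = np.sqrt(var_j)
            w = np.maximum(w, 1.0 / n)
            w = w / w.sum(axis=1, keepdims=True)
    else:
        # perturbed restart: centers at random data points, block-free spread
        cols = rng.integers(0, n, size=(B, K))
        mu = np.sort(np.take_along_axis(X, cols, axis=1), axis=1)
        sd = np.repeat(X.std(axis=1)[:, None] / K, K, axis=1)
        w = np.full((B, K), 1.0 / K)
    pooled_sd = np.maximum(X.std(axis=1), 1e-300)
    sd = np.maximum(sd, 0.05 * pooled_sd[:, None])
    if family == "normal":
        return w, mu, sd
    # weibull: map block mean/sd to (shape, scale) via the cv heuristic
    mu_pos = np.maximum(mu, 1e-300)
    shape = np.clip((sd / mu_pos) ** -1.086, 5e-2, 5e2)
    scale = mu_pos / np.exp(special.gammaln(1.0 + 1.0 / shape))
    return w, shape, scale


# ---------------------------------------------------------------------------
# batched fitting (kernel drivers)
# ---------------------------------------------------------------------------

def _c(a):
    return np.ascontiguousarray(a, dtype=np.float64)


def _run_em_batch(X, family, K, w0, a0, b0, tol, max_iter):
    """Run the EM kernel on a (B, n) batch; returns a result dict."""
    B, n = X.shape
    w, a, b = _c(w0), _c(a0), _c(b0)
    if family == "normal":
        sd_floors = _c(_SD_FLOOR_REL * X.std(axis=1))
        ll, nit, conv, deg = _emkern.em_normal_batch(
            _c(X), w, a, b, tol, max_iter, sd_floors
        )
    else:
        row_scale = X.max(axis=1, keepdims=True)
        Xn = X / row_scale
        b = _c(b / row_scale)
        sd_floors = _c(_SD_FLOOR_REL * Xn.std(axis=1))
        ll, nit, conv, deg = _emkern.em_weibull_batch(
            _c(Xn), _c(np.log(Xn)), w, a, b, tol, max_iter, sd_floors
        )
        b = b * row_scale
        ll = ll - n * np.log(row_scale[:, 0])
    return {
        "w": w,
        "a": a,
        "b": b,
        "ll": ll,
        "n_iter": nit,
        "converged": conv,
        "degenerate": deg,
    }


def _fit_batch(X, family, K, init, n_restarts, tol, max_iter, rng):
    """Best-of-restarts batched EM; returns per-row params and loglik."""
    best = None
    for r in range(n_restarts):
        w0, a0, b0 = _init_batch(X, family, K, init, r, rng)
        out = _run_em_batch(X, family, K, w0, a0, b0, tol, max_iter)
        valid = ~out["degenerate"]
        if best is None:
            best = out
            best["valid"] = valid
            continue
        better = valid & (
            (~best["valid"]) | (out["ll"] > best["ll"]) | ~np.isfinite(best["ll"])
        )
        for key in ("w", "a", "b", "ll", "n_iter"):
            best[key][better] = out[key][better]
        best["converged"][better] = out["converged"][better]
        best["valid"] = best["valid"] | valid
    best["degenerate"] = ~best["valid"]
    return best


def _fit_k1_batch(X, family):
    """Single-component MLE per row (closed form / profiled Newton)."""
    B, n = X.shape
    if family == "normal":
        mu = X.mean(axis=1)
        sg = X.std(axis=1)
        ll = -0.5 * n * (_LOG_2PI + 1.0) - n * np.log(sg)
        return {
            "w": np.ones((B, 1)),
            "a": mu[:, None],
            "b": sg[:, None],
            "ll": ll,
            "degenerate": sg <= 0,
        }
    row_scale = X.max(axis=1, keepdims=True)
    Xn = X / row_scale
    out = _emkern.fit1_weibull_batch(_c(Xn), _c(np.log(Xn)))
    shape, scale, ll = out[:, 0], out[:, 1], out[:, 2]
    ll = ll - n * np.log(row_scale[:, 0])
    return {
        "w": np.ones((B, 1)),
        "a": shape[:, None],
        "b": (scale * row_scale[:, 0])[:, None],
        "ll": ll,
        "degenerate": ~np.isfinite(ll) | (shape < 0),
    }


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _component_specs(family, a, b):
    if family == "normal":
        return [
            DistributionSpec("normal", {"mean": float(m), "sd": float(s)})
            for m, s in zip(a, b)
        ]
    if family == "weibull":
        return [
            DistributionSpec("weibull", {"shape": float(k), "scale": float(s)})
            for k, s in zip(a, b)
        ]
    return [
        DistributionSpec("lognormal", {"meanlog": float(m), "sdlog": float(s)})
        for m, s in zip(a, b)
    ]


def _sort_key(family, a, b):
    if family in ("normal", "lognormal"):
        return a  # mean / meanlog
    return b * np.exp(special.gammaln(1.0 + 1.0 / a))  # weibull mean


def em_fit(
    values,
    family: str,
    k: int = 2,
    init: str = "quantile",
    n_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
) -> MixtureFit:
    """Fit a K-component mixture by EM, best of ``n_restarts`` starts.

    Restart 0 uses the deterministic ``init`` (quantile blocks, or 1-d
    k-means refined from them); later restarts seed component locations at
    random data points.  Components collapsing below a weight of 1e-4 or an
    SD floor of 1e-6 x SD(data) invalidate a restart; if every restart
    collapses a :class:`DegenerateFitError` is raised.
    """
    if family not in ("normal", "lognormal", "weibull"):
        raise ParameterError(f"unsupported mixture family {family!r}")
    if init not in ("quantile", "kmeans"):
        raise ParameterError("init must be 'quantile' or 'kmeans'")
    if k < 1:
        raise ParameterError("k must be >= 1")
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 5 * k:
        raise ParameterError(f"em_fit needs n >= 5*k = {5 * k}, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise SupportError("values must be finite")
    _check_support(x, family)

    if family == "lognormal":
        jac = float(np.sum(np.log(x)))
        inner = em_fit(
            np.log(x), "normal", k, init, n_restarts, tol, max_iter, seed
        )
        comps = _component_specs(
            "lognormal",
            [c.params["mean"] for c in inner.components],
            [c.params["sd"] for c in inner.components],
        )
        return MixtureFit(
            family="lognormal",
            k=k,
            weights=inner.weights,
            components=tuple(comps),
            log_likelihood=inner.log_likelihood - jac,
            posteriors=inner.posteriors,
            n_iter=inner.n_iter,
            converged=inner.converged,
            loglik_trace=inner.loglik_trace - jac,
            n_obs=inner.n_obs,
        )

    rng = substream(seed, "em_fit", family, k)
    n = x.size
    X1 = x[None, :]
    best = None
    best_trace = None
    for r in range(n_restarts):
        w0, a0, b0 = _init_batch(X1, family, k, init, r, rng)
        # single-row run through the kernel, keeping the loglik trace
        trace = np.empty(max_iter)
        resp = np.empty((n, k))
        if family == "normal":
            w_, a_, b_ = _c(w0[0]), _c(a0[0]), _c(b0[0])
            sd_floor = _SD_FLOOR_REL * x.std()
            ll, nit, conv, deg = _emkern.em_normal(
                _c(x), w_, a_, b_, tol, max_iter, sd_floor, trace, resp
            )
        else:
            scale0 = x.max()
            xn = x / scale0
            w_, a_, b_ = _c(w0[0]), _c(a0[0]), _c(b0[0] / scale0)
            sd_floor = _SD_FLOOR_REL * xn.std()
            ll, nit, conv, deg = _emkern.em_weibull(
                _c(xn), _c(np.log(xn)), w_, a_, b_, tol, max_iter, sd_floor,
                trace, resp,
            )
            b_ = b_ * scale0
            jac_scale = n * math.log(scale0)
            ll = ll - jac_scale
            trace = trace - jac_scale
        if deg:
            continue
        if best is None or ll > best["ll"]:
            best = {"w": w_, "a": a_, "b": b_, "ll": ll, "n_iter": int(nit),
                    "converged": bool(conv)}
            best_trace = trace[:nit].copy()
    if best is None:
        raise DegenerateFitError(
            f"all {n_restarts} EM restarts collapsed for {family} K={k}"
        )
    order = np.argsort(_sort_key(family, best["a"], best["b"]), kind="stable")
    w = best["w"][order]
    a, b = best["a"][order], best["b"][order]
    ll_final, resp = _e_step(x, family, w, a, b)
    return MixtureFit(
        family=family,
        k=k,
        weights=w,
        components=tuple(_component_specs(family, a, b)),
        log_likelihood=float(best["ll"]),
        posteriors=resp,
        n_iter=best["n_iter"],
        converged=best["converged"],
        loglik_trace=best_trace,
        n_obs=n,
    )


def classify_modes(fit: MixtureFit) -> np.ndarray:
    """Most-probable-mode labels (0-based); posterior ties go to the
    lower-mean component (components are sorted ascending and argmax takes
    the first maximum)."""
    return np.argmax(fit.posteriors, axis=1)


def bic(fit: MixtureFit) -> float:
    """Bayesian information criterion, smaller is better.

    Free parameters: (K-1) mixing weights + 2 per component.
    """
    p = (fit.k - 1) + 2 * fit.k
    return float(-2.0 * fit.log_likelihood + p * math.log(fit.n_obs))


def _sample_from_params(family, w, a, b, B, n, rng):
    cw = np.cumsum(w)
    cw[-1] = 1.0
    labels = np.searchsorted(cw, rng.random((B, n)), side="right")
    if family == "normal":
        return rng.normal(a[labels], b[labels])
    return b[labels] * rng.weibull(a[labels])


def _fit_with_rescue(x, family, k, seed, em_kw):
    """em_fit, escalating to extra random restarts if every start collapses.

    Returns None when even the escalated attempt collapses.
    """
    try:
        return em_fit(x, family, k, seed=seed, **em_kw)
    except DegenerateFitError:
        pass
    rescue_kw = dict(em_kw)
    rescue_kw["n_restarts"] = em_kw.get("n_restarts", 5) + 5
    try:
        return em_fit(x, family, k, seed=seed + 1, **rescue_kw)
    except DegenerateFitError:
        return None


def bootstrap_lrt(
    values,
    family: str,
    k0: int = 1,
    k1: int = 2,
    n_boot: int = 100,
    seed: int = 0,
    init: str = "quantile",
    n_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 1000,
    max_redraw_rounds: int = 5,
) -> BootstrapLRTResult:
    """Parametric-bootstrap likelihood-ratio test of K0 vs K1 components.

    Both models are fitted to the data; ``n_boot`` datasets of the same size
    are then simulated from the fitted K0 model and both models refitted on
    each, giving the null reference distribution of ``LRT = 2 (l1 - l0)``.
    ``p = (1 + #{LRT* >= LRT_obs}) / (n_boot + 1)``.  Replicates whose refits
    collapse are redrawn (bounded rounds) and, failing that, dropped with a
    warning.
    """
    if not (1 <= k0 < k1):
        raise ParameterError("need 1 <= k0 < k1")
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    x = np.asarray(values, dtype=float)
    em_kw = dict(init=init, n_restarts=n_restarts, tol=tol, max_iter=max_iter)

    if family == "lognormal":
        # exact reparameterization: run the whole test on logs
        _check_support(x, "lognormal")
        inner = bootstrap_lrt(
            np.log(x), "normal", k0, k1, n_boot, seed, **em_kw,
            max_redraw_rounds=max_redraw_rounds,
        )
        null_fit = em_fit(x, "lognormal", k0, seed=seed, **em_kw)
        alt_fit = em_fit(x, "lognormal", k1, seed=seed, **em_kw)
        return BootstrapLRTResult(
            lrt_statistic=inner.lrt_statistic,
            p_value=inner.p_value,
            n_boot=inner.n_boot,
            null_fit=null_fit,
            alt_fit=alt_fit,
            seed=seed,
        )

    null_fit = _fit_with_rescue(x, family, k0, seed, em_kw)
    if null_fit is None:
        raise DegenerateFitError(
            f"the K0={k0} fit collapsed on every restart; cannot bootstrap"
        )
    alt_fit = _fit_with_rescue(x, family, k1, seed, em_kw)
    if alt_fit is None:
        # every K1 restart collapsed: the richer model degenerates to the
        # null on these data, so there is no evidence for extra components
        warnings.warn(
            f"all K1={k1} restarts collapsed even after escalation; "
            "reporting LRT = 0, p = 1"
        )
        return BootstrapLRTResult(
            lrt_statistic=0.0,
            p_value=1.0,
            n_boot=0,
            null_fit=null_fit,
            alt_fit=None,
            seed=seed,
        )
    lrt_obs = 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood)
    if lrt_obs < -1e-6:
        warnings.warn(
            f"negative LRT ({lrt_obs:.3g}) clamped to 0; K1 fit may be at a "
            "worse local optimum than K0"
        )
    lrt_obs = max(lrt_obs, 0.0)

    n = x.size
    w0 = np.asarray(null_fit.weights)
    if family == "normal":
        a0 = np.array([c.params["mean"] for c in null_fit.components])
        b0 = np.array([c.params["sd"] for c in null_fit.components])
    else:
        a0 = np.array([c.params["shape"] for c in null_fit.components])
        b0 = np.array([c.params["scale"] for c in null_fit.components])

    rng = substream(seed, "bootstrap_lrt", family, k0, k1)
    lrt_star = np.full(n_boot, np.nan)
    need = np.arange(n_boot)
    for _ in range(max_redraw_rounds):
        if need.size == 0:
            break
        Xb = _sample_from_params(family, w0, a0, b0, need.size, n, rng)
        if k0 == 1:
            fit0 = _fit_k1_batch(Xb, family)
        else:
            fit0 = _fit_batch(Xb, family, k0, init, n_restarts, tol, max_iter, rng)
        fit1 = _fit_batch(Xb, family, k1, init, n_restarts, tol, max_iter, rng)
        ok = ~(fit0["degenerate"] | fit1["degenerate"])
        vals = 2.0 * (fit1["ll"] - fit0["ll"])
        lrt_star[need[ok]] = np.maximum(vals[ok], 0.0)
        need = need[~ok]
    if need.size:
        warnings.warn(
            f"{need.size} bootstrap replicates remained degenerate after "
            f"{max_redraw_rounds} redraw rounds; dropped from the reference"
        )
    kept = lrt_star[np.isfinite(lrt_star)]
    p = (1.0 + np.count_nonzero(kept >= lrt_obs)) / (kept.size + 1.0)
    return BootstrapLRTResult(
        lrt_statistic=float(lrt_obs),
        p_value=float(p),
        n_boot=int(kept.size),
        null_fit=null_fit,
        alt_fit=alt_fit,
        seed=seed,
    )
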