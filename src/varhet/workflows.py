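"""End-to-end analysis recipes and the synthetic fixture generator.

Four recipes cover the package's applied workflows:

* :func:`eda_summary` — distributional triage (moments plus a bootstrapped
  skewness/kurtosis cloud for the Cullen-Frey plane);
* the two-group variance-heterogeneity pipeline (ingest + the tests in
  :mod:`varhet.dispersion`), reached through the CLI;
* the single-cohort bimodality pipeline with downstream mode-vs-outcome
  association (:func:`mode_group_association`), as used to link a bimodal
  expression marker to survival subgroups;
* the twin-discordance screen (:func:`compute_deltas`,
  :func:`top_variable_features`, :func:`screen_bimodal_features`): per-gene
  expression deltas between cotwins — oriented as the higher-covariate twin
  minus the lower — are tested for bimodality with the bootstrap LRT,
  Benjamini-Hochberg corrected, and filtered on the minority-mode proportion.

The fixture generator (:func:`generate_fixture` and the ``make_*`` helpers)
emulates the shapes of the controlled-access cohorts these recipes target:
a two-group table with mean/SD effects, a several-hundred-patient cohort
whose marker is a two-component mixture, and a genes x twin-pairs delta
matrix in which a planted minority of genes is bimodal around nonzero deltas
and the rest are unimodal around zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import child_seed, substream
from .dispersion import TestResult
from .distributions import DistributionSpec, EffectSpec, MixtureSpec, apply_effect, sample, sample_mixture
from .exceptions import (
    DegenerateDataError,
    IncompletePairError,
    ParameterError,
    VarhetError,
)
from .mixtures import bootstrap_lrt

__all__ = [
    "EdaSummary",
    "DeltaMatrix",
    "ScreenResult",
    "eda_summary",
    "compute_deltas",
    "top_variable_features",
    "screen_bimodal_features",
    "bh_adjust",
    "mode_group_association",
    "make_two_group_vh",
    "make_bimodal_cohort",
    "make_twin_matrix",
    "generate_fixture",
]


# ---------------------------------------------------------------------------
# exploratory summaries
# ---------------------------------------------------------------------------

@dataclass
class EdaSummary:
    """Moment summary plus a bootstrap cloud on the Cullen-Frey plane."""

    n: int
    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float
    cullen_frey: tuple  # (skewness^2, kurtosis) of the sample
    boot_cullen_frey: np.ndarray  # (n_boot, 2) bootstrap points

    def to_record(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "skewness": self.skewness,
            "excess_kurtosis": self.excess_kurtosis,
            "cf_sq_skewness": self.cullen_frey[0],
            "cf_kurtosis": self.cullen_frey[1],
        }


def eda_summary(values, n_boot: int = 100, seed: int = 0) -> EdaSummary:
    """Sample moments and the bootstrapped Cullen-Frey cloud.

    The Cullen-Frey plane plots squared skewness against (raw) kurtosis; the
    bootstrap cloud conveys how uncertain the sample's position is, guiding
    the choice between unimodal families and mixture modelling.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ParameterError("eda_summary needs a 1-d sample with n >= 4")
    if not np.all(np.isfinite(x)):
        raise ParameterError("values must be finite")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("degenerate (constant) sample")
    g1 = float(stats.skew(x, bias=False))
    g2 = float(stats.kurtosis(x, fisher=True, bias=False))
    boot = np.empty((n_boot, 2))
    rng = substream(seed, "eda_boot")
    for b in range(n_boot):
        xb = rng.choice(x, size=x.size, replace=True)
        boot[b, 0] = stats.skew(xb, bias=False) ** 2
        boot[b, 1] = stats.kurtosis(xb, fisher=True, bias=False) + 3.0
    return EdaSummary(
        n=x.size,
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        skewness=g1,
        excess_kurtosis=g2,
        cullen_frey=(g1**2, g2 + 3.0),
        boot_cullen_frey=boot,
    )


# ---------------------------------------------------------------------------
# twin-discordance deltas
# ---------------------------------------------------------------------------

@dataclass
class DeltaMatrix:
    """Features x pairs matrix of cotwin discordance values.

    The sign convention is fixed by the orienting covariate: each column is
    the higher-covariate member's value minus the lower's.  Pairs whose
    covariates tie keep the declared sample order and are flagged.
    """

    deltas: pd.DataFrame  # index: features, columns: pair ids
    pair_info: pd.DataFrame  # index: pair ids; high/low sample, covariates, tie

    @property
    def n_features(self) -> int:
        return self.deltas.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.deltas.shape[1]


def compute_deltas(expr: pd.DataFrame, pair_map, covariate) -> DeltaMatrix:
    """Per-pair discordance: higher-covariate member minus lower.

    ``expr`` is features x samples; ``pair_map`` maps sample -> pair id and
    ``covariate`` maps sample -> orienting value (e.g. BMI).  Every pair must
    have exactly two members, both present in ``expr`` with covariates;
    anything else raises :class:`IncompletePairError`.
    """
    pair_map = pd.Series(dict(pair_map) if not isinstance(pair_map, pd.Series) else pair_map)
    covariate = pd.Series(dict(covariate) if not isinstance(covariate, pd.Series) else covariate)
    samples = list(expr.columns)
    missing = [s for s in samples if s not in pair_map.index]
    if missing:
        raise IncompletePairError(f"samples without a pair id: {missing[:5]}")
    cols, info = {}, []
    for pair_id in pd.unique(pair_map.loc[samples].to_numpy()):
        members = [s for s in samples if pair_map[s] == pair_id]
        if len(members) != 2:
            raise IncompletePairError(
                f"pair {pair_id!r} has {len(members)} member(s); need exactly 2"
            )
        s1, s2 = members  # declared (column) order
        for s in (s1, s2):
            if s not in covariate.index or not np.isfinite(float(covariate[s])):
                raise IncompletePairError(f"sample {s!r} lacks a covariate value")
        c1, c2 = float(covariate[s1]), float(covariate[s2])
        tie = c1 == c2
        if c1 >= c2:
            high, low = s1, s2
        else:
            high, low = s2, s1
        cols[pair_id] = expr[high].to_numpy(float) - expr[low].to_numpy(float)
        info.append(
            {
                "pair": pair_id,
                "high_sample": high,
                "low_sample": low,
                "covariate_high": max(c1, c2),
                "covariate_low": min(c1, c2),
                "tied": tie,
            }
        )
    if any(r["tied"] for r in info):
        warnings.warn(
            f"{sum(r['tied'] for r in info)} pair(s) have tied covariates; "
            "kept declared sample order"
        )
    deltas = pd.DataFrame(cols, index=expr.index)
    pair_info = pd.DataFrame(info).set_index("pair").loc[deltas.columns]
    return DeltaMatrix(deltas=deltas, pair_info=pair_info)


def top_variable_features(deltas: DeltaMatrix, k: int = 4000) -> DeltaMatrix:
    """Keep the k features with the largest SD of delta across pairs.

    The default of 4000 matches the screening depth of the twin analysis
    this recipe reproduces.  Ties are broken by input order (stable sort).
    """
    if k > deltas.n_features:
        raise ParameterError(
            f"k={k} exceeds the {deltas.n_features} available features"
        )
    sds = deltas.deltas.std(axis=1, ddof=1).to_numpy()
    order = np.argsort(-sds, kind="stable")[:k]
    keep = deltas.deltas.index[np.sort(order)]
    return DeltaMatrix(deltas=deltas.deltas.loc[keep], pair_info=deltas.pair_info)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScreenResult:
    """Per-feature outcome of the twin bimodality screen."""

    table: pd.DataFrame  # feature, lrt, p_raw, p_adj, minority_prop, passed, fail_reason
    fdr_level: float
    min_mode_prop: float
    settings: dict = field(default_factory=dict)

    @property
    def passing_features(self) -> list:
        return list(self.table.loc[self.table["passed"], "feature"])


def screen_bimodal_features(
    deltas: DeltaMatrix,
    family: str = "normal",
    n_boot: int = 10_000,
    fdr_level: float = 0.05,
    min_mode_prop: float = 0.10,
    seed: int = 0,
    mode_prop_from: str = "weights",
    min_pairs: int = 10,
    **em_settings,
) -> ScreenResult:
    """Bootstrap-LRT bimodality screen across all features of a delta matrix.

    Each feature's deltas are tested 1-vs-2 components (``n_boot``
    parametric bootstraps; 10,000 matches the reference analysis), p-values
    are Benjamini-Hochberg adjusted across tested features, and features
    whose minority mode holds less than ``min_mode_prop`` of the sample are
    excluded as outlier-driven.  ``mode_prop_from`` chooses between the
    fitted minority weight ("weights", default) and the classified-label
    fraction ("labels").
    """
    if deltas.n_pairs < min_pairs:
        raise ParameterError(
            f"need at least {min_pairs} pairs, have {deltas.n_pairs}"
        )
    if mode_prop_from not in ("weights", "labels"):
        raise ParameterError("mode_prop_from must be 'weights' or 'labels'")
    rows = []
    for idx, (feature, series) in enumerate(deltas.deltas.iterrows()):
        values = series.to_numpy(float)
        try:
            res = bootstrap_lrt(
                values,
                family,
                1,
                2,
                n_boot=n_boot,
                seed=child_seed(seed, "screen", idx),
                **em_settings,
            )
        except VarhetError as exc:
            rows.append(
                {
                    "feature": feature,
                    "lrt": np.nan,
                    "p_raw": np.nan,
                    "minority_prop": np.nan,
                    "failed": True,
                    "fail_detail": str(exc),
                }
            )
            continue
        if res.alt_fit is None:
            minority = np.nan
        elif mode_prop_from == "weights":
            minority = float(np.min(res.alt_fit.weights))
        else:
            from .mixtures import classify_modes

            labels = classify_modes(res.alt_fit)
            counts = np.bincount(labels, minlength=res.alt_fit.k)
            minority = float(counts.min() / counts.sum())
        rows.append(
            {
                "feature": feature,
                "lrt": res.lrt_statistic,
                "p_raw": res.p_value,
                "minority_prop": minority,
                "failed": False,
                "fail_detail": "",
            }
        )
    table = pd.DataFrame(rows)
    ok = ~table["failed"]
    table["p_adj"] = np.nan
    if ok.any():
        table.loc[ok, "p_adj"] = bh_adjust(table.loc[ok, "p_raw"].to_numpy())
    sig = ok & (table["p_adj"] <= fdr_level)
    big_enough = table["minority_prop"] >= min_mode_prop
    table["passed"] = sig & big_enough
    reason = np.where(
        table["failed"],
        "fit_error",
        np.where(~sig, "fdr", np.where(~big_enough, "min_mode", "")),
    )
    table["fail_reason"] = np.where(table["passed"], "", reason)
    table = table[
        [
            "feature",
            "lrt",
            "p_raw",
            "p_adj",
            "minority_prop",
            "passed",
            "fail_reason",
            "fail_detail",
        ]
    ]
    return ScreenResult(
        table=table,
        fdr_level=fdr_level,
        min_mode_prop=min_mode_prop,
        settings={
            "family": family,
            "n_boot": n_boot,
            "seed": seed,
            "mode_prop_from": mode_prop_from,
            **em_settings,
        },
    )


# ---------------------------------------------------------------------------
# mode/outcome association
# ---------------------------------------------------------------------------

def mode_group_association(mode_labels, outcome_labels) -> TestResult:
    """Pearson chi-square (no continuity correction) on the mode x outcome
    cross-tabulation — the downstream check that a marker's modes align with
    an outcome grouping.

    Levels absent from the data are dropped; a warning is issued when any
    expected cell count falls below 5.
    """
    modes = pd.Series(np.asarray(mode_labels), name="mode")
    outcomes = pd.Series(np.asarray(outcome_labels), name="outcome")
    if modes.size != outcomes.size:
        raise ParameterError("label vectors must have equal length")
    tab = pd.crosstab(modes, outcomes)
    # crosstab drops absent levels already; guard against degenerate margins
    tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise DegenerateDataError(
            "need at least 2 observed levels in each label vector"
        )
    res = stats.chi2_contingency(tab.to_numpy(), correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn(
            "some expected cell counts are < 5; the chi-square approximation "
            "may be poor"
        )
    return TestResult(
        method="chi_square",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        extras={
            "dof": int(res.dof),
            "table": tab,
            "expected": res.expected_freq,
        },
    )


# ---------------------------------------------------------------------------
# synthetic fixtures (stand-ins for the controlled-access cohorts)
# ---------------------------------------------------------------------------

def make_two_group_vh(
    n1: int = 100,
    n2: int = 100,
    baseline: DistributionSpec | None = None,
    effect: EffectSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-group table (columns ``group``, ``value``) with a mean/SD effect.

    Defaults: standard-normal baseline, SD doubled in the second group —
    a variance-only alternative at the center of the two-group design grid.
    """
    baseline = baseline or DistributionSpec("normal", {"mean": 0.0, "sd": 1.0})
    effect = effect or EffectSpec(mean_effect=0.0, variance_effect=2.0)
    rng = substream(seed, "fixture_two_group")
    g1 = sample(baseline, n1, rng)
    g2 = sample(apply_effect(baseline, effect), n2, rng)
    return pd.DataFrame(
        {
            "group": ["g1"] * n1 + ["g2"] * n2,
            "value": np.concatenate([g1, g2]),
        }
    )


def make_bimodal_cohort(
    n: int = 470,
    spec: MixtureSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Single-cohort values from a two-component mixture plus true labels.

    Defaults emulate a bimodal expression marker in a several-hundred-patient
    cohort: log expression with modes 1.55 apart on the log scale (about a
    4.7-fold difference in expression between modes), minority weight 0.28.
    """
    spec = spec or MixtureSpec(
        [
            DistributionSpec("normal", {"mean": 0.0, "sd": 0.5}),
            DistributionSpec("normal", {"mean": 1.548, "sd": 0.5}),
        ],
        [0.72, 0.28],
    )
    values, labels = sample_mixture(spec, n, substream(seed, "fixture_cohort"))
    return pd.DataFrame({"value": values}), labels


def make_twin_matrix(
    n_pairs: int = 146,
    n_features: int = 4000,
    n_bimodal: int = 292,
    separation_sd: float = 4.0,
    minority_low: float = 0.10,
    minority_high: float = 0.50,
    feature_sd_log_sd: float = 0.3,
    seed: int = 0,
) -> tuple[DeltaMatrix, pd.DataFrame]:
    """Features x pairs delta matrix with a planted bimodal minority.

    Null features are unimodal around zero with heterogeneous per-feature
    SDs; planted features are two-component normal mixtures centered at zero
    overall, with modes ``separation_sd`` within-mode SDs apart and a
    minority-mode weight drawn uniformly from
    [``minority_low``, ``minority_high``].  Defaults mirror the twin screen's
    dimensions (146 pairs, 4000 genes, 292 bimodal).
    """
    if n_bimodal > n_features:
        raise ParameterError("n_bimodal cannot exceed n_features")
    rng = substream(seed, "fixture_twins")
    feature_ids = [f"gene_{i+1:05d}" for i in range(n_features)]
    pair_ids = [f"pair_{j+1:04d}" for j in range(n_pairs)]
    sigma = np.exp(rng.normal(0.0, feature_sd_log_sd, size=n_features))
    bimodal_idx = np.sort(rng.choice(n_features, size=n_bimodal, replace=False))
    is_bimodal = np.zeros(n_features, dtype=bool)
    is_bimodal[bimodal_idx] = True

    X = rng.normal(0.0, 1.0, size=(n_features, n_pairs)) * sigma[:, None]
    w_minor = np.full(n_features, np.nan)
    for i in bimodal_idx:
        w = rng.uniform(minority_low, minority_high)
        w_minor[i] = w
        delta = separation_sd * sigma[i]
        # zero-mean mixture: minority at delta*(1-w), majority at -delta*w
        mu_minor, mu_major = delta * (1.0 - w), -delta * w
        minor = rng.random(n_pairs) < w
        X[i] = rng.normal(0.0, sigma[i], size=n_pairs)
        X[i, minor] += mu_minor
        X[i, ~minor] += mu_major
        if rng.random() < 0.5:  # random orientation of the minority mode
            X[i] = -X[i]
    deltas = pd.DataFrame(X, index=feature_ids, columns=pair_ids)
    pair_info = pd.DataFrame(
        {
            "high_sample": [f"{p}_high" for p in pair_ids],
            "low_sample": [f"{p}_low" for p in pair_ids],
            "covariate_high": np.nan,
            "covariate_low": np.nan,
            "tied": False,
        },
        index=pd.Index(pair_ids, name="pair"),
    )
    truth = pd.DataFrame(
        {
            "feature": feature_ids,
            "is_bimodal": is_bimodal,
            "minority_weight": w_minor,
            "sigma": sigma,
            "separation_sd": np.where(is_bimodal, separation_sd, np.nan),
        }
    )
    return DeltaMatrix(deltas=deltas, pair_info=pair_info), truth


def generate_fixture(kind: str, out_dir, seed: int = 0, params: dict | None = None):
    """Write a synthetic fixture of the given kind to ``out_dir``.

    Kinds: ``two_group_vh`` (group/value CSV), ``bimodal_cohort``
    (single-column CSV + true-label CSV), ``twin_matrix`` (features x pairs
    delta CSV + planted-feature manifest CSV).  Same seed, same parameters:
    byte-identical files.  Returns the list of paths written.
    """
    params = dict(params or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if kind == "two_group_vh":
        df = make_two_group_vh(seed=seed, **params)
        path = out_dir / "two_group_vh.csv"
        df.to_csv(path, index=False)
        written.append(path)
    elif kind == "bimodal_cohort":
        df, labels = make_bimodal_cohort(seed=seed, **params)
        path = out_dir / "bimodal_cohort.csv"
        df.to_csv(path, index=False)
        lab_path = out_dir / "bimodal_cohort_labels.csv"
        pd.DataFrame({"label": labels}).to_csv(lab_path, index=False)
        written += [path, lab_path]
    elif kind == "twin_matrix":
        dm, truth = make_twin_matrix(seed=seed, **params)
        path = out_dir / "twin_deltas.csv"
        dm.deltas.to_csv(path, index_label="feature")
        truth_path = out_dir / "twin_truth.csv"
        truth.to_csv(truth_path, index=False)
        written += [path, truth_path]
    else:
        raise ParameterError(f"unknown fixture kind {kind!r}")
    manifest = {
        "kind": kind,
        "seed": seed,
        "params": {k: repr(v) for k, v in params.items()},
        "files": [p.name for p in written],
    }
    man_path = out_dir / f"{kind}_manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(man_path)
    return written
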