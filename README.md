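# varhet

Variance-heterogeneity and bimodality analysis for biomedical data, with a
Monte-Carlo power engine for study design.

## Why

Standard pipelines compare group *means* and treat everything else as noise.
But when a biomarker's spread differs between groups, or a cohort's
distribution splits into two modes, that "noise" is often structure: latent
patient subgroups with different prognosis or treatment response. `varhet`
makes that structure testable:

* **Two-group dispersion tests** — permutation tests on the standard
  deviation, the median absolute deviation (MAD), or Gini's mean difference
  (GMD), using the scale-free statistic `T = |log(D1/D2)|` with the add-one
  permutation p-value, plus Levene/Brown-Forsythe, ANOVA/Welch, and the
  two-sample Kolmogorov-Smirnov test behind one interface.
* **Bimodality tests** — the parametric-bootstrap likelihood-ratio test for
  1 vs 2 mixture components (normal, lognormal, Weibull; EM with quantile
  initialization and restarts), Hartigan's dip test with a Monte-Carlo
  uniform null, and the bimodality coefficient
  `BC = (g1² + 1)/(g2 + 3(n−1)²/((n−2)(n−3)))` with its 5/9 uniform
  benchmark.
* **Power / FPR engine** — simulate any of the above under a parametric
  design (mean shift + SD fold-change between two groups; mixtures within or
  between cohorts) across a sample-size grid, or estimate power empirically
  by bootstrapped subsampling of pilot data.
* **Applied recipes** — Cullen-Frey exploratory summaries, mixture-mode
  classification with a chi-square mode/outcome association, and a
  genome-scale monozygotic-twin discordance screen (per-gene deltas oriented
  by a covariate such as BMI, bootstrap-LRT bimodality, Benjamini-Hochberg
  FDR, minority-mode filter).

See `docs/methods.md` for the statistical details and design decisions.

## Worked example

Detecting a variance effect between two groups, then dissecting a bimodal
marker in a single cohort:

```python
import numpy as np
from varhet import (DistributionSpec, EffectSpec, SampleSet, apply_effect,
                    sample, permutation_dispersion_test, bootstrap_lrt,
                    classify_modes, mode_group_association)

# -- two groups, same mean, doubled SD -----------------------------------
baseline = DistributionSpec("normal", {"mean": 10.0, "sd": 1.0})
wide = apply_effect(baseline, EffectSpec(mean_effect=0.0, variance_effect=2.0))
g1, g2 = sample(baseline, 80, seed=1), sample(wide, 80, seed=2)
data = SampleSet(np.concatenate([g1, g2]), np.repeat(["ctrl", "case"], 80))
res = permutation_dispersion_test(data, metric="gini", n_perm=1000, seed=3)
print(f"perm-GiniMD: T = {res.statistic:.3f}, p = {res.p_value:.4f}")

# -- one cohort, bimodal log-expression marker ---------------------------
from varhet.workflows import make_bimodal_cohort
expr = make_bimodal_cohort(n=470, seed=4)[0]["value"].to_numpy()
lrt = bootstrap_lrt(expr, "normal", k0=1, k1=2, n_boot=100, seed=5)
print(f"bootstrap LRT (1 vs 2 components): LRT = {lrt.lrt_statistic:.1f}, "
      f"p = {lrt.p_value:.4f}")
fit = lrt.alt_fit
mus = [c.params["mean"] for c in fit.components]
print(f"fitted modes at {mus[0]:.2f} and {mus[1]:.2f} "
      f"(weights {fit.weights[0]:.2f}/{fit.weights[1]:.2f}) -> "
      f"{np.exp(mus[1] - mus[0]):.1f}-fold separation on the natural scale")
modes = classify_modes(fit)  # most-probable mode per patient
```

Output:

```
perm-GiniMD: T = 0.888, p = 0.0010
bootstrap LRT (1 vs 2 components): LRT = 70.8, p = 0.0099
fitted modes at -0.03 and 1.52 (weights 0.68/0.32) -> 4.7-fold separation on the natural scale
```

The permutation test rejects equality of spread (the case group's Gini mean
difference is e^0.888 ≈ 2.4 times the control's; p is the smallest value
1000 permutations can produce). In the cohort, the 2-component model beats
the 1-component model by 70.8 log-likelihood-ratio units — none of the 100
parametric bootstraps from the unimodal null comes close (p = 1/101) — and
the fitted modes sit 1.55 apart on the log scale, a 4.7-fold difference in
expression, with a 32% minority mode. `classify_modes` then gives each
patient's most probable mode, which `mode_group_association` can
cross-tabulate against an outcome grouping (chi-square, no continuity
correction).

Power for designing such a study, from the command line:

```bash
varhet power --config design.yaml --out power.csv   # design.yaml: baseline,
                                                    # effect, test, n grid
varhet fixture twin_matrix --seed 1 --out-dir fx    # synthetic twin deltas
varhet screen-twins --deltas fx/twin_deltas.csv --n-boot 200 --out-dir out
```

Other CLI verbs: `eda`, `test`, `bimodality`. Every run writes tidy CSV plus
a JSON manifest (settings + seed) and is byte-reproducible.

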