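# Methods

This note documents the statistical machinery in `varhet`: the models and
test statistics, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical decisions that
affect results.

## Problem setting

Biomedical cohorts are routinely analysed as if each group were a single
homogeneous population. When a measurement's *spread* differs between groups
(variance heterogeneity), or a single cohort's distribution has more than one
mode, that structure often marks latent subpopulations — treatment-response
subgroups, molecular endotypes — rather than noise. `varhet` provides

1. two-group tests for differences in dispersion and in location,
2. one-group bimodality tests,
3. a Monte-Carlo engine that estimates the power and false-positive rate
   (FPR) of any of those tests under a parametric study design, and
4. applied recipes: exploratory triage, mode/outcome association, and a
   genome-scale twin-discordance bimodality screen.

## Distribution layer

Four families cover the package's use cases: **normal** (symmetric noise),
**lognormal** (right-skewed positive measurements; `meanlog`/`sdlog` are the
parameters of log X), **Weibull** (shape/scale; survival-type times), and
**beta** (alpha/beta; bounded proportions such as methylation beta-values).
Moments come from the families' closed forms (verified in the test suite
against numerical integration of the density to 1e-6 relative error).

**Effect parameterization.** A comparison group is derived from a baseline by
`EffectSpec(mean_effect, variance_effect)`: an additive shift of the
natural-scale mean and a multiplicative fold-change of the *standard
deviation* (so `variance_effect=1` is the identity on both the SD and the
variance scale; the SD convention matches the "fold-change in spread"
reading of a variance effect). The family's parameters are re-solved from
the requested (mean, sd): directly for the normal; by the closed-form
inversions for lognormal (`sdlog^2 = log(1 + cv^2)`) and beta
(`nu = m(1-m)/v - 1`); for the Weibull by solving the CV equation for the
shape with a bracketed root finder (`brentq` on the log-CV, bracket
[1e-3, 1e4]). Requests outside a family's feasible set (non-positive Weibull
mean, beta variance at or above `m(1-m)`) raise an error; nothing is
silently clipped.

**Single-component MLE.** Normal and lognormal are closed form; Weibull uses
Newton on the profile shape equation with a bisection fallback; beta uses
Newton on the digamma score equations from a method-of-moments start with a
Nelder-Mead fallback. The fitted log-likelihood is checked against the
moment-matched start in the tests.

## Dispersion tests

The package's dispersion metrics are the standard deviation, the median
absolute deviation (MAD; the raw metric by default, with the conventional
1.4826 normal-consistency factor available as a flag — the factor cancels in
the ratio statistic below), and Gini's mean difference
(GMD = mean |x_i - x_j| over unordered pairs), computed in O(n log n) via
the sorted-order identity `GMD = 2/(n(n-1)) * sum_i (2i - n - 1) x_(i)`.

The **permutation dispersion test** compares two groups with

    T = | log( D_1 / D_2 ) |

where `D_g` is the chosen metric in group g. The log-ratio is symmetric in
the groups and scale-free (multiplying all data by c > 0 changes nothing),
which removes the arbitrary choice between "difference of spreads" and
"ratio of spreads". Group labels are permuted B times (default 1000) and the
p-value uses the add-one rule `p = (1 + #{T* >= T})/(B + 1)`, which is a
valid p-value under exchangeability and can never be exactly zero. If one
group has zero dispersion it is mapped to a tiny positive floor
(1e-12 x pooled SD) with a warning so the log stays finite while the
extremeness ordering is preserved; two zero-dispersion groups are an error.

Classical wrappers share the same interface: Levene (mean-centered) /
Brown-Forsythe (median-centered) via the one-way ANOVA F on absolute
deviations, one-way ANOVA and Welch's t for means, a permutation test on
|mean_1 - mean_2|, and the two-sample Kolmogorov-Smirnov test (scipy's
`auto` convention: exact small-sample distribution where feasible,
asymptotic otherwise).

## Mixture layer

K-component mixtures (normal, lognormal, Weibull) are fitted by EM.

* **E-step**: Bayes responsibilities from the current parameters.
* **M-step**: weighted MLE per component — closed form for the normal;
  for the Weibull, Newton on the weighted profile shape equation
  (warm-started at the previous shape, data pre-normalized by the sample
  maximum so `x^k` cannot overflow; the solver's stationarity is asserted to
  |score| < 1e-8 in the tests).
* **Lognormal = normal on logs**, exactly: weights and posteriors coincide,
  log-likelihoods differ by the fixed Jacobian `sum(log x)`, parameters map
  by exp/log. The whole pipeline (including bootstrap p-values at matched
  seeds) inherits this equivalence. For this reason lognormal components are
  ordered by `meanlog` (the Gaussian order on logs); normal components by
  mean and Weibull components by their distribution mean.
* **Initialization**: quantile blocks (component j from the j-th block of
  the sorted data) by default — deterministic and robust on skewed data —
  with a 1-d k-means refinement available; restarts beyond the first seed
  component locations at random data points. Default 5 restarts, tolerance
  1e-8 on the relative log-likelihood change, at most 1000 iterations.
* **Degeneracy**: the mixture likelihood is unbounded when a component
  collapses onto a point, so component SDs are floored at 1e-6 x SD(data)
  and weights at 1e-4; a restart that hits either floor is discarded. If
  every restart collapses, `em_fit` raises.

The EM inner loops are JIT-compiled (numba) with a pure-Python fallback;
bootstrap replicates are fitted in batches. The log-likelihood trace is
recorded and its monotonicity asserted in the tests.

**Bootstrap likelihood-ratio test** (K0 vs K1 components, default 1 vs 2):
fit both models, then simulate `n_boot` datasets of the observed size from
the fitted K0 model and refit both models on each, giving the null reference
for `LRT = 2 (l1 - l0)`; `p = (1 + #{LRT* >= LRT_obs})/(n_boot + 1)`. Small
negative LRTs from local optima are clamped to zero with a warning.
Replicates whose refits collapse are redrawn a bounded number of times, then
dropped with a warning. If the observed K1 fit collapses on every restart
(even after an automatic escalation to extra random restarts), the richer
model offers nothing beyond the null on these data and the test reports
LRT = 0, p = 1. Weibull mixtures treat the data as exact (uncensored)
observations; applying them to survival times ignores censoring, which
mirrors how such mixtures are used for mode discovery rather than hazard
estimation.

`classify_modes` assigns each observation to its highest-posterior
component (ties to the lower-mean component); `bic` uses
`-2 l + p log n` with `p = (K-1) + 2K`.

## Non-mixture bimodality detectors

**Bimodality coefficient**: `BC = (g1^2 + 1) / (g2 + 3(n-1)^2/((n-2)(n-3)))`
with bias-adjusted sample skewness `g1` and excess kurtosis `g2`. BC is
affine-invariant; its uniform benchmark 5/9 is reported alongside the
statistic and never silently converted into a p-value (in the power engine,
"rejection" for BC means exceeding 5/9, and that convention is labelled).

**Hartigan-Hartigan dip**: the sup-norm distance from the ECDF to the
nearest unimodal CDF, computed by the classical iterative greatest-convex-
minorant / least-concave-majorant algorithm with the modern `1/(2n)`
lower-bound convention. The implementation is validated against an
independent linear-programming oracle (exact minimization over unimodal
piecewise-linear CDFs, including an atom at the mode, which the unimodal
class admits — this is why heavily tied data can have small dips). The dip
test's null is Monte-Carlo sampling from the uniform (default 2000 draws),
the standard calibration distribution: transparent, seed-reproducible, and
exact on the uniform, at the cost of conservativeness on lighter-tailed
unimodal data such as the normal (measured FPR about 0.005 at nominal 0.05,
n = 50). Silverman's critical-bandwidth and excess-mass tests are natural
extension points but are not part of the core.

## Power engine

`estimate_power` simulates `n_sim` datasets per sample size under a
`PowerDesign` — two unimodal groups linked by an `EffectSpec`
(`two_group`), one cohort from a mixture (`one_group_bimodality`), or two
cohorts from two mixtures (`two_group_mixture`) — applies the chosen test,
and reports the rejection proportion (`p <= alpha`) with a Wilson 95%
interval. With an identity effect the same number *is* the FPR; one engine,
two labels. Defaults mirror the reference analyses: sample-size grid
{40, 50, 60, 70, 80, 90, 100}, 1000 simulations, alpha = 0.05, 100
bootstraps inside the mixture LRT.

Seeding: every (design, test, n, replicate) tuple draws from its own
substream of the root seed (SHA-256-keyed `SeedSequence` spawn keys), so
results are independent of evaluation order and adding sample sizes or
replicates never changes existing rows. Replicates are therefore trivially
parallelizable, though the engine runs them serially.

`empirical_power_subsample` estimates power without distributional
assumptions by drawing with-replacement resamples of the target size from a
pilot dataset and applying the test. With-replacement resampling (rather
than subsampling without replacement) keeps targets at or above the pilot
size meaningful; a warning is emitted when a target exceeds the pilot.
The engine's self-consistency check mirrors how a pilot-based study design
actually runs: fit the mixture to the pilot, drive the parametric simulation
with the fitted parameters, and compare with subsampling the same pilot.
The two estimates are asserted to agree within ±0.1 at every grid size in
the acceptance tests (the measured gap is well below that).

## Applied recipes

**EDA**: sample moments plus a bootstrapped cloud of (skewness², kurtosis)
points on the Cullen-Frey plane, the usual triage for choosing between
unimodal families and mixture modelling.

**Mode/outcome association**: cross-tabulate mixture-mode labels against an
outcome grouping and apply Pearson's chi-square without continuity
correction (hand-verifiable; Yates' correction available as a flag), warning
when expected cell counts fall below 5.

**Twin-discordance screen**: for each feature (gene), the discordance
`delta = value in the higher-covariate twin minus the lower` is computed per
monozygotic pair (ties keep the declared sample order and are flagged;
incomplete pairs are an error). Features are optionally restricted to the
k = 4000 most variable (SD of delta across pairs), each is tested 1-vs-2
components with the normal-family bootstrap LRT (default 10,000 bootstraps,
matching the screening depth of the reference analysis), p-values are
Benjamini-Hochberg adjusted at FDR 5%, and features whose minority mode
holds less than 10% of the sample are excluded as outlier-driven. The
minority-mode filter uses the fitted minority *weight* by default — the most
direct reading of "a mode comprising less than 10% of samples" — with the
classified-label fraction available as an option. The screen's downstream
survival analyses (Kaplan-Meier, log-rank) are out of scope; the recipe ends
at mode classification and the chi-square association.

## Synthetic data generator

The generator produces the three study shapes the analyses expect, and its
defaults are the package's reference conditions:

* `two_group_vh`: a group/value table; default standard-normal baseline with
  the SD doubled in the second group (n = 100 per group).
* `bimodal_cohort`: one cohort (default n = 470, a typical large trial
  cohort) whose marker is a two-component normal mixture on the log scale —
  modes 1.548 apart (about a 4.7-fold expression difference between modes),
  SD 0.5 within mode, minority weight 0.28 — emulating a bimodal prognostic
  marker. True component labels are written alongside.
* `twin_matrix`: a features x pairs delta matrix (defaults 4000 x 146 with
  292 planted bimodal features). Null features are centered normals with
  per-feature SDs drawn lognormally (sdlog 0.3), so variability ranking is
  non-trivial; planted features are zero-mean two-component mixtures with
  modes 4 within-mode SDs apart, minority weight uniform on [0.1, 0.5], and
  random mode orientation. A truth table lists exactly the planted features.

What the generator deliberately does **not** emulate: count-level
normalization (expression is assumed pre-normalized/logged on input),
gene-gene correlation (features are independent, so the FDR behaviour shown
under independence is an idealization), batch effects, missingness, and
censoring in survival-like values. Passing tests on these fixtures
demonstrate that the machinery is correct and calibrated under its stated
model, not that any particular real dataset satisfies that model.

## Desk-scale problem sizes

The test suite and `scripts/acceptance.py` run every Monte-Carlo study at
sizes chosen so the whole suite completes in well under half an hour on one
CPU, while keeping the statistical assertions meaningful: 1000 null
replicates for calibration bands (the exact binomial 99% band at
alpha = 0.05), 200 permutations / 100 LRT bootstraps when resampling nests
inside simulation, 200-400 replicates for power points, a 500-feature twin
screen with 200 bootstraps, and EM at one quantile restart with tolerance
1e-6 and 200 iterations inside simulations (the observed-data fits in the
applied recipes keep the full defaults). The acceptance script reports
calibration at 500 null replicates.

## Known limitations

* The bootstrap LRT's p-value resolution is `1/(n_boot+1)`; genome-scale
  FDR control at 5% therefore needs `n_boot` large enough that the smallest
  achievable adjusted p clears the BH threshold (hence 10,000 in the
  reference screen, 200 at desk scale with 500 features).
* EM finds local optima; the quantile start plus random restarts is robust
  for well-separated two-component problems but K > 2 on overlapping
  components may need more restarts.
* The dip test inherits the uniform null's conservativeness on sub-uniform
  tails; it is the right default only when no family can be trusted.
* Weibull mixtures ignore censoring (see above).
* The chi-square association assumes independent observations and enough
  expected counts; it warns, but does not switch to an exact test.
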