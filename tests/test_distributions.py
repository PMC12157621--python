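import numpy as np
import pytest
from scipy import integrate, stats

from varhet.distributions import (
    DistributionSpec,
    EffectSpec,
    MixtureSpec,
    apply_effect,
    fit_single,
    log_likelihood,
    moments,
    sample,
    sample_mixture,
)
from varhet.exceptions import (
    DegenerateDataError,
    InfeasibleEffectError,
    ParameterError,
    SupportError,
)

SPECS = [
    DistributionSpec("normal", {"mean": -1.5, "sd": 2.0}),
    DistributionSpec("lognormal", {"meanlog": 0.3, "sdlog": 0.6}),
    DistributionSpec("weibull", {"shape": 2.0, "scale": 3.0}),
    DistributionSpec("beta", {"alpha": 2.0, "beta": 5.0}),
]


class TestSpecValidation:
    @pytest.mark.parametrize(
        "family,params",
        [
            ("normal", {"mean": 5, "sd": 0}),
            ("normal", {"mean": 5, "sd": -1}),
            ("weibull", {"shape": -2, "scale": 1}),
            ("weibull", {"shape": 1, "scale": 0}),
            ("beta", {"alpha": 0, "beta": 2}),
            ("lognormal", {"meanlog": 0, "sdlog": 0}),
        ],
    )
    def test_nonpositive_scale_params_rejected(self, family, params):
        with pytest.raises(ParameterError):
            DistributionSpec(family, params)

    def test_unknown_family_rejected(self):
        with pytest.raises(ParameterError):
            DistributionSpec("gamma", {"shape": 1, "scale": 1})

    def test_config_roundtrip(self):
        for spec in SPECS:
            assert DistributionSpec.from_config(spec.to_config()) == spec


class TestMoments:
    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.family)
    def test_matches_numerical_integration(self, spec):
        """Closed-form moments agree with direct density integration."""
        frozen = spec.frozen()
        a, b = frozen.support()
        # integrate in three pieces (bulk plus both tails to the support
        # limits) so heavy tails keep their 4th-moment mass
        cuts = [a, frozen.ppf(0.001), frozen.ppf(0.999), b]
        raw = [
            sum(
                integrate.quad(
                    lambda x, k=k: x**k * frozen.pdf(x), lo, hi, limit=500
                )[0]
                for lo, hi in zip(cuts[:-1], cuts[1:])
            )
            for k in range(1, 5)
        ]
        mean = raw[0]
        var = raw[1] - mean**2
        mu3 = raw[2] - 3 * mean * raw[1] + 2 * mean**3
        mu4 = raw[3] - 4 * mean * raw[2] + 6 * mean**2 * raw[1] - 3 * mean**4
        expected = (mean, var, mu3 / var**1.5, mu4 / var**2 - 3.0)
        got = moments(spec)
        assert np.allclose(got, expected, rtol=1e-6, atol=1e-8)

    def test_gaussian_moments_exact(self):
        assert moments(DistributionSpec("normal", {"mean": 2.5, "sd": 3.0})) == (
            2.5,
            9.0,
            0.0,
            0.0,
        )

    def test_exponential_special_case(self):
        # weibull with shape 1 is exponential: mean=scale, var=scale^2, skew=2
        m, v, s, _ = moments(DistributionSpec("weibull", {"shape": 1, "scale": 1}))
        assert np.allclose([m, v, s], [1.0, 1.0, 2.0], rtol=1e-9)

    def test_symmetric_beta_has_zero_skewness(self):
        assert moments(DistributionSpec("beta", {"alpha": 3, "beta": 3}))[2] == pytest.approx(0.0, abs=1e-12)


class TestSampling:
    def test_large_sample_moments_normal(self):
        x = sample(DistributionSpec("normal", {"mean": 0, "sd": 1}), 100_000, 5)
        assert abs(x.mean()) < 0.02
        assert abs(x.std(ddof=1) - 1.0) < 0.02

    def test_large_sample_mean_exponential(self):
        x = sample(DistributionSpec("weibull", {"shape": 1, "scale": 2}), 100_000, 6)
        assert abs(x.mean() - 2.0) < 0.03

    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.family)
    def test_support_and_reproducibility(self, spec):
        x1 = sample(spec, 5000, 11)
        x2 = sample(spec, 5000, 11)
        assert np.array_equal(x1, x2)
        lo, hi = spec.support
        assert np.all(x1 > lo) and np.all(x1 < hi)
        assert np.all(np.isfinite(x1))
        # different seeds: same distribution (KS), different draws
        x3 = sample(spec, 10_000, 12)
        x4 = sample(spec, 10_000, 13)
        assert not np.array_equal(x3[: x1.size], x1)
        assert stats.ks_2samp(x3, x4).pvalue > 0.001

    def test_n_must_be_positive(self):
        with pytest.raises(ParameterError):
            sample(SPECS[0], 0, 1)


class TestMixtures:
    def test_degenerate_single_component_matches_sample(self):
        spec = DistributionSpec("normal", {"mean": 1, "sd": 2})
        mix = MixtureSpec([spec], [1.0])
        vm, labels = sample_mixture(mix, 10_000, 3)
        assert np.all(labels == 0)
        assert stats.ks_2samp(vm, sample(spec, 10_000, 4)).pvalue > 0.001

    def test_label_frequencies_match_weights(self):
        mix = MixtureSpec(
            [
                DistributionSpec("normal", {"mean": 0, "sd": 1}),
                DistributionSpec("normal", {"mean": 5, "sd": 1}),
            ],
            [0.5, 0.5],
        )
        _, labels = sample_mixture(mix, 10_000, 21)
        assert abs(labels.mean() - 0.5) < 0.015

    def test_sample_mean_matches_mixture_moment(self):
        mix = MixtureSpec(
            [
                DistributionSpec("normal", {"mean": 0, "sd": 1}),
                DistributionSpec("normal", {"mean": 5, "sd": 1}),
            ],
            [0.3, 0.7],
        )
        v, _ = sample_mixture(mix, 20_000, 22)
        se = np.sqrt(mix.var() / v.size)
        assert abs(v.mean() - mix.mean()) < 3 * se

    def test_components_sorted_by_mean(self):
        mix = MixtureSpec(
            [
                DistributionSpec("normal", {"mean": 5, "sd": 1}),
                DistributionSpec("normal", {"mean": 0, "sd": 1}),
            ],
            [0.7, 0.3],
        )
        assert mix.components[0].params["mean"] == 0
        assert mix.weights == (0.3, 0.7)

    def test_weights_validation(self):
        comps = [DistributionSpec("normal", {"mean": 0, "sd": 1})] * 2
        with pytest.raises(ParameterError):
            MixtureSpec(comps, [0.5, 0.6])
        with pytest.raises(ParameterError):
            MixtureSpec([], [])


class TestApplyEffect:
    def test_normal_is_direct(self):
        spec = DistributionSpec("normal", {"mean": 0, "sd": 1})
        out = apply_effect(spec, EffectSpec(1.0, 2.0))
        assert out.params == {"mean": 1.0, "sd": 2.0}

    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.family)
    def test_identity_preserves_moments(self, spec):
        out = apply_effect(spec, EffectSpec(0.0, 1.0))
        m0, v0, _, _ = moments(spec)
        m1, v1, _, _ = moments(out)
        assert m1 == pytest.approx(m0, rel=1e-9)
        assert np.sqrt(v1) == pytest.approx(np.sqrt(v0), rel=1e-9)

    def test_weibull_sd_fold_change(self):
        spec = DistributionSpec("weibull", {"shape": 2, "scale": 1})
        out = apply_effect(spec, EffectSpec(0.0, 1.5))
        _, v0, _, _ = moments(spec)
        m1, v1, _, _ = moments(out)
        assert np.sqrt(v1) == pytest.approx(1.5 * np.sqrt(v0), rel=1e-9)
        assert m1 == pytest.approx(moments(spec)[0], rel=1e-9)

    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.family)
    @pytest.mark.parametrize("effect", [EffectSpec(0.05, 1.25), EffectSpec(-0.02, 0.8)])
    def test_requested_moments_recovered(self, spec, effect):
        """apply_effect then moments() returns the requested mean and sd."""
        m0, v0, _, _ = moments(spec)
        out = apply_effect(spec, effect)
        m1, v1, _, _ = moments(out)
        assert m1 == pytest.approx(m0 + effect.mean_effect, rel=1e-6, abs=1e-9)
        assert np.sqrt(v1) == pytest.approx(
            np.sqrt(v0) * effect.variance_effect, rel=1e-6
        )

    def test_infeasible_effects_raise(self):
        weib = DistributionSpec("weibull", {"shape": 2, "scale": 1})
        with pytest.raises(InfeasibleEffectError):
            apply_effect(weib, EffectSpec(mean_effect=-5.0))  # nonpositive mean
        bet = DistributionSpec("beta", {"alpha": 2, "beta": 2})
        with pytest.raises(InfeasibleEffectError):
            apply_effect(bet, EffectSpec(variance_effect=3.0))  # var > m(1-m)
        logn = DistributionSpec("lognormal", {"meanlog": 0, "sdlog": 1})
        with pytest.raises(InfeasibleEffectError):
            apply_effect(logn, EffectSpec(mean_effect=-10.0))


class TestFitSingle:
    def test_weibull_parameter_recovery(self):
        spec = DistributionSpec("weibull", {"shape": 2, "scale": 3})
        x = sample(spec, 5000, 17)
        fit = fit_single(x, "weibull")
        assert fit.params["shape"] == pytest.approx(2.0, rel=0.05)
        assert fit.params["scale"] == pytest.approx(3.0, rel=0.05)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_single(np.full(20, 3.0), "normal")

    def test_lognormal_is_normal_on_logs(self):
        x = sample(DistributionSpec("lognormal", {"meanlog": 1, "sdlog": 0.5}), 500, 2)
        ln = fit_single(x, "lognormal")
        nm = fit_single(np.log(x), "normal")
        assert ln.params["meanlog"] == pytest.approx(nm.params["mean"], abs=1e-12)
        assert ln.params["sdlog"] == pytest.approx(nm.params["sd"], abs=1e-12)

    def test_support_violations_raise(self):
        with pytest.raises(SupportError):
            fit_single(np.array([-1.0, 1, 2, 3, 4]), "weibull")
        with pytest.raises(SupportError):
            fit_single(np.array([0.1, 0.2, 0.5, 1.2, 0.3]), "beta")

    @pytest.mark.parametrize("family", ["weibull", "beta"])
    def test_loglik_at_fit_beats_moment_start(self, family):
        """The MLE must dominate the moment-matched starting point."""
        true = {
            "weibull": DistributionSpec("weibull", {"shape": 1.7, "scale": 2.0}),
            "beta": DistributionSpec("beta", {"alpha": 2.0, "beta": 6.0}),
        }[family]
        x = sample(true, 400, 23)
        fit = fit_single(x, family)
        m, s = x.mean(), x.std(ddof=0)
        m0, v0, _, _ = moments(true)
        start = apply_effect(true, EffectSpec(m - m0, s / np.sqrt(v0)))
        assert log_likelihood(x, fit) >= log_likelihood(x, start) - 1e-9

    @pytest.mark.parametrize("family", ["normal", "lognormal", "weibull", "beta"])
    def test_consistency_error_shrinks_with_n(self, family):
        """Median absolute parameter error decreases over n=200 -> 2000 -> 20000."""
        true = {
            "normal": DistributionSpec("normal", {"mean": 1.0, "sd": 2.0}),
            "lognormal": DistributionSpec("lognormal", {"meanlog": 0.5, "sdlog": 0.7}),
            "weibull": DistributionSpec("weibull", {"shape": 2.0, "scale": 3.0}),
            "beta": DistributionSpec("beta", {"alpha": 2.0, "beta": 5.0}),
        }[family]
        names = list(true.params)
        med_errs = []
        for n in (200, 2000, 20000):
            errs = []
            for seed in range(50):
                x = sample(true, n, 1000 + seed)
                fit = fit_single(x, family)
                errs.append(
                    [abs(fit.params[p] - true.params[p]) for p in names]
                )
            med_errs.append(np.median(np.array(errs), axis=0))
        med_errs = np.array(med_errs)
        assert np.all(med_errs[1] < med_errs[0])
        assert np.all(med_errs[2] < med_errs[1])
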