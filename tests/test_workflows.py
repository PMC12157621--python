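import json

import numpy as np
import pandas as pd
import pytest

from varhet.exceptions import (
    DegenerateDataError,
    IncompletePairError,
    ParameterError,
)
from varhet.workflows import (
    bh_adjust,
    compute_deltas,
    eda_summary,
    generate_fixture,
    make_bimodal_cohort,
    make_twin_matrix,
    mode_group_association,
    screen_bimodal_features,
    top_variable_features,
)

from _oracles import bh_stepup_byhand


def small_expr():
    # 3 features x 4 samples = 2 twin pairs
    expr = pd.DataFrame(
        {
            "s1": [2.0, 1.0, 0.0],
            "s2": [3.5, 0.5, 0.0],
            "s3": [1.0, 2.0, 1.0],
            "s4": [0.0, 5.0, 1.0],
        },
        index=["gA", "gB", "gC"],
    )
    pairs = {"s1": "p1", "s2": "p1", "s3": "p2", "s4": "p2"}
    bmi = {"s1": 22.0, "s2": 30.0, "s3": 28.0, "s4": 24.0}
    return expr, pairs, bmi


class TestComputeDeltas:
    def test_direct_subtraction_and_orientation(self):
        expr, pairs, bmi = small_expr()
        dm = compute_deltas(expr, pairs, bmi)
        # p1: heavier twin is s2 -> delta = s2 - s1 = +1.5 for gA
        assert dm.deltas.loc["gA", "p1"] == pytest.approx(1.5)
        # p2: heavier twin is s3 -> delta = s3 - s4
        assert dm.deltas.loc["gB", "p2"] == pytest.approx(-3.0)
        assert dm.deltas.shape == (3, 2)

    def test_swapping_covariates_flips_sign(self):
        expr, pairs, bmi = small_expr()
        flipped = dict(bmi, s1=30.0, s2=22.0)
        a = compute_deltas(expr, pairs, bmi)
        b = compute_deltas(expr, pairs, flipped)
        assert np.allclose(b.deltas["p1"], -a.deltas["p1"])
        assert np.allclose(b.deltas["p2"], a.deltas["p2"])

    def test_tied_covariates_flagged(self):
        expr, pairs, bmi = small_expr()
        tied = dict(bmi, s3=25.0, s4=25.0)
        with pytest.warns(UserWarning, match="tied covariates"):
            dm = compute_deltas(expr, pairs, tied)
        assert bool(dm.pair_info.loc["p2", "tied"])
        # declared column order: s3 treated as the 'high' member
        assert dm.pair_info.loc["p2", "high_sample"] == "s3"

    def test_incomplete_pair_raises(self):
        expr, pairs, bmi = small_expr()
        expr3 = expr[["s1", "s2", "s3"]]
        with pytest.raises(IncompletePairError):
            compute_deltas(expr3, pairs, bmi)
        with pytest.raises(IncompletePairError):
            compute_deltas(expr, pairs, {k: v for k, v in bmi.items() if k != "s4"})


class TestTopVariableFeatures:
    def test_k_equal_to_all_is_identity(self):
        expr, pairs, bmi = small_expr()
        dm = compute_deltas(expr, pairs, bmi)
        kept = top_variable_features(dm, k=3)
        pd.testing.assert_frame_equal(kept.deltas, dm.deltas)

    def test_constant_delta_feature_ranks_last(self):
        expr, pairs, bmi = small_expr()
        dm = compute_deltas(expr, pairs, bmi)  # gC has delta 0 in both pairs
        kept = top_variable_features(dm, k=2)
        assert "gC" not in kept.deltas.index

    def test_k_too_large_raises(self):
        expr, pairs, bmi = small_expr()
        dm = compute_deltas(expr, pairs, bmi)
        with pytest.raises(ParameterError):
            top_variable_features(dm, k=10)


class TestBhAdjust:
    def test_textbook_stepup_example(self):
        assert np.allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_matches_byhand_oracle_in_input_order(self, rng):
        p = rng.uniform(size=25)
        assert np.allclose(bh_adjust(p), bh_stepup_byhand(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 0.0])


class TestModeGroupAssociation:
    def test_diagonal_table_chi_square(self):
        # 2x2 table [[10,0],[0,10]]: chi2 = n (ad-bc)^2 / (r1 r2 c1 c2) = 20
        modes = np.repeat([0, 1], 10)
        outcomes = np.repeat(["poor", "good"], 10)
        res = mode_group_association(modes, outcomes)
        assert res.statistic == pytest.approx(20.0)

    def test_proportional_table_is_zero(self):
        modes = np.array([0, 0, 1, 1] * 5)
        outcomes = np.array(["a", "b", "a", "b"] * 5)
        assert mode_group_association(modes, outcomes).statistic == pytest.approx(0.0)

    def test_null_pvalues_roughly_uniform(self):
        pvals = []
        for seed in range(300):
            r = np.random.default_rng(seed)
            modes = r.integers(0, 2, 80)
            outcomes = r.integers(0, 2, 80)
            pvals.append(mode_group_association(modes, outcomes).p_value)
        from scipy import stats

        # chi-square p-values are discrete-ish at n=80 but close to uniform
        assert abs(np.mean(np.array(pvals) <= 0.5) - 0.5) < 0.1

    def test_low_expected_counts_warn(self):
        modes = np.array([0, 0, 0, 1, 0, 0, 0, 1])
        outcomes = np.array(["a", "b", "a", "b", "a", "b", "a", "a"])
        with pytest.warns(UserWarning, match="expected cell counts"):
            mode_group_association(modes, outcomes)

    def test_single_level_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            mode_group_association(np.zeros(10), np.repeat(["a", "b"], 5))


class TestEdaSummary:
    def test_gaussian_cullen_frey_position(self):
        x = np.random.default_rng(1).normal(size=10_000)
        s = eda_summary(x, n_boot=10, seed=0)
        assert s.cullen_frey[0] == pytest.approx(0.0, abs=0.02)
        assert s.cullen_frey[1] == pytest.approx(3.0, abs=0.15)

    def test_uniform_kurtosis(self):
        x = np.random.default_rng(2).uniform(size=20_000)
        s = eda_summary(x, n_boot=0, seed=0)
        assert s.cullen_frey[1] == pytest.approx(1.8, abs=0.1)
        assert s.boot_cullen_frey.shape == (0, 2)

    def test_bootstrap_cloud_size(self, rng):
        s = eda_summary(rng.normal(size=100), n_boot=37, seed=3)
        assert s.boot_cullen_frey.shape == (37, 2)
        assert np.all(np.isfinite(s.boot_cullen_frey))

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateDataError):
            eda_summary(np.full(10, 1.0))


class TestFixtures:
    def test_twin_truth_marks_exactly_the_planted_features(self):
        dm, truth = make_twin_matrix(
            n_pairs=30, n_features=50, n_bimodal=7, seed=4
        )
        assert truth["is_bimodal"].sum() == 7
        assert dm.deltas.shape == (50, 30)
        assert truth.loc[truth["is_bimodal"], "minority_weight"].between(
            0.1, 0.5
        ).all()
        assert truth.loc[~truth["is_bimodal"], "minority_weight"].isna().all()

    def test_bimodal_cohort_label_frequencies(self):
        df, labels = make_bimodal_cohort(n=2000, seed=5)
        # default minority weight 0.28; binomial 99.9% margin at n=2000
        frac_minor = min(labels.mean(), 1 - labels.mean())
        assert abs(frac_minor - 0.28) < 3.3 * np.sqrt(0.28 * 0.72 / 2000)
        assert len(df) == 2000

    def test_generate_fixture_is_byte_deterministic(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        params = {"n_pairs": 12, "n_features": 8, "n_bimodal": 2}
        f1 = generate_fixture("twin_matrix", d1, seed=9, params=params)
        f2 = generate_fixture("twin_matrix", d2, seed=9, params=params)
        for a, b in zip(f1, f2):
            assert a.read_bytes() == b.read_bytes()
        manifest = json.loads((d1 / "twin_matrix_manifest.json").read_text())
        assert manifest["seed"] == 9

    def test_unknown_kind_rejected(self, tmp_path):
        with pytest.raises(ParameterError):
            generate_fixture("nonsense", tmp_path)


class TestScreen:
    def test_planted_features_recovered_small_scale(self):
        dm, truth = make_twin_matrix(
            n_pairs=100,
            n_features=60,
            n_bimodal=8,
            separation_sd=5.0,
            minority_low=0.2,
            seed=11,
        )
        res = screen_bimodal_features(
            dm, n_boot=200, seed=12, n_restarts=1, tol=1e-6, max_iter=300
        )
        planted = set(truth.loc[truth["is_bimodal"], "feature"])
        found = set(res.passing_features)
        recall = len(found & planted) / len(planted)
        assert recall >= 0.7
        fdp = len(found - planted) / max(len(found), 1)
        assert fdp <= 0.25

    def test_minority_mode_filter_reason(self):
        # one clearly bimodal feature with a 5% minority mode: significant
        # LRT but excluded by the minority-proportion rule
        rng = np.random.default_rng(13)
        n_pairs = 200
        minor = rng.random(n_pairs) < 0.05
        vals = np.where(minor, rng.normal(8, 0.5, n_pairs), rng.normal(0, 0.5, n_pairs))
        deltas = pd.DataFrame(
            {f"pair_{i}": [vals[i]] for i in range(n_pairs)}, index=["gX"]
        )
        from varhet.workflows import DeltaMatrix

        dm = DeltaMatrix(
            deltas=deltas,
            pair_info=pd.DataFrame(index=deltas.columns),
        )
        res = screen_bimodal_features(
            dm, n_boot=100, seed=14, n_restarts=2, tol=1e-6, max_iter=300
        )
        row = res.table.iloc[0]
        assert row["p_adj"] <= 0.05
        assert row["minority_prop"] < 0.10
        assert not row["passed"]
        assert row["fail_reason"] == "min_mode"

    def test_too_few_pairs_rejected(self):
        dm, _ = make_twin_matrix(n_pairs=5, n_features=4, n_bimodal=1, seed=1)
        with pytest.raises(ParameterError):
            screen_bimodal_features(dm, n_boot=10)
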