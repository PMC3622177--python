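import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from moderseq.de_moderated import (HALF_NORMAL_FACTOR, LogExpression,
                                   VarianceModel, bh_adjust, call_de, de_test,
                                   fit_abs_diff_trend, fit_variance_model,
                                   log_transform, moderate_variance,
                                   pairwise_log_differences, per_gene_variance,
                                   rank_top_expressed, trend_only_model,
                                   trigamma_inverse, volcano_table, z_test)
from moderseq.synthetic_data import CountSimConfig, simulate_counts
from oracles import bh_step_up_oracle, trigamma_inverse_bisect


def make_le(values, design=("cond1", "cond1", "cond2", "cond2")):
    df = pd.DataFrame(np.asarray(values, float),
                      columns=[f"s{i}" for i in range(len(design))])
    return LogExpression(df, df.mean(axis=1),
                         pd.Series(list(design), index=df.columns), 0.25)


class TestLogTransform:
    @pytest.mark.parametrize("rpkm,expected", [(0.0, -2.0), (3.75, 2.0)])
    def test_pseudocount_arithmetic(self, small_expr, rpkm, expected):
        small_expr.rpkm.iloc[0, 0] = rpkm
        le = log_transform(small_expr, pseudocount=0.25)
        assert le.x.iloc[0, 0] == pytest.approx(expected)

    def test_intensity_is_row_mean(self, small_expr):
        le = log_transform(small_expr)
        assert np.allclose(le.A, le.x.mean(axis=1))

    def test_positive_pseudocount_required(self, small_expr):
        with pytest.raises(ValueError):
            log_transform(small_expr, pseudocount=0.0)


class TestPairwiseDifferences:
    def test_one_vs_one_single_between_pair(self):
        le = make_le([[1.0, 3.0]], design=("cond1", "cond2"))
        d, meta = pairwise_log_differences(le)
        assert d.shape == (1, 1) and meta[0][2] == "between"
        assert d[0, 0] == pytest.approx(-2.0)

    def test_two_vs_two_pair_structure(self):
        le = make_le([[1.0, 2.0, 3.0, 4.0]])
        d, meta = pairwise_log_differences(le)
        kinds = [m[2] for m in meta]
        assert d.shape == (1, 6)
        assert kinds.count("within") == 2 and kinds.count("between") == 4

    def test_constant_gene_all_zero(self):
        le = make_le([[2.0, 2.0, 2.0, 2.0]])
        d, _ = pairwise_log_differences(le)
        assert (d == 0).all()


class TestAbsDiffTrend:
    def test_constant_abs_diff_maps_to_half_normal_sigma(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(0, 10, 200)
        d = np.full((200, 2), 0.8) * np.array([1, -1])
        sigma = fit_abs_diff_trend(A, d)
        grid = np.linspace(1, 9, 20)
        assert np.allclose(sigma(grid), 0.8 * HALF_NORMAL_FACTOR, atol=1e-6)

    def test_linear_signal_fit_exact_on_interior(self):
        A = np.linspace(0, 10, 300)
        absd = 0.1 + 0.05 * A
        sigma = fit_abs_diff_trend(A, absd[:, None] * np.array([[1.0]]))
        interior = np.linspace(2, 8, 50)
        expected = (0.1 + 0.05 * interior) * HALF_NORMAL_FACTOR
        assert np.allclose(sigma(interior), expected, atol=1e-3)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(0, 5, 150)
        d = rng.normal(0, 0.5, (150, 3))
        perm = rng.permutation(150)
        s1 = fit_abs_diff_trend(A, d)
        s2 = fit_abs_diff_trend(A[perm], d[perm])
        grid = np.linspace(0.5, 4.5, 30)
        assert np.allclose(s1(grid), s2(grid))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_abs_diff_trend(np.arange(10.0), np.ones((10, 1)))


class TestPerGeneVariance:
    def test_pooled_variance_hand_example(self):
        le = make_le([[1.0, 3.0, 2.0, 2.0]])
        s2, d_g = per_gene_variance(le)
        assert s2[0] == pytest.approx(1.0) and d_g == 2

    def test_identical_replicates_zero_variance(self):
        le = make_le([[2.0, 2.0, 5.0, 5.0]])
        s2, _ = per_gene_variance(le)
        assert s2[0] == 0.0

    def test_shift_invariance(self):
        le1 = make_le([[1.0, 3.0, 2.0, 4.0]])
        le2 = make_le([[1.0, 3.0, 12.0, 14.0]])
        assert per_gene_variance(le1)[0] == pytest.approx(per_gene_variance(le2)[0])

    def test_unreplicated_design_directs_to_trend_only(self):
        le = make_le([[1.0, 2.0]], design=("cond1", "cond2"))
        with pytest.raises(ValueError, match="trend_only"):
            per_gene_variance(le)


class TestTrigammaInverse:
    @pytest.mark.parametrize("y", np.logspace(-3, 3, 13).tolist())
    def test_inverts_trigamma_on_grid(self, y):
        x = trigamma_inverse(y)
        assert abs(special.polygamma(1, x) - y) < 1e-8

    def test_agrees_with_bisection_oracle(self):
        for y in (0.01, 0.5, 1.0, 2.0, 100.0):
            assert trigamma_inverse(y) == pytest.approx(trigamma_inverse_bisect(y),
                                                        rel=1e-6)


class TestVarianceModel:
    def test_prior_df_recovery_hierarchical_sim(self):
        # s_g^2 ~ sigma_g^2 chi2_dg / dg with 1/sigma_g^2 ~ chi2_d0 / (d0 s0^2)
        rng = np.random.default_rng(123)
        n, d0, s0_sq, d_g = 10_000, 4.0, 0.05, 2.0
        sigma_sq = s0_sq * d0 / rng.chisquare(d0, n)
        s2 = sigma_sq * rng.chisquare(d_g, n) / d_g
        le = make_le(np.zeros((n, 4)))
        le.A = pd.Series(rng.uniform(0, 10, n))
        model = fit_variance_model(le, s2, d_g)
        assert 3.2 <= model.d0 <= 4.8
        # prior variance near truth on the flat trend
        assert np.median(model.s0_sq(le.A.to_numpy())) == pytest.approx(s0_sq, rel=0.25)

    def test_no_excess_spread_gives_infinite_d0(self):
        # constant sample variances have no excess spread -> pure trend
        le = make_le(np.zeros((100, 4)))
        le.A = pd.Series(np.linspace(0, 10, 100))
        model = fit_variance_model(le, np.full(100, 0.5), 2.0)
        assert np.isinf(model.d0)
        assert np.allclose(model.s0_sq(np.array([5.0])), np.exp(model.trend(np.array([5.0]))))


class TestModerateVariance:
    @staticmethod
    def model(d0):
        return VarianceModel("moderated", lambda a: a, d0, lambda a: np.full_like(a, 2.0), 2.0)

    def test_shrinkage_formula(self):
        s_tilde = moderate_variance(np.array([1.0]), 2.0, self.model(4.0), np.array([0.0]))
        assert s_tilde[0] == pytest.approx(5.0 / 3.0)

    def test_infinite_prior_df_returns_prior(self):
        s_tilde = moderate_variance(np.array([1.0]), 2.0, self.model(np.inf), np.array([0.0]))
        assert s_tilde[0] == 2.0

    def test_zero_prior_df_returns_sample_variance(self):
        s_tilde = moderate_variance(np.array([1.0]), 2.0, self.model(0.0), np.array([0.0]))
        assert s_tilde[0] == 1.0

    def test_shrinkage_bounded_between_sample_and_prior(self):
        rng = np.random.default_rng(2)
        s2 = rng.chisquare(2, 500) / 2
        s_tilde = moderate_variance(s2, 2.0, self.model(4.0), np.zeros(500))
        assert (s_tilde >= np.minimum(s2, 2.0) - 1e-12).all()
        assert (s_tilde <= np.maximum(s2, 2.0) + 1e-12).all()


class TestZTest:
    def test_unit_difference_unit_variance(self):
        le = make_le([[0.0, 0.0, 1.0, 1.0]])
        zt = z_test(le, np.array([1.0]), TestModerateVariance.model(np.inf))
        assert zt["z"].iloc[0] == pytest.approx(1.0)
        assert zt["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(1), abs=1e-6)

    def test_zero_difference(self):
        le = make_le([[1.0, 1.0, 1.0, 1.0]])
        zt = z_test(le, np.array([1.0]), TestModerateVariance.model(np.inf))
        assert zt["z"].iloc[0] == 0 and zt["p"].iloc[0] == 1

    def test_p_even_in_sign(self):
        up = z_test(make_le([[0.0, 0.0, 2.0, 2.0]]), np.array([0.5]),
                    TestModerateVariance.model(np.inf))
        dn = z_test(make_le([[2.0, 2.0, 0.0, 0.0]]), np.array([0.5]),
                    TestModerateVariance.model(np.inf))
        assert up["p"].iloc[0] == pytest.approx(dn["p"].iloc[0])

    def test_degenerate_zero_variance_flagged(self):
        le = make_le([[0.0, 0.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0]])
        zt = z_test(le, np.array([0.0, 0.0]), TestModerateVariance.model(np.inf))
        assert zt["degenerate"].all()
        assert zt["p"].tolist() == [0.0, 1.0]

    def test_t_reference_heavier_tail(self):
        le = make_le([[0.0, 0.0, 1.0, 1.0]])
        model = VarianceModel("moderated", lambda a: a, 4.0,
                              lambda a: np.ones_like(a), 2.0)
        p_norm = z_test(le, np.array([1.0]), model, "normal")["p"].iloc[0]
        p_t = z_test(le, np.array([1.0]), model, "t")["p"].iloc[0]
        assert p_t == pytest.approx(2 * stats.t.sf(1, 6), abs=1e-9)
        assert p_t > p_norm


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == 0.3

    def test_hand_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_identical_ps_unchanged(self):
        assert np.allclose(bh_adjust([0.2] * 5), 0.2)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(bh_adjust(p), bh_step_up_oracle(np.array(p)))

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        p = rng.random(1000)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallsAndReports:
    @staticmethod
    def row(q, log2fc, rpkm=5.0):
        return pd.DataFrame({"gene_id": ["g"], "mean_rpkm_cond1": [rpkm],
                             "mean_rpkm_cond2": [rpkm], "log2fc": [log2fc],
                             "q": [q]})

    @pytest.mark.parametrize("q,lfc,rpkm,expected", [
        (0.04, 1.5, 5.0, "up"),
        (0.04, -1.5, 5.0, "down"),
        (0.04, 0.5, 5.0, "ns"),      # fold fails
        (0.06, 1.5, 5.0, "ns"),      # fdr fails
        (0.04, 1.0, 5.0, "ns"),      # strict inequality at the boundary
        (0.04, 1.5, 0.05, "ns"),     # rpkm floor fails
    ])
    def test_call_thresholds(self, q, lfc, rpkm, expected):
        out = call_de(self.row(q, lfc, rpkm))
        assert out["call"].iloc[0] == expected

    def test_rank_top_expressed(self, small_expr):
        top = rank_top_expressed(small_expr, k=5)
        assert len(top) == 5
        assert (top["mean_rpkm"].diff().dropna() <= 0).all()
        all_genes = rank_top_expressed(small_expr, k=10_000)
        assert len(all_genes) == small_expr.rpkm.shape[0]
        # invariant under sample permutation
        shuffled = small_expr.rpkm[["mut_2", "wt_1", "mut_1", "wt_2"]]
        assert list(top["gene_id"]) == list(
            shuffled.mean(axis=1).sort_values(ascending=False).index[:5])

    def test_volcano_table_caps_and_maps(self):
        res = pd.DataFrame({"gene_id": ["a", "b", "c"],
                            "log2fc": [1.0, -1.0, 0.0],
                            "log2fc_reverse": [-1.0, 1.0, 0.0],
                            "p": [0.01, 1.0, 0.0],
                            "call": ["up", "ns", "ns"]})
        v = volcano_table(res)
        assert v["neg_log10_p"].tolist() == [2.0, 0.0, 320.0]


class TestEndToEndDE:
    def test_trend_only_equals_moderated_with_fed_trend(self, small_expr):
        le = log_transform(small_expr)
        tmodel = trend_only_model(le)
        mmodel = VarianceModel("moderated", tmodel.trend, np.inf, tmodel.s0_sq, 0.0)
        A = le.A.to_numpy()
        s_t = moderate_variance(None, 0.0, tmodel, A)
        s_m = moderate_variance(np.ones(len(A)), 0.0, mmodel, A)
        assert np.array_equal(s_t, s_m)
        zt = z_test(le, s_t, tmodel)
        zm = z_test(le, s_m, mmodel)
        assert np.array_equal(zt["z"].to_numpy(), zm["z"].to_numpy())

    def test_de_test_modes_and_attrs(self):
        expr, _ = simulate_counts(CountSimConfig(n_genes=400, seed=21))
        res = de_test(expr)
        assert res.attrs["mode"] == "moderated"
        assert ((res["q"] >= res["p"] - 1e-12) | res["q"].isna()).all()
        assert set(res["call"]) <= {"up", "down", "ns"}

    def test_trend_only_mode_on_1v1(self):
        expr, _ = simulate_counts(CountSimConfig(n_genes=400, design=(1, 1), seed=22))
        res = de_test(expr)
        assert res.attrs["mode"] == "trend_only"
        assert np.isfinite(res["p"]).all()

    def test_spiked_genes_rank_first(self):
        expr, truth = simulate_counts(CountSimConfig(
            n_genes=2000, pi_de=0.02, lfc_dist=(3.0, 0.3), seed=23))
        res = de_test(expr, reference="t")
        top = res.nsmallest(10, "p")
        truth_idx = truth.set_index("gene_id")
        assert truth_idx.loc[top["gene_id"], "is_de"].mean() >= 0.8
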