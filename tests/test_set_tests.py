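"""Component tests: Beta-MAF weights, burden, SKAT, ACAT-V, Cauchy combination."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from staarlite.null_model import ScoreStats, single_variant_pvalues
from staarlite.set_tests import (
    WeightSetting,
    acatv_test,
    beta_maf_weight,
    burden_test,
    cauchy_combine,
    skat_test,
)


def brute_force_cauchy(pvals, weights=None):
    """Independent implementation of the Cauchy combination."""
    if weights is None:
        weights = [1.0] * len(pvals)
    num = sum(
        w * (1.0 / (p * math.pi) if p < 1e-16 else math.tan((0.5 - min(p, 1 - 1e-16)) * math.pi))
        for p, w in zip(pvals, weights)
    )
    t = num / sum(weights)
    return 0.5 - math.atan(t) / math.pi


class TestBetaMafWeight:
    def test_uniform_setting_is_flat(self):
        w = beta_maf_weight([0.001, 0.1, 0.5], WeightSetting(1, 1))
        assert np.allclose(w, 1.0)

    def test_rare_upweighting_closed_form(self):
        w = beta_maf_weight(0.001, WeightSetting(1, 25))
        assert w == pytest.approx(25 * 0.999**24, rel=1e-12)
        assert w == pytest.approx(24.41, abs=0.01)

    @given(st.floats(1e-4, 0.49))
    def test_strictly_decreasing_for_1_25(self, maf):
        w1 = beta_maf_weight(maf, WeightSetting(1, 25))
        w2 = beta_maf_weight(maf + 0.005, WeightSetting(1, 25))
        assert w1 > w2

    def test_rejects_out_of_range_maf(self):
        with pytest.raises(ValueError):
            beta_maf_weight(0.0)
        with pytest.raises(ValueError):
            beta_maf_weight(0.6)


class TestBurden:
    def test_single_variant_reduces_to_score_test(self, random_score_stats):
        stats_, _ = random_score_stats
        one = stats_.subset([2])
        p_b = burden_test(one.S, one.Sigma, [1.0])
        assert p_b == pytest.approx(single_variant_pvalues(one)[0], abs=1e-14)

    def test_zero_weighted_score_gives_p_one(self):
        S = np.array([1.0, -1.0])
        Sigma = np.eye(2)
        assert burden_test(S, Sigma, [1.0, 1.0]) == 1.0

    def test_dense_projection_oracle(self):
        # recompute G'PG with P formed densely and compare the p-value
        rng = np.random.default_rng(5)
        n, m = 50, 4
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        mu = 1 / (1 + np.exp(-(0.1 + 0.5 * X[:, 1])))
        y = rng.binomial(1, mu).astype(float)
        import pandas as pd

        from staarlite.null_model import fit_null_model, score_statistics

        ph = pd.DataFrame({"sample_id": [str(i) for i in range(n)], "outcome": y, "x": X[:, 1]})
        model = fit_null_model(ph, ["x"])
        G = rng.binomial(2, 0.15, size=(n, m)).astype(float)
        st_ = score_statistics(model, G)
        W = np.diag(model.working_weights)
        Xd = model.covariate_matrix
        P = W - W @ Xd @ np.linalg.inv(Xd.T @ W @ Xd) @ Xd.T @ W
        w = rng.uniform(0.5, 2.0, size=m)
        q_direct = float(w @ G.T @ (y - model.mu_hat)) ** 2 / float(w @ G.T @ P @ G @ w)
        assert burden_test(st_.S, st_.Sigma, w) == pytest.approx(
            stats.chi2.sf(q_direct, 1), abs=1e-12
        )

    def test_all_zero_weights_rejected(self, random_score_stats):
        stats_, _ = random_score_stats
        with pytest.raises(ValueError):
            burden_test(stats_.S, stats_.Sigma, np.zeros(len(stats_.S)))


class TestSkat:
    def test_single_variant_collapse(self, random_score_stats):
        stats_, _ = random_score_stats
        one = stats_.subset([1])
        assert skat_test(one.S, one.Sigma, [2.0]) == pytest.approx(
            single_variant_pvalues(one)[0], abs=1e-12
        )

    def test_diagonal_sigma_monte_carlo_oracle(self):
        # with diagonal Sigma the statistic is a sum of independent scaled
        # chi-squares; simulate it directly
        rng = np.random.default_rng(11)
        d = np.array([0.8, 1.5, 0.3, 2.0])
        w = np.array([1.0, 0.7, 1.3, 0.5])
        S = rng.normal(0, np.sqrt(d))
        p = skat_test(S, np.diag(d), w)
        ndraw = 300_000
        draws = ((w**2 * d) * rng.chisquare(1, size=(ndraw, 4))).sum(axis=1)
        q = float(((w * S) ** 2).sum())
        mc = (draws > q).mean()
        se = np.sqrt(mc * (1 - mc) / ndraw)
        assert p == pytest.approx(mc, abs=4 * se)

    def test_all_zero_weights_rejected(self, random_score_stats):
        stats_, _ = random_score_stats
        with pytest.raises(ValueError):
            skat_test(stats_.S, stats_.Sigma, np.zeros(len(stats_.S)))


class TestCauchyCombine:
    def test_single_p_is_identity(self):
        assert cauchy_combine([0.03]) == pytest.approx(0.03, abs=1e-12)

    def test_symmetric_half(self):
        assert cauchy_combine([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_two_component_oracle(self):
        p = cauchy_combine([0.01, 0.5])
        assert p == pytest.approx(brute_force_cauchy([0.01, 0.5]), abs=1e-14)
        assert p == pytest.approx(0.0200, abs=2e-4)

    def test_tiny_p_tail_substitution(self):
        p = cauchy_combine([1e-20, 0.4])
        assert p == pytest.approx(2e-20, rel=1e-3)

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=8))
    def test_matches_brute_force(self, pvals):
        assert cauchy_combine(pvals) == pytest.approx(brute_force_cauchy(pvals), abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cauchy_combine([])
        with pytest.raises(ValueError):
            cauchy_combine([0.0])
        with pytest.raises(ValueError):
            cauchy_combine([0.5], [0.0])


class TestAcatV:
    def test_all_ultra_rare_equals_burden(self, random_score_stats):
        # when every variant has MAC below the threshold ACAT-V IS the
        # burden test - the degeneracy behind the omnibus safeguards
        stats_, G = random_score_stats
        maf = G.sum(0) / (2 * G.shape[0])
        maf = np.minimum(maf, 1 - maf)
        mac = np.minimum(G.sum(0), 2 * G.shape[0] - G.sum(0))
        setting = WeightSetting(1, 25)
        p_acatv = acatv_test(stats_.S, stats_.Sigma, maf, mac, setting, mac_threshold=10_000)
        w = beta_maf_weight(maf, setting)
        p_burden = burden_test(stats_.S, stats_.Sigma, w)
        assert p_acatv == p_burden

    def test_no_ultra_rare_is_cauchy_of_singles(self, random_score_stats):
        stats_, G = random_score_stats
        maf = np.minimum(G.sum(0), 2 * G.shape[0] - G.sum(0)) / (2 * G.shape[0])
        mac = np.minimum(G.sum(0), 2 * G.shape[0] - G.sum(0))
        setting = WeightSetting(1, 1)
        p = acatv_test(stats_.S, stats_.Sigma, maf, mac, setting, mac_threshold=0)
        singles = single_variant_pvalues(stats_)
        w = beta_maf_weight(maf, setting) ** 2 * maf * (1 - maf)
        assert p == pytest.approx(brute_force_cauchy(list(singles), list(w)), abs=1e-12)

    def test_mixed_set_manual_assembly(self, null_model_300):
        # MACs {1, 1, 12}: one single-variant component (MAC 12) plus one
        # pooled burden component over the two singletons
        from tests.conftest import block_from_columns

        from staarlite.masks import compute_mac_maf
        from staarlite.null_model import score_statistics

        model, _ = null_model_300
        n = 300
        c1, c2 = np.zeros(n), np.zeros(n)
        c1[5] = 1
        c2[17] = 1
        c3 = np.zeros(n)
        c3[np.arange(30, 42)] = 1
        block = block_from_columns([c1, c2, c3])
        mac, maf, _ = compute_mac_maf(block)
        st_ = score_statistics(model, block.dosage)
        setting = WeightSetting(1, 25)
        p = acatv_test(st_.S, st_.Sigma, maf, mac, setting, mac_threshold=10)
        # manual two-component assembly
        w_full = beta_maf_weight(maf, setting)
        w_cauchy = w_full**2 * maf * (1 - maf)
        p_single = single_variant_pvalues(st_.subset([2]))[0]
        p_pool = burden_test(st_.subset([0, 1]).S, st_.subset([0, 1]).Sigma, w_full[:2])
        expected = brute_force_cauchy(
            [p_single, p_pool], [w_cauchy[2], float(np.mean(w_cauchy[:2]))]
        )
        assert p == pytest.approx(expected, abs=1e-12)


class TestSingleVariantCollapse:
    @pytest.mark.parametrize("seed", range(10))
    def test_all_tests_agree_on_m1_sets(self, seed, null_model_300):
        from staarlite.null_model import score_statistics

        model, _ = null_model_300
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, rng.uniform(0.01, 0.2), size=300).astype(float)
        if g.sum() == 0:
            g[0] = 1
        st_ = score_statistics(model, g)
        maf = min(g.sum(), 600 - g.sum()) / 600
        mac = int(min(g.sum(), 600 - g.sum()))
        p0 = single_variant_pvalues(st_)[0]
        for setting in (WeightSetting(1, 25), WeightSetting(1, 1)):
            w = beta_maf_weight([maf], setting)
            assert burden_test(st_.S, st_.Sigma, w) == pytest.approx(p0, abs=1e-10)
            assert skat_test(st_.S, st_.Sigma, w) == pytest.approx(p0, abs=1e-10)
            assert acatv_test(
                st_.S, st_.Sigma, np.array([maf]), np.array([mac]), setting
            ) == pytest.approx(p0, abs=1e-10)
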