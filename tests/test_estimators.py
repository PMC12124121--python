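"""Estimator suite: closed forms vs independent oracles, robustness, selection."""

import numpy as np
import pytest
import statsmodels.api as sm

from lipidmr import (
    QTestResult,
    SimConfig,
    cochran_q,
    egger,
    harmonize,
    ivw,
    leave_one_out,
    presso_global,
    select_primary,
    simulate_triplet,
    wald_ratio,
    weighted_median,
    weighted_mode,
)

from helpers import make_hset


def random_hset(rng, k=50):
    bx = rng.normal(0.2, 0.1, k)
    bx[np.abs(bx) < 0.02] = 0.05
    sx = rng.uniform(0.005, 0.02, k)
    sy = rng.uniform(0.005, 0.05, k)
    by = 0.2 * bx + rng.normal(0, sy)
    return make_hset(bx, sx, by, sy)


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.5, 0.02, 0.1, 0.05)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_beta(self):
        assert wald_ratio(0.5, 0.02, 0.0, 0.05).beta == 0.0

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.02, 0.1, 0.05)

    def test_second_order_se_larger(self):
        first = wald_ratio(0.5, 0.05, 0.1, 0.05)
        second = wald_ratio(0.5, 0.05, 0.1, 0.05, second_order=True)
        assert second.se > first.se

    def test_noise_free_ratios_equal_theta(self):
        cfg = SimConfig(n_snps=20, n_exposure=10**12, n_mediator=10**12,
                        n_outcome=10**12, theta_total=0.2, seed=2)
        exposure, _, outcome, _ = simulate_triplet(cfg)
        h = harmonize(exposure, outcome)
        for _, r in h.data.iterrows():
            est = wald_ratio(r["beta_exp"], r["se_exp"], r["beta_out"], r["se_out"])
            assert est.beta == pytest.approx(0.2, abs=1e-3)


class TestIVW:
    def test_equal_weights_is_mean_of_ratios(self):
        h = make_hset([1.0, 1.0], [0.01, 0.01], [0.1, 0.3], [0.1, 0.1])
        assert ivw(h).beta == pytest.approx(0.2)

    def test_single_snp_rejected(self):
        h = make_hset([0.5], [0.01], [0.1], [0.05])
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw(h)

    def test_duplicated_snp_equals_wald_with_shrunk_se(self):
        wald = wald_ratio(0.5, 0.02, 0.1, 0.05)
        for k in (2, 4):
            h = make_hset([0.5] * k, [0.02] * k, [0.1] * k, [0.05] * k)
            est = ivw(h)
            assert est.beta == pytest.approx(wald.beta)
            assert est.se == pytest.approx(wald.se / np.sqrt(k))

    def test_matches_wls_oracle_to_1e10(self):
        """Closed form vs statsmodels weighted regression through the origin."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            h = random_hset(rng, k=int(rng.integers(5, 40)))
            est = ivw(h)
            d = h.data
            fit = sm.WLS(d["beta_out"], d["beta_exp"], weights=1 / d["se_out"] ** 2).fit()
            assert est.beta == pytest.approx(fit.params.iloc[0], abs=1e-10)

    def test_mre_se_never_below_fe(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            h = random_hset(rng)
            fe, mre = ivw(h, "fixed"), ivw(h, "mre")
            assert mre.se >= fe.se
            assert mre.beta == pytest.approx(fe.beta)
            q = fe.extra["q"]
            assert (mre.se == pytest.approx(fe.se)) == (q <= len(h) - 1)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.1 + 0.3 * bx
        h = make_hset(bx, [0.01] * 5, by, [0.02] * 5)
        est = egger(h)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert est.extra["intercept"] == pytest.approx(0.1, abs=1e-12)

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            h = random_hset(rng, k=int(rng.integers(5, 30)))
            est = egger(h)
            d = h.data
            sign = np.sign(d["beta_exp"]).replace(0, 1)
            X = sm.add_constant(np.abs(d["beta_exp"]))
            fit = sm.WLS(d["beta_out"] * sign, X, weights=1 / d["se_out"] ** 2).fit()
            assert est.beta == pytest.approx(fit.params.iloc[1], abs=1e-10)
            assert est.extra["intercept"] == pytest.approx(fit.params.iloc[0], abs=1e-10)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(5)
        h = random_hset(rng, k=10)
        flipped = h.data.copy()
        flipped.loc[:4, ["beta_exp", "beta_out"]] *= -1
        h2 = make_hset(flipped["beta_exp"], flipped["se_exp"],
                       flipped["beta_out"], flipped["se_out"])
        assert egger(h2).beta == pytest.approx(egger(h).beta)
        assert egger(h2).extra["intercept"] == pytest.approx(egger(h).extra["intercept"])

    def test_too_few_snps(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.02, 0.04], [0.02] * 2)
        with pytest.raises(ValueError):
            egger(h)

    def test_directional_pleiotropy_recovered(self):
        """Injected directional pleiotropy shows up in the intercept while the
        slope stays near the causal effect."""
        ints = []
        for seed in range(60):
            cfg = SimConfig(n_snps=50, theta_total=0.2, pleiotropy_mean=0.05,
                            pleiotropy_sd=0.02, seed=seed)
            exposure, _, outcome, _ = simulate_triplet(cfg)
            est = egger(harmonize(exposure, outcome))
            ints.append(est.extra["intercept"])
        ints = np.asarray(ints)
        assert abs(ints.mean() - 0.05) < 3 * ints.std() / np.sqrt(len(ints))


class TestWeightedMedian:
    def test_equal_weights_simple_median(self):
        h = make_hset([1, 1, 1], [0.01] * 3, [0.1, 0.2, 0.9], [0.1] * 3)
        assert weighted_median(h, n_boot=50, seed=1).beta == pytest.approx(0.2)

    def test_dominant_weight_returns_its_ratio(self):
        # middle SNP carries 90% of the weight (se_out scaled accordingly)
        h = make_hset([1, 1, 1], [0.01] * 3,
                      [0.1, 0.2, 0.9],
                      [3 / np.sqrt(0.05), 1 / np.sqrt(0.90), 3 / np.sqrt(0.05)])
        assert weighted_median(h, n_boot=50, seed=1).beta == pytest.approx(0.2)

    def test_robust_to_half_invalid_instruments(self):
        rng = np.random.default_rng(9)
        k = 40
        bx = rng.uniform(0.1, 0.5, k)
        sy = np.full(k, 0.005)
        by = 0.2 * bx + rng.normal(0, sy)
        by[: k // 2 - 1] += 0.1  # 19/40 invalid with inflated ratios
        h = make_hset(bx, np.full(k, 0.005), by, sy)
        med = weighted_median(h, n_boot=200, seed=2)
        assert abs(med.beta - 0.2) < 0.05
        assert ivw(h).beta - 0.2 > 0.05  # IVW visibly biased upward


class TestWeightedMode:
    def test_identical_ratios(self):
        h = make_hset([0.1, 0.2, 0.4], [0.01] * 3, [0.02, 0.04, 0.08], [0.02] * 3)
        assert weighted_mode(h, n_boot=50, seed=1).beta == pytest.approx(0.2)

    def test_majority_cluster_wins(self):
        rng = np.random.default_rng(3)
        k = 30
        bx = rng.uniform(0.2, 0.5, k)
        sy = np.full(k, 0.004)
        by = 0.2 * bx + rng.normal(0, sy)
        by[:8] = 1.0 * bx[:8]  # minority cluster at ratio 1.0
        h = make_hset(bx, np.full(k, 0.004), by, sy)
        est = weighted_mode(h, n_boot=100, seed=4)
        assert abs(est.beta - 0.2) < 0.05

    def test_bandwidth_scaling_smoke(self):
        rng = np.random.default_rng(6)
        h = random_hset(rng, k=20)
        e1 = weighted_mode(h, bandwidth_phi=1.0, n_boot=50, seed=1)
        e2 = weighted_mode(h, bandwidth_phi=2.0, n_boot=50, seed=1)
        assert np.isfinite(e1.beta) and np.isfinite(e2.beta)
        assert abs(e1.beta - e2.beta) < 0.1


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.02, 0.04], [0.02] * 2)
        res = cochran_q(h, reference_beta=0.2)
        assert res.q == pytest.approx(0.0)
        assert res.pval == pytest.approx(1.0)

    def test_arithmetic_example(self):
        # ratios 0 and 1 with unit ratio-scale weights, reference 0.5
        h = make_hset([1.0, 1.0], [0.01] * 2, [0.0, 1.0], [1.0, 1.0])
        res = cochran_q(h, reference_beta=0.5)
        assert res.q == pytest.approx(0.5)
        assert res.df == 1


class TestPresso:
    def test_deterministic_under_fixed_seed(self, hset):
        a = presso_global(hset, n_sim=500, seed=3)
        b = presso_global(hset, n_sim=500, seed=3)
        assert a.rss_obs == b.rss_obs
        assert a.global_p == b.global_p
        assert list(a.outlier_pvals) == list(b.outlier_pvals)

    def test_spiked_snp_flagged(self):
        exposure, _, outcome, _ = simulate_triplet(SimConfig(n_snps=50, theta_total=0.2, seed=21))
        h = harmonize(exposure, outcome)
        h.data.loc[3, "beta_out"] += 10 * h.data.loc[3, "se_out"]
        res = presso_global(h, n_sim=1000, seed=5)
        spiked = h.data.loc[3, "snp"]
        assert res.outlier_pvals.idxmin() == spiked
        assert spiked in res.outliers
        assert res.global_p <= 0.01

    def test_pvalue_resolution(self, hset):
        res = presso_global(hset, n_sim=500, seed=9)
        assert res.global_p >= 1 / 501
        assert res.global_p <= 1.0

    def test_too_few_snps(self):
        h = make_hset([0.1] * 3, [0.01] * 3, [0.02] * 3, [0.02] * 3)
        with pytest.raises(ValueError):
            presso_global(h)


class TestLeaveOneOut:
    def test_row_per_snp(self):
        h = make_hset([0.1, 0.2, 0.3], [0.01] * 3, [0.02, 0.04, 0.06], [0.02] * 3)
        assert len(leave_one_out(h)) == 3

    def test_homogeneous_loo_within_full_ci(self, hset):
        full = ivw(hset)
        loo = leave_one_out(hset)
        assert ((loo["beta"] >= full.ci_low) & (loo["beta"] <= full.ci_high)).all()

    def test_outlier_omission_moves_estimate_most(self):
        exposure, _, outcome, _ = simulate_triplet(SimConfig(n_snps=30, theta_total=0.2, seed=13))
        h = harmonize(exposure, outcome)
        i = int(h.data["beta_exp"].idxmax())  # strongest instrument: maximal leverage
        h.data.loc[i, "beta_out"] += 10 * h.data.loc[i, "se_out"]
        full = ivw(h)
        loo = leave_one_out(h, model="fixed")
        shifts = (loo["beta"] - full.beta).abs()
        assert loo.loc[shifts.idxmax(), "snp_omitted"] == h.data.loc[i, "snp"]


class TestSelectPrimary:
    @staticmethod
    def _fits():
        h = make_hset([0.1, 0.2, 0.3, 0.4], [0.01] * 4,
                      [0.02, 0.04, 0.06, 0.08], [0.02] * 4)
        return ivw(h, "fixed"), ivw(h, "mre"), egger(h)

    def test_homogeneous_no_pleiotropy_uses_fe(self):
        fe, mre, eg = self._fits()
        q = QTestResult(q=1.0, df=3, pval=0.8)
        sel = select_primary(fe, mre, eg, q, intercept_p=0.9)
        assert sel.method == "ivw_fe"

    def test_heterogeneity_uses_mre(self):
        fe, mre, eg = self._fits()
        q = QTestResult(q=20.0, df=3, pval=0.01)
        sel = select_primary(fe, mre, eg, q, intercept_p=0.5)
        assert sel.method == "ivw_mre"

    def test_material_significant_intercept_uses_egger(self):
        fe, mre, eg = self._fits()
        eg.extra["intercept"] = 0.05
        q = QTestResult(q=1.0, df=3, pval=0.8)
        sel = select_primary(fe, mre, eg, q, intercept_p=0.01)
        assert sel.method == "egger"

    def test_tiny_intercept_not_declared_pleiotropic(self):
        fe, mre, eg = self._fits()
        eg.extra["intercept"] = 0.005  # significant but below magnitude floor
        q = QTestResult(q=20.0, df=3, pval=0.01)
        sel = select_primary(fe, mre, eg, q, intercept_p=0.01)
        assert sel.method == "ivw_mre"
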