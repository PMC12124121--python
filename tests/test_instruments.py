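"""Instrument selection: thresholding, clumping, outcome/Steiger filters."""

import numpy as np
import pandas as pd
import pytest

from lipidmr import (
    LDMatrix,
    SimConfig,
    clump,
    f_statistic,
    filter_outcome_associated,
    harmonize,
    simulate_triplet,
    steiger_filter,
    threshold_instruments,
)

from helpers import make_hset, make_stats


class TestThreshold:
    def test_strict_cut(self):
        stats = make_stats(pval=[1e-7, 1e-5, 0.2])
        kept = threshold_instruments(stats, 5e-6)
        assert list(kept.data["pval"]) == [1e-7]

    def test_threshold_one_keeps_all(self):
        stats = make_stats(pval=[1e-7, 1e-5, 0.2])
        assert len(threshold_instruments(stats, 1.0)) == 3

    def test_matches_brute_force_on_simulated_set(self):
        stats = simulate_triplet(SimConfig(n_snps=200, null_fraction=0.5, seed=6))[0]
        kept = threshold_instruments(stats, 5e-6)
        brute = sum(1 for p in stats.data["pval"] if p < 5e-6)
        assert len(kept) == brute

    def test_empty_result_is_not_fatal(self):
        stats = make_stats(pval=[0.5, 0.9])
        assert len(threshold_instruments(stats, 5e-8)) == 0


class TestClump:
    def test_full_ld_same_position_keeps_best_p(self):
        stats = make_stats(pval=[1e-6, 1e-8, 1e-4], pos=[100, 100, 100])
        ld = LDMatrix(stats.data["snp"], np.ones((3, 3)))
        kept = clump(stats, ld, r2_threshold=0.001, window_kb=10_000)
        assert list(kept.data["pval"]) == [1e-8]

    def test_identity_ld_keeps_all(self):
        stats = make_stats(pval=[1e-6, 1e-8, 1e-4])
        kept = clump(stats, LDMatrix.identity(stats.data["snp"]))
        assert len(kept) == 3

    def test_missing_snp_treated_unlinked(self):
        stats = make_stats(pval=[1e-6, 1e-8], pos=[100, 200])
        ld = LDMatrix(["rs0000"], np.ones((1, 1)))
        assert len(clump(stats, ld)) == 2

    def test_against_pairwise_verification_oracle(self):
        """Every retained pair respects the r2/window rule; every removed SNP
        conflicts with a better-p retained SNP."""
        rng = np.random.default_rng(0)
        k = 20
        stats = make_stats(
            pval=list(rng.uniform(1e-10, 1e-4, k)),
            pos=list(rng.integers(1, 30_000_000, k)),
            chr=[1] * k,
        )
        a = rng.uniform(0, 1, (k, k))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(stats.data["snp"], r2)
        kept = clump(stats, ld, r2_threshold=0.3, window_kb=10_000)
        kept_ids = set(kept.data["snp"])

        d = stats.data.set_index("snp")

        def conflicts(s1, s2):
            near = abs(d.at[s1, "pos"] - d.at[s2, "pos"]) <= 10_000_000
            return near and ld.lookup(s1, s2) >= 0.3

        for s1 in kept_ids:
            for s2 in kept_ids:
                if s1 < s2:
                    assert not conflicts(s1, s2)
        for s in d.index:
            if s not in kept_ids:
                better = [
                    t for t in kept_ids
                    if (d.at[t, "pval"], t) < (d.at[s, "pval"], s) and conflicts(t, s)
                ]
                assert better, f"{s} removed without a better-p conflicting index SNP"

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        stats = make_stats(pval=list(rng.uniform(0, 1e-4, 10)), pos=[100] * 10)
        a = rng.uniform(0, 1, (10, 10))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(stats.data["snp"], r2)
        kept1 = clump(stats, ld, 0.3, 10_000)
        shuffled = make_stats(pval=[0.5])  # placeholder, replaced below
        shuffled.data = stats.data.sample(frac=1, random_state=1).reset_index(drop=True)
        kept2 = clump(shuffled, ld, 0.3, 10_000)
        assert set(kept1.data["snp"]) == set(kept2.data["snp"])

    def test_ld_free_simulated_panel_is_untouched(self):
        stats = simulate_triplet(SimConfig(n_snps=30, seed=5))[0]
        kept = clump(stats, LDMatrix.identity(stats.data["snp"]))
        assert list(kept.data["snp"]) == list(stats.data["snp"])


class TestLDMatrix:
    def test_round_trip(self, tmp_path):
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.4], [0.4, 1.0]]))
        ld.write_tsv(tmp_path / "ld.tsv")
        back = LDMatrix.read_tsv(tmp_path / "ld.tsv")
        assert back.snp_ids == ["a", "b"]
        np.testing.assert_allclose(back.r2, ld.r2)

    @pytest.mark.parametrize(
        "r2",
        [
            np.array([[1.0, 0.5], [0.4, 1.0]]),   # asymmetric
            np.array([[0.9, 0.4], [0.4, 1.0]]),   # diagonal != 1
            np.array([[1.0, 1.4], [1.4, 1.0]]),   # out of range
        ],
    )
    def test_validation(self, r2):
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], r2)


class TestOutcomeFilter:
    def test_strong_outcome_association_removed(self):
        h = make_hset([0.1, 0.1], [0.01, 0.01], [0.05, 0.0], [0.01, 0.01])
        filtered, dropped = filter_outcome_associated(h, 5e-5)
        assert dropped == ["rs0000"]  # z = 5, p ~ 5.7e-7
        assert len(filtered) == 1

    def test_matches_brute_force(self, hset):
        from scipy import stats as sps

        filtered, dropped = filter_outcome_associated(hset, 5e-5)
        brute = {
            row["snp"]
            for _, row in hset.data.iterrows()
            if 2 * sps.norm.sf(abs(row["beta_out"] / row["se_out"])) < 5e-5
        }
        assert set(dropped) == brute
        assert len(filtered) + len(dropped) == len(hset)


class TestSteiger:
    def test_exposure_stronger_retained(self):
        h = make_hset([0.1], [0.01], [0.01], [0.01])
        filtered, dropped = steiger_filter(h)
        assert dropped == []
        assert len(filtered) == 1

    def test_equal_strength_retained(self):
        h = make_hset([0.05], [0.01], [0.05], [0.01])
        filtered, dropped = steiger_filter(h)
        assert dropped == []  # strict inequality drops

    def test_outcome_stronger_dropped(self):
        h = make_hset([0.01], [0.01], [0.1], [0.01])
        _, dropped = steiger_filter(h)
        assert dropped == ["rs0000"]

    def test_small_samples_fatal(self):
        h = make_hset([0.1], [0.01], [0.01], [0.01], n_exp=2)
        with pytest.raises(ValueError):
            steiger_filter(h)

    def test_rarely_drops_under_true_forward_causation(self):
        dropped_total = snps_total = 0
        for seed in range(20):
            exposure, _, outcome, _ = simulate_triplet(
                SimConfig(n_snps=50, theta_total=0.2, seed=seed)
            )
            h = harmonize(exposure, outcome)
            _, dropped = steiger_filter(h)
            dropped_total += len(dropped)
            snps_total += len(h)
        assert dropped_total / snps_total < 0.05


def test_f_statistic_arithmetic():
    assert f_statistic(0.1, 0.05) == pytest.approx(4.0)
    assert f_statistic(0.0, 0.05) == 0.0
    bx = np.array([0.1, 0.2, -0.3])
    sx = np.array([0.05, 0.1, 0.1])
    np.testing.assert_allclose(f_statistic(bx, sx), (bx / sx) ** 2)
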