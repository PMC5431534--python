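import math

import dendropy
import numpy as np
import pytest

from plastocomp.comparative_stats import (
    BMParams,
    blomberg_K,
    bm_simulate,
    group_ttest,
    mc_phylo_anova,
    pic_contrasts,
    pic_rate,
    sma_common_slope_test,
    sma_fit,
    vcv_matrix,
)
from plastocomp.synthetic_data import simulate_tree


class TestSMA:
    def test_exact_linear_data(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = sma_fit(x, 2 * x)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.ci_lo == pytest.approx(fit.ci_hi, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_negative_relationship_sign(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        fit = sma_fit(x, -x)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)

    def test_matches_closed_form_oracle(self, rng):
        x = rng.normal(size=10)
        y = 1.7 * x + rng.normal(size=10)
        fit = sma_fit(x, y)
        r = np.corrcoef(x, y)[0, 1]
        oracle = math.copysign(np.std(y, ddof=1) / np.std(x, ddof=1), r)
        assert fit.slope == pytest.approx(oracle, abs=1e-12)
        assert fit.r2 == pytest.approx(r * r, abs=1e-12)
        assert fit.ci_lo <= fit.slope <= fit.ci_hi

    def test_slope_squared_equals_variance_ratio(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        fit = sma_fit(x, y)
        assert fit.slope ** 2 == pytest.approx(np.var(y, ddof=1) / np.var(x, ddof=1),
                                               rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            sma_fit([1, 2], [1, 2])
        with pytest.raises(ValueError):
            sma_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCommonSlope:
    def test_single_group_equals_sma_fit(self, rng):
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30) * 0.3
        res = sma_common_slope_test([(x, y)])
        assert res.common_slope == sma_fit(x, y).slope
        assert res.p == 1.0

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(42)
        reps, rej = 300, 0
        for _ in range(reps):
            groups = []
            for _g in range(2):
                x = rng.normal(size=50)
                groups.append((x, 1.5 * x + rng.normal(size=50) * 0.8))
            if sma_common_slope_test(groups).p < 0.05:
                rej += 1
        assert 0.02 <= rej / reps <= 0.09

    def test_power_against_unequal_slopes(self):
        rng = np.random.default_rng(7)
        hits = 0
        reps = 50
        for _ in range(reps):
            x1 = rng.normal(size=100)
            x2 = rng.normal(size=100)
            groups = [
                (x1, x1 + rng.normal(size=100) * 0.5),
                (x2, 3 * x2 + rng.normal(size=100) * 0.5),
            ]
            if sma_common_slope_test(groups).p < 0.01:
                hits += 1
        assert hits / reps >= 0.95


class TestPIC:
    def test_two_tip_hand_case(self):
        tree = dendropy.Tree.get(data="(a:2,b:2);", schema="newick")
        cs = pic_contrasts(tree, {"a": 5.0, "b": 1.0})
        assert len(cs) == 1
        assert cs.contrasts[0] == pytest.approx((5 - 1) / math.sqrt(4), abs=1e-12)

    def test_equal_tips_give_zero_contrasts(self, balanced4_tree):
        cs = pic_contrasts(balanced4_tree, {t: 3.3 for t in "ABCD"})
        assert np.allclose(cs.contrasts, 0.0)

    def test_four_taxon_hand_worked_pruning(self, balanced4_tree):
        # pruning by hand: (A,B) node value 2, branch 1 + 1/2; (C,D) node
        # value 8, branch 1 + 1; root contrast (2-8)/sqrt(1.5 + 2)
        cs = pic_contrasts(balanced4_tree, {"A": 1.0, "B": 3.0, "C": 6.0, "D": 10.0})
        expected = [
            (1 - 3) / math.sqrt(2),
            (6 - 10) / math.sqrt(4),
            (2 - 8) / math.sqrt(3.5),
        ]
        assert cs.contrasts == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n_tips", [2, 5, 40])
    def test_contrast_count_is_n_minus_1(self, n_tips):
        tree = simulate_tree(n_tips, seed=n_tips)
        trait = {f"t{i+1}": float(i) for i in range(n_tips)}
        assert len(pic_contrasts(tree, trait)) == n_tips - 1

    def test_translation_invariance(self, rng):
        tree = simulate_tree(15, seed=3)
        trait = {f"t{i+1}": v for i, v in enumerate(rng.normal(size=15))}
        shifted = {k: v + 100.0 for k, v in trait.items()}
        a = pic_contrasts(tree, trait).contrasts
        b = pic_contrasts(tree, shifted).contrasts
        assert np.allclose(a, b, atol=1e-10)

    def test_polytomy_resolved_with_zero_branches(self, star5_tree):
        trait = {t: float(i) for i, t in enumerate("abcde")}
        cs = pic_contrasts(star5_tree, trait)
        assert len(cs) == 4
        assert np.all(np.isfinite(cs.contrasts))


class TestBMSimulate:
    def test_zero_rate_gives_root_value(self, balanced4_tree):
        sims = bm_simulate(balanced4_tree, BMParams(sigma2=0.0, root_value=7.5,
                                                    seed=1), n_reps=10)
        assert (sims.to_numpy() == 7.5).all()

    def test_tip_variance_and_covariance_match_analytics(self):
        tree = dendropy.Tree.get(data="((a:1,b:1):1,c:2);", schema="newick")
        sims = bm_simulate(tree, BMParams(sigma2=2.0, seed=9), n_reps=10_000)
        # var(tip) = sigma2 * depth = 4; cov(a, b) = sigma2 * shared path = 2
        assert sims["a"].var(ddof=1) == pytest.approx(4.0, rel=0.05)
        assert np.cov(sims["a"], sims["b"])[0, 1] == pytest.approx(2.0, rel=0.05)
        assert sims.mean().to_numpy() == pytest.approx([0, 0, 0], abs=4 * 0.02)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            BMParams(sigma2=-1.0)

    def test_vcv_matches_bm_definition(self):
        tree = dendropy.Tree.get(data="((a:1,b:1):1,c:2);", schema="newick")
        labels, V = vcv_matrix(tree)
        i = {lab: k for k, lab in enumerate(labels)}
        assert V[i["a"], i["a"]] == pytest.approx(2.0)
        assert V[i["a"], i["b"]] == pytest.approx(1.0)
        assert V[i["a"], i["c"]] == pytest.approx(0.0)


class TestBlombergK:
    def test_star_tree_K_is_one_for_any_data(self, star5_tree, rng):
        for _ in range(5):
            trait = dict(zip("abcde", rng.normal(size=5)))
            k = blomberg_K(star5_tree, trait)
            assert k.K == pytest.approx(1.0, abs=1e-10)

    def test_shuffled_traits_lose_signal(self):
        tree = simulate_tree(60, seed=21)
        sims = bm_simulate(tree, BMParams(sigma2=1.0, seed=22), n_reps=50)
        rng = np.random.default_rng(23)
        ks = []
        for i in range(50):
            vals = sims.iloc[i].to_numpy()
            rng.shuffle(vals)
            ks.append(blomberg_K(tree, dict(zip(sims.columns, vals))).K)
        assert np.mean(ks) < 1.0

    def test_ratio_fields_consistent(self):
        tree = simulate_tree(20, seed=5)
        trait = bm_simulate(tree, BMParams(seed=6), n_reps=1).iloc[0].to_dict()
        k = blomberg_K(tree, trait)
        assert k.K == pytest.approx(
            k.mse0_over_mse_observed / k.mse0_over_mse_expected, rel=1e-12
        )
        assert k.K > 0


class TestMCAnova:
    def test_identical_traits_give_p_zero(self):
        tree = simulate_tree(20, seed=2)
        trait = bm_simulate(tree, BMParams(seed=3), n_reps=1).iloc[0].to_dict()
        res = mc_phylo_anova(tree, trait, trait, n_sim=200, seed=4)
        assert math.isinf(res.F_observed)
        assert res.p == 0.0

    def test_C_is_95th_order_statistic(self):
        tree = simulate_tree(15, seed=8)
        sims = bm_simulate(tree, BMParams(seed=9), n_reps=2)
        res = mc_phylo_anova(tree, sims.iloc[0].to_dict(), sims.iloc[1].to_dict(),
                             n_sim=250, seed=10)
        assert res.C == np.sort(res.F_simulated)[math.ceil(0.95 * 250) - 1]

    def test_seed_reproducibility(self):
        tree = simulate_tree(15, seed=8)
        sims = bm_simulate(tree, BMParams(seed=9), n_reps=2)
        y, x = sims.iloc[0].to_dict(), sims.iloc[1].to_dict()
        a = mc_phylo_anova(tree, y, x, n_sim=150, seed=77)
        b = mc_phylo_anova(tree, y, x, n_sim=150, seed=77)
        assert np.array_equal(a.F_simulated, b.F_simulated)
        assert (a.C, a.p) == (b.C, b.p)

    def test_small_n_sim_rejected(self):
        tree = simulate_tree(10, seed=1)
        sims = bm_simulate(tree, BMParams(seed=2), n_reps=2)
        with pytest.raises(ValueError):
            mc_phylo_anova(tree, sims.iloc[0].to_dict(), sims.iloc[1].to_dict(),
                           n_sim=50, seed=3)


class TestPICRate:
    def test_rate_recovers_sigma2_on_average(self):
        tree = simulate_tree(100, seed=31)
        sims = bm_simulate(tree, BMParams(sigma2=3.0, seed=32), n_reps=100)
        rates = [pic_rate(tree, sims.iloc[i].to_dict()) for i in range(100)]
        assert np.mean(rates) == pytest.approx(3.0, rel=0.1)


class TestGroupTTest:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        t, p = group_ttest(a, list(a))
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_welch_formula(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 2, 17)
        t, p = group_ttest(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = math.sqrt(va / len(a) + vb / len(b))
        t_oracle = (a.mean() - b.mean()) / se
        df_oracle = (va / len(a) + vb / len(b)) ** 2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
        from scipy import stats

        p_oracle = 2 * stats.t.sf(abs(t_oracle), df_oracle)
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(99)
        sig = sum(
            group_ttest(rng.normal(0, 1, 50), rng.normal(2, 1, 50))[1] < 0.001
            for _ in range(100)
        )
        assert sig >= 99

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_ttest([1.0], [1.0, 2.0])
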