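import math

import numpy as np
import pytest
from scipy import stats

from popout import (
    SiblingPairTable,
    SynthSpec,
    conditional_sib_params,
    denovo_tail_test,
    gen_sibling_pairs,
    mendelian_tail_test,
    sib_h2_mle,
    standout_test,
)


class TestConditionalParams:
    @pytest.mark.parametrize(
        "s1,h2,mean,var",
        [
            (2.0, 1.0, 1.0, 0.75),
            (3.7, 0.0, 0.0, 1.0),  # independence limit
            (-1.5, 0.5, -0.375, 0.9375),
        ],
    )
    def test_known_values(self, s1, h2, mean, var):
        m, v = conditional_sib_params(s1, h2)
        assert m == pytest.approx(mean, abs=1e-12)
        assert v == pytest.approx(var, abs=1e-12)

    def test_invalid_h2_raises(self):
        with pytest.raises(ValueError):
            conditional_sib_params(1.0, 1.5)

    @pytest.mark.parametrize("h2", [0.0, 0.5, 1.0])
    def test_generator_reproduces_conditional_moments(self, h2):
        """Polygenic pairs match the conditional model across the s1 range."""
        pairs = gen_sibling_pairs(SynthSpec(n=200_000, h2=h2, seed=11))
        s1, s2 = pairs.s1, pairs.s2
        for lo, hi in [(-2.0, -1.0), (-0.5, 0.5), (1.0, 2.0)]:
            sel = (s1 >= lo) & (s1 < hi)
            m_exp = np.mean([conditional_sib_params(v, h2)[0] for v in s1[sel]])
            v_exp = conditional_sib_params(0.0, h2)[1]
            assert s2[sel].mean() == pytest.approx(m_exp, abs=0.05)
            assert s2[sel].var() == pytest.approx(v_exp, abs=0.05)


class TestH2MLE:
    def test_exact_fit_hits_upper_boundary(self):
        s1 = np.linspace(-3, 3, 200)
        pairs = SiblingPairTable(np.arange(200), s1, s1 / 2)
        est = sib_h2_mle(pairs)
        assert est.h2_hat == 1.0
        assert est.boundary

    def test_independent_pairs_estimate_near_zero(self, rng):
        pairs = SiblingPairTable(
            np.arange(50_000), rng.standard_normal(50_000), rng.standard_normal(50_000)
        )
        est = sib_h2_mle(pairs)
        assert est.h2_hat < 0.1

    @pytest.mark.parametrize("h2", [0.2, 0.5, 0.8])
    def test_recovery_from_synthetic_pairs(self, h2):
        pairs = gen_sibling_pairs(SynthSpec(n=10_000, h2=h2, seed=21))
        est = sib_h2_mle(pairs)
        assert est.h2_hat == pytest.approx(h2, abs=0.05)

    def test_matches_dense_grid_oracle(self):
        """Refined optimum agrees with an independent brute-force grid search."""
        pairs = gen_sibling_pairs(SynthSpec(n=5_000, h2=0.6, seed=33))
        est = sib_h2_mle(pairs)
        s1, s2 = pairs.both_orderings()
        grid = np.linspace(0, 1, 20_001)
        v = 1 - grid**2 / 4
        rss = np.array([np.sum((s2 - s1 * h / 2) ** 2) for h in grid])
        ll = -s1.size * np.log(v) - rss / v
        assert est.h2_hat == pytest.approx(grid[np.argmax(ll)], abs=1e-3)

    def test_too_few_pairs_raises(self, rng):
        with pytest.raises(ValueError):
            sib_h2_mle(SiblingPairTable(np.arange(10), rng.standard_normal(10), rng.standard_normal(10)))


class TestMendelianTailTest:
    def test_h2_zero_pi0_equals_tail_mass(self, rng):
        pairs = SiblingPairTable(
            np.arange(100_000), rng.standard_normal(100_000), rng.standard_normal(100_000)
        )
        res = mendelian_tail_test(pairs, h2=0.0, q=0.01, tail="upper")
        assert res.pi0 == pytest.approx(0.01, abs=1e-12)

    def test_null_center_when_r_matches_expectation(self):
        # constructed so that r equals n*pi0 exactly: z = 0, p = 0.5
        z = (10 - 10) / 1.0
        assert stats.norm.sf(z) == 0.5

    def test_family_segregating_effects_inflate_concordance(self):
        spec = SynthSpec(
            n=50_000, h2=0.5, architecture="mendelian", mendelian_effect=4.0,
            carrier_prob=0.01, seed=5,
        )
        pairs = gen_sibling_pairs(spec)
        res = mendelian_tail_test(pairs, h2=0.5, q=0.01, tail="upper")
        assert res.z > 3
        assert res.p < 1e-3
        # oracle: concordant count exceeds polygenic expectation directly
        assert res.r > res.n * res.pi0

    def test_power_against_family_segregating_effects(self):
        """Family-segregating +3 effects (transmission 1/2) push the upper-tail
        Mendelian z past the null 95th percentile in >= 90% of replicates."""
        hits = 0
        n_rep = 30
        for r in range(n_rep):
            pairs = gen_sibling_pairs(
                SynthSpec(n=20_000, h2=0.5, architecture="mendelian",
                          mendelian_effect=3.0, carrier_prob=0.01, seed=6000 + r)
            )
            res = mendelian_tail_test(pairs, h2=0.5, q=0.01, tail="upper")
            hits += res.z > 1.645
        assert hits / n_rep >= 0.9

    def test_calibrated_under_polygenic_null(self):
        """Concordance matches mean pi0 within binomial error under the null."""
        pairs = gen_sibling_pairs(SynthSpec(n=50_000, h2=0.5, seed=17))
        res = mendelian_tail_test(pairs, h2=sib_h2_mle(pairs).h2_hat, q=0.01, tail="upper")
        se = math.sqrt(res.n * res.pi0 * (1 - res.pi0))
        assert abs(res.r - res.n * res.pi0) < 4 * se

    def test_each_pair_enters_once_through_its_index_sibling(self):
        # a doubly-extreme pair is one index entry and one concordance success
        s1 = np.concatenate([[5.0], np.random.default_rng(0).standard_normal(999)])
        s2 = np.concatenate([[5.0], np.random.default_rng(1).standard_normal(999)])
        pairs = SiblingPairTable(np.arange(1000), s1, s2)
        res = mendelian_tail_test(pairs, h2=0.5, q=0.01, tail="upper")
        assert res.r == 1
        # pairs whose only extreme member is the conditional sibling are not indexed
        n_s1_tail = (s1 >= np.quantile(pairs.pooled(), 0.99)).sum()
        assert res.n == n_s1_tail


class TestDenovoTailTest:
    def test_zero_when_sibs_match_polygenic_expectation(self):
        s1 = np.linspace(2.5, 4.0, 100)
        rest1 = np.random.default_rng(2).standard_normal(9900) * 0.5
        pairs = SiblingPairTable(
            np.arange(10_000),
            np.concatenate([s1, rest1]),
            np.concatenate([s1 * 0.25, rest1 * 0.25]),  # s2 = s1 h2/2 with h2=0.5
        )
        res = denovo_tail_test(pairs, h2=0.5, q=0.01, tail="upper")
        # tail pairs sit exactly at the conditional mean except ordering swaps
        assert abs(res.z) < 2

    def test_h2_zero_reduces_to_standardized_sum(self, rng):
        s1 = rng.standard_normal(20_000)
        s2 = rng.standard_normal(20_000)
        pairs = SiblingPairTable(np.arange(20_000), s1, s2)
        res = denovo_tail_test(pairs, h2=0.0, q=0.01, tail="upper")
        thr = np.quantile(pairs.pooled(), 0.99)
        sel = s1 >= thr
        oracle = s2[sel].sum() / math.sqrt(sel.sum())
        assert res.z == pytest.approx(oracle, abs=1e-10)

    def test_denovo_architecture_gives_negative_upper_z(self):
        spec = SynthSpec(
            n=20_000, h2=0.8, architecture="denovo", denovo_effect=3.0,
            carrier_prob=0.01, seed=8,
        )
        pairs = gen_sibling_pairs(spec)
        res = denovo_tail_test(pairs, h2=0.8, q=0.01, tail="upper")
        assert res.z < -3
        assert res.p < 1e-4


class TestStandoutTest:
    def test_fisher_combination_arithmetic(self):
        # chi2 = -2(ln pM + ln pD); with both p = 0.05, chi2 ~ 11.98, p ~ 0.0175
        chi2 = -4 * math.log(0.05)
        assert chi2 == pytest.approx(11.9829, abs=1e-3)
        assert stats.chi2.sf(chi2, 4) == pytest.approx(0.01747, abs=1e-4)

    def test_combined_statistic_consistency(self):
        pairs = gen_sibling_pairs(SynthSpec(n=20_000, h2=0.5, seed=31))
        res = standout_test(pairs, tail="upper")
        expected = -2 * (math.log(res.mendelian.p) + math.log(res.denovo.p))
        assert res.chi2 == pytest.approx(expected, abs=1e-12)
        assert res.p == pytest.approx(stats.chi2.sf(expected, 4), abs=1e-15)

    def test_pinned_h2_is_respected(self):
        pairs = gen_sibling_pairs(SynthSpec(n=5_000, h2=0.5, seed=41))
        res = standout_test(pairs, tail="lower", h2=0.3)
        assert res.h2_hat == 0.3

    def test_null_p_not_degenerate(self):
        pairs = gen_sibling_pairs(SynthSpec(n=50_000, h2=0.5, seed=51))
        res = standout_test(pairs, tail="upper")
        assert 1e-4 < res.p <= 1.0

    @pytest.mark.parametrize("architecture", ["mendelian", "denovo"])
    def test_combined_no_weaker_than_worst_component(self, architecture):
        """Against non-polygenic tails, the median combined p does not exceed
        the median of the larger component p-value."""
        combined, worst = [], []
        for r in range(20):
            pairs = gen_sibling_pairs(
                SynthSpec(n=20_000, h2=0.5, architecture=architecture,
                          mendelian_effect=3.0, denovo_effect=3.0,
                          carrier_prob=0.01, seed=8100 + r)
            )
            res = standout_test(pairs, tail="upper", h2=0.5)
            combined.append(res.p)
            worst.append(max(res.mendelian.p, res.denovo.p))
        assert np.median(combined) <= np.median(worst)

    def test_component_pvalues_uniform_under_null(self):
        """Mendelian and de novo p-values are each calibrated under Eq.-style
        polygenic sibling pairs (KS uniformity over 200 replicates)."""
        pm, pd_ = [], []
        for r in range(200):
            pairs = gen_sibling_pairs(SynthSpec(n=20_000, h2=0.5, seed=700 + r))
            res = standout_test(pairs, tail="upper", h2=0.5)
            pm.append(res.mendelian.p)
            pd_.append(res.denovo.p)
        assert stats.kstest(pm, "uniform").pvalue > 0.01
        assert stats.kstest(pd_, "uniform").pvalue > 0.01

    def test_combined_test_is_not_anticonservative(self):
        """The Fisher combination may run conservative (its components share
        the tail pairs and are positively correlated) but must never exceed
        the nominal rate by more than binomial noise."""
        rejections = 0
        n_rep = 200
        for r in range(n_rep):
            pairs = gen_sibling_pairs(SynthSpec(n=20_000, h2=0.5, seed=1500 + r))
            rejections += standout_test(pairs, tail="upper", h2=0.5).p < 0.05
        # 99.9% one-sided binomial bound at p = 0.05, n = 200
        assert rejections / n_rep <= 0.05 + 3.09 * math.sqrt(0.05 * 0.95 / n_rep)
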