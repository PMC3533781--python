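import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from hlapop.frequency_inference import FrequencyEstimate, em_allele_frequencies
from hlapop.popgen_tests import (
    ewens_watterson_test,
    exact_ewens_null,
    expected_k,
    hwe_test,
    observed_homozygosity,
    sample_ewens_counts,
    watterson_theta,
)
from hlapop.synthetic_data import GeneratorConfig, generate_genotypes

from conftest import make_sample, unambiguous_from_counts


class TestHWE:
    def test_monomorphic_degenerate(self):
        s = make_sample([["A*01+A*01"]] * 5)
        with pytest.warns(UserWarning):
            r = hwe_test(s)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_two_allele_fixture_matches_profile_likelihood_oracle(self):
        s = unambiguous_from_counts(
            {("A*01", "A*01"): 30, ("A*01", "A*02"): 40, ("A*02", "A*02"): 30})
        r = hwe_test(s, alternative="inbreeding")

        def ll(p, f):
            paa = p * p + f * p * (1 - p)
            pbb = (1 - p) ** 2 + f * p * (1 - p)
            pab = 2 * p * (1 - p) * (1 - f)
            if min(paa, pbb, pab) <= 0:
                return -np.inf
            return 30 * np.log(paa) + 40 * np.log(pab) + 30 * np.log(pbb)

        ll_null = ll(0.5, 0.0)  # counting MLE under HWE
        best = -np.inf
        for f in np.linspace(-0.4, 0.9, 13001):
            opt = minimize_scalar(lambda p: -ll(p, f), bounds=(0.01, 0.99),
                                  method="bounded")
            best = max(best, -opt.fun)
        oracle_stat = 2 * (best - ll_null)
        assert r.statistic == pytest.approx(oracle_stat, abs=1e-5)
        assert r.df == 1
        assert r.f_hat == pytest.approx(0.2, abs=1e-4)  # het deficit of 40/50

    def test_saturated_matches_g_test_on_unambiguous_data(self):
        s = unambiguous_from_counts(
            {("A*01", "A*01"): 22, ("A*01", "A*02"): 46, ("A*02", "A*02"): 20,
             ("A*01", "A*03"): 8, ("A*03", "A*03"): 4})
        r = hwe_test(s, alternative="saturated", fallback=True)
        # classical G statistic on the genotype table at the counting MLE
        est = em_allele_frequencies(s, seed=0)
        p = est.frequencies
        N = s.n_individuals
        obs = {("A*01", "A*01"): 22, ("A*01", "A*02"): 46, ("A*02", "A*02"): 20,
               ("A*01", "A*03"): 8, ("A*03", "A*03"): 4}
        G = 0.0
        for (a, b), o in obs.items():
            e = N * (p[a] ** 2 if a == b else 2 * p[a] * p[b])
            G += 2 * o * np.log(o / e)
        assert r.statistic == pytest.approx(G, abs=1e-9)
        assert r.df == 3 * 4 // 2 - 3
        assert r.fallback is not None and r.fallback.method == "chi_square"

    def test_statistic_invariant_under_relabeling(self):
        s1 = unambiguous_from_counts(
            {("A*01", "A*01"): 12, ("A*01", "A*02"): 16, ("A*02", "A*02"): 12})
        s2 = unambiguous_from_counts(
            {("A*97", "A*97"): 12, ("A*97", "A*98"): 16, ("A*98", "A*98"): 12})
        r1, r2 = hwe_test(s1), hwe_test(s2)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-8)

    def test_duplicating_data_grows_statistic_on_hwe_violation(self):
        counts = {("A*01", "A*01"): 30, ("A*01", "A*02"): 20, ("A*02", "A*02"): 30}
        s1 = unambiguous_from_counts(counts)
        s2 = unambiguous_from_counts({k: 2 * v for k, v in counts.items()})
        assert hwe_test(s2).statistic >= hwe_test(s1).statistic - 1e-9

    def test_ambiguous_sample_accepted(self):
        cfg = GeneratorConfig(N=120, k_alleles=4, seed=2,
                              ambiguity_mode="random_merge", random_merge_rate=0.6)
        s = generate_genotypes(cfg)
        r = hwe_test(s)
        assert 0.0 <= r.p_value <= 1.0
        assert r.ambiguity_fraction > 0
        assert -1.0 <= r.f_hat <= 1.0


class TestObservedHomozygosity:
    def test_uniform_four_alleles(self):
        est = FrequencyEstimate(loci=["A"], frequencies={f"A*{i:02d}": 0.25 for i in range(1, 5)},
                                n_individuals=10, log_likelihood=0.0)
        assert observed_homozygosity(est) == pytest.approx(0.25)

    def test_single_allele(self):
        est = FrequencyEstimate(loci=["A"], frequencies={"A*01": 1.0},
                                n_individuals=10, log_likelihood=0.0)
        assert observed_homozygosity(est) == 1.0

    def test_direct_arithmetic(self):
        est = FrequencyEstimate(
            loci=["A"], frequencies={"A*01": 0.5, "A*02": 0.3, "A*03": 0.2},
            n_individuals=10, log_likelihood=0.0)
        assert observed_homozygosity(est) == pytest.approx(0.38)


class TestExactEwensNull:
    def test_n4_k2_hand_enumeration(self):
        ex = exact_ewens_null(4, 2)
        dist = ex.f_distribution()
        assert dist[0.625] == pytest.approx(8 / 11)   # partition 3+1
        assert dist[0.5] == pytest.approx(3 / 11)     # partition 2+2
        assert ex.mean_F == pytest.approx(6.5 / 11)

    @pytest.mark.parametrize("n", [3, 7, 12])
    def test_degenerate_k(self, n):
        one = exact_ewens_null(n, 1)
        assert len(one.partitions) == 1 and one.partitions[0][1] == 1.0
        alln = exact_ewens_null(n, n)
        assert len(alln.partitions) == 1
        assert alln.partitions[0][1] == pytest.approx(1 / n)

    def test_probabilities_sum_to_one(self):
        for n, k in [(10, 3), (12, 5), (8, 8)]:
            assert sum(p for _, _, p in exact_ewens_null(n, k).partitions) == (
                pytest.approx(1.0))

    def test_n_cap(self):
        with pytest.raises(ValueError):
            exact_ewens_null(40, 3)


class TestWattersonTheta:
    @pytest.mark.parametrize("n, k", [(10, 3), (100, 10), (50, 2)])
    def test_root_solves_expected_k(self, n, k):
        theta = watterson_theta(k, n)
        assert expected_k(theta, n) == pytest.approx(k, abs=1e-9)


class TestEwensWattersonTest:
    def _uniform_estimate(self, k, N):
        return FrequencyEstimate(
            loci=["A"], frequencies={f"A*{i:02d}": 1 / k for i in range(1, k + 1)},
            n_individuals=N, log_likelihood=0.0)

    def test_matches_exact_null_small_n(self):
        # MC null vs exact enumeration on all n <= 12 at a grid of k
        rng_checks = 0
        for n in (4, 6, 9, 12):
            for k in range(2, n):
                est = self._uniform_estimate(k, n // 2) if n % 2 == 0 else None
                if est is None:
                    continue
                r = ewens_watterson_test(est, replicates=3000, seed=n * 100 + k)
                ex = exact_ewens_null(n, k)
                se = np.sqrt(ex.var_F / r.replicates)
                assert abs(r.F_null_mean - ex.mean_F) <= 3 * se + 1e-12
                rng_checks += 1
        assert rng_checks >= 10

    def test_support_equals_exact_support(self):
        est = self._uniform_estimate(3, 4)  # n = 8, k = 3
        r = ewens_watterson_test(est, replicates=5000, seed=1)
        ex = exact_ewens_null(8, 3)
        # regenerate the accepted F values to compare support sets
        rng = np.random.default_rng(1)
        labels = sample_ewens_counts(8, r.theta_hat, 20000, rng)
        from hlapop.popgen_tests import _labels_to_F_and_k
        F, K = _labels_to_F_and_k(labels)
        support_mc = {round(f, 12) for f in F[K == 3]}
        support_exact = {round(f, 12) for f in ex.f_distribution()}
        assert support_mc == support_exact

    def test_all_singletons_extreme(self):
        est = self._uniform_estimate(4, 2)  # k = n = 4
        r = ewens_watterson_test(est, replicates=2000, seed=0)
        assert r.F_obs == pytest.approx(1 / 4)
        assert r.F_null_sd == 0.0
        assert r.p_low == 1.0 and r.p_high == 1.0  # every replicate ties
        assert r.p_low_mid == pytest.approx(0.5)

    def test_k_exceeding_n_rejected(self):
        est = self._uniform_estimate(5, 2)  # k=5 > n=4
        with pytest.raises(ValueError):
            ewens_watterson_test(est, replicates=100, seed=0)

    def test_tail_conventions(self):
        est = self._uniform_estimate(3, 10)
        r = ewens_watterson_test(est, replicates=4000, seed=5)
        assert r.p_low + r.p_high >= 1.0            # tie mass in both tails
        assert r.p_low_mid + r.p_high_mid == pytest.approx(1.0)
        assert 0 <= r.p_low <= 1 and 0 <= r.p_high <= 1
        assert 1 / r.k <= r.F_obs <= 1.0

    def test_balancing_selection_flagged_low(self):
        # maximally even frequencies: F_obs at its minimum given k
        est = self._uniform_estimate(6, 50)
        r = ewens_watterson_test(est, replicates=4000, seed=9)
        assert r.p_low < 0.1  # uniform frequencies are atypically heterozygous
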