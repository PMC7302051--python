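"""Sampler correctness: prior recovery, HPD/summary oracles, determinism."""

import math

import numpy as np
import pytest
from scipy import stats

import clockbench as cb
from clockbench import jc, mcmc as mc
from clockbench.seqsim import PatternCounts


@pytest.fixture
def three_taxon():
    return cb.make_three_taxon_tree()


class TestPriorDensities:
    def test_yule_small_lam_limit_uniform(self):
        # lam -> 0 tends to the uniform density 1/T per free node
        ages = np.array([[0.3]])
        v0 = mc.yule_log_density(ages, 1.0, 1e-15)
        assert v0[0] == pytest.approx(0.0)  # log(1/1.0)
        v = mc.yule_log_density(ages, 2.0, 1e-15)
        assert v[0] == pytest.approx(-math.log(2.0))
        # continuity: tiny but nonzero lam agrees with the limit
        v1 = mc.yule_log_density(ages, 1.0, 1e-9)
        assert v1[0] == pytest.approx(v0[0], abs=1e-6)

    def test_yule_out_of_range(self):
        assert mc.yule_log_density(np.array([[1.2]]), 1.0, 1.0) == -np.inf
        assert mc.yule_log_density(np.array([[-0.1]]), 1.0, 1.0) == -np.inf

    def test_yule_density_shape(self):
        # density decreases with age: younger divergences are more likely
        lam = 2.0
        lo = mc.yule_log_density(np.array([[0.2]]), 1.0, lam)
        hi = mc.yule_log_density(np.array([[0.8]]), 1.0, lam)
        assert lo[0] - hi[0] == pytest.approx(lam * 0.6)

    def test_clock_prior_strict(self):
        assert mc.clock_log_prior(None, mc.StrictClock(0.05)) == 0.0

    def test_clock_prior_ucln_matches_scipy(self):
        rates = np.array([0.05, 0.04, 0.06, 0.049])
        val = mc.clock_log_prior(rates, mc.UCLNClock(-3.01, 0.15))
        oracle = stats.lognorm.logpdf(rates, s=0.15,
                                      scale=np.exp(-3.01)).sum()
        assert val == pytest.approx(float(oracle), rel=1e-10)

    def test_clock_prior_nonpositive_rates(self):
        assert mc.clock_log_prior(np.array([0.05, -0.01]),
                                  mc.UCLNClock()) == -np.inf

    def test_clock_prior_dirichlet_flat_simplex(self):
        # alpha=1 Dirichlet log density is log((L-1)!)
        L = 5
        props = np.full(L, 1.0 / L)
        rates = np.full((L, 4), np.exp(-3.01))
        prior = mc.DirichletRateClock()
        val = mc.clock_log_prior((np.exp(-3.01), props, rates), prior)
        expect = math.lgamma(L)  # log((L-1)!)
        expect += float(stats.lognorm.logpdf(np.exp(-3.01), s=0.15,
                                             scale=np.exp(-3.01)))
        loc = np.exp(-3.01) * L * props  # locus means; all equal mu_bar here
        expect += float(stats.lognorm.logpdf(rates, s=0.15,
                                             scale=loc[:, None]).sum())
        assert val == pytest.approx(expect, rel=1e-10)


class TestHPD:
    def test_uniform_grid_width(self):
        s = np.linspace(0, 1, 10_001)
        h = mc.hpd_interval(s, 0.95)
        assert h.width == pytest.approx(0.95, abs=1e-3)

    def test_point_mass(self):
        h = mc.hpd_interval(np.zeros(500) + 3.2)
        assert h.width == 0.0
        assert h.lower == 3.2

    def test_normal_width_oracle(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(100_000)
        h = mc.hpd_interval(s, 0.95)
        assert h.width == pytest.approx(2 * 1.959964, rel=0.02)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            mc.hpd_interval(np.arange(50))

    def test_empirical_mass(self):
        rng = np.random.default_rng(1)
        s = rng.exponential(1.0, 5000)
        h = mc.hpd_interval(s, 0.9)
        assert np.mean((s >= h.lower) & (s <= h.upper)) >= 0.9


class TestPosteriorMean:
    def test_constant_trace(self):
        assert mc.posterior_mean(np.full((200, 1), 0.37)) == pytest.approx(0.37)

    def test_symmetric_trace(self):
        s = np.concatenate([0.5 - np.linspace(0, 0.2, 50),
                            0.5 + np.linspace(0, 0.2, 50)])
        assert mc.posterior_mean(s[:, None]) == pytest.approx(0.5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mc.posterior_mean(np.empty((0, 1)))


@pytest.fixture(scope="module")
def prior_trace():
    tree = cb.make_three_taxon_tree()
    sched = mc.MCMCSchedule(40_000, 0.25, 20)
    return mc.run_mcmc(None, tree, mc.UCLNClock(), mc.YulePrior(),
                       schedule=sched, seed=11)


class TestPriorRecovery:
    """Likelihood-disabled runs must reproduce every prior marginal."""

    def test_node_age_uniform(self, prior_trace):
        # with lam ~ Exp(10) the marginal age prior is uniform on (0, 1) to
        # within ~0.01 in CDF; a KS test at this sample size cannot and
        # should not reject
        ages = prior_trace.node_ages[:, 0]
        assert stats.kstest(ages, "uniform").pvalue > 0.01
        assert ages.mean() == pytest.approx(0.5, abs=0.02)

    def test_branch_rates_lognormal(self, prior_trace):
        for b in range(4):
            r = prior_trace.rates[:, b]
            p = stats.kstest(np.log(r), "norm", args=(-3.01, 0.15)).pvalue
            assert p > 0.005

    def test_lambda_exponential(self, prior_trace):
        lam = prior_trace.lam
        # lam is tilted away from Exp(10) by the Yule normalizer; mean and
        # support checks only
        assert lam.min() > 0
        assert lam.mean() == pytest.approx(0.1, rel=0.5)

    def test_strict_clock_prior_only(self):
        tree = cb.make_three_taxon_tree()
        sched = mc.MCMCSchedule(20_000, 0.25, 10)
        trace = mc.run_mcmc(None, tree, mc.StrictClock(), mc.YulePrior(),
                            schedule=sched, seed=12)
        assert stats.kstest(trace.node_ages[:, 0], "uniform").pvalue > 0.01


class TestSampler:
    def test_seed_determinism(self, three_taxon):
        rng = np.random.default_rng(0)
        pats = jc.pattern_matrix(3)
        counts = PatternCounts(["A", "B", "C"], pats,
                               rng.multinomial(800, np.full(64, 1 / 64)))
        sched = mc.MCMCSchedule(2000, 0.25, 5)
        t1 = mc.run_mcmc(counts, three_taxon, mc.UCLNClock(), mc.YulePrior(),
                         schedule=sched, seed=42)
        t2 = mc.run_mcmc(counts, three_taxon, mc.UCLNClock(), mc.YulePrior(),
                         schedule=sched, seed=42)
        assert np.array_equal(t1.node_ages, t2.node_ages)
        t3 = mc.run_mcmc(counts, three_taxon, mc.UCLNClock(), mc.YulePrior(),
                         schedule=sched, seed=43)
        assert not np.array_equal(t1.node_ages, t3.node_ages)

    def test_posterior_concentrates_on_truth_strict(self, three_taxon):
        # strict clock, correct rate, long alignment: posterior hugs 0.5
        from clockbench.trees import RatedTree
        rng = np.random.default_rng(5)
        rated = RatedTree(three_taxon, three_taxon.branch_durations())
        pc = cb.simulate_pattern_counts(rated, 320_000, jc.JCParams(0.05), rng)
        sched = mc.MCMCSchedule(8000, 0.25, 5)
        trace = mc.run_mcmc(pc, three_taxon, mc.StrictClock(0.05),
                            mc.YulePrior(), jc.JCParams(0.05), sched, seed=1)
        assert mc.posterior_mean(trace) == pytest.approx(0.5, abs=0.02)
        assert trace.node_ages[:, 0].std() < 0.01

    def test_multi_locus_equals_concatenated_counts(self, three_taxon):
        # shared-rate likelihood collapses onto pooled patterns: identical
        # traces from per-locus data and the pooled equivalent
        from clockbench.trees import RateClassConfig
        from clockbench import experiment as ex
        rng = np.random.default_rng(9)
        counts, pats = ex.simulate_condition_counts(
            three_taxon, RateClassConfig(n_loci=10), 200, jc.JCParams(0.05),
            1, rng)
        per_locus = [PatternCounts(["A", "B", "C"], pats, counts[0, l])
                     for l in range(10)]
        pooled = PatternCounts(["A", "B", "C"], pats, counts[0].sum(axis=0))
        sched = mc.MCMCSchedule(2000, 0.25, 5)
        a = mc.run_mcmc(per_locus, three_taxon, mc.UCLNClock(),
                        mc.YulePrior(), schedule=sched, seed=3)
        b = mc.run_mcmc(pooled, three_taxon, mc.UCLNClock(),
                        mc.YulePrior(), schedule=sched, seed=3)
        assert np.array_equal(a.node_ages, b.node_ages)

    def test_batch_chain_view_consistent(self, three_taxon):
        rng = np.random.default_rng(2)
        pats = jc.pattern_matrix(3)
        counts = rng.multinomial(800, np.full(64, 1 / 64), size=(3,))
        sched = mc.MCMCSchedule(1000, 0.25, 5)
        batch = mc.run_mcmc_batch(counts, pats, three_taxon, mc.UCLNClock(),
                                  mc.YulePrior(), schedule=sched, seed=4)
        assert batch.node_ages.shape[0] == 3
        tr = batch.chain(1)
        assert np.array_equal(tr.node_ages, batch.node_ages[1])


class TestDetailedBalance:
    def test_metropolis_kernel_transition_symmetry(self):
        """Empirical detailed balance of the MH accept rule on a 2-state
        discretized target: pi_i P(i->j) == pi_j P(j->i)."""
        rng = np.random.default_rng(0)
        # continuous chain with the package's reflected-window proposal,
        # discretized into two states at 0.5; target: Beta(2, 1) on (0, 1)
        from clockbench.mcmc import _reflect

        def logpi(x):
            return np.log(2 * x)

        x = 0.7
        lp = logpi(x)
        w = 0.3
        n = 150_000
        flows = {(0, 1): 0, (1, 0): 0}
        occup = [0, 0]
        for _ in range(n):
            s0 = int(x > 0.5)
            y = _reflect(np.array([x + w * (2 * rng.random() - 1)]),
                         np.array([0.0]), np.array([1.0]))[0]
            lpy = logpi(y)
            if np.log(rng.random()) < lpy - lp:
                x, lp = y, lpy
            s1 = int(x > 0.5)
            occup[s1] += 1
            if s0 != s1:
                flows[(s0, s1)] += 1
        # stationary flow balance between the two halves
        assert flows[(0, 1)] == pytest.approx(flows[(1, 0)], rel=0.05)
        # occupancy matches the target mass split (0.25 / 0.75)
        assert occup[1] / n == pytest.approx(0.75, abs=0.02)
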