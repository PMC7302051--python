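"""Tree construction, Yule simulation, and rate-class overlay tests."""

import numpy as np
import pytest

import clockbench as cb
from clockbench.trees import LognormalSpec, RateClassConfig


@pytest.fixture
def three_taxon():
    return cb.make_three_taxon_tree()


class TestThreeTaxonTree:
    def test_branch_durations(self, three_taxon):
        dur = three_taxon.branch_durations()
        # A, B, internal at 0.5; outgroup C spans the full root age
        assert dur[0] == dur[1] == dur[3] == 0.5
        assert dur[2] == 1.0
        assert dur.sum() == pytest.approx(2.5)

    def test_ultrametric_paths(self, three_taxon):
        # both cherry tips sit 1.0 below the root
        assert three_taxon.ages[4] == 1.0
        assert three_taxon.ages[3] == 0.5
        assert np.all(three_taxon.ages[:3] == 0)

    def test_four_branches(self, three_taxon):
        assert three_taxon.branch_nodes.size == 4

    def test_newick_roundtrip(self, three_taxon):
        back = cb.TimeTree.from_newick(three_taxon.to_newick())
        assert sorted(back.labels) == ["A", "B", "C"]
        assert back.root_age == pytest.approx(1.0)
        assert sorted(back.ages[back.n_tips:]) == pytest.approx([0.5, 1.0])


class TestYule:
    def test_two_taxon_is_cherry(self):
        t = cb.simulate_yule_tree(2, 1.0, np.random.default_rng(0))
        assert t.n_tips == 2 and t.n_nodes == 3
        assert t.root_age > 0

    def test_internal_node_count(self):
        for seed in range(20):
            t = cb.simulate_yule_tree(8, 1.0, np.random.default_rng(seed))
            assert t.n_nodes - t.n_tips == 7
            assert np.all(t.ages[t.n_tips:] > 0)

    def test_invalid_args(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            cb.simulate_yule_tree(1, 1.0, rng)
        with pytest.raises(ValueError):
            cb.simulate_yule_tree(4, 0.0, rng)

    def test_waiting_times_match_exponential_rates(self):
        # while k lineages exist the wait to the next split is Exp(k * lam):
        # Monte-Carlo means against the 1/(k lam) oracle
        lam, n = 1.0, 6
        waits = {k: [] for k in range(2, n)}
        rng = np.random.default_rng(2024)
        for _ in range(4000):
            t = cb.simulate_yule_tree(n, lam, rng)
            splits = np.sort(t.ages[t.n_tips:])[::-1]  # oldest first
            for k in range(2, n):
                waits[k].append(splits[k - 2] - splits[k - 1])
        for k in range(2, n):
            mean = np.mean(waits[k])
            expected = 1.0 / (k * lam)
            assert mean == pytest.approx(expected, rel=0.06)


class TestRateClasses:
    def test_sigma_zero_identity(self, three_taxon):
        rng = np.random.default_rng(0)
        rt = cb.apply_lineage_rates(three_taxon, LognormalSpec(0.0, 0.0), rng)
        assert rt.branch_lengths == pytest.approx(three_taxon.branch_durations())

    def test_lineage_mean_multiplier(self, three_taxon):
        # sample mean multiplier ~ exp(mu + sigma^2/2) = 1.00127
        rng = np.random.default_rng(1)
        spec = LognormalSpec(-0.01, 0.15)
        dur = three_taxon.branch_durations()
        mults = []
        for _ in range(2500):
            rt = cb.apply_lineage_rates(three_taxon, spec, rng)
            mults.append(rt.branch_lengths[:4] / dur[:4])
        assert np.mean(mults) == pytest.approx(spec.mean, abs=3 * 0.15 / 100)
        assert spec.mean == pytest.approx(1.0012508, abs=1e-6)

    def test_one_draw_per_branch(self, three_taxon):
        # lineage rates consume exactly 4 normal draws on the 3-taxon tree
        rng1 = np.random.default_rng(7)
        cb.apply_lineage_rates(three_taxon, LognormalSpec(-0.01, 0.15), rng1)
        rng2 = np.random.default_rng(7)
        rng2.standard_normal(4)
        assert rng1.standard_normal() == rng2.standard_normal()

    def test_gene_rate_uniform_scaling(self, three_taxon):
        rng = np.random.default_rng(2)
        base = cb.apply_lineage_rates(three_taxon, LognormalSpec(0.0, 0.0), rng)
        scaled = cb.apply_gene_rate(base, LognormalSpec(-0.01, 0.15), rng)
        ratio = scaled.branch_lengths[:4] / base.branch_lengths[:4]
        assert np.ptp(ratio) == pytest.approx(0.0, abs=1e-12)

    def test_residual_mean_equal_across_branches(self, three_taxon):
        # averaged over many loci each branch has the same expected multiplier
        rng = np.random.default_rng(3)
        spec = LognormalSpec(-0.01, 0.15)
        cfg = RateClassConfig(residual=spec, n_loci=4000)
        trees = cb.generate_gene_trees(three_taxon, cfg, rng)
        dur = three_taxon.branch_durations()
        mults = np.stack([g.branch_lengths[:4] / dur[:4] for g in trees])
        per_branch = mults.mean(axis=0)
        se = 3 * 0.15 / np.sqrt(4000)
        assert per_branch == pytest.approx([spec.mean] * 4, abs=se)

    def test_lineage_only_identical_across_loci(self, three_taxon):
        rng = np.random.default_rng(4)
        cfg = RateClassConfig(lineage=LognormalSpec(-0.01, 0.15), n_loci=10)
        trees = cb.generate_gene_trees(three_taxon, cfg, rng)
        for g in trees[1:]:
            assert g.branch_lengths == pytest.approx(trees[0].branch_lengths)

    def test_lineage_plus_residual_branch_means_differ(self, three_taxon):
        # per-branch means across loci recover the lineage factors
        rng = np.random.default_rng(5)
        spec = LognormalSpec(-0.01, 0.15)
        lineage = cb.apply_lineage_rates(three_taxon, spec, rng)
        cfg = RateClassConfig(residual=spec, n_loci=6000)
        dur = three_taxon.branch_durations()
        loci = []
        for g in cb.generate_gene_trees(three_taxon, cfg, rng):
            loci.append(g.branch_lengths[:4] * lineage.branch_lengths[:4] / dur[:4])
        per_branch = np.stack(loci).mean(axis=0)
        expected = lineage.branch_lengths[:4] * spec.mean
        assert per_branch == pytest.approx(expected, rel=0.02)

    def test_seeded_reproducibility(self, three_taxon):
        cfg = RateClassConfig(LognormalSpec(-0.01, 0.15),
                              LognormalSpec(-0.01, 0.15),
                              LognormalSpec(-0.01, 0.15), n_loci=5)
        a = cb.generate_gene_trees(three_taxon, cfg, np.random.default_rng(9))
        b = cb.generate_gene_trees(three_taxon, cfg, np.random.default_rng(9))
        for x, y in zip(a, b):
            assert np.array_equal(x.branch_lengths, y.branch_lengths)

    def test_composed_log_variance(self, three_taxon):
        # log multiplier of k composed classes is normal with summed variance
        from scipy import stats

        rng = np.random.default_rng(6)
        cfg = RateClassConfig(LognormalSpec(-0.01, 0.15),
                              LognormalSpec(-0.01, 0.2),
                              LognormalSpec(-0.01, 0.1), n_loci=5000)
        dur = three_taxon.branch_durations()
        logm = []
        for g in cb.generate_gene_trees(three_taxon, cfg, rng):
            logm.append(np.log(g.branch_lengths[0] / dur[0]))
        logm = np.asarray(logm)
        sigma = np.sqrt(0.15**2 + 0.2**2 + 0.1**2)
        # lineage draw is shared across loci: subtract it before testing the
        # per-locus normal component
        gene_resid_sd = np.sqrt(0.2**2 + 0.1**2)
        p = stats.kstest(logm - logm.mean(), "norm",
                         args=(0.0, gene_resid_sd)).pvalue
        assert p > 0.01
        assert sigma > gene_resid_sd  # composition adds variance

    def test_invalid_n_loci(self):
        with pytest.raises(ValueError):
            RateClassConfig(n_loci=0)
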