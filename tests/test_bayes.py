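import numpy as np
import pytest
from scipy import stats

from dompop import (BandCounts, MarkerMatrix, model_loglik, pairwise_theta,
                    sample_theta, simulate_from_hierarchy)

REDUCED = dict(burn_in=1000, run_length=4000, thin=10, n_chains=1)


def single_cell(n, x):
    return BandCounts(n=np.array([[n]]), x=np.array([[x]]))


class TestModelLoglik:
    def test_hand_value_binomial(self):
        # n=2, x=1, q=0.5: P = C(2,1) q^2 (1-q^2) = 2 * 0.25 * 0.75
        ll = model_loglik(np.array([[0.5]]), single_cell(2, 1))
        assert ll == pytest.approx(np.log(0.375))

    def test_boundary_limit(self):
        # n=1, x=1: log P = 2 log q -> 0 as q -> 1
        eps = 1e-6
        ll = model_loglik(np.array([[1 - eps]]), single_cell(1, 1))
        assert ll == pytest.approx(2 * np.log(1 - eps), abs=1e-12)

    def test_additive_over_cells(self):
        rng = np.random.default_rng(1)
        n = np.full((2, 8), 20)
        x = rng.integers(0, 21, size=(2, 8))
        q = rng.uniform(0.1, 0.9, size=(2, 8))
        counts = BandCounts(n=n, x=x)
        total = model_loglik(q, counts)
        parts = sum(model_loglik(q[:, [j]], BandCounts(n=n[:, [j]], x=x[:, [j]]))
                    for j in range(8))
        assert total == pytest.approx(parts)

    def test_matches_scipy_binom(self):
        rng = np.random.default_rng(2)
        n = rng.integers(1, 30, size=(3, 5))
        x = rng.binomial(n, 0.4)
        q = rng.uniform(0.05, 0.95, size=(3, 5))
        counts = BandCounts(n=n, x=x)
        expected = stats.binom.logpmf(x, n, q ** 2).sum()
        assert model_loglik(q, counts) == pytest.approx(expected)

    def test_rejects_boundary_q(self):
        with pytest.raises(ValueError):
            model_loglik(np.array([[1.0]]), single_cell(2, 1))


class TestBandCounts:
    def test_from_matrix_tallies(self, small_matrix):
        c = BandCounts.from_matrix(small_matrix)
        assert c.populations == ["A", "B"]
        # population B, locus L2 has one missing call
        assert c.n[1, 2] == 2 and c.x[1, 2] == 1

    def test_x_bounded_by_n(self):
        with pytest.raises(ValueError):
            BandCounts(n=np.array([[2]]), x=np.array([[3]]))


class TestSampleTheta:
    def test_same_seed_bit_identical(self):
        c, _ = simulate_from_hierarchy(2, 30, 20, 0.2, seed=5)
        p1 = sample_theta(c, seed=7, **REDUCED)
        p2 = sample_theta(c, seed=7, **REDUCED)
        assert np.array_equal(p1.samples, p2.samples)
        assert p1.point == p2.point and p1.dic == p2.dic

    def test_dic_identity_and_shapes(self):
        c, _ = simulate_from_hierarchy(2, 40, 20, 0.25, seed=8)
        p = sample_theta(c, seed=9, **REDUCED)
        assert p.dic == pytest.approx(p.dbar + p.pd)
        assert p.pd >= 0
        assert len(p.samples) == REDUCED["run_length"] // REDUCED["thin"]
        assert np.all((p.samples > 0) & (p.samples < 1))
        lo, hi = p.ci95
        assert lo <= np.median(p.samples) <= hi

    def test_identical_populations_low_theta(self):
        # two populations with the same counts at every locus: no signal
        rng = np.random.default_rng(3)
        x = rng.integers(2, 18, size=(1, 60))
        c = BandCounts(n=np.full((2, 60), 100), x=np.vstack([x, x]) * 5)
        p = sample_theta(c, seed=4, **REDUCED)
        assert p.point < 0.1

    def test_prior_predictive_is_uniform(self):
        """With no observations the theta posterior must reproduce its
        Uniform(0, 1) prior."""
        c = BandCounts(n=np.zeros((2, 20), dtype=int), x=np.zeros((2, 20), dtype=int))
        p = sample_theta(c, burn_in=2000, run_length=50_000, thin=10,
                         seed=11, n_chains=1)
        assert len(p.samples) == 5000
        ks = stats.kstest(p.samples, "uniform").statistic
        assert ks < 0.05

    def test_recovers_generating_theta(self):
        c, _ = simulate_from_hierarchy(2, 100, 20, 0.3, seed=1)
        p = sample_theta(c, burn_in=2000, run_length=10_000, thin=10,
                         seed=2, n_chains=1)
        assert p.point == pytest.approx(0.3, abs=0.1)

    def test_needs_two_populations(self):
        with pytest.raises(ValueError):
            sample_theta(single_cell(5, 1), **REDUCED)


class TestPairwiseTheta:
    @pytest.fixture(scope="class")
    def three_pop_posts(self):
        rng = np.random.default_rng(12)
        bands = rng.integers(0, 2, size=(30, 25)).astype(np.int8)
        m = MarkerMatrix(bands, [f"i{k}" for k in range(30)],
                         ["A"] * 10 + ["B"] * 10 + ["C"] * 10,
                         [f"L{j}" for j in range(25)])
        return pairwise_theta(m, burn_in=500, run_length=2000, thin=10,
                              seed=3, n_chains=1)

    def test_three_pops_three_pairs(self, three_pop_posts):
        assert set(three_pop_posts) == {("A", "B"), ("A", "C"), ("B", "C")}

    def test_symmetric_by_construction(self, three_pop_posts):
        """The pair's stream is derived from the sorted pair, so the
        estimate cannot depend on argument order."""
        from dompop.bayes import theta_table
        df = theta_table(three_pop_posts)
        assert df.loc["A", "B"] != "" and df.loc["B", "A"] != ""
        assert float(df.loc["A", "B"]) == pytest.approx(
            three_pop_posts[("A", "B")].point, abs=1e-4)

    def test_ordering_recovered_between_strong_and_weak_pairs(self):
        cw, _ = simulate_from_hierarchy(2, 80, 20, 0.1, seed=21)
        cs, _ = simulate_from_hierarchy(2, 80, 20, 0.4, seed=22)
        pw = sample_theta(cw, seed=23, **REDUCED)
        ps = sample_theta(cs, seed=24, **REDUCED)
        assert pw.point < ps.point


class TestHierarchySimulator:
    def test_moments_of_hierarchy(self):
        """Var(q | pi) = pi (1 - pi) theta under the Beta hierarchy."""
        theta = 0.3
        _, truth = simulate_from_hierarchy(200, 50, 20, theta, seed=6)
        pi, q = truth["pi"], truth["q"]
        expected = pi * (1 - pi) * theta
        observed = q.var(axis=0, ddof=1)
        # average over loci: each locus has 200 population draws
        assert observed.mean() == pytest.approx(expected.mean(), rel=0.1)

    def test_theta_zero_limit(self):
        _, truth = simulate_from_hierarchy(5, 40, 20, 1e-4, seed=7)
        assert truth["q"].var(axis=0).max() < 1e-3

    def test_reproducible(self):
        c1, _ = simulate_from_hierarchy(3, 20, 20, 0.2, seed=9)
        c2, _ = simulate_from_hierarchy(3, 20, 20, 0.2, seed=9)
        assert np.array_equal(c1.x, c2.x)

    def test_theta_domain(self):
        with pytest.raises(ValueError):
            simulate_from_hierarchy(2, 10, 10, 0.0, seed=1)
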