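import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dompop import (MISSING, MarkerMatrix, compare_populations,
                    locus_diversity, population_diversity, shannon_ci)
from dompop.diversity import diversity_table, pairwise_mannwhitney


def brute_force_u(a, b):
    """U statistic for sample a by direct pair counting (ties count 1/2)."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


def one_pop(bands):
    bands = np.asarray(bands, dtype=np.int8)
    n = bands.shape[0]
    return MarkerMatrix(bands, [f"i{k}" for k in range(n)], ["P"] * n,
                        [f"L{j}" for j in range(bands.shape[1])])


class TestLocusDiversity:
    def test_quarter_null_closed_form(self):
        col = np.array([0] * 4 + [1] * 12, dtype=np.int8)  # 4 of 16 absent
        d = locus_diversity(col)
        assert d.q == pytest.approx(0.5)
        assert d.p == pytest.approx(0.5)
        assert d.h == pytest.approx(0.5)
        assert d.ne == pytest.approx(2.0)
        assert d.na == 2
        assert d.s == pytest.approx(np.log(2))

    @pytest.mark.parametrize("value,q_expected", [(1, 0.0), (0, 1.0)])
    def test_monomorphic_limits(self, value, q_expected):
        d = locus_diversity(np.full(20, value, dtype=np.int8))
        assert d.q == pytest.approx(q_expected)
        assert (d.h, d.ne, d.na, d.s) == (0.0, 1.0, 1, 0.0)

    def test_unscored_locus_rejected(self):
        with pytest.raises(ValueError):
            locus_diversity(np.full(5, MISSING, dtype=np.int8))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2 ** 30))
    def test_closed_forms_to_machine_precision(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        col = rng.integers(0, 2, size=n).astype(np.int8)
        d = locus_diversity(col)
        q = np.sqrt((col == 0).sum() / n)
        f = (col == 1).sum() / n
        assert d.q == pytest.approx(q, abs=1e-12)
        assert d.h == pytest.approx(1 - (1 - q) ** 2 - q ** 2, abs=1e-12)
        assert d.ne == pytest.approx(1 / ((1 - q) ** 2 + q ** 2), abs=1e-12)
        assert d.band_freq == pytest.approx(f, abs=1e-12)
        s = 0.0 if q in (0.0, 1.0) else -((1 - q) * np.log(1 - q) + q * np.log(q))
        assert d.s == pytest.approx(s, abs=1e-12)
        assert 0 <= d.h <= 0.5 and 1 <= d.ne <= 2 and 0 <= d.s <= np.log(2) + 1e-15


class TestPopulationDiversity:
    def test_monomorphic_population(self):
        m = one_pop(np.ones((10, 6)))
        d = population_diversity(m, "P", n_boot=None)
        assert d.pct_poly == 0.0 and d.mean_h == 0.0

    def test_polymorphic_fraction(self):
        bands = np.ones((10, 10), dtype=np.int8)
        bands[0, :3] = 0  # 3 of 10 loci polymorphic
        d = population_diversity(one_pop(bands), "P", n_boot=None)
        assert d.pct_poly == pytest.approx(30.0)
        assert d.n_poly == 3

    def test_reordering_invariance_and_oracle(self):
        rng = np.random.default_rng(7)
        bands = rng.integers(0, 2, size=(20, 30)).astype(np.int8)
        d1 = population_diversity(one_pop(bands), "P", n_boot=None)
        d2 = population_diversity(one_pop(bands[rng.permutation(20)]), "P", n_boot=None)
        assert d1.mean_h == pytest.approx(d2.mean_h)
        assert d1.mean_s == pytest.approx(d2.mean_s)
        # brute-force recomputation
        hs = []
        for j in range(30):
            q = np.sqrt((bands[:, j] == 0).mean())
            hs.append(1 - q * q - (1 - q) ** 2)
        assert d1.mean_h == pytest.approx(np.mean(hs))

    def test_flip_in_monomorphic_locus_increases_h(self):
        base = np.ones((20, 1), dtype=np.int8)
        h0 = population_diversity(one_pop(base), "P", n_boot=None).mean_h
        flipped = base.copy()
        flipped[0, 0] = 0
        h1 = population_diversity(one_pop(flipped), "P", n_boot=None).mean_h
        assert h1 > h0 == 0.0


class TestShannonCI:
    def test_identical_individuals_degenerate_interval(self):
        m = one_pop(np.tile([1, 0, 1], (10, 1)))
        assert shannon_ci(m, "P", n_boot=200, seed=0) == (0.0, 0.0)

    def test_deterministic_given_seed(self, small_matrix):
        a = shannon_ci(small_matrix, "A", n_boot=300, seed=11)
        b = shannon_ci(small_matrix, "A", n_boot=300, seed=11)
        assert a == b

    def test_endpoints_bounded_and_ordered(self):
        rng = np.random.default_rng(3)
        m = one_pop(rng.integers(0, 2, size=(15, 40)))
        lo, hi = shannon_ci(m, "P", n_boot=400, seed=5)
        assert 0.0 <= lo <= hi <= np.log(2)

    def test_bootstrap_interval_covers_generating_mean(self):
        """Nominal 95% interval covers the generating-model mean Shannon
        term in roughly 95% of replicate simulations.

        Run with many individuals per locus: the sqrt-estimator's O(1/n)
        bias must be small against the per-locus-averaged standard error
        (O(1/sqrt(nL))) for a percentile interval to attain its nominal
        level, so coverage requires n >> L.
        """
        rng = np.random.default_rng(42)
        L, n = 20, 400
        band_p = rng.uniform(0.1, 0.9, size=L)
        q = np.sqrt(1 - band_p)  # generating null-allele frequencies
        truth = float(np.mean(-(q * np.log(q) + (1 - q) * np.log(1 - q))))
        hits = 0
        reps = 200
        for r in range(reps):
            bands = (rng.random((n, L)) < band_p).astype(np.int8)
            lo, hi = shannon_ci(one_pop(bands), "P", n_boot=400, seed=r)
            hits += lo <= truth <= hi
        assert hits / reps >= 0.90


class TestMannWhitney:
    def test_identical_samples(self):
        a = list(range(1, 13))
        U, p = compare_populations(a, a)
        assert U == pytest.approx(len(a) ** 2 / 2)
        assert p > 0.9

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20)
        U, p = compare_populations(a, a + 10)
        assert p < 0.001
        assert U == brute_force_u(a, a + 10)

    def test_complete_separation(self):
        U, p = compare_populations([1, 2, 3], [4, 5, 6])
        assert U == 0.0

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 30))
    def test_u_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 6, size=rng.integers(3, 15)).astype(float)
        b = rng.integers(0, 6, size=rng.integers(3, 15)).astype(float)
        U, _ = compare_populations(a, b)
        assert U == pytest.approx(brute_force_u(a, b))


class TestTables:
    def test_diversity_table_one_row_per_population(self, small_matrix):
        df = diversity_table(small_matrix, n_boot=100, seed=1)
        assert list(df["population"]) == ["A", "B"]
        assert (df["s_ci_low"] <= df["s_ci_high"]).all()

    def test_pairwise_table_counts_pairs(self, small_matrix):
        df = pairwise_mannwhitney(small_matrix)
        assert len(df) == 1
        assert set(df.columns) == {"pop_a", "pop_b", "U", "p_value"}
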