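import numpy as np
import pytest
from scipy import stats as sps

from poolcomp import structure as stx
from poolcomp.datatypes import FrequencyTable
from poolcomp.synthetic import SimConfig, TrueFrequencies, simulate_genotypes
from tests.test_frequencies import make_scores


def freq_table(p, accession="A"):
    p = np.asarray(p, dtype=float)
    return FrequencyTable(
        accession=accession, source="ind", size=10,
        marker_ids=np.array([f"M{i}" for i in range(len(p))], dtype=object),
        p=p, n_used=np.full(len(p), 10),
    )


class TestNeiDistance:
    def test_identical_tables_zero(self):
        a = freq_table([0.2, 0.7, 0.5])
        b = freq_table([0.2, 0.7, 0.5], accession="B")
        assert stx.nei_distance(a, b) == pytest.approx(0.0)

    def test_opposite_fixation_infinite(self):
        assert stx.nei_distance(freq_table([1.0]), freq_table([0.0], "B")) == float("inf")

    def test_hand_evaluated_single_locus(self):
        # J_ab = 0.58, J_a = 0.82, J_b = 0.52 -> D = 0.1185
        d = stx.nei_distance(freq_table([0.9]), freq_table([0.6], "B"))
        assert d == pytest.approx(0.1185, abs=1e-4)

    def test_no_shared_loci(self):
        a = freq_table([0.5])
        b = FrequencyTable(
            accession="B", source="ind", size=10,
            marker_ids=np.array(["other"], dtype=object),
            p=np.array([0.5]), n_used=np.array([10]),
        )
        with pytest.raises(ValueError):
            stx.nei_distance(a, b)

    def test_matrix_symmetry_and_diagonal(self):
        tables = [freq_table([0.1, 0.5], a) for a in "ABC"]
        tables[1].p = np.array([0.4, 0.6])
        tables[2].p = np.array([0.9, 0.2])
        dm = stx.nei_matrix(tables)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)


class TestRogersDistance:
    def test_identical_vectors(self):
        assert stx.rogers_distance([0.3, 0.8], [0.3, 0.8]) == 0.0

    def test_opposite_fixation(self):
        assert stx.rogers_distance([1.0], [0.0]) == pytest.approx(1.0)

    def test_arithmetic(self):
        # sqrt(0.5 * (0.09 + 0.09)) = 0.3
        assert stx.rogers_distance([0.9], [0.6]) == pytest.approx(0.3)

    def test_pairwise_complete(self):
        d = stx.rogers_distance([0.5, np.nan, 1.0], [0.1, 0.7, np.nan])
        assert d == pytest.approx(0.4)

    def test_label_permutation_equivariance(self, rng):
        X = rng.random((4, 20))
        dm = stx.rogers_matrix(X, list("abcd"))
        perm = [2, 0, 3, 1]
        dm2 = stx.rogers_matrix(X[perm], [dm.labels[i] for i in perm])
        assert np.allclose(dm2.values, dm.values[np.ix_(perm, perm)])


def wc_theta_oracle(genotype_lists):
    """Independent plain-Python coding of the two-level variance components.

    ``genotype_lists``: per population, list of per-locus genotype lists
    (codes 0/1/2). Returns the ratio-of-sums estimator.
    """
    n_loci = len(genotype_lists[0][0])
    r = len(genotype_lists)
    num = den = 0.0
    for locus in range(n_loci):
        ns, ps, hs = [], [], []
        for pop in genotype_lists:
            genos = [ind[locus] for ind in pop]
            n_i = len(genos)
            ns.append(n_i)
            ps.append(sum(2 - g for g in genos) / (2 * n_i))
            hs.append(sum(1 for g in genos if g == 1) / n_i)
        n_bar = sum(ns) / r
        n_c = (r * n_bar - sum(n * n for n in ns) / (r * n_bar)) / (r - 1)
        p_bar = sum(n * p for n, p in zip(ns, ps)) / (r * n_bar)
        s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * n_bar)
        h_bar = sum(n * h for n, h in zip(ns, hs)) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2
        num += a
        den += a + b + c
    return num / den


class TestWeirCockerhamFst:
    def test_null_simulation_near_zero(self):
        p = np.random.default_rng(4).uniform(0.2, 0.8, 2000)
        truth = TrueFrequencies(
            ancestral_p=p, accession_p={"A1": p, "A2": p}
        )
        a = simulate_genotypes(truth, "A1", 50, 0.0, seed=1)
        b = simulate_genotypes(truth, "A2", 50, 0.0, seed=2, sample_prefix="B")
        merged = make_scores(np.hstack([a.genotypes, b.genotypes]))
        acc = {}
        for i, s in enumerate(merged.sample_ids):
            acc[s] = "P1" if i < 50 else "P2"
        merged.accession_of_sample = acc
        theta = stx.pairwise_fst(merged, "P1", "P2")
        assert abs(theta) < 0.02

    def test_fixed_opposite_no_hets(self):
        g = np.array([[0, 0, 0, 2, 2, 2]] * 5, dtype=np.int8)
        scores = make_scores(g)
        scores.accession_of_sample = {
            s: ("P1" if i < 3 else "P2") for i, s in enumerate(scores.sample_ids)
        }
        assert stx.pairwise_fst(scores, "P1", "P2") == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        # 2 populations x 4 individuals, 2 loci, enumerated genotypes
        pop1 = [[0, 1], [1, 1], [0, 2], [0, 0]]
        pop2 = [[2, 0], [1, 0], [2, 1], [1, 0]]
        g = np.array([[ind[locus] for ind in pop1 + pop2] for locus in range(2)],
                     dtype=np.int8)
        scores = make_scores(g)
        scores.accession_of_sample = {
            s: ("P1" if i < 4 else "P2") for i, s in enumerate(scores.sample_ids)
        }
        expected = wc_theta_oracle([pop1, pop2])
        assert stx.pairwise_fst(scores, "P1", "P2") == pytest.approx(expected, abs=1e-8)

    def test_monotone_in_divergence(self):
        from poolcomp.synthetic import simulate_all_genotypes, simulate_metapopulation

        estimates = []
        for theta in (0.05, 0.15, 0.30):
            cfg = SimConfig(n_accessions=3, n_markers=2000, divergence_theta=theta, seed=6)
            truth = simulate_metapopulation(cfg)
            scores = simulate_all_genotypes(truth, cfg)
            estimates.append(stx.weir_cockerham_fst(scores, scores.accessions()))
        assert estimates[0] < estimates[1] < estimates[2]

    def test_insufficient_individuals(self):
        scores = make_scores([[0, 1]])
        scores.accession_of_sample = {"S0": "P1", "S1": "P2"}
        with pytest.raises(ValueError):
            stx.pairwise_fst(scores, "P1", "P2")


class TestAmova:
    def test_identical_units_between_groups(self):
        X = np.tile(np.array([0.5, 1.0, 0.0]), (6, 1))
        res = stx.amova(X, ["a"] * 3 + ["b"] * 3, n_permutations=0)
        assert res.pct_between == pytest.approx(0.0)
        assert res.pct_within == pytest.approx(100.0)

    def test_fixed_opposite_groups(self):
        X = np.vstack([np.zeros((5, 10)), np.ones((5, 10))])
        res = stx.amova(X, ["a"] * 5 + ["b"] * 5, n_permutations=499, seed=1)
        assert res.pct_between == pytest.approx(100.0)
        assert res.p_value <= 0.05

    def test_percentages_sum_and_dfs(self, rng):
        X = rng.random((12, 30))
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = stx.amova(X, groups, n_permutations=99, seed=3)
        assert res.pct_between + res.pct_within == pytest.approx(100.0)
        assert res.df_between == 2
        assert res.df_within == 9

    def test_permutation_p_reproducible(self, rng):
        X = rng.random((10, 20))
        groups = ["a"] * 5 + ["b"] * 5
        p1 = stx.amova(X, groups, n_permutations=199, seed=7).p_value
        p2 = stx.amova(X, groups, n_permutations=199, seed=7).p_value
        assert p1 == p2

    def test_degenerate_grouping_rejected(self, rng):
        X = rng.random((4, 5))
        with pytest.raises(ValueError):
            stx.amova(X, ["a"] * 4)
        with pytest.raises(ValueError):
            stx.amova(X, ["a", "a", "a", "b"])


class TestClassicalMds:
    def test_collinear_points(self):
        dm = stx.DistanceMatrix(
            labels=["x", "y", "z"], metric="rogers",
            values=np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float),
        )
        res = stx.classical_mds(dm, n_dims=2)
        assert res.explained[0] == pytest.approx(1.0)

    def test_euclidean_round_trip(self, rng):
        pts = rng.random((6, 3))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dm = stx.DistanceMatrix(labels=[str(i) for i in range(6)], metric="rogers", values=D)
        res = stx.classical_mds(dm, n_dims=5)
        C = res.coordinates
        D2 = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
        assert np.allclose(D2, D, atol=1e-8)

    def test_equilateral_triangle_equal_eigenvalues(self):
        dm = stx.DistanceMatrix(
            labels=list("abc"), metric="rogers",
            values=np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
        )
        res = stx.classical_mds(dm, n_dims=2)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_all_zero_rejected(self):
        dm = stx.DistanceMatrix(labels=list("ab"), metric="nei", values=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            stx.classical_mds(dm)


class TestMantel:
    @staticmethod
    def _dm(values, labels=None):
        values = np.asarray(values, dtype=float)
        return stx.DistanceMatrix(
            labels=labels or [str(i) for i in range(len(values))],
            metric="rogers", values=values,
        )

    def _random_dm(self, rng, n):
        vals = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals[iu] = rng.random(len(iu[0]))
        return self._dm(vals + vals.T)

    def test_self_correlation(self, rng):
        d = self._random_dm(rng, 5)
        r, p = stx.mantel_test(d, d, n_permutations=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_reversed_correlation(self, rng):
        d1 = self._random_dm(rng, 5)
        vals = d1.values.max() - d1.values
        np.fill_diagonal(vals, 0.0)
        r, _ = stx.mantel_test(d1, self._dm(vals), n_permutations=99, seed=0)
        assert r == pytest.approx(-1.0)

    def test_label_mismatch(self, rng):
        d1 = self._random_dm(rng, 4)
        d2 = self._dm(d1.values, labels=list("wxyz"))
        with pytest.raises(ValueError, match="labels"):
            stx.mantel_test(d1, d2)

    def test_null_p_uniform(self):
        """Independent random matrices give a uniform permutation p."""
        rng = np.random.default_rng(13)
        pvals = []
        for _ in range(200):
            d1 = self._random_dm(rng, 6)
            d2 = self._random_dm(rng, 6)
            _, p = stx.mantel_test(d1, d2, n_permutations=99, seed=int(rng.integers(1e9)))
            pvals.append(p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestGenotypeEncoding:
    def test_codes_map_to_frequencies(self):
        scores = make_scores([[0, 1, 2, -1]])
        enc = stx.genotype_frequency_encoding(scores, list(scores.sample_ids))
        assert enc.shape == (4, 1)
        assert enc[0, 0] == 1.0 and enc[1, 0] == 0.5 and enc[2, 0] == 0.0
        assert np.isnan(enc[3, 0])
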