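import itertools

import numpy as np
import pandas as pd
import pytest

from pavkit.catalog import MISSING
from pavkit.intervals import GenomicInterval
from pavkit.tajima import (
    matched_resampling_test,
    tail_enrichment,
    tajima_constants,
    tajimas_d,
)

from conftest import balanced_matrix, neutral_matrix


def oracle_tajimas_d(matrix):
    """From-scratch D: enumerate all sample pairs, evaluate constants directly."""
    matrix = np.asarray(matrix)
    n = matrix.shape[1]
    pairs = list(itertools.combinations(range(n), 2))
    pi = sum(
        np.sum(matrix[:, i] != matrix[:, j]) for i, j in pairs
    ) / len(pairs)
    S = sum(1 for row in matrix if 0 < row.sum() < n)
    if S == 0:
        return float("nan")
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestConstants:
    @pytest.mark.parametrize("n", [4, 5, 10, 60, 1301])
    def test_all_positive_for_n_at_least_4(self, n):
        c = tajima_constants(n)
        for name in ("a1", "a2", "b1", "b2", "c1", "c2", "e1", "e2"):
            assert getattr(c, name) > 0, name

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            tajima_constants(1)


class TestTajimasD:
    def test_monomorphic_matrix_is_na(self):
        assert np.isnan(tajimas_d(np.zeros((10, 8), dtype=np.int8)).D)

    def test_matches_pairwise_enumeration_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 9))
            sites = int(rng.integers(5, 20))
            matrix = rng.choice([0, 1], size=(sites, n)).astype(np.int8)
            got = tajimas_d(matrix)
            want = oracle_tajimas_d(matrix)
            if np.isnan(want):
                assert got.is_na
            else:
                assert got.D == pytest.approx(want, rel=1e-10)

    def test_invariant_to_sample_and_site_order(self, rng):
        matrix = rng.choice([0, 1, MISSING], size=(30, 10),
                            p=[0.5, 0.4, 0.1]).astype(np.int8)
        base = tajimas_d(matrix).D
        shuffled = matrix[rng.permutation(30)][:, rng.permutation(10)]
        assert tajimas_d(shuffled).D == pytest.approx(base, rel=1e-12)

    def test_intermediate_shift_never_decreases_d(self):
        """Moving derived counts toward n/2 at fixed S raises theta_pi, hence D."""
        n = 10

        def matrix_from_counts(counts):
            m = np.zeros((len(counts), n), dtype=np.int8)
            for i, k in enumerate(counts):
                m[i, :k] = 1
            return m

        low = tajimas_d(matrix_from_counts([1, 1, 2, 1, 1]))
        mid = tajimas_d(matrix_from_counts([3, 2, 4, 2, 3]))
        high = tajimas_d(matrix_from_counts([5, 5, 5, 5, 5]))
        assert low.D < mid.D < high.D

    def test_missing_data_uses_per_site_informative_counts(self):
        # one site, 3 of 5 called, one carrier: pi = 2*(1/3)*(2/3)*(3/2) = 2/3
        matrix = np.array([[1, 0, 0, MISSING, MISSING]], dtype=np.int8)
        res = tajimas_d(matrix)
        assert res.theta_pi == pytest.approx(2 / 3)
        assert res.S == 1


class TestMatchedResampling:
    def test_observed_at_null_maximum_gives_smallest_p(self, rng):
        universe = neutral_matrix(rng, 60, 12)
        res = matched_resampling_test(universe, universe[:20], n_reps=200, seed=3)
        max_reachable = (1 + 1) / (1 + 200)
        assert res.empirical_p >= max_reachable

    def test_reproducible_under_seed(self, rng):
        universe = neutral_matrix(rng, 60, 12)
        a = matched_resampling_test(universe, universe[:15], n_reps=300, seed=9)
        b = matched_resampling_test(universe, universe[:15], n_reps=300, seed=9)
        assert a.empirical_p == b.empirical_p
        assert np.array_equal(a.null_Ds, b.null_Ds, equal_nan=True)

    def test_focal_larger_than_universe_rejected(self, rng):
        universe = neutral_matrix(rng, 10, 12)
        with pytest.raises(ValueError):
            matched_resampling_test(universe[:5], universe, n_reps=100)

    def test_few_reps_warn(self, rng):
        universe = neutral_matrix(rng, 30, 12)
        with pytest.warns(UserWarning):
            matched_resampling_test(universe, universe[:5], n_reps=50, seed=1)

    def test_null_calibration(self):
        """Focal sets drawn from the genic universe itself give uniform p."""
        rng = np.random.default_rng(0)
        hits = 0
        n_trials = 200
        for trial in range(n_trials):
            universe = neutral_matrix(rng, 150, 24)
            focal_idx = rng.choice(150, size=40, replace=False)
            res = matched_resampling_test(universe, universe[focal_idx],
                                          n_reps=1_000, seed=trial)
            hits += res.empirical_p <= 0.05
        # binomial 99% bounds around 0.05 for 200 trials: [0.010, 0.090]
        assert 2 <= hits <= 18

    def test_balanced_focal_class_separates(self):
        rng = np.random.default_rng(1)
        universe = neutral_matrix(rng, 200, 24)
        focal = balanced_matrix(rng, 50, 24, kappa=20.0)
        res = matched_resampling_test(universe, focal, n_reps=1_000, seed=2)
        assert res.empirical_p <= 0.01

    def test_focal_class_more_positive_in_most_replicates(self):
        """Balanced focal D exceeds the neutral genic D in >= 95% of replicates."""
        rng = np.random.default_rng(2)
        wins = 0
        for _ in range(100):
            genic = neutral_matrix(rng, 120, 16)
            focal = balanced_matrix(rng, 40, 16, kappa=20.0)
            if tajimas_d(focal).D > tajimas_d(genic).D:
                wins += 1
        assert wins >= 95


class TestTailEnrichment:
    def _genes(self):
        return {
            f"g{i}": GenomicInterval("c", 1_000 * i, 1_000 * i + 500)
            for i in range(20)
        }

    def test_perfect_concentration_gives_minimal_p(self, rng):
        genes = self._genes()
        focal = {"g0", "g1"}
        rows = []
        for i, gene in enumerate(genes.values()):
            score = 100.0 if i < 2 else rng.uniform(0, 1)
            rows.append({"chrom": "c", "pos": gene.start + 10, "score": score})
        table = pd.DataFrame(rows)
        res = tail_enrichment(table, genes, focal, tail_fraction=0.1)
        # tail = the 2 focal-gene SNPs; hypergeometric minimum for k=n=2, K=2, N=20
        assert res.p == pytest.approx((2 / 20) * (1 / 19))

    def test_matches_hypergeometric_oracle(self):
        from scipy.stats import hypergeom

        genes = self._genes()
        focal = {f"g{i}" for i in range(5)}
        rows = [
            {"chrom": "c", "pos": g.start + 1, "score": float(i)}
            for i, g in enumerate(genes.values())
        ]
        res = tail_enrichment(pd.DataFrame(rows), genes, focal, tail_fraction=0.25)
        # top 5 scores are genes g15..g19, none focal: k=0, n=5, K=5, N=20
        assert res.p == pytest.approx(float(hypergeom.sf(-1, 20, 5, 5)))
        assert res.p == pytest.approx(1.0)

    def test_null_scores_give_uniform_p(self):
        rng = np.random.default_rng(3)
        genes = self._genes()
        focal = {f"g{i}" for i in range(4)}
        pvals = []
        for _ in range(200):
            rows = [
                {"chrom": "c", "pos": g.start + 1, "score": rng.normal()}
                for g in genes.values()
            ]
            pvals.append(
                tail_enrichment(pd.DataFrame(rows), genes, focal, 0.25).p
            )
        # discrete p, but the 0.25-quantile of its distribution must be ~0.25
        assert 0.10 < np.mean(np.array(pvals) <= 0.3) < 0.5

    def test_bad_tail_fraction_rejected(self):
        with pytest.raises(ValueError):
            tail_enrichment(pd.DataFrame({"chrom": [], "pos": [], "score": []}),
                            {}, set(), tail_fraction=1.5)
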