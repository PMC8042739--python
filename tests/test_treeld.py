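import numpy as np
import pandas as pd
import pytest

from pavkit.catalog import MISSING
from pavkit.treeld import (
    DistanceMatrix,
    best_tag_snp,
    neighbor_joining,
    pav_distance,
)


class TestPavDistance:
    def test_identical_vectors_distance_zero(self):
        mat = np.array([[0, 0], [1, 1], [0, 0], [1, 1]], dtype=np.int8)
        dm = pav_distance(mat)
        assert dm.matrix[0, 1] == 0.0

    def test_complementary_vectors_distance_one(self):
        mat = np.array([[0, 1]] * 10, dtype=np.int8)
        dm = pav_distance(mat)
        assert dm.matrix[0, 1] == 1.0
        assert dm.informative[0, 1] == 10

    def test_matches_per_pair_brute_force_with_missing(self, rng):
        mat = rng.choice([0, 1, MISSING], size=(40, 8),
                         p=[0.45, 0.45, 0.1]).astype(np.int8)
        dm = pav_distance(mat)
        for i in range(8):
            for j in range(8):
                ok = (mat[:, i] != MISSING) & (mat[:, j] != MISSING)
                n_inf = int(ok.sum())
                assert dm.informative[i, j] == n_inf
                if i == j:
                    assert dm.matrix[i, j] == 0.0
                elif n_inf:
                    expect = np.mean(mat[ok, i] != mat[ok, j])
                    assert dm.matrix[i, j] == pytest.approx(expect)

    def test_invariant_to_site_order_and_monomorphic_sites(self, rng):
        mat = rng.choice([0, 1], size=(30, 6)).astype(np.int8)
        base = pav_distance(mat).matrix
        shuffled = pav_distance(mat[rng.permutation(30)]).matrix
        padded = pav_distance(np.vstack([mat, np.zeros((10, 6), dtype=np.int8)]))
        assert np.allclose(base, shuffled)
        # adding monomorphic sites dilutes distances by a constant factor of
        # informative sites; invariance holds for the zero/nonzero pattern
        assert np.allclose(base * 30 / 40, padded.matrix)

    def test_symmetry_and_zero_diagonal(self, rng):
        mat = rng.choice([0, 1, MISSING], size=(25, 7)).astype(np.int8)
        dm = pav_distance(mat)
        assert np.allclose(dm.matrix, dm.matrix.T, equal_nan=True)
        assert np.all(np.diag(dm.matrix) == 0)


def _random_additive_tree(rng, taxa):
    """Random binary tree; returns (newick, tip-to-tip distance DataFrame)."""

    def build(names):
        if len(names) == 1:
            return names[0], {names[0]: 0.0}
        k = int(rng.integers(1, len(names)))
        left, dl = build(names[:k])
        right, dr = build(names[k:])
        bl = rng.uniform(0.5, 2.0)
        br = rng.uniform(0.5, 2.0)
        dists = {t: d + bl for t, d in dl.items()}
        dists.update({t: d + br for t, d in dr.items()})
        return f"({left}:{bl:.6f},{right}:{br:.6f})", dists

    # accumulate pairwise distances by summing paths through each merge
    pair_d = {}

    def build2(names):
        if len(names) == 1:
            return names[0], {names[0]: 0.0}
        k = int(rng.integers(1, len(names)))
        left, dl = build2(names[:k])
        right, dr = build2(names[k:])
        bl = rng.uniform(0.5, 2.0)
        br = rng.uniform(0.5, 2.0)
        for t1, d1 in dl.items():
            for t2, d2 in dr.items():
                pair_d[frozenset((t1, t2))] = d1 + bl + d2 + br
        dists = {t: d + bl for t, d in dl.items()}
        dists.update({t: d + br for t, d in dr.items()})
        return f"({left}:{bl:.6f},{right}:{br:.6f})", dists

    newick, _ = build2(list(taxa))
    n = len(taxa)
    mat = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i != j:
                mat[i, j] = pair_d[frozenset((a, b))]
    return newick + ";", pd.DataFrame(mat, index=list(taxa), columns=list(taxa))


def _topologies_equal(newick_a, newick_b):
    import io

    from skbio import TreeNode

    ta = TreeNode.read(io.StringIO(newick_a))
    tb = TreeNode.read(io.StringIO(newick_b))
    return ta.compare_rfd(tb) == 0.0


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        dm = DistanceMatrix(["A", "B", "C"], d, np.full((3, 3), 10))
        tree = neighbor_joining(dm)
        lengths = tree.raw_branch_lengths
        assert lengths[("A",)] == pytest.approx((5 + 9 - 10) / 2)   # 2
        assert lengths[("B",)] == pytest.approx((5 + 10 - 9) / 2)   # 3
        assert lengths[("C",)] == pytest.approx((9 + 10 - 5) / 2)   # 7

    def test_four_taxon_tree_recovered_exactly(self, worked):
        frame = worked["four_taxon_distances"]
        dm = DistanceMatrix(list(frame.index), frame.to_numpy(),
                            np.full(frame.shape, 10))
        tree = neighbor_joining(dm)
        # the generating tree is ((A:1,B:2):1,(C:3,D:1));
        assert _topologies_equal(tree.newick(), "((A:1,B:2):1,(C:3,D:1));")
        # additive data: branch lengths are recovered exactly
        assert tree.raw_branch_lengths[("A",)] == pytest.approx(1.0)
        assert tree.raw_branch_lengths[("B",)] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(50))
    def test_recovers_random_additive_six_taxon_trees(self, seed):
        rng = np.random.default_rng(seed)
        taxa = list("ABCDEF")
        true_newick, frame = _random_additive_tree(rng, taxa)
        dm = DistanceMatrix(taxa, frame.to_numpy(), np.full((6, 6), 10))
        tree = neighbor_joining(dm)
        assert _topologies_equal(tree.newick(clamp_negative=False), true_newick)

    def test_leaf_set_preserved(self, rng):
        n = 9
        d = rng.uniform(0.1, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        names = [f"s{i}" for i in range(n)]
        tree = neighbor_joining(DistanceMatrix(names, d, np.full((n, n), 5)))
        import io

        from skbio import TreeNode

        parsed = TreeNode.read(io.StringIO(tree.newick()))
        assert {t.name for t in parsed.tips()} == set(names)

    def test_negative_lengths_clamped_only_in_newick(self):
        d = np.array(
            [[0, 1, 8, 8], [1, 0, 8, 8], [8, 8, 0, 1], [8, 8, 1, 0]],
            dtype=float,
        )
        d[0, 1] = d[1, 0] = 7.9  # near-degenerate: can push a length negative
        dm = DistanceMatrix(list("ABCD"), d, np.full((4, 4), 5))
        tree = neighbor_joining(dm)
        raw = list(tree.raw_branch_lengths.values())
        clamped = tree.newick(clamp_negative=True)
        assert ":-" not in clamped
        if min(raw) < 0:
            assert ":-" in tree.newick(clamp_negative=False)

    def test_too_few_samples_rejected(self):
        dm = DistanceMatrix(["A", "B"], np.zeros((2, 2)), np.ones((2, 2)))
        with pytest.raises(ValueError):
            neighbor_joining(dm)


class TestBestTagSnp:
    def test_identical_snp_gives_r2_one(self):
        pav = np.array([[0, 1, 0, 1, 1, 0]], dtype=np.int8)
        snps = np.vstack([pav[0], 1 - pav[0], [0, 0, 0, 1, 1, 1]]).astype(np.int8)
        pav_pos = pd.DataFrame({"chrom": ["c"], "pos": [5_000]})
        snp_pos = pd.DataFrame({"chrom": ["c"] * 3, "pos": [4_000, 6_000, 9_000]})
        report = best_tag_snp(pav, pav_pos, snps, snp_pos, window_bp=10_000)
        assert report.table["best_r2"].iloc[0] == pytest.approx(1.0)

    def test_r2_invariant_to_allele_label_swap(self, rng):
        pav = rng.choice([0, 1], size=(1, 50)).astype(np.int8)
        snp = rng.choice([0, 1], size=(1, 50)).astype(np.int8)
        pos = pd.DataFrame({"chrom": ["c"], "pos": [100]})
        r_direct = best_tag_snp(pav, pos, snp, pos, 1_000).table["best_r2"].iloc[0]
        r_flip = best_tag_snp(1 - pav, pos, snp, pos, 1_000).table["best_r2"].iloc[0]
        assert r_direct == pytest.approx(r_flip)

    def test_no_snp_in_window_reported_na(self):
        pav = np.array([[0, 1, 0, 1]], dtype=np.int8)
        pav_pos = pd.DataFrame({"chrom": ["c"], "pos": [1_000]})
        snp_pos = pd.DataFrame({"chrom": ["c"], "pos": [50_000]})
        report = best_tag_snp(pav, pav_pos, np.array([[0, 1, 1, 0]], dtype=np.int8),
                              snp_pos, window_bp=10_000)
        assert report.n_without_snp == 1
        assert np.isnan(report.mean_r2)

    def test_independent_vectors_match_monte_carlo_maximum(self):
        """Mean best-r² over many trials ~ a from-scratch Monte Carlo of the
        maximum of k independent r² values at the same n and k."""
        rng = np.random.default_rng(7)
        n, k, trials = 200, 5, 300
        means = []
        for _ in range(trials):
            pav = rng.choice([0, 1], size=(1, n)).astype(np.int8)
            snps = rng.choice([0, 1], size=(k, n)).astype(np.int8)
            pos = pd.DataFrame({"chrom": ["c"], "pos": [100]})
            snp_pos = pd.DataFrame({"chrom": ["c"] * k, "pos": [100] * k})
            rep = best_tag_snp(pav, pos, snps, snp_pos, 1_000)
            means.append(rep.table["best_r2"].iloc[0])
        oracle_rng = np.random.default_rng(17)
        oracle = []
        for _ in range(trials):
            x = oracle_rng.choice([0, 1], size=n)
            r2s = []
            for _ in range(k):
                y = oracle_rng.choice([0, 1], size=n)
                r = np.corrcoef(x, y)[0, 1]
                r2s.append(r * r)
            oracle.append(max(r2s))
        assert np.mean(means) == pytest.approx(np.mean(oracle), abs=0.01)

    def test_recovers_generator_target_r2(self, sim_output):
        """Synthetic tag SNPs engineered to r²=0.75 are recovered within 0.05."""
        out = sim_output
        cat = out.pav_catalog
        defense_ids = set(
            out.truth.loc[out.truth["class"] == "defense", "record_id"]
        )
        recs = [r for r in cat.records if r.record_id in defense_ids]
        pav_geno = np.stack([r.genotypes for r in recs])
        pav_pos = pd.DataFrame(
            {"chrom": [r.chrom for r in recs],
             "pos": [r.interval.midpoint for r in recs]}
        )
        report = best_tag_snp(pav_geno, pav_pos, out.snp_matrix,
                              out.snp_positions, window_bp=10_000)
        assert report.mean_r2 == pytest.approx(out.config.snp_target_r2, abs=0.05)
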