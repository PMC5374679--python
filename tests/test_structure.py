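"""DISTATIS against a classical-MDS oracle, neighbor joining on additive
distances, the Mantel permutation test, and f3/f4 with block jackknife."""

import numpy as np
import pytest

import poolcline as pc
from poolcline.structure import (
    DEFAULT_QUANTILES,
    _block_jackknife,
    enumerate_f3,
    enumerate_f4,
)


class TestQuantileMatrices:
    def test_constant_pair_values(self):
        vals = np.full((100, 3), [0.1, 0.2, 0.3])
        pairs = [(0, 1), (0, 2), (1, 2)]
        dset = pc.quantile_distance_matrices(vals, pairs, 3)
        assert dset.shape == (5, 3, 3)
        for k in range(5):
            assert dset[k, 0, 1] == pytest.approx(0.1)
            assert dset[k, 1, 2] == pytest.approx(0.3)
            assert np.allclose(dset[k], dset[k].T)
            assert np.all(np.diag(dset[k]) == 0)

    def test_median_of_uniform_grid(self):
        vals = np.linspace(0, 1, 101)[:, None]
        dset = pc.quantile_distance_matrices(vals, [(0, 1)], 2)
        k_med = list(DEFAULT_QUANTILES).index(0.5)
        assert dset[k_med, 0, 1] == pytest.approx(0.5)

    def test_number_of_matrices_fixed(self):
        vals = np.random.default_rng(0).uniform(size=(17, 1))
        assert pc.quantile_distance_matrices(vals, [(0, 1)], 2).shape[0] == 5


class TestDistatis:
    def triangle(self):
        return np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])

    def test_identical_matrices_equal_weights(self):
        sp = pc.distatis(np.stack([self.triangle()] * 4))
        assert np.allclose(sp.alphas, 0.25)

    def test_reproduces_classical_mds(self):
        d = self.triangle()
        sp = pc.distatis(np.stack([d] * 3))
        # oracle: eigendecomposition of the normalized double-centered d
        j = np.eye(3) - np.ones((3, 3)) / 3
        s = -0.5 * j @ d @ j
        s = s / np.linalg.eigvalsh(s)[-1]
        w, v = np.linalg.eigh(s)
        order = np.argsort(w)[::-1]
        oracle = v[:, order] * np.sqrt(np.clip(w[order], 0, None))
        assert np.allclose(np.abs(sp.scores[:, :2]), np.abs(oracle[:, :2]),
                           atol=1e-10)

    def test_eigenvalues_nonnegative_for_euclidean_input(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(5, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        sp = pc.distatis(np.stack([d, 1.3 * d]))
        assert (sp.eigenvalues > -1e-10).all()

    def test_admixed_population_intermediate_on_axis_one(self, neutral_dataset):
        fst = pc.pairwise_fst_table(neutral_dataset.table)
        cols = [c for c in fst.columns if c.startswith("fst_")]
        pairs = [tuple(int(x) for x in c.split("_")[1:]) for c in cols]
        vals = fst[cols].to_numpy()
        dset = pc.quantile_distance_matrices(vals, pairs, 6)
        with pytest.warns(UserWarning, match="all-zero"):
            sp = pc.distatis(dset, n_boot=50, seed=1, fst_values=vals,
                             pair_index=pairs)
        ax1 = sp.scores[:, 0]
        lo, hi = sorted([ax1[[0, 1, 2, 3]].mean(), ax1[5]])
        assert lo < ax1[4] < hi
        assert len(sp.ellipses) == 6

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            pc.distatis(np.zeros((3, 4, 4)))


class TestNeighborJoining:
    def test_three_taxon_branch_lengths(self):
        nwk = pc.nj_tree(
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
            ["A", "B", "C"],
        )
        import re

        lengths = {m[0]: float(m[1])
                   for m in re.findall(r"([A-C]):([\d.]+)", nwk)}
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1.5,C:3,D:4) -> additive distances
        d = np.array(
            [
                [0, 3, 5.5, 6.5],
                [3, 0, 6.5, 7.5],
                [5.5, 6.5, 0, 7],
                [6.5, 7.5, 7, 0],
            ],
            dtype=float,
        )
        from io import StringIO

        from skbio import TreeNode

        tree = TreeNode.read(StringIO(pc.nj_tree(d, list("ABCD"))))
        tips = list("ABCD")
        for i in range(4):
            for j in range(i + 1, 4):
                got = tree.find(tips[i]).distance(tree.find(tips[j]))
                assert got == pytest.approx(d[i, j], abs=1e-10)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            pc.nj_tree(np.zeros((2, 2)), ["A", "B"])


class TestMantel:
    def random_distance(self, seed, n=6):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        return np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))

    def test_identity_and_affine_invariance(self):
        m = self.random_distance(1)
        r, _ = pc.mantel(m, m, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        r2, _ = pc.mantel(m, 2 * m + 3, n_perm=99, seed=0)
        assert r2 == pytest.approx(1.0)

    def test_constant_matrix_flagged(self):
        m = self.random_distance(1)
        c = np.ones((6, 6)) - np.eye(6)
        r, p = pc.mantel(m, c, n_perm=9, seed=0)
        assert np.isnan(r) and np.isnan(p)

    def test_p_value_floor(self):
        # strongly matched matrices large enough that no sampled
        # permutation (identity included, 12! of them) reaches observed r
        m1 = self.random_distance(2, n=12)
        m2 = m1 + np.abs(np.random.default_rng(3).normal(0, 1e-3, m1.shape))
        m2 = (m2 + m2.T) / 2
        np.fill_diagonal(m2, 0)
        r, p = pc.mantel(m1, m2, n_perm=999, seed=4)
        assert r > 0.99
        assert p == pytest.approx(1 / 1000)

    def test_agrees_with_skbio_r(self):
        from skbio.stats.distance import mantel as sk_mantel

        m1 = self.random_distance(5)
        m2 = self.random_distance(6)
        r, _ = pc.mantel(m1, m2, n_perm=9, seed=0)
        r_sk = sk_mantel(m1, m2, permutations=0)[0]
        assert r == pytest.approx(r_sk, abs=1e-12)


class TestFStatistics:
    def test_identical_sources_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, size=(2000, 3))
        p[:, 1] = p[:, 0]
        r3 = pc.f3_statistic(p, 0, 1, 2, block_size=100, correct=False)
        assert r3.estimate == pytest.approx(0.0, abs=1e-12)
        p4 = np.column_stack([p[:, 0], p[:, 0], p[:, 2], rng.uniform(size=2000)])
        r4 = pc.f4_statistic(p4, 0, 1, 2, 3, block_size=100)
        assert r4.estimate == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        p = np.array([[0.5, 0.2, 0.8], [0.5, 0.9, 0.1]])
        per_snp = (p[:, 0] - p[:, 1]) * (p[:, 0] - p[:, 2])
        assert per_snp.mean() == pytest.approx(-0.125)
        r = pc.f3_statistic(p, 0, 1, 2, block_size=1, correct=False)
        assert r.estimate == pytest.approx(-0.125)

    def test_f4_symmetries(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.05, 0.95, size=(3000, 4))
        f = lambda a, b, c, d: pc.f4_statistic(p, a, b, c, d, 250).estimate
        assert f(0, 1, 2, 3) == pytest.approx(-f(1, 0, 2, 3))
        assert f(0, 1, 2, 3) == pytest.approx(f(2, 3, 0, 1))

    def test_configuration_counts_for_six_pools(self):
        assert len(list(enumerate_f3(6))) == 60
        assert len(list(enumerate_f4(6))) == 45  # 3 * C(6, 4)

    def test_jackknife_matches_classical_se_iid(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0.3, 1.0, 50_000)
        _, se = _block_jackknife(x, 500)
        classical = x.std(ddof=1) / np.sqrt(len(x))
        assert 0.8 < se / classical < 1.2

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError):
            _block_jackknife(np.ones(100), 500)

    def test_admixed_pool_negative_f3(self, neutral_dataset):
        freqs, depths, _ = pc.pool_frequencies(neutral_dataset.table)
        r = pc.f3_statistic(freqs, 4, 0, 5, depths=depths)
        assert r.z < -3

    def test_correction_reduces_positive_bias(self):
        # pure drift-free noise: raw f3 of a pool with itself as target is
        # positively biased; the depth correction removes most of it
        rng = np.random.default_rng(5)
        S, M = 20_000, 90
        p0 = rng.uniform(0.2, 0.8, S)
        obs = rng.binomial(M, p0[:, None] * np.ones((1, 3))) / M
        depths = np.full((S, 3), M)
        raw = pc.f3_statistic(obs, 0, 1, 2, correct=False)
        corrected = pc.f3_statistic(obs, 0, 1, 2, depths=depths, correct=True)
        assert raw.estimate > 0
        assert abs(corrected.estimate) < raw.estimate / 3
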