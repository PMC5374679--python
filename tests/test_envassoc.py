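"""Environmental PCA, the moment estimator of the population covariance,
and the grid-integrated Z / Bayes-factor scorer."""

import numpy as np
import pandas as pd
import pytest

import poolcline as pc
from poolcline.envassoc import EnvScoreParams, _corr, _moment_omega


def env_table(values: dict, pops=6):
    idx = pd.Index([f"pop{i+1}" for i in range(pops)], name="population")
    return pd.DataFrame(values, index=idx)


class TestEnvPca:
    def test_rank_one_table(self):
        alt = np.array([100, 300, 500, 800, 1100, 1300], dtype=float)
        t = env_table({"elev": alt, "v1": 2 * alt, "v2": -0.5 * alt + 7})
        comp = pc.env_pca(t)
        assert comp.variance_fraction == pytest.approx(1.0)
        assert abs(comp.scores.mean()) < 1e-9

    def test_anticorrelated_pair(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        comp = pc.env_pca(env_table({"a": x, "b": -x}))
        assert comp.variance_fraction == pytest.approx(1.0)
        assert np.sign(comp.loadings["a"]) == -np.sign(comp.loadings["b"])

    def test_constant_variable_dropped(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        with pytest.warns(UserWarning, match="constant"):
            comp = pc.env_pca(env_table({"a": x, "b": x + 1, "c": np.ones(6)}))
        assert "c" not in comp.loadings.index

    def test_orientation_follows_first_column(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        comp = pc.env_pca(env_table({"elev": x, "b": x * 1.1}))
        assert np.corrcoef(comp.scores, x)[0, 1] > 0


class TestCovariance:
    def test_independent_drift_moments(self):
        # independent Balding-Nichols drift, F = 0.05 per pool: diagonals
        # near F (less the mean-centering loss), off-diagonals near zero
        rng = np.random.default_rng(2)
        S, P, F = 10_000, 6, 0.05
        p0 = rng.uniform(0.2, 0.8, S)
        a = p0 * (1 - F) / F
        b = (1 - p0) * (1 - F) / F
        freqs = rng.beta(a[:, None], b[:, None], size=(S, P))
        omega = _moment_omega(freqs)
        diag = np.diag(omega)
        off = omega[~np.eye(P, dtype=bool)]
        assert np.all(np.abs(diag - F) < 0.2 * F + 0.01)
        assert np.all(np.abs(off) < 0.02)

    def test_convergence_between_subsamples(self, neutral_dataset):
        freqs, _, _ = pc.pool_frequencies(neutral_dataset.table)
        model = pc.estimate_covariance(freqs, n_snps=5000, seed=0)
        assert model.convergence < 0.05
        assert model.omega.shape == (6, 6)
        # PSD after projection
        assert np.linalg.eigvalsh(model.omega).min() > -1e-10

    def test_cluster_structure_visible(self, neutral_dataset):
        freqs, _, _ = pc.pool_frequencies(neutral_dataset.table)
        model = pc.estimate_covariance(freqs, n_snps=3000, seed=1)
        corr = _corr(model.omega)
        within = [corr[i, j] for i in range(4) for j in range(i + 1, 4)]
        across = [corr[i, 5] for i in range(4)]
        assert np.mean(within) > np.mean(across)

    def test_too_few_snps_rejected(self):
        freqs = np.random.default_rng(0).uniform(0.2, 0.8, (30, 6))
        with pytest.raises(ValueError, match="polymorphic"):
            pc.estimate_covariance(freqs, seed=0)


class TestEnvScore:
    def setup_model(self, seed=0, S=2000, F=0.05):
        rng = np.random.default_rng(seed)
        p0 = rng.uniform(0.2, 0.8, S)
        a = p0 * (1 - F) / F
        b = (1 - p0) * (1 - F) / F
        freqs = rng.beta(a[:, None], b[:, None], size=(S, 6))
        model = pc.estimate_covariance(freqs, n_snps=S, seed=seed)
        comp = pc.env_pca(env_table({
            "elev": np.array([176.0, 297, 588, 842, 1125, 1303]),
            "v": np.array([1.0, 2, 4, 6, 8, 9]),
        }))
        return freqs, model, comp

    def test_flat_frequencies_no_signal(self):
        freqs, model, comp = self.setup_model()
        flat = np.full((200, 6), 0.5)
        depths = np.full((200, 6), 90.0)
        sc = pc.env_score(flat, depths, model, comp)
        assert np.all(sc.z_support < 1e-6)
        # no positive evidence; BF below 1 is the Occam factor of the
        # wider beta-free model
        assert np.all(sc.bayes_factor < 1.0)

    def test_perfect_cline_saturates_z(self):
        freqs, model, comp = self.setup_model()
        e = comp.scores
        cline = 0.5 + 0.45 * (e / np.abs(e).max())
        big = np.tile(cline, (50, 1))
        depths = np.full((50, 6), 5000.0)
        sc = pc.env_score(big, depths, model, comp)
        assert np.all(sc.z_support > 0.49)

    def test_allele_flip_invariance(self):
        freqs, model, comp = self.setup_model(seed=3, S=300)
        depths = np.full_like(freqs, 90.0)
        a = pc.env_score(freqs, depths, model, comp)
        b = pc.env_score(1 - freqs, depths, model, comp)
        assert np.allclose(a.z_support, b.z_support, atol=1e-9)
        assert np.allclose(a.bayes_factor, b.bayes_factor, rtol=1e-6)
        assert np.allclose(a.beta_hat, -b.beta_hat, atol=1e-9)

    def test_score_stability_across_covariance_subsamples(self, gradient_dataset):
        freqs, depths, _ = pc.pool_frequencies(gradient_dataset.table)
        comp = pc.env_pca(gradient_dataset.env)
        m = pc.estimate_covariance(freqs, n_snps=2000, seed=5)
        m2 = pc.CovarianceModel(m.omega_second, m.omega, m.convergence,
                                m.n_snps, m.snp_indices)
        s1 = pc.env_score(freqs, depths, m, comp)
        s2 = pc.env_score(freqs, depths, m2, comp)
        stat = s1.z_support * s1.bayes_factor
        stat2 = s2.z_support * s2.bayes_factor
        rho = pd.Series(stat).corr(pd.Series(stat2), method="spearman")
        assert rho > 0.95

    def test_enrichment_monotone_in_effect_size(self):
        hits = []
        for beta in (0.75, 3.0):
            cfg = pc.SimulationConfig(seed=99, n_snps=8000, beta_env=beta)
            ds = pc.simulate_gradient_experiment(cfg)
            freqs, depths, idx = pc.pool_frequencies(ds.table)
            comp = pc.env_pca(ds.env)
            model = pc.estimate_covariance(freqs, n_snps=4000, seed=1)
            sc = pc.env_score(freqs, depths, model, comp)
            sel = set(zip(ds.truth.scaffold[ds.truth.selected],
                          ds.truth.position[ds.truth.selected]))
            keys = list(zip(ds.table.scaffold[idx], ds.table.position[idx]))
            is_sel = np.array([k in sel for k in keys])
            n_top = int(round(0.01 * len(sc)))
            top = sc["rank"].to_numpy() <= n_top
            hits.append(top[is_sel].mean())
        assert hits[1] > hits[0]

    def test_grid_matches_conjugate_closed_form(self):
        # the grid integration must agree with the exact Gaussian posterior
        freqs, model, comp = self.setup_model(seed=8, S=50)
        depths = np.full_like(freqs, 90.0)
        sc = pc.env_score(freqs, depths, model, comp,
                          EnvScoreParams(grid_points=2001))
        from scipy.stats import norm

        e = comp.scores - comp.scores.mean()
        P = 6
        omega = model.omega + 1e-6 * np.eye(P)
        pbar = freqs.mean(axis=1)
        sig2 = np.clip(pbar * (1 - pbar), 1e-6, None)
        pn = (freqs * depths + 0.5) / (depths + 1)
        noise = pn * (1 - pn) / depths
        prior_sd = 1.0 / (e.max() - e.min())
        for i in range(0, 50, 7):
            V = sig2[i] * omega + np.diag(noise[i])
            Vi = np.linalg.inv(V)
            one = np.ones(P)
            Q = Vi - np.outer(Vi @ one, Vi @ one) / (one @ Vi @ one)
            A = e @ Q @ e
            B = freqs[i] @ Q @ e
            tau = A + 1 / prior_sd**2
            mu = B / tau
            expect = norm.cdf(mu * np.sqrt(tau))
            assert sc.sign_prob[i] == pytest.approx(expect, abs=1e-3)


class TestOverlapReport:
    def test_published_style_arithmetic(self):
        env_top = set(range(2978))
        fst_top = set(range(90)) | set(range(10_000, 50_000))
        rep = pc.overlap_report(env_top, fst_top)
        assert rep["n_overlap"] == 90
        assert rep["percent"] == 3.02

    def test_disjoint_and_subset(self):
        assert pc.overlap_report({1, 2}, {3, 4})["percent"] == 0.0
        assert pc.overlap_report({1, 2}, {1, 2, 3})["percent"] == 100.0

    def test_empty_env_set_flagged(self):
        rep = pc.overlap_report(set(), {1})
        assert not rep["defined"]
        assert np.isnan(rep["percent"])
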