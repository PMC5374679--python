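"""Covariance-controlled gene-environment association for Pool-seq data.

The scorer follows the hierarchical-normal generative model behind
Bayenv-style analyses: observed pool allele frequencies are modelled as

    p = alpha * 1 + beta * env1 + eps,
    eps ~ MVN(0, sigma^2_snp * Omega + diag(read noise)),

where Omega is the among-population allele-frequency covariance matrix
(estimated by method of moments from a 10,000-SNP subsample, projected
to the nearest positive semi-definite matrix), sigma^2_snp = pbar(1-pbar)
scales the SNP, and the read-noise term is p(1-p)/coverage per pool.
The intercept alpha is marginalized with a flat prior, beta carries a
zero-centered normal prior, and the posterior over beta is computed by
numerical integration on a symmetric grid.  The support statistic is

    Z = |P(beta > 0 | data) - 0.5|  in [0, 0.5],

maximal (0.5) for a perfectly supported monotone cline, together with a
Bayes factor (marginal likelihood of beta free vs beta = 0).  This is a
deterministic, desk-scale replacement for the MCMC machinery; equality
with any MCMC implementation's output is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


# ---------------------------------------------------------------------------
# Composite environmental axis
# ---------------------------------------------------------------------------

@dataclass
class EnvComposite:
    loadings: pd.Series
    scores: np.ndarray  # env1 per population, zero mean
    variance_fraction: float
    correlations: pd.DataFrame


def env_pca(env: pd.DataFrame) -> EnvComposite:
    """First principal component of the standardized environmental table.

    Variables are z-scored first; constant variables are dropped with a
    warning.  The component is oriented to correlate positively with the
    first column (elevation when present), and its per-population scores
    form the composite axis env1.
    """
    if env.shape[1] < 2 or env.shape[0] < 3:
        raise ValueError("need >= 2 variables and >= 3 populations")
    sd = env.std(ddof=0)
    keep = sd > 0
    if not keep.all():
        import warnings

        warnings.warn(
            f"dropping constant variables: {list(env.columns[~keep])}",
            stacklevel=2,
        )
    x = env.loc[:, keep]
    z = (x - x.mean()) / x.std(ddof=0)
    corr = z.corr()
    pca = PCA(n_components=min(z.shape))
    scores = pca.fit_transform(z.to_numpy())
    pc1 = scores[:, 0]
    loadings = pd.Series(pca.components_[0], index=x.columns)
    anchor = x.iloc[:, 0].to_numpy()
    if np.corrcoef(pc1, anchor)[0, 1] < 0:
        pc1, loadings = -pc1, -loadings
    frac = float(pca.explained_variance_ratio_[0])
    return EnvComposite(loadings, pc1 - pc1.mean(), frac, corr)


# ---------------------------------------------------------------------------
# Neutral covariance matrix
# ---------------------------------------------------------------------------

@dataclass
class CovarianceModel:
    omega: np.ndarray
    omega_second: np.ndarray
    convergence: float  # max |corr(omega) - corr(omega')|
    n_snps: int
    snp_indices: np.ndarray


def _nearest_psd(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh((m + m.T) / 2)
    return (v * np.clip(w, 0, None)) @ v.T


def _corr(m: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.clip(np.diag(m), 1e-12, None))
    return m / np.outer(d, d)


def _moment_omega(freqs: np.ndarray) -> np.ndarray:
    pbar = freqs.mean(axis=1)
    x = (freqs - pbar[:, None]) / np.sqrt(pbar * (1 - pbar))[:, None]
    return _nearest_psd(x.T @ x / len(x))


def polymorphic_frequencies(table, min_minor_count: int = 1):
    """Minor-allele frequency matrix (n_snps, P) and read depths for all
    polymorphic sites of a count table."""
    from .structure import pool_frequencies

    return pool_frequencies(table, min_minor_count=min_minor_count)


def estimate_covariance(
    table_or_freqs, n_snps: int = 10_000, seed: int = 0
) -> CovarianceModel:
    """Method-of-moments estimate of the among-population covariance.

    For each sampled polymorphic SNP the standardized deviation vector
    x = (p - pbar) / sqrt(pbar(1-pbar)) is formed and Omega-hat is the
    average of x x^T, projected to the nearest positive semi-definite
    matrix.  A second disjointly-seeded subsample produces Omega-hat';
    the convergence metric is the max absolute elementwise difference of
    the two correlation matrices.
    """
    if isinstance(table_or_freqs, np.ndarray):
        freqs = table_or_freqs
        idx_all = np.arange(len(freqs))
    else:
        freqs, _, idx_all = polymorphic_frequencies(table_or_freqs)
    poly = (freqs > 0).any(axis=1) & (freqs < 1).any(axis=1)
    freqs = freqs[poly]
    idx_all = idx_all[poly]
    n_poly = len(freqs)
    if n_poly < 50:
        raise ValueError(f"only {n_poly} polymorphic SNPs; need >= 50")
    rng = np.random.default_rng(seed)
    if n_poly < n_snps:
        import warnings

        warnings.warn(
            f"only {n_poly} polymorphic SNPs available; using all", stacklevel=2
        )
        take1 = np.arange(n_poly)
        take2 = rng.permutation(n_poly)
    else:
        take1 = rng.choice(n_poly, n_snps, replace=False)
        take2 = rng.choice(n_poly, n_snps, replace=False)
    omega1 = _moment_omega(freqs[take1])
    omega2 = _moment_omega(freqs[take2])
    conv = float(np.max(np.abs(_corr(omega1) - _corr(omega2))))
    return CovarianceModel(omega1, omega2, conv, len(take1), idx_all[take1])


# ---------------------------------------------------------------------------
# Per-SNP environmental score
# ---------------------------------------------------------------------------

@dataclass
class EnvScoreParams:
    grid_points: int = 401
    prior_sd_multiplier: float = 1.0
    ridge: float = 1e-6


def env_score(
    freqs: np.ndarray,
    depths: np.ndarray,
    model: CovarianceModel,
    env: EnvComposite,
    params: EnvScoreParams | None = None,
) -> pd.DataFrame:
    """Per-SNP support for a non-zero environmental effect.

    Returns a DataFrame with columns beta_hat, sign_prob
    (P(beta > 0 | data)), z_support (= |sign_prob - 0.5|, in [0, 0.5]),
    bayes_factor, and rank (descending z_support * bayes_factor).

    The prior sd on beta is set so that +-3 sd spans the maximal slope a
    frequency cline can take over the observed env1 range; the grid has
    ``grid_points`` symmetric points over +-4 prior sd.
    """
    params = params or EnvScoreParams()
    freqs = np.asarray(freqs, dtype=float)
    depths = np.asarray(depths, dtype=float)
    e = env.scores - env.scores.mean()
    S, P = freqs.shape
    if len(e) != P:
        raise ValueError("env scores and pools disagree")
    omega = model.omega + params.ridge * np.eye(P)

    env_range = e.max() - e.min()
    prior_sd = params.prior_sd_multiplier * (1.0 / env_range) * (3.0 / 3.0)
    grid = np.linspace(-4 * prior_sd, 4 * prior_sd, params.grid_points)
    log_prior = -0.5 * (grid / prior_sd) ** 2

    pbar = freqs.mean(axis=1)
    sigma2 = np.clip(pbar * (1 - pbar), 1e-6, None)
    # read-noise floor keeps fixed pools from claiming zero variance
    p_noise = (freqs * depths + 0.5) / (depths + 1.0)
    noise = p_noise * (1 - p_noise) / np.clip(depths, 1.0, None)
    V = sigma2[:, None, None] * omega[None, :, :]
    V[:, np.arange(P), np.arange(P)] += noise
    Vi = np.linalg.inv(V)

    one = np.ones(P)
    Vi1 = Vi @ one  # (S, P)
    s11 = Vi1 @ one  # (S,)
    # Q = Vi - Vi 1 1' Vi / (1' Vi 1): flat-prior marginalization of alpha
    Qe = Vi @ e - Vi1 * ((Vi1 @ e) / s11)[:, None]
    A = np.einsum("j,sj->s", e, Qe)
    B = np.einsum("sj,sj->s", freqs, Qe)

    # log-likelihood on the grid, normalized at beta = 0
    ll = -(0.5 * A[:, None] * grid[None, :] ** 2) + B[:, None] * grid[None, :]
    post = ll + log_prior[None, :]
    post -= post.max(axis=1, keepdims=True)
    w = np.exp(post)
    total = np.trapezoid(w, grid, axis=1)
    # grid is symmetric with an odd point count, so grid[mid] == 0 and the
    # upper half-integral is exactly the posterior mass of beta > 0
    mid = params.grid_points // 2
    num = np.trapezoid(w[:, mid:], grid[mid:], axis=1)
    sign_prob = num / total
    z = np.abs(sign_prob - 0.5)
    # Bayes factor: integral of prior * L over grid, with L(0) = 1
    prior_dens = np.exp(log_prior) / (prior_sd * np.sqrt(2 * np.pi))
    bf = np.trapezoid(np.exp(ll) * prior_dens[None, :], grid, axis=1)
    beta_hat = B / (A + 1.0 / prior_sd**2)  # posterior mean (conjugate form)
    df = pd.DataFrame(
        {
            "beta_hat": beta_hat,
            "sign_prob": sign_prob,
            "z_support": z,
            "bayes_factor": bf,
        }
    )
    df["rank"] = (
        (df.z_support * df.bayes_factor).rank(ascending=False, method="first")
    ).astype(int)
    return df


def overlap_report(env_top, fst_top) -> dict:
    """Intersection statistics between two candidate-SNP (or gene) sets.

    Percentage is 100 * |intersection| / |env_top| rounded to 2 decimals;
    an empty env_top yields a flagged, undefined percentage.
    """
    env_top, fst_top = set(env_top), set(fst_top)
    inter = env_top & fst_top
    out = dict(
        n_env=len(env_top),
        n_fst=len(fst_top),
        n_overlap=len(inter),
        overlap=sorted(inter),
    )
    if env_top:
        out["percent"] = round(100.0 * len(inter) / len(env_top), 2)
        out["defined"] = True
    else:
        out["percent"] = float("nan")
        out["defined"] = False
    return out
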