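"""Population-structure ordination and formal admixture tests.

* DISTATIS: a three-way generalization of classical MDS.  Each distance
  matrix is double-centered, normalized by its first eigenvalue, the
  matrices are weighted by the first eigenvector of their RV-coefficient
  similarity matrix, and the weighted average (the compromise) is
  eigendecomposed to ordinate populations.  Bootstrap resampling of SNPs
  yields 95% confidence ellipses around each population's position.
* Neighbor-joining trees (via scikit-bio) and a Mantel test with the
  permutation p-value convention (count + 1) / (n_perm + 1).
* f3 / f4 admixture statistics on pool allele frequencies with
  delete-one block jackknife standard errors over consecutive SNP
  blocks; a significantly negative f3(X; A, B) z-score marks X as
  admixed between sources related to A and B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

DEFAULT_QUANTILES = (0.975, 0.75, 0.5, 0.25, 0.025)


# ---------------------------------------------------------------------------
# Quantile distance matrices and DISTATIS
# ---------------------------------------------------------------------------

def quantile_distance_matrices(
    fst_values: np.ndarray,
    pair_index: list[tuple[int, int]],
    n_pops: int,
    levels=DEFAULT_QUANTILES,
) -> np.ndarray:
    """Stack of symmetric P x P distance matrices, one per quantile level.

    ``fst_values`` is (n_snps, n_pairs) of per-SNP pairwise F_ST;
    ``pair_index`` lists the (i, j) pool pair of each column.  Entry
    (i, j) of matrix k is the type-7 sample quantile at level k of that
    pair's values; diagonals are zero.
    """
    fst_values = np.asarray(fst_values, dtype=float)
    if fst_values.shape[0] < 1:
        raise ValueError("need at least one SNP per pair")
    K = len(levels)
    out = np.zeros((K, n_pops, n_pops))
    for c, (i, j) in enumerate(pair_index):
        col = fst_values[:, c]
        col = col[np.isfinite(col)]
        if len(col) == 0:
            raise ValueError(f"pair ({i},{j}) has no finite F_ST values")
        qs = np.quantile(col, levels, method="linear")
        for k in range(K):
            out[k, i, j] = out[k, j, i] = qs[k]
    return out


@dataclass
class CompromiseSpace:
    """DISTATIS output: table weights, compromise eigendecomposition,
    factor scores, and optional bootstrap ellipses per population."""

    alphas: np.ndarray
    compromise: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    scores: np.ndarray  # (P, n_axes)
    rv_matrix: np.ndarray
    boot_scores: np.ndarray | None = None  # (n_boot, P, 2)
    ellipses: list = field(default_factory=list)


def _double_center(d: np.ndarray) -> np.ndarray:
    p = d.shape[0]
    j = np.eye(p) - np.ones((p, p)) / p
    return -0.5 * j @ d @ j


def _normalized_crossproduct(d: np.ndarray) -> np.ndarray:
    s = _double_center(d)
    lam = np.linalg.eigvalsh(s)[-1]
    if lam <= 0:
        raise ValueError("degenerate (all-zero or non-informative) matrix")
    return s / lam


def _rv(a: np.ndarray, b: np.ndarray) -> float:
    num = np.sum(a * b)
    return float(num / (np.linalg.norm(a) * np.linalg.norm(b)))


def distatis(
    dmats: np.ndarray,
    n_boot: int = 0,
    seed: int = 0,
    fst_values: np.ndarray | None = None,
    pair_index: list[tuple[int, int]] | None = None,
    levels=DEFAULT_QUANTILES,
) -> CompromiseSpace:
    """Compromise ordination of K distance matrices.

    Dissimilarities are double-centered directly (not squared), each
    cross-product normalized by its first eigenvalue, and weighted by the
    first eigenvector of the RV-coefficient matrix rescaled to sum 1.
    When ``fst_values``/``pair_index`` are given, ``n_boot`` bootstrap
    resamples of SNPs are projected into the compromise space and 95%
    normal-approximation ellipses fitted on the first two axes.
    """
    dmats = np.asarray(dmats, dtype=float)
    if dmats.shape[0] < 2:
        raise ValueError("need at least two matrices")
    informative = [k for k in range(dmats.shape[0]) if np.any(dmats[k] != 0)]
    if len(informative) < len(dmats):
        import warnings

        warnings.warn(
            f"dropping {dmats.shape[0] - len(informative)} all-zero distance "
            "matrix(es); a low quantile of clamped F_ST values can be "
            "identically zero",
            stacklevel=2,
        )
    dmats = dmats[informative]
    levels = tuple(np.asarray(levels)[informative])
    K, P, _ = dmats.shape
    if K < 2:
        raise ValueError("fewer than two informative matrices")
    tilde = np.stack([_normalized_crossproduct(d) for d in dmats])
    C = np.ones((K, K))
    for k in range(K):
        for l in range(k + 1, K):
            C[k, l] = C[l, k] = _rv(tilde[k], tilde[l])
    w, v = np.linalg.eigh(C)
    alpha = v[:, -1]
    if alpha.sum() < 0:
        alpha = -alpha
    alpha = alpha / alpha.sum()
    compromise = np.tensordot(alpha, tilde, axes=1)
    lam, vec = np.linalg.eigh(compromise)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    pos = np.clip(lam, 0.0, None)
    scores = vec * np.sqrt(pos)[None, :]
    space = CompromiseSpace(
        alphas=alpha,
        compromise=compromise,
        eigenvalues=lam,
        eigenvectors=vec,
        scores=scores,
        rv_matrix=C,
    )
    if n_boot and fst_values is not None and pair_index is not None:
        rng = np.random.default_rng(seed)
        n_snps = fst_values.shape[0]
        keep = pos > 1e-12
        proj = vec[:, keep] / np.sqrt(pos[keep])[None, :]
        boots = np.empty((n_boot, P, 2))
        for bi in range(n_boot):
            take = rng.integers(0, n_snps, n_snps)
            dset = quantile_distance_matrices(
                fst_values[take], pair_index, P, levels
            )
            tilde_b = np.stack(
                [
                    _normalized_crossproduct(d) if np.any(d != 0) else np.zeros((P, P))
                    for d in dset
                ]
            )
            comp_b = np.tensordot(alpha, tilde_b, axes=1)
            fb = comp_b @ proj  # supplementary projection
            boots[bi] = fb[:, :2]
        space.boot_scores = boots
        chi2_95 = 5.991464547107979  # chi^2(2) 0.95 quantile
        for p in range(P):
            cloud = boots[:, p, :]
            center = cloud.mean(axis=0)
            cov = np.cov(cloud.T)
            ew, ev = np.linalg.eigh(np.atleast_2d(cov))
            angle = float(np.arctan2(ev[1, -1], ev[0, -1]))
            space.ellipses.append(
                dict(
                    population=p,
                    center=center,
                    semi_axes=np.sqrt(np.clip(ew[::-1], 0, None) * chi2_95),
                    angle=angle,
                )
            )
    return space


# ---------------------------------------------------------------------------
# Neighbor joining and Mantel
# ---------------------------------------------------------------------------

def nj_tree(distance_matrix: np.ndarray, labels: list[str]) -> str:
    """Neighbor-joining newick string; negative branch lengths clamped to
    zero with the excess moved to the sister branch (scikit-bio)."""
    d = np.asarray(distance_matrix, dtype=float)
    if d.shape[0] < 3:
        raise ValueError("need at least three taxa")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    dm = DistanceMatrix(d, ids=list(labels))
    tree = _skbio_nj(dm)
    return str(tree).strip()


def mantel(
    m1: np.ndarray, m2: np.ndarray, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Mantel correlation between two symmetric matrices.

    r is the Pearson correlation of the off-diagonal upper triangles;
    the one-sided p-value over ``n_perm`` joint row/column permutations
    is (count >= observed + 1) / (n_perm + 1).  A constant matrix yields
    r = NaN.
    """
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must share a square shape")
    iu = np.triu_indices(a.shape[0], k=1)
    x, y = a[iu], b[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")

    def corr(u, v):
        return float(np.corrcoef(u, v)[0, 1])

    r_obs = corr(x, y)
    rng = np.random.default_rng(seed)
    count = 0
    n = a.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        if corr(x, bp[iu]) >= r_obs:
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# f3 / f4 statistics with block jackknife
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FStatResult:
    statistic: str  # "f3" | "f4"
    configuration: tuple
    estimate: float
    se: float
    z: float
    block_size: int
    n_snps: int


def _block_jackknife(per_snp: np.ndarray, block_size: int):
    n = len(per_snp)
    n_blocks = int(np.ceil(n / block_size))
    if n_blocks < 2:
        raise ValueError("need at least two SNP blocks for the jackknife")
    total = per_snp.sum()
    est = total / n
    loo = np.empty(n_blocks)
    for g in range(n_blocks):
        sl = slice(g * block_size, min((g + 1) * block_size, n))
        k = sl.stop - sl.start
        loo[g] = (total - per_snp[sl].sum()) / (n - k)
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()))
    return float(est), se


def f3_statistic(
    freqs: np.ndarray,
    target: int,
    source1: int,
    source2: int,
    block_size: int = 500,
    depths: np.ndarray | None = None,
    correct: bool = True,
) -> FStatResult:
    """f3(target; source1, source2) = E[(pT - p1)(pT - p2)].

    With ``correct`` (and read depths supplied) the per-SNP finite-
    sampling bias of the target frequency is removed by subtracting
    h_T / M_T = p(1-p) / (M_T - 1); the pool-plus-read two-stage noise
    makes the exact correction model-dependent, so it can be disabled.
    A z-score below -3 is strong evidence that the target is admixed.
    """
    f = np.asarray(freqs, dtype=float)
    pt, p1, p2 = f[:, target], f[:, source1], f[:, source2]
    per_snp = (pt - p1) * (pt - p2)
    if correct and depths is not None:
        m = np.asarray(depths, dtype=float)[:, target]
        with np.errstate(divide="ignore", invalid="ignore"):
            corr_term = pt * (1 - pt) / (m - 1.0)
        per_snp = per_snp - np.where(m > 1, corr_term, 0.0)
    est, se = _block_jackknife(per_snp, block_size)
    z = est / se if se > 0 else float("nan")
    return FStatResult(
        "f3", (target, source1, source2), est, se, z, block_size, len(per_snp)
    )


def f4_statistic(
    freqs: np.ndarray,
    a: int,
    b: int,
    c: int,
    d: int,
    block_size: int = 500,
) -> FStatResult:
    """f4(A, B; C, D) = E[(pA - pB)(pC - pD)]; |z| > 3 rejects treeness."""
    f = np.asarray(freqs, dtype=float)
    per_snp = (f[:, a] - f[:, b]) * (f[:, c] - f[:, d])
    est, se = _block_jackknife(per_snp, block_size)
    z = est / se if se > 0 else float("nan")
    return FStatResult("f4", (a, b, c, d), est, se, z, block_size, len(per_snp))


def enumerate_f3(n_pops: int):
    """All ordered-target triplets (target; {s1, s2}): P * C(P-1, 2)."""
    for t in range(n_pops):
        rest = [p for p in range(n_pops) if p != t]
        for s1, s2 in combinations(rest, 2):
            yield (t, s1, s2)


def enumerate_f4(n_pops: int):
    """The 3 * C(P, 4) distinct four-population topologies."""
    for quad in combinations(range(n_pops), 4):
        a, b, c, d = quad
        yield (a, b, c, d)
        yield (a, c, b, d)
        yield (a, d, b, c)


def f_statistics_table(
    freqs: np.ndarray,
    block_size: int = 500,
    depths: np.ndarray | None = None,
    correct: bool = True,
) -> pd.DataFrame:
    """All f3 and f4 configurations for the pools in ``freqs``."""
    P = freqs.shape[1]
    rows = []
    for t, s1, s2 in enumerate_f3(P):
        r = f3_statistic(freqs, t, s1, s2, block_size, depths, correct)
        rows.append(
            dict(statistic="f3", configuration=f"{t};{s1},{s2}",
                 estimate=r.estimate, se=r.se, z=r.z)
        )
    for a, b, c, d in enumerate_f4(P):
        r = f4_statistic(freqs, a, b, c, d, block_size)
        rows.append(
            dict(statistic="f4", configuration=f"{a},{b};{c},{d}",
                 estimate=r.estimate, se=r.se, z=r.z)
        )
    return pd.DataFrame(rows)


def pool_frequencies(table, min_minor_count: int = 4):
    """Major/minor allele frequencies per pool for f statistics.

    Returns (freqs, depths, snp_index): the frequency of the minor allele
    (defined on counts summed across pools) in each pool, the per-pool
    read depth over the two alleles, and the row indices of retained
    SNPs.
    """
    base = table.counts[:, :, :4]
    totals = base.sum(axis=1)
    order = np.argsort(totals, axis=1)
    major, minor = order[:, -1], order[:, -2]
    minor_count = np.take_along_axis(totals, minor[:, None], 1)[:, 0]
    keep = ((totals > 0).sum(axis=1) >= 2) & (minor_count >= min_minor_count)
    idx = np.where(keep)[0]
    s_ix = idx[:, None]
    p_ix = np.arange(table.n_pools)[None, :]
    cmin = base[s_ix, p_ix, minor[idx][:, None]]
    cmaj = base[s_ix, p_ix, major[idx][:, None]]
    depth = cmin + cmaj
    with np.errstate(divide="ignore", invalid="ignore"):
        f = cmin / depth
    f = np.where(depth > 0, f, np.nan)
    ok = ~np.isnan(f).any(axis=1)
    return f[ok], depth[ok], idx[ok]
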