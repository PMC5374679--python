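"""Window-based diversity estimation from pooled read counts.

Estimates nucleotide diversity (pi), Watterson's theta and Tajima's D in
non-overlapping windows, applying the two corrections Pool-seq pipelines
require: (i) subsampling every site to a uniform target coverage M*
without replacement, and (ii) restricting the usable allele-frequency
spectrum to read counts in [b, M* - b] for a minimum allele count b,
which rescales both estimators.

The truncation corrections follow from the neutral site-frequency
spectrum restricted to counts in [b, M - b]:

    f_pi(M, b) = (2 / (M (M-1))) * sum_{i=b}^{M-b} (M - i)
    a_W(M, b)  = sum_{i=b}^{M-b} 1 / i

``f_pi`` normalizes the summed per-site heterozygosity (the untruncated
sum equals 1) and ``a_W`` generalizes Watterson's a1.  Tajima's D uses
the classical constants at sample size M with a1 replaced by a_W, an
approximation whose adequacy is asserted by the neutral-simulation
property tests rather than by equality with any external tool.

With pool size n >> M* the reads are treated as draws from the
population allele frequency; the additional n-dependent correction of
the original Pool-seq estimators is omitted (bias O(M/n), < 2% at the
default n = 100, M* = 30).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ConfigurationError, SiteCountsTable


@dataclass(frozen=True)
class DiversityParams:
    """Window length L, minimum count b, target coverage M*, and the
    minimum fraction of usable sites below which a window is nulled."""

    window_length: int = 10_000
    min_count: int = 2
    target_coverage: int = 30
    min_usable_fraction: float = 0.5
    #: Treat sites absent from the table as usable monomorphic sites
    #: (appropriate when the table carries segregating sites only).
    assume_missing_monomorphic: bool = False
    #: Haploid pool size n.  When given, per-site heterozygosities are
    #: rescaled by n/(n-1), removing the O(1/n) downward bias reads
    #: inherit from estimating the pool's plug-in heterozygosity.  Left
    #: unset, the reads are treated as draws from the population
    #: frequency itself (bias ~1% at n = 100).
    pool_size: int | None = None

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ConfigurationError("min_count must be >= 1")
        if self.target_coverage <= 2 * self.min_count:
            raise ConfigurationError("target_coverage must exceed 2 * min_count")
        if self.window_length <= 0:
            raise ConfigurationError("window_length must be positive")


def correction_factors(M: int, b: int) -> tuple[float, float]:
    """Truncation corrections (f_pi, a_W) for coverage M and min count b."""
    if M < 2 * b:
        raise ConfigurationError("require M >= 2b")
    i = np.arange(b, M - b + 1)
    f_pi = 2.0 / (M * (M - 1)) * np.sum(M - i)
    a_w = float(np.sum(1.0 / i))
    return float(f_pi), a_w


def tajima_constants(M: int, b: int) -> dict:
    """Tajima's variance constants at sample size M, a1 -> a_W(M, b)."""
    _, a1 = correction_factors(M, b)
    n = M
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajima_d(pi_window: float, S: int, M: int, b: int) -> float:
    """Tajima's D for a window.

    ``pi_window`` is the corrected sum of per-site heterozygosities over
    the window (i.e. pi-hat times the usable length); ``S`` the number of
    segregating sites.  Returns NaN when S < 2 (undefined, never zero).
    """
    if S < 2:
        return math.nan
    c = tajima_constants(M, b)
    num = pi_window - S / c["a1"]
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return math.nan
    return float(num / math.sqrt(var))


def subsample_coverage(counts, target: int, rng) -> np.ndarray | None:
    """Reduce one pool's count sextet to uniform coverage ``target``.

    Draws without replacement (multivariate hypergeometric).  Returns the
    sextet unchanged if coverage equals the target, ``None`` (excluded)
    if coverage is below it.
    """
    if target <= 0:
        raise ConfigurationError("target coverage must be positive")
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total < target:
        return None
    if total == target:
        return counts.copy()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return rng.multivariate_hypergeometric(counts, target)


def _subsample_matrix(counts: np.ndarray, target: int, rng: np.random.Generator):
    """Vectorized without-replacement subsampling of (n_sites, 4) counts
    whose row sums all exceed ``target``."""
    n = len(counts)
    out = np.zeros_like(counts)
    remaining = np.full(n, target, dtype=np.int64)
    rest = counts.sum(axis=1)
    for j in range(counts.shape[1]):
        rest = rest - counts[:, j]
        draw = np.zeros(n, dtype=np.int64)
        mask = remaining > 0
        if mask.any():
            draw[mask] = rng.hypergeometric(
                counts[mask, j], rest[mask], remaining[mask]
            )
        out[:, j] = draw
        remaining -= draw
    return out


def _site_stats(base_counts: np.ndarray, M: int, b: int):
    """Per-site heterozygosity and segregating flag after filtering
    alleles below count b.  h = (M/(M-1)) (1 - sum f^2) over passing
    alleles, zero when fewer than two alleles pass."""
    passing = base_counts >= b
    seg = passing.sum(axis=1) >= 2
    f = np.where(passing, base_counts, 0) / M
    h = (M / (M - 1.0)) * (1.0 - (f**2).sum(axis=1))
    h = np.where(seg, h, 0.0)
    return h, seg


def window_diversity(
    table: SiteCountsTable, params: DiversityParams, seed: int = 0
) -> pd.DataFrame:
    """Per-window, per-population diversity statistics.

    Returns a DataFrame with one row per (scaffold, window, population):
    columns scaffold, start, end (0-based half-open), population, pi,
    theta_w, tajima_d, n_segregating, usable_sites, ok.  Windows with
    fewer usable sites than ``min_usable_fraction * L`` carry NaN
    estimates and ok = False.
    """
    M = params.target_coverage
    b = params.min_count
    L = params.window_length
    f_pi, a_w = correction_factors(M, b)
    pool_factor = 1.0
    if params.pool_size is not None:
        n = params.pool_size
        if n < 2:
            raise ConfigurationError("pool_size must be >= 2")
        pool_factor = n / (n - 1.0)
    rng = np.random.default_rng(seed)
    rows = []
    base = table.counts[:, :, :4]  # alleles are A/C/G/T; N and del ignored
    win = (table.position - 1) // L
    # stable group keys in order of appearance
    keys = pd.DataFrame({"scaffold": table.scaffold, "win": win})
    grouped = keys.groupby(["scaffold", "win"], sort=False).indices
    for (scaf, w), idx in grouped.items():
        idx = np.asarray(idx)
        for k in range(table.n_pools):
            counts = base[idx, k, :]
            cov = counts.sum(axis=1)
            excluded = cov < M
            kept = counts[~excluded]
            covk = cov[~excluded]
            over = covk > M
            sub = kept.copy()
            if over.any():
                sub[over] = _subsample_matrix(kept[over], M, rng)
            h, seg = _site_stats(sub, M, b)
            h = h * pool_factor
            n_usable = len(sub)
            if params.assume_missing_monomorphic:
                n_usable = L - int(excluded.sum())
            S = int(seg.sum())
            ok = n_usable >= params.min_usable_fraction * L
            if ok and n_usable > 0:
                pi_sum = h.sum() / f_pi
                pi = pi_sum / n_usable
                theta = S / (a_w * n_usable)
                d = tajima_d(pi_sum, S, M, b)
            else:
                pi = theta = d = math.nan
            rows.append(
                dict(
                    scaffold=scaf,
                    start=int(w) * L,
                    end=(int(w) + 1) * L,
                    population=k,
                    pi=pi,
                    theta_w=theta,
                    tajima_d=d,
                    n_segregating=S,
                    usable_sites=n_usable,
                    ok=bool(ok),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "scaffold", "start", "end", "population", "pi", "theta_w",
            "tajima_d", "n_segregating", "usable_sites", "ok",
        ],
    )
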