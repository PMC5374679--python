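"""Small-sample ecophysiology statistics.

Covers the trait comparisons of the field experiment: exact Mann-Whitney
U tests for biomass and chlorophyll content, Welch t-tests for thallus
water content (TWC) and maximal net photosynthesis (NP), and polynomial
response curves of NP or dark respiration (DR) against thallus water
content with the 90%-of-maximum criterion for optimal water saturation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Mann-Whitney U with an exact two-sided p for small samples.

    The exact p doubles the one-tailed probability (capped at 1).  When
    nx * ny exceeds 10,000 or ties are present, the tie-corrected normal
    approximation is used with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    exact_ok = (len(x) * len(y) <= 10_000) and not has_ties
    if not exact_ok:
        warnings.warn(
            "ties or large samples: using normal approximation", stacklevel=2
        )
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact_ok else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df.

    Returns (t, df, two-sided p); both groups constant yields NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return float("nan"), float("nan"), float("nan")
    res = stats.ttest_ind(x, y, equal_var=False)
    se2 = vx / len(x) + vy / len(y)
    df = se2**2 / (
        (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass
class ResponseCurve:
    """Polynomial fit of a gas-exchange trait against thallus water
    content, with the water content at maximum and the range sustaining
    >= 90% of the maximum response."""

    coefficients: np.ndarray  # ascending powers
    degree: int
    r_squared: float
    wc_at_max: float
    max_response: float
    wc_range_90: tuple  # (low, high) where fitted response >= 0.9 max
    wc_observed: tuple  # (min, max) observed water contents


def fit_response_curve(wc, response, degree: int = 3) -> ResponseCurve:
    """Least-squares polynomial of ``response`` on water content.

    The fitted maximum is located on the observed WC interval; the
    90%-of-maximum interval is obtained from the real roots of
    p(x) = 0.9 * max intersected with the observed range.  An
    ill-conditioned fit reduces the degree with a warning.
    """
    wc = np.asarray(wc, dtype=float)
    response = np.asarray(response, dtype=float)
    if len(wc) < degree + 2:
        raise ValueError("need at least degree + 2 points")
    order = np.argsort(wc)
    wc, response = wc[order], response[order]
    while degree >= 2:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            coef = np.polynomial.polynomial.polyfit(wc, response, degree)
            if not any(issubclass(c.category, np.exceptions.RankWarning)
                       for c in caught):
                break
        warnings.warn(f"ill-conditioned fit; reducing degree to {degree - 1}",
                      stacklevel=2)
        degree -= 1
    poly = np.polynomial.Polynomial(coef)
    # trailing coefficients at rounding-noise level make the derivative's
    # companion-matrix roots ill-conditioned; trim them before root-finding
    trimmed = np.polynomial.polynomial.polytrim(
        coef, tol=1e-9 * np.max(np.abs(coef))
    )
    poly_roots = np.polynomial.Polynomial(trimmed)
    fitted = poly(wc)
    ss_res = float(((response - fitted) ** 2).sum())
    ss_tot = float(((response - response.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    lo, hi = float(wc.min()), float(wc.max())
    crit = [r.real for r in poly_roots.deriv().roots()
            if abs(r.imag) < 1e-9 and lo <= r.real <= hi]
    cand = np.array([lo, hi] + crit)
    vals = poly(cand)
    imax = int(np.argmax(vals))
    wc_max, v_max = float(cand[imax]), float(vals[imax])
    # 90% interval: sign changes of p(x) - 0.9*max on a fine grid
    thresh = 0.9 * v_max
    xs = np.linspace(lo, hi, 2001)
    above = poly(xs) >= thresh
    if above.any():
        rng90 = (float(xs[above].min()), float(xs[above].max()))
    else:
        rng90 = (wc_max, wc_max)
    return ResponseCurve(
        coefficients=coef,
        degree=degree,
        r_squared=r2,
        wc_at_max=wc_max,
        max_response=v_max,
        wc_range_90=rng90,
        wc_observed=(lo, hi),
    )


def compare_group_optima(
    curves: pd.DataFrame, degree: int = 3
) -> pd.DataFrame:
    """Per-group response-curve optima from a tidy table with columns
    sample, group, wc, response.  Reports each group's mean and sd of the
    per-sample WC at maximum response."""
    rows = []
    for group, gdf in curves.groupby("group"):
        optima = []
        for _, sdf in gdf.groupby("sample"):
            fit = fit_response_curve(sdf.wc, sdf.response, degree)
            optima.append(fit.wc_at_max)
        optima = np.asarray(optima)
        rows.append(
            dict(
                group=group,
                n=len(optima),
                wc_opt_mean=float(optima.mean()),
                wc_opt_sd=float(optima.std(ddof=1)) if len(optima) > 1 else 0.0,
            )
        )
    return pd.DataFrame(rows)


def trait_summary(tidy: pd.DataFrame) -> pd.DataFrame:
    """Mean +- SD per population and trait from a tidy table with columns
    sample, population, trait, value (shape of a dry-weight/chlorophyll
    summary table)."""
    g = tidy.groupby(["trait", "population"])["value"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"std": "sd", "count": "n"})
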