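"""Analytic sensitivity (power) model for detecting tissue-specific TFs.

A TF highly expressed only in a minor fraction ``w`` of cells within the
tissue of interest shows a diluted bulk-level effect: on the log2 scale the
expected group-mean difference is

    e = log2(FC*w + (1-w)) / sigma,

with ``FC`` the linear fold change in the expressing cells and ``sigma``
the pooled SD (a scaled basis with sigma = 1 is the default).  The
two-group t-statistic then follows a non-central t distribution with
non-centrality

    mu = sqrt(n1*n2 / (n1+n2)) * e

and the sensitivity at a significance threshold ``t`` is the tail mass of
that distribution beyond the threshold.  Two forms are provided: the
one-tail approximation doubled (``paper_approx``, clipped to 1) and the
exact two-sided rejection probability (default), which also counts the
vanishingly small lower-tail mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps


def nct_cdf(t: float, df: float, mu: float) -> float:
    """Non-central t CDF, robust at very large degrees of freedom.

    scipy's implementation can return NaN for df in the thousands; in that
    case the CDF is evaluated from its defining mixture representation
    P(T <= t) = E[Phi(t*S - mu)] with S = sqrt(V/df), V ~ chi-square(df),
    by adaptive quadrature over the chi density (S concentrates near 1 with
    spread ~ sqrt(1/(2*df)), so the integrand is smooth and narrow).
    """
    val = float(sps.nct.cdf(t, df, mu))
    if not math.isnan(val):
        return val
    s_dist = sps.chi(df, scale=1.0 / math.sqrt(df))
    lo, hi = s_dist.ppf(1e-12), s_dist.isf(1e-12)
    out, _ = integrate.quad(
        lambda s: sps.norm.cdf(t * s - mu) * s_dist.pdf(s), lo, hi,
        limit=200)
    return float(min(max(out, 0.0), 1.0))


def nct_sf(t: float, df: float, mu: float) -> float:
    val = float(sps.nct.sf(t, df, mu))
    if not math.isnan(val):
        return val
    return 1.0 - nct_cdf(t, df, mu)


@dataclass
class PowerParams:
    """Inputs to the sensitivity calculation.

    n1/n2: sample counts in the tissue of interest / all other tissues;
    FC: average linear fold change (>= 1) in the expressing cells;
    w: minor cell fraction in [0, 1]; sigma: pooled SD on the log2 scale;
    t: positive significance threshold on the t-statistic scale.
    """

    n1: int
    n2: int
    FC: float
    w: float
    sigma: float = 1.0
    t: float | None = None

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("n1 and n2 must be >= 2")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")

    @property
    def df(self) -> int:
        return self.n1 + self.n2 - 2


def effect_size(FC: float, w: float, sigma: float = 1.0) -> float:
    """Standardized log2 effect of a TF expressed at fold change FC in a
    fraction w of cells: log2(FC*w + (1-w)) / sigma."""
    if FC < 1:
        raise ValueError("model is defined for overexpression (FC >= 1)")
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return math.log2(FC * w + (1.0 - w)) / sigma


def noncentrality(n1: int, n2: int, e: float) -> float:
    """Non-centrality parameter mu = sqrt(n1*n2/(n1+n2)) * e."""
    return math.sqrt(n1 * n2 / (n1 + n2)) * e


def threshold_from_alpha(alpha: float, m: int, df: int) -> float:
    """Two-sided critical t for significance level ``alpha`` Bonferroni-
    corrected over ``m`` tests."""
    if not 0 < alpha < 1 or m < 1:
        raise ValueError("need 0 < alpha < 1 and m >= 1")
    return float(sps.t.isf(alpha / (2.0 * m), df))


def sensitivity_at_threshold(params: PowerParams,
                             mode: str = "exact_two_sided") -> float:
    """Sensitivity to call the TF significant at threshold ``params.t``.

    ``paper_approx``: 2*(1 - F_nct(t; df, mu)), clipped to [0, 1];
    ``exact_two_sided``: 1 - F_nct(t) + F_nct(-t), the exact two-sided
    rejection probability.  The two agree whenever the lower-tail mass is
    negligible.
    """
    if params.t is None or params.t <= 0:
        raise ValueError("threshold t must be a positive critical value")
    e = effect_size(params.FC, params.w, params.sigma)
    mu = noncentrality(params.n1, params.n2, e)
    df = params.df
    upper = nct_sf(params.t, df, mu)
    if mode == "paper_approx":
        return float(np.clip(2.0 * upper, 0.0, 1.0))
    if mode == "exact_two_sided":
        lower = nct_cdf(-params.t, df, mu)
        return float(np.clip(upper + lower, 0.0, 1.0))
    raise ValueError(f"unknown mode {mode!r}")


def power_curve(vary: str, grid, fixed: PowerParams,
                mode: str = "exact_two_sided") -> pd.DataFrame:
    """Sensitivity over a grid of one varied parameter (t, w, n1 or FC)."""
    grid = np.asarray(list(grid))
    if grid.size == 0:
        raise ValueError("empty grid")
    if vary not in ("t", "w", "n1", "FC"):
        raise ValueError(f"cannot vary {vary!r}")
    rows = []
    for v in grid:
        p = replace(fixed, **{vary: int(v) if vary == "n1" else float(v)})
        rows.append(sensitivity_at_threshold(p, mode=mode))
    return pd.DataFrame({vary: grid, "SE": rows})


def simulate_power_mc(n1: int, n2: int, e: float, t: float,
                      n_reps: int = 100_000, seed=None) -> float:
    """Monte-Carlo check of the analytic sensitivity.

    Simulates the two-group equal-variance t-test through its sufficient
    statistics — group means are Normal with variance 1/n_i and the pooled
    variance is a scaled chi-square with n1+n2-2 df — which is exactly
    distributed as simulating all n1+n2 unit-variance observations with a
    mean shift of ``e``.  Returns the fraction of |t| >= t.
    """
    rng = np.random.default_rng(seed)
    df = n1 + n2 - 2
    m1 = rng.normal(e, 1.0 / math.sqrt(n1), n_reps)
    m2 = rng.normal(0.0, 1.0 / math.sqrt(n2), n_reps)
    s2 = rng.chisquare(df, n_reps) / df
    tstat = (m1 - m2) / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    return float((np.abs(tstat) >= t).mean())
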