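"""Differential-activity statistics, Monte-Carlo nulls and benchmark metrics.

Differential activity between binary phenotypes (e.g. normal vs cancer
cells) uses a two-sided Wilcoxon rank-sum or t-test per TF with Bonferroni
correction over the TFs tested; ordinal phenotypes (timepoints, stages) use
Spearman rank correlation.  Two-sided p-values are converted to signed
z-statistics using the normal quantile, signed by the direction of the
effect (AUC vs 0.5, or the sign of rho).

The Monte-Carlo regulon null asks whether an observed fraction of
significantly inactivated TFs could arise from regulons of the same sizes
and sign composition drawn at random from the gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .activity import TFActivityMatrix, _tfa_from_zscored, make_target_profile
from .io_preprocess import ExpressionMatrix, zscore_rows
from .netinfer import RegulatoryNetwork

Z_CAP = 38.0


# ---------------------------------------------------------------------------
# Vectorized rank tests (validated against scipy per-row in the test suite)
# ---------------------------------------------------------------------------

def rank_sum_rows(values: np.ndarray, group1_mask: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided Wilcoxon rank-sum test, normal approximation with
    midranks, tie correction and continuity correction.

    Returns (auc, p); ``auc`` > 0.5 means higher values in group 1.
    """
    values = np.atleast_2d(values)
    g1 = np.asarray(group1_mask, dtype=bool)
    n1 = int(g1.sum())
    n2 = values.shape[1] - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    ranks = sps.rankdata(values, axis=1)
    r1 = ranks[:, g1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    auc = u1 / (n1 * n2)
    # tie correction per row; only rows that actually contain ties need the
    # per-row run-length count
    tie_term = np.zeros(values.shape[0])
    sv = np.sort(values, axis=1)
    has_ties = (sv[:, 1:] == sv[:, :-1]).any(axis=1)
    for i in np.flatnonzero(has_ties):
        _, counts = np.unique(values[i], return_counts=True)
        tie_term[i] = (counts ** 3 - counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    mu = n1 * n2 / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        num = u1 - mu
        z = np.where(sigma2 > 0,
                     (num - 0.5 * np.sign(num)) / np.sqrt(sigma2), 0.0)
    p = np.minimum(1.0, 2.0 * sps.norm.sf(np.abs(z)))
    return auc, p


def spearman_rows(values: np.ndarray, ordinal: np.ndarray,
                  exact: bool | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman correlation against an ordinal vector.

    Two-sided p-values come from the t approximation (df = n - 2) for large
    n, or from full enumeration of the n! orderings when ``exact`` is True
    (the default below 10 observations, where the approximation is poor).
    """
    values = np.atleast_2d(values)
    n = values.shape[1]
    if n < 3:
        raise ValueError("need >= 3 observations")
    if exact is None:
        exact = n <= 9
    ry = sps.rankdata(np.asarray(ordinal, dtype=float))
    if np.ptp(ry) == 0:
        raise ValueError("ordinal vector is constant")
    rx = sps.rankdata(values, axis=1)
    rxc = rx - rx.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum(axis=1) * (ryc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, (rxc @ ryc) / denom, 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    if exact:
        from itertools import permutations

        perms = np.array(list(permutations(ry)))          # n! x n
        pc = perms - perms.mean(axis=1, keepdims=True)
        pnorm = np.sqrt((pc ** 2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            null_rho = (pc @ rxc.T) / (
                pnorm[:, None] * np.sqrt((rxc ** 2).sum(axis=1))[None, :])
        null_rho = np.nan_to_num(null_rho, nan=0.0)
        p = ((np.abs(null_rho) >= np.abs(rho)[None, :] - 1e-12)
             .mean(axis=0))
        return rho, p
    safe = np.abs(rho) < 1.0
    t = np.empty_like(rho)
    t[safe] = rho[safe] * np.sqrt((n - 2) / (1.0 - rho[safe] ** 2))
    t[~safe] = np.sign(rho[~safe]) * np.inf
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    return rho, p


# ---------------------------------------------------------------------------
# p -> z and simple exact tests
# ---------------------------------------------------------------------------

def pvalue_to_z(p: float, direction_stat: float,
                null_value: float | None = None) -> float:
    """Convert a two-sided p-value to a signed z-statistic.

    The sign is positive when ``direction_stat`` exceeds its null value
    (0.5 for an AUC in [0,1], 0 otherwise, unless ``null_value`` is given).
    p = 1 maps to z = 0; p = 0 is capped at +/-38.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if null_value is None:
        null_value = 0.5 if 0.0 <= direction_stat <= 1.0 else 0.0
    sign = 1.0 if direction_stat > null_value else (
        -1.0 if direction_stat < null_value else 0.0)
    if p == 0.0:
        return sign * Z_CAP
    z = sps.norm.isf(p / 2.0)
    return float(sign * min(z, Z_CAP))


def binomial_skew_test(n_down: int, n_up: int) -> float:
    """Exact one-tailed binomial tail P(X >= n_down | n_down+n_up, 1/2),
    testing a skew towards inactivation."""
    if n_down < 0 or n_up < 0:
        raise ValueError("counts must be non-negative")
    n = n_down + n_up
    if n < 1:
        raise ValueError("need at least one call")
    return float(sps.binomtest(n_down, n, 0.5, alternative="greater").pvalue)


# ---------------------------------------------------------------------------
# Differential-activity tables
# ---------------------------------------------------------------------------

def _direction(p_bonf: np.ndarray, effect_sign: np.ndarray,
               alpha: float) -> np.ndarray:
    out = np.where(p_bonf < alpha,
                   np.where(effect_sign > 0, "UP", "DN"), "NC")
    out[(p_bonf < alpha) & (effect_sign == 0)] = "NC"
    return out


def diff_activity_binary(tfa: TFActivityMatrix, groups,
                         test: str = "wilcoxon",
                         alpha: float = 0.05) -> pd.DataFrame:
    """Per-TF two-group differential activity.

    ``groups`` is a binary label per cell; the second label in sorted order
    is treated as the case group, and positive statistics (AUC > 0.5, t > 0)
    mean higher activity in cases.  Returns a table with columns
    (stat, p, p_bonf, z, direction), Bonferroni-corrected over the TFs
    tested.
    """
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq.size}")
    case = labels == uniq[1]
    if case.sum() < 3 or (~case).sum() < 3:
        raise ValueError("each group needs >= 3 cells")
    m = tfa.values.shape[0]
    if test == "wilcoxon":
        auc, p = rank_sum_rows(tfa.values[:, :], case)
        stat = auc
        effect_sign = np.sign(auc - 0.5)
    elif test == "t":
        res = sps.ttest_ind(tfa.values[:, case], tfa.values[:, ~case],
                            axis=1)
        stat = res.statistic
        p = res.pvalue
        effect_sign = np.sign(stat)
    else:
        raise ValueError(f"unknown test {test!r}")
    p_bonf = np.minimum(1.0, p * m)
    null_val = 0.5 if test == "wilcoxon" else 0.0
    z = np.array([pvalue_to_z(pi, si, null_value=null_val)
                  for pi, si in zip(p, stat)])
    return pd.DataFrame({"stat": stat, "p": p, "p_bonf": p_bonf, "z": z,
                         "direction": _direction(p_bonf, effect_sign, alpha)},
                        index=tfa.tf_ids)


def diff_activity_ordinal(tfa: TFActivityMatrix, stage,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Per-TF Spearman correlation of activity against an ordinal phenotype
    (timepoint/stage), Bonferroni-corrected."""
    stage = np.asarray(stage, dtype=float)
    if np.unique(stage).size < 3:
        raise ValueError("need >= 3 distinct stages")
    rho, p = spearman_rows(tfa.values, stage)
    m = tfa.values.shape[0]
    p_bonf = np.minimum(1.0, p * m)
    z = np.array([pvalue_to_z(pi, ri, null_value=0.0)
                  for pi, ri in zip(p, rho)])
    return pd.DataFrame({"stat": rho, "p": p, "p_bonf": p_bonf, "z": z,
                         "direction": _direction(p_bonf, np.sign(rho),
                                                 alpha)},
                        index=tfa.tf_ids)


# ---------------------------------------------------------------------------
# Monte-Carlo regulon null
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloNull:
    """Null distribution of the fraction of significantly inactivated TFs
    under size- and sign-matched random regulons."""

    observed_fraction: float
    null_fractions: np.ndarray
    n_runs: int
    alpha: float
    empirical_p: float


def _significant_dn_fraction(values: np.ndarray, case_mask: np.ndarray,
                             alpha: float) -> float:
    auc, p = rank_sum_rows(values, case_mask)
    m = values.shape[0]
    p_bonf = np.minimum(1.0, p * m)
    dn = (p_bonf < alpha) & (auc < 0.5)
    return float(dn.mean())


def montecarlo_regulon_null(sc: ExpressionMatrix, net: RegulatoryNetwork,
                            groups, n_runs: int = 1000,
                            alpha: float = 0.05,
                            seed=None) -> MonteCarloNull:
    """Monte-Carlo significance of the observed inactivation fraction.

    Each run replaces every TF's regulon by a uniformly random gene set of
    identical size and sign composition (excluding the TF's own gene),
    recomputes per-cell activity and the fraction of TFs significantly
    inactivated in the case group (Bonferroni p < alpha, AUC < 0.5).  The
    empirical p-value uses the (1 + k)/(1 + n) estimator so it can never be
    exactly zero.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("need exactly 2 groups")
    case = labels == uniq[1]

    z = zscore_rows(sc).matrix
    n_genes = z.n_genes
    gene_upper = np.array([str(g).upper() for g in z.gene_ids])
    gene_pos = {g: i for i, g in enumerate(gene_upper)}

    profiles = []
    sign_multisets = []
    own_gene = []
    for tf in net.tf_ids:
        prof = make_target_profile(net, tf, z.gene_ids)
        profiles.append(prof.values)
        nz = prof.values[prof.values != 0]
        sign_multisets.append(nz.copy())
        own_gene.append(gene_pos.get(str(tf).upper(), -1))
        if nz.size >= n_genes:
            raise ValueError(
                f"gene universe ({n_genes}) smaller than regulon of {tf!r}")
    P_obs = np.asarray(profiles, dtype=float).T

    observed = _significant_dn_fraction(
        _tfa_from_zscored(z.values, P_obs), case, alpha)

    null = np.empty(n_runs)
    for run in range(n_runs):
        P = np.zeros((n_genes, len(profiles)))
        for j, signs in enumerate(sign_multisets):
            pool = n_genes
            idx = rng.choice(pool, size=signs.size, replace=False)
            if own_gene[j] >= 0:
                while own_gene[j] in idx:
                    idx = rng.choice(pool, size=signs.size, replace=False)
            P[idx, j] = signs
        null[run] = _significant_dn_fraction(
            _tfa_from_zscored(z.values, P), case, alpha)

    emp_p = (1.0 + (null >= observed).sum()) / (1.0 + n_runs)
    return MonteCarloNull(observed, null, n_runs, alpha, float(emp_p))


# ---------------------------------------------------------------------------
# Benchmark metrics
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    """Sensitivity and false-discovery rate against a gold standard.

    SE = fraction of gold TFs significant in the expected direction; FDR =
    fraction of significant gold-TF calls in the contrary direction (None
    when nothing is significant, since the ratio is then undefined).
    """

    se: float
    fdr: float | None
    n_true_positive: int
    n_false_positive: int
    n_gold: int
    se_ci: tuple
    fdr_ci: tuple | None


def _wilson_ci(k: int, n: int) -> tuple:
    if n == 0:
        return (np.nan, np.nan)
    lo, hi = sps.binomtest(k, n).proportion_ci(0.95, method="wilson")
    return (float(lo), float(hi))


def sensitivity_fdr(table: pd.DataFrame, gold_direction: dict,
                    alpha: float = 0.05) -> BenchmarkResult:
    """Score a differential-activity table against gold-standard expected
    directions ({tf: 'UP' | 'DN'})."""
    if not gold_direction:
        raise ValueError("empty gold standard")
    tp = fp = n_sig = 0
    for tf, expect in gold_direction.items():
        if tf not in table.index:
            continue
        row = table.loc[tf]
        sig = row["p_bonf"] < alpha and row["direction"] != "NC"
        if not sig:
            continue
        n_sig += 1
        if row["direction"] == expect:
            tp += 1
        else:
            fp += 1
    n_gold = len(gold_direction)
    se = tp / n_gold
    fdr = None if n_sig == 0 else fp / n_sig
    return BenchmarkResult(se, fdr, tp, fp, n_gold,
                           _wilson_ci(tp, n_gold),
                           None if n_sig == 0 else _wilson_ci(fp, n_sig))


def method_comparison_meta(outcomes_a: dict, outcomes_b: dict
                           ) -> tuple[dict, float]:
    """Paired comparison of two methods' per-TF success indicators.

    ``outcomes_a``/``outcomes_b`` map tissue -> boolean array (aligned
    per TF).  Per tissue, an exact one-tailed binomial test on the
    discordant pairs (a-succeeds-b-fails vs b-succeeds-a-fails, p = 1/2)
    asks whether method a outperforms method b; tissue p-values are
    combined with Fisher's statistic -2*sum(log p) ~ chi2(2k).
    """
    if set(outcomes_a) != set(outcomes_b):
        raise ValueError("tissue sets differ between methods")
    per_tissue = {}
    for tissue in outcomes_a:
        a = np.asarray(outcomes_a[tissue], dtype=bool)
        b = np.asarray(outcomes_b[tissue], dtype=bool)
        if a.size != b.size:
            raise ValueError(f"unaligned outcomes for {tissue!r}")
        n10 = int((a & ~b).sum())
        n01 = int((~a & b).sum())
        if n10 + n01 == 0:
            per_tissue[tissue] = 1.0
        else:
            per_tissue[tissue] = float(
                sps.binomtest(n10, n10 + n01, 0.5,
                              alternative="greater").pvalue)
    ps = np.array(list(per_tissue.values()))
    chi2 = -2.0 * np.log(ps).sum()
    combined = float(sps.chi2.sf(chi2, 2 * ps.size))
    return per_tissue, combined


def inactivation_frequency(per_patient_tables: list[pd.DataFrame]
                           ) -> pd.Series:
    """Fraction of patients in which each TF is called DN; patients whose
    table lacks the TF are excluded from its denominator.  TFs absent from
    every table are NaN."""
    if not per_patient_tables:
        raise ValueError("need at least one table")
    all_tfs: list = []
    for t in per_patient_tables:
        for tf in t.index:
            if tf not in all_tfs:
                all_tfs.append(tf)
    out = {}
    for tf in all_tfs:
        dn = tot = 0
        for t in per_patient_tables:
            if tf in t.index:
                tot += 1
                dn += int(t.loc[tf, "direction"] == "DN")
        out[tf] = dn / tot if tot else np.nan
    return pd.Series(out, dtype=float)
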