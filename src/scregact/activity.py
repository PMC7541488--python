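"""Per-cell TF regulatory-activity estimation.

The central estimator regresses a cell's z-scored expression profile (over
all genes) on the TF's signed target profile (+1 activating regulon member,
-1 inhibitory, 0 otherwise) and reports the slope t-statistic as the TF's
activity in that cell.  Because the score pools evidence over the whole
regulon, it remains informative even when the TF's own transcript drops out
in every cell — the failure mode that defeats expression-based activity
calls in sparse scRNA-Seq data.

A threshold-free rank-based alternative is also provided: the Wilcoxon AUC
comparing the expression ranks of regulon genes against all other genes
within a cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_preprocess import ExpressionMatrix, NormState, zscore_rows
from .netinfer import RegulatoryNetwork

#: cap applied when the regression is an exact fit (|r| = 1)
T_SENTINEL = 1e6


@dataclass
class TargetProfile:
    """Signed regulon of one TF aligned to a gene universe."""

    tf_id: object
    values: np.ndarray            # int8 over the gene universe, in {-1,0,1}
    gene_universe: np.ndarray
    n_matched: int
    unmatched: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)


@dataclass
class TFActivityMatrix:
    """TFs x cells matrix of activity scores."""

    values: np.ndarray
    tf_ids: np.ndarray
    cell_ids: np.ndarray
    method: str = "regression_t"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.tf_ids = np.asarray(self.tf_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (self.tf_ids.size, self.cell_ids.size):
            raise ValueError("activity matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite activity scores")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.tf_ids,
                            columns=self.cell_ids)


def make_target_profile(net: RegulatoryNetwork, tf,
                        gene_universe) -> TargetProfile:
    """Align a TF's signed regulon to a gene universe.

    Matching is exact string match after case normalization; regulon genes
    absent from the universe are reported, and the TF's own gene is always
    0 in the profile.  Fewer than 3 matched regulon genes is an error (the
    regression would be meaningless).
    """
    if tf not in set(net.tf_ids):
        raise KeyError(f"TF {tf!r} not in network")
    universe = np.asarray(list(gene_universe), dtype=object)
    pos = {str(g).upper(): i for i, g in enumerate(universe)}
    regulon = net.regulon(tf)
    values = np.zeros(universe.size, dtype=np.int8)
    unmatched = []
    for gene, sign in regulon.items():
        key = str(gene).upper()
        if key == str(tf).upper():
            continue
        if key in pos:
            values[pos[key]] = sign
        else:
            unmatched.append(gene)
    tf_key = str(tf).upper()
    if tf_key in pos:
        values[pos[tf_key]] = 0
    n_matched = int(np.count_nonzero(values))
    if n_matched < 3:
        raise ValueError(
            f"TF {tf!r}: only {n_matched} regulon genes matched the data "
            f"(need >= 3)")
    return TargetProfile(tf, values, universe, n_matched, unmatched)


def _t_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Slope t-statistic of a simple regression from the correlation r."""
    r = np.asarray(r, dtype=float)
    out = np.empty_like(r)
    exact = np.abs(r) >= 1.0 - 1e-12
    safe = ~exact
    out[safe] = r[safe] * np.sqrt((n - 2) / (1.0 - r[safe] ** 2))
    if exact.any():
        warnings.warn("perfect fit in activity regression; capping t",
                      stacklevel=2)
        out[exact] = np.sign(r[exact]) * T_SENTINEL
    return out


def estimate_tfa(cell_profile: np.ndarray, profile: TargetProfile) -> float:
    """Activity of one TF in one cell.

    Simple linear regression (with intercept) of the cell's z-scored
    expression vector on the signed target profile, over all genes; returns
    the slope t-statistic, which equals r*sqrt((n-2)/(1-r^2)) with r the
    Pearson correlation of the two vectors.
    """
    y = np.asarray(cell_profile, dtype=float)
    x = profile.values.astype(float)
    if y.size != x.size:
        raise ValueError("cell profile and target profile lengths differ")
    if y.size < 10:
        raise ValueError("gene universe too small (< 10 genes)")
    if np.ptp(x) == 0:
        raise ValueError("target profile is constant")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return 0.0
    r = float((xc * yc).sum() / denom)
    return float(_t_from_r(np.array([r]), y.size)[0])


def estimate_tfa_matrix(sc: ExpressionMatrix,
                        net: RegulatoryNetwork) -> TFActivityMatrix:
    """Activity of every network TF in every cell.

    Rows are z-scored first (constant genes dropped); the per-(TF, cell)
    regression t-statistics are computed in one vectorized pass.  TFs with
    fewer than 3 matched regulon genes are dropped with a warning.
    """
    if sc.norm_state is NormState.RAW_COUNTS:
        raise ValueError("expected log-normalized input")
    z = zscore_rows(sc).matrix
    profiles = []
    kept_tfs = []
    for tf in net.tf_ids:
        try:
            profiles.append(make_target_profile(net, tf, z.gene_ids).values)
            kept_tfs.append(tf)
        except ValueError as exc:
            warnings.warn(str(exc), stacklevel=2)
    if not kept_tfs:
        raise ValueError("no TF has >= 3 regulon genes in the data")
    P = np.asarray(profiles, dtype=float).T          # genes x TFs
    values = _tfa_from_zscored(z.values, P)
    return TFActivityMatrix(values, np.asarray(kept_tfs, dtype=object),
                            z.column_ids, method="regression_t")


def _tfa_from_zscored(z_values: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Vectorized regression t-statistics.

    ``z_values``: genes x cells (rows z-scored); ``P``: genes x TFs signed
    profiles.  Returns TFs x cells.
    """
    n = z_values.shape[0]
    Pc = P - P.mean(axis=0, keepdims=True)
    Yc = z_values - z_values.mean(axis=0, keepdims=True)
    pn = np.sqrt((Pc ** 2).sum(axis=0))              # TFs
    yn = np.sqrt((Yc ** 2).sum(axis=0))              # cells
    if (pn == 0).any():
        raise ValueError("constant target profile")
    yn[yn == 0] = np.inf                             # all-zero cell -> r = 0
    r = (Pc.T @ Yc) / (pn[:, None] * yn[None, :])
    return _t_from_r(r, n)


# ---------------------------------------------------------------------------
# Rank-based AUC score
# ---------------------------------------------------------------------------

def auc_activity_score(expression: np.ndarray, regulon_mask) -> float:
    """Wilcoxon AUC of a regulon's expression ranks within one cell.

    Genes are ranked by expression (midranks at ties); the score is the
    probability that a random regulon gene outranks a random non-regulon
    gene: 1 when the regulon occupies the top ranks, 0 at the bottom, 0.5
    for an uninformative (all-tied) profile.
    """
    x = np.asarray(expression, dtype=float)
    mask = np.asarray(regulon_mask)
    if mask.dtype != bool:
        idx = np.zeros(x.size, dtype=bool)
        idx[np.asarray(mask, dtype=int)] = True
        mask = idx
    n1 = int(mask.sum())
    n2 = x.size - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("regulon must be a non-empty strict subset of genes")
    if np.ptp(x) == 0:
        warnings.warn("all expression values identical; AUC = 0.5",
                      stacklevel=2)
        return 0.5
    ranks = sps.rankdata(x)
    u = ranks[mask].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def auc_activity_matrix(sc: ExpressionMatrix,
                        net: RegulatoryNetwork) -> TFActivityMatrix:
    """AUC activity of every TF (positively-signed regulon members) in every
    cell."""
    ranks = sps.rankdata(sc.values, axis=0)
    n = sc.n_genes
    universe = set(str(g).upper() for g in sc.gene_ids)
    pos = {str(g).upper(): i for i, g in enumerate(sc.gene_ids)}
    out = []
    kept = []
    for tf in net.tf_ids:
        reg = net.regulon(tf)
        members = [pos[str(g).upper()] for g, s in reg.items()
                   if s > 0 and str(g).upper() in universe]
        if len(members) < 3 or len(members) >= n:
            warnings.warn(f"TF {tf!r}: unusable positive regulon for AUC",
                          stacklevel=2)
            continue
        m = np.zeros(n, dtype=bool)
        m[members] = True
        n1 = len(members)
        n2 = n - n1
        u = ranks[m].sum(axis=0) - n1 * (n1 + 1) / 2.0
        out.append(u / (n1 * n2))
        kept.append(tf)
    if not kept:
        raise ValueError("no TF has a usable positive regulon")
    return TFActivityMatrix(np.asarray(out), np.asarray(kept, dtype=object),
                            sc.column_ids, method="auc")
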