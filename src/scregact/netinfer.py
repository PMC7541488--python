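"""Tissue-specific regulatory-network inference from multi-tissue bulk data.

The pipeline identifies, for a tissue of interest, transcription factors
(TFs) with significantly elevated expression and a signed regulon of target
genes per TF.  It proceeds in three stages:

1. *Marginal screen* — Pearson correlation of every TF against every
   non-TF gene; edges kept at a stringent p-value threshold and capped to
   the strongest fraction of all pairs.
2. *Greedy partial correlation* — for each target gene separately, the
   partial correlation with each of its candidate regulators is computed
   from the inverse covariance of the (target, regulators) block,

       rho_gf = -Omega_gf / sqrt(Omega_gg * Omega_ff),

   which removes indirect dependencies while keeping the covariance block
   small enough (regulators << samples) that inversion is always well
   conditioned.
3. *Tissue-specificity selection* — an empirical-Bayes moderated t-test
   comparing the tissue of interest against all other tissues (and,
   optionally, against designated confounding tissues such as blood/spleen
   to guard against immune-cell infiltration) restricts the network to
   tissue-specific TFs.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .io_preprocess import ExpressionMatrix, NormState

DEFAULT_PARAMS = dict(sdth=0.25, sigth=1e-6, pcorth=0.2, spTH=0.01,
                      minNtgts=10, degth=(0.05, 0.05),
                      lfcth=(math.log2(1.5), 0.0))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CandidateEdgeSet:
    """Output of the marginal Pearson screen.

    ``r``/``p`` are dense (targets x TFs) matrices; ``mask`` flags the
    retained candidate edges.  Self-edges cannot occur because targets are
    by construction genes not annotated as TFs.
    """

    tf_ids: np.ndarray
    target_ids: np.ndarray
    r: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    sigth: float
    spTH: float
    minNtgts: int

    @property
    def n_edges_per_tf(self) -> np.ndarray:
        return self.mask.sum(axis=0)


@dataclass
class RegulatoryNetwork:
    """Signed regulons: adjacency (targets x TFs) in {-1, 0, +1} plus the
    retained partial correlations as companion weights."""

    adjacency: np.ndarray
    weights: np.ndarray
    tf_ids: np.ndarray
    target_ids: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tf_ids = np.asarray(self.tf_ids, dtype=object)
        self.target_ids = np.asarray(self.target_ids, dtype=object)
        self.adjacency = np.asarray(self.adjacency)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.adjacency.shape != (self.target_ids.size, self.tf_ids.size):
            raise ValueError("adjacency shape mismatch")
        if self.weights.shape != self.adjacency.shape:
            raise ValueError("weights shape mismatch")

    @property
    def n_tfs(self) -> int:
        return self.tf_ids.size

    def regulon(self, tf) -> pd.Series:
        """Signed regulon of one TF as a Series (gene -> +/-1)."""
        j = int(np.flatnonzero(self.tf_ids == tf)[0])
        nz = self.adjacency[:, j] != 0
        return pd.Series(self.adjacency[nz, j], index=self.target_ids[nz])

    def subset_tfs(self, keep: np.ndarray) -> "RegulatoryNetwork":
        adj = self.adjacency[:, keep]
        w = self.weights[:, keep]
        row_keep = (adj != 0).any(axis=1)
        return RegulatoryNetwork(adj[row_keep], w[row_keep],
                                 self.tf_ids[keep],
                                 self.target_ids[row_keep],
                                 params=dict(self.params))

    # -- persistence -------------------------------------------------------
    def save(self, prefix: str) -> None:
        """Write ``<prefix>.tsv`` (signs), ``<prefix>.weights.tsv`` and
        ``<prefix>.params.json``."""
        adj = pd.DataFrame(self.adjacency, index=self.target_ids,
                           columns=self.tf_ids)
        adj.to_csv(prefix + ".tsv", sep="\t")
        pd.DataFrame(self.weights, index=self.target_ids,
                     columns=self.tf_ids).to_csv(
            prefix + ".weights.tsv", sep="\t")
        with open(prefix + ".params.json", "w") as fh:
            json.dump(self.params, fh, indent=2, default=str)

    @classmethod
    def load(cls, prefix: str) -> "RegulatoryNetwork":
        adj = pd.read_csv(prefix + ".tsv", sep="\t", index_col=0)
        wpath = prefix + ".weights.tsv"
        w = (pd.read_csv(wpath, sep="\t", index_col=0).to_numpy()
             if os.path.exists(wpath) else adj.to_numpy(dtype=float))
        params = {}
        ppath = prefix + ".params.json"
        if os.path.exists(ppath):
            with open(ppath) as fh:
                params = json.load(fh)
        return cls(adj.to_numpy(dtype=np.int8), w,
                   adj.columns.to_numpy(dtype=object),
                   adj.index.to_numpy(dtype=object), params=params)


# ---------------------------------------------------------------------------
# Stage 1: marginal screen
# ---------------------------------------------------------------------------

def _rowwise_standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = np.nan
    return (x - mu) / sd


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via t = r*sqrt((n-2)/(1-r^2)), df = n-2."""
    rr = np.clip(np.abs(r), 0.0, 1.0 - 1e-15)
    t = rr * np.sqrt((n - 2) / (1.0 - rr ** 2))
    return 2.0 * sps.t.sf(t, n - 2)


def marginal_screen(bulk: ExpressionMatrix, tf_ids,
                    sigth: float = 1e-6, spTH: float = 0.01,
                    minNtgts: int = 10) -> CandidateEdgeSet:
    """Pearson screen of every TF against every non-TF target gene.

    Edges are kept when two conditions hold: the correlation p-value is at
    most ``sigth`` and the pair ranks within the top ``spTH`` fraction of
    all TF-target pairs by |r| (the cap that controls how many marginal
    interactions feed the partial-correlation stage).  TFs retaining fewer
    than ``minNtgts`` edges are removed.
    """
    n = bulk.n_columns
    if n < 4:
        raise ValueError("need at least 4 samples for the marginal screen")
    tf_ids = np.asarray(list(tf_ids), dtype=object)
    if tf_ids.size == 0:
        raise ValueError("empty TF list")
    tf_set = set(tf_ids)
    is_tf = np.array([g in tf_set for g in bulk.gene_ids])
    present = [t for t in tf_ids if t in set(bulk.gene_ids)]
    if not present:
        raise ValueError("no TF ids present in the expression matrix")
    tf_ids = np.asarray(present, dtype=object)
    gene_pos = {g: i for i, g in enumerate(bulk.gene_ids)}
    tf_rows = np.array([gene_pos[t] for t in tf_ids])
    tgt_rows = np.flatnonzero(~is_tf)
    if tgt_rows.size == 0:
        raise ValueError("no target genes (every gene is a TF)")

    X = _rowwise_standardize(bulk.values[tf_rows])       # TFs x n
    Y = _rowwise_standardize(bulk.values[tgt_rows])      # targets x n
    r = (Y @ X.T) / (n - 1)                              # targets x TFs
    r = np.nan_to_num(r, nan=0.0)
    p = correlation_pvalues(r, n)

    mask = p <= sigth
    total_pairs = r.size
    k = int(np.floor(spTH * total_pairs))
    if k < total_pairs:
        if k == 0:
            mask[:] = False
        else:
            absr = np.abs(r).ravel()
            # threshold = k-th largest |r|; ties share the boundary value
            thr = np.partition(absr, total_pairs - k)[total_pairs - k]
            mask &= np.abs(r) >= thr

    keep_tf = mask.sum(axis=0) >= minNtgts
    if not keep_tf.any():
        raise ValueError("no TF retained >= minNtgts candidate targets")
    return CandidateEdgeSet(tf_ids[keep_tf],
                            bulk.gene_ids[tgt_rows],
                            r[:, keep_tf], p[:, keep_tf], mask[:, keep_tf],
                            sigth=sigth, spTH=spTH, minNtgts=minNtgts)


# ---------------------------------------------------------------------------
# Stage 2: greedy partial correlations
# ---------------------------------------------------------------------------

def partial_correlations_for_target(data: np.ndarray) -> np.ndarray:
    """Partial correlations of row 0 with rows 1..k given all other rows.

    ``data`` is a (1+k) x n matrix: the target gene first, its candidate
    regulators after.  Computed from the inverse covariance:
    rho_gf = -Omega_gf / sqrt(Omega_gg * Omega_ff).
    """
    cov = np.cov(data, ddof=1)
    cov = np.atleast_2d(cov)
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond):
        raise np.linalg.LinAlgError("singular covariance")
    if cond > 1e10:
        warnings.warn(f"ill-conditioned covariance (cond={cond:.3g})",
                      stacklevel=2)
    omega = np.linalg.inv(cov)
    d = np.sqrt(np.diag(omega))
    return -omega[0, 1:] / (d[0] * d[1:])


def greedy_partial_correlation(bulk: ExpressionMatrix,
                               cands: CandidateEdgeSet,
                               pcorth: float = 0.2,
                               minNtgts: int | None = None
                               ) -> RegulatoryNetwork:
    """For each target, keep regulators whose partial correlation (given the
    target's other candidate regulators) has magnitude >= ``pcorth``.

    Edge signs come from the sign of the retained partial correlation; TFs
    left with fewer than ``minNtgts`` targets are dropped.
    """
    if minNtgts is None:
        minNtgts = cands.minNtgts
    gene_pos = {g: i for i, g in enumerate(bulk.gene_ids)}
    tf_rows = np.array([gene_pos[t] for t in cands.tf_ids])
    weights = np.zeros_like(cands.r)
    for gi, g in enumerate(cands.target_ids):
        regs = np.flatnonzero(cands.mask[gi])
        if regs.size == 0:
            continue
        rows = np.concatenate(([gene_pos[g]], tf_rows[regs]))
        if rows.size - 1 >= bulk.n_columns:
            raise ValueError(
                f"target {g}: {rows.size - 1} regulators >= "
                f"{bulk.n_columns} samples")
        try:
            pc = partial_correlations_for_target(bulk.values[rows])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular covariance for target {g} with regulators "
                f"{list(cands.tf_ids[regs])}") from exc
        keep = np.abs(pc) >= pcorth
        weights[gi, regs[keep]] = pc[keep]

    adjacency = np.sign(weights).astype(np.int8)
    keep_tf = (adjacency != 0).sum(axis=0) >= minNtgts
    if not keep_tf.any():
        raise ValueError("no TF retained >= minNtgts targets after "
                         "partial-correlation thresholding")
    row_keep = (adjacency[:, keep_tf] != 0).any(axis=1)
    return RegulatoryNetwork(adjacency[np.ix_(row_keep, keep_tf)],
                             weights[np.ix_(row_keep, keep_tf)],
                             cands.tf_ids[keep_tf],
                             cands.target_ids[row_keep],
                             params=dict(pcorth=pcorth, minNtgts=minNtgts,
                                         sigth=cands.sigth, spTH=cands.spTH))


# ---------------------------------------------------------------------------
# Stage 3: moderated t-test and tissue-specific selection
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float
                            ) -> tuple[float, float]:
    """Moment-match a scaled-F prior for gene-wise variances.

    Under the hierarchical model s2_g ~ s0^2 * F(df, d0), the log variances
    have known mean/variance in terms of digamma/trigamma functions; solving
    the moment equations yields the prior degrees of freedom d0 and prior
    variance s0^2.  Returns (d0, s0sq); d0 = inf when the observed spread of
    log variances is no larger than expected from sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive gene-wise variances")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(
        polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0sq = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        # no excess spread beyond sampling noise: infinite prior df, and the
        # common variance is estimated by the plain mean
        d0 = math.inf
        s0sq = float(s2[ok].mean())
    return d0, s0sq


@dataclass
class ModeratedTestResult:
    """Per-gene two-group comparison with shrunken variances."""

    table: pd.DataFrame          # columns: lfc, t, p, p_adj
    d0: float
    s0sq: float

    def __getitem__(self, col):
        return self.table[col]


def moderated_t_test(bulk: ExpressionMatrix, group1, group2,
                     prior_df: float | None = None,
                     adjust: str = "fdr_bh") -> ModeratedTestResult:
    """Empirical-Bayes moderated t-test between two sample groups.

    Gene-wise pooled variances s2_g (df d_g = n1+n2-2) are shrunk toward a
    common prior s0^2 with weight d0:

        s2_tilde = (d0*s0^2 + d_g*s2_g) / (d0 + d_g)

    and the moderated t = dmean / (s_tilde*sqrt(1/n1+1/n2)) is referred to a
    t distribution with d0 + d_g degrees of freedom.  (d0, s0^2) are
    estimated from the variance distribution unless ``prior_df`` forces a
    value (0 recovers the ordinary t-test; inf uses a single shared
    variance).
    """
    g1 = np.asarray(group1)
    g2 = np.asarray(group2)
    if g1.dtype == bool:
        g1 = np.flatnonzero(g1)
    if g2.dtype == bool:
        g2 = np.flatnonzero(g2)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs >= 2 columns")
    if set(g1) & set(g2):
        raise ValueError("groups overlap")
    x1 = bulk.values[:, g1]
    x2 = bulk.values[:, g2]
    n1, n2 = g1.size, g2.size
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    if np.all(v1 == 0) or np.all(v2 == 0):
        raise ValueError("a group has zero variance in every gene")
    dg = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / dg
    if prior_df is None:
        d0, s0sq = estimate_variance_prior(s2, dg)
    else:
        d0 = float(prior_df)
        s0sq = float(np.exp(np.log(s2[s2 > 0]).mean())) if d0 > 0 else 0.0
        if math.isinf(d0):
            _, s0sq = estimate_variance_prior(s2, dg)
    if math.isinf(d0):
        s2_tilde = np.full_like(s2, s0sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    lfc = m1 - m2
    denom = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, lfc / denom, 0.0)
    if math.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p_adj = multipletests(p, method=adjust)[1]
    table = pd.DataFrame({"lfc": lfc, "t": t, "p": p, "p_adj": p_adj},
                         index=bulk.gene_ids)
    return ModeratedTestResult(table, d0, s0sq)


def select_tissue_specific_tfs(bulk: ExpressionMatrix,
                               net: RegulatoryNetwork,
                               toi: str,
                               cft=None,
                               degth: tuple = (0.05, 0.05),
                               lfcth: tuple = (math.log2(1.5), 0.0),
                               adjust: str = "fdr_bh") -> RegulatoryNetwork:
    """Restrict a network to TFs overexpressed in the tissue of interest.

    Comparison A: ``toi`` vs all other tissues, requiring adjusted p <
    degth[0] and log2 fold change > lfcth[0].  If confounding tissues
    ``cft`` are given (e.g. blood/spleen whose immune cells infiltrate solid
    tissue), comparison B additionally requires adjusted p < degth[1] and
    log2 fold change > lfcth[1] against those tissues only, so that TFs
    merely tracking infiltration levels are rejected.
    """
    if bulk.column_labels is None:
        raise ValueError("bulk matrix has no column labels")
    labels = bulk.column_labels
    toi_mask = labels == toi
    if not toi_mask.any():
        raise ValueError(f"tissue {toi!r} absent from labels")
    if toi_mask.sum() < 2:
        raise ValueError(f"fewer than 2 samples labelled {toi!r}")

    resA = moderated_t_test(bulk, np.flatnonzero(toi_mask),
                            np.flatnonzero(~toi_mask), adjust=adjust)
    tf_in = np.array([t in set(bulk.gene_ids) for t in net.tf_ids])
    passing = np.zeros(net.n_tfs, dtype=bool)
    tA = resA.table
    for j, tf in enumerate(net.tf_ids):
        if not tf_in[j]:
            continue
        row = tA.loc[tf]
        passing[j] = (row["p_adj"] < degth[0]) and (row["lfc"] > lfcth[0])

    if cft is not None:
        cft = [cft] if isinstance(cft, str) else list(cft)
        missing = [c for c in cft if c not in set(labels)]
        if missing:
            raise ValueError(f"confounding tissues absent: {missing}")
        cft_mask = np.isin(labels, cft)
        resB = moderated_t_test(bulk, np.flatnonzero(toi_mask),
                                np.flatnonzero(cft_mask), adjust=adjust)
        tB = resB.table
        for j, tf in enumerate(net.tf_ids):
            if not passing[j]:
                continue
            row = tB.loc[tf]
            passing[j] = (row["p_adj"] < degth[1]) and (row["lfc"] > lfcth[1])

    if not passing.any():
        raise ValueError(f"no tissue-specific TF for {toi!r}")
    out = net.subset_tfs(passing)
    out.params.update(toi=toi, cft=cft, degth=tuple(degth),
                      lfcth=tuple(lfcth))
    return out


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def infer_network(bulk: ExpressionMatrix, tf_ids, toi: str, cft=None,
                  sdth: float = 0.25, sigth: float = 1e-6,
                  pcorth: float = 0.2, spTH: float = 0.01,
                  minNtgts: int = 10, degth: tuple = (0.05, 0.05),
                  lfcth: tuple = (math.log2(1.5), 0.0)) -> RegulatoryNetwork:
    """Variance filter -> marginal screen -> partial correlations ->
    tissue-specificity selection, with a provenance record of all
    parameters."""
    from .io_preprocess import variance_filter
    filt = variance_filter(bulk, sdth)
    cands = marginal_screen(filt, tf_ids, sigth=sigth, spTH=spTH,
                            minNtgts=minNtgts)
    net = greedy_partial_correlation(filt, cands, pcorth=pcorth,
                                     minNtgts=minNtgts)
    net = select_tissue_specific_tfs(filt, net, toi, cft=cft,
                                     degth=degth, lfcth=lfcth)
    net.params.update(sdth=sdth, sigth=sigth, pcorth=pcorth, spTH=spTH,
                      minNtgts=minNtgts, degth=tuple(degth),
                      lfcth=tuple(lfcth), toi=toi, cft=cft)
    return net
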