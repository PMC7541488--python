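"""Synthetic bulk and single-cell data with known regulatory ground truth.

These generators emulate the study conditions the rest of the package is
validated against:

* multi-tissue bulk expression on the log2 scale (Gaussian, sigma = 1) with
  planted tissue-specific TFs whose bulk effect is diluted by a minor cell
  fraction ``w`` — the mean shift in the tissue of interest is
  log2(FC*w + (1-w)) — and regulon targets generated as
  sign * beta * TF + noise so that the partial-correlation structure is
  recoverable;
* scRNA-Seq with per-cell TF activity states driving regulon genes, an
  expression-dependent logistic dropout model (low-expression transcripts
  are zeroed more often), and the option of forcing the TF's own transcript
  to 100% dropout — the regime that motivates regulon-based activity
  scoring;
* differentiation time courses in which a subset of TFs ramps up linearly
  with stage.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_preprocess import ExpressionMatrix, NormState
from .netinfer import RegulatoryNetwork


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated dataset."""

    tf_ids: list
    tf_tissue: dict                  # tf -> tissue label or None (null TF)
    regulons: dict                   # tf -> pd.Series(sign, index=targets)
    fc: float = 1.0
    w: float = 1.0
    beta: float = 1.0
    seed: int | None = None
    activity_states: np.ndarray | None = None
    dropout: tuple | None = None
    extras: dict = field(default_factory=dict)

    def network(self) -> RegulatoryNetwork:
        """The planted regulons as a RegulatoryNetwork (weights = sign)."""
        targets: list = []
        for reg in self.regulons.values():
            targets.extend(g for g in reg.index if g not in targets)
        adj = np.zeros((len(targets), len(self.tf_ids)), dtype=np.int8)
        tpos = {g: i for i, g in enumerate(targets)}
        for j, tf in enumerate(self.tf_ids):
            for g, s in self.regulons[tf].items():
                adj[tpos[g], j] = s
        return RegulatoryNetwork(adj, adj.astype(float),
                                 np.asarray(self.tf_ids, dtype=object),
                                 np.asarray(targets, dtype=object),
                                 params={"synthetic": True})

    def edge_set(self) -> set:
        return {(tf, g) for tf, reg in self.regulons.items()
                for g in reg.index}


def random_network(n_tfs: int = 10, targets_per_tf: int = 20,
                   p_inhib: float = 0.3, seed=None) -> RegulatoryNetwork:
    """A disjoint-regulon network with random activating/inhibitory signs,
    for tests that need a regulon structure without a bulk-inference step."""
    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{j + 1:02d}" for j in range(n_tfs)]
    regulons = {}
    k = 0
    for tf in tf_ids:
        genes = [f"G{k + i + 1:04d}" for i in range(targets_per_tf)]
        k += targets_per_tf
        signs = np.where(rng.random(targets_per_tf) < p_inhib, -1, 1)
        regulons[tf] = pd.Series(signs, index=genes)
    truth = SyntheticTruth(tf_ids, {t: None for t in tf_ids}, regulons,
                           seed=seed)
    return truth.network()


# ---------------------------------------------------------------------------
# Bulk multi-tissue generator
# ---------------------------------------------------------------------------

def simulate_bulk_multitissue(n_tissues: int = 5, n_per_tissue: int = 60,
                              n_genes: int = 1500,
                              n_specific_tfs: int = 8,
                              n_null_tfs: int = 8,
                              targets_per_tf: int = 20,
                              fc: float = 4.0, w: float = 1.0,
                              beta: float = 1.0, noise_sd: float = 1.0,
                              p_inhib: float = 0.3,
                              toi: str = "Tissue1",
                              seed=None
                              ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Multi-tissue bulk expression with planted tissue-specific TFs.

    Baseline expression is Gaussian on the log2 scale (SD 1 per gene).
    The first ``n_specific_tfs`` TFs receive a mean shift of
    log2(fc*w + (1-w)) in the tissue of interest; the remaining
    ``n_null_tfs`` have regulons but no tissue effect.  Each regulon target
    is sign * beta * (TF deviation) + independent noise, so both the
    marginal screen and the partial-correlation pruning see the planted
    structure.  At fc = 1 the planted TFs are indistinguishable from
    background.
    """
    rng = np.random.default_rng(seed)
    n_tfs = n_specific_tfs + n_null_tfs
    n_targets = n_tfs * targets_per_tf
    if n_tfs + n_targets > n_genes:
        raise ValueError("more planted genes than n_genes")
    n_bg = n_genes - n_tfs - n_targets
    n_samples = n_tissues * n_per_tissue

    tissues = np.repeat([f"Tissue{i + 1}" for i in range(n_tissues)],
                        n_per_tissue).astype(object)
    if toi not in set(tissues):
        raise ValueError(f"toi {toi!r} not among simulated tissues")

    tf_ids = [f"TF{j + 1:02d}" for j in range(n_tfs)]
    tgt_ids = [f"G{i + 1:04d}" for i in range(n_targets)]
    bg_ids = [f"BG{i + 1:04d}" for i in range(n_bg)]
    gene_ids = np.asarray(tf_ids + tgt_ids + bg_ids, dtype=object)

    base = rng.normal(6.0, 1.0, n_genes)
    shift = float(np.log2(fc * w + (1.0 - w)))
    in_toi = tissues == toi

    values = np.empty((n_genes, n_samples))
    tf_tissue = {}
    regulons = {}
    # TFs
    for j, tf in enumerate(tf_ids):
        mu = base[j]
        x = mu + rng.normal(0.0, 1.0, n_samples)
        if j < n_specific_tfs:
            x = x + shift * in_toi
            tf_tissue[tf] = toi
        else:
            tf_tissue[tf] = None
        values[j] = x
    # regulon targets
    k = n_tfs
    for j, tf in enumerate(tf_ids):
        genes = tgt_ids[j * targets_per_tf:(j + 1) * targets_per_tf]
        signs = np.where(rng.random(targets_per_tf) < p_inhib, -1, 1)
        regulons[tf] = pd.Series(signs, index=genes)
        tf_dev = values[j] - base[j]
        for s in signs:
            values[k] = (base[k] + s * beta * tf_dev
                         + rng.normal(0.0, noise_sd, n_samples))
            k += 1
    # background
    values[k:] = base[k:, None] + rng.normal(0.0, 1.0, (n_bg, n_samples))

    col_ids = np.asarray([f"S{i + 1:04d}" for i in range(n_samples)],
                         dtype=object)
    x = ExpressionMatrix(values, gene_ids, col_ids, column_labels=tissues,
                         norm_state=NormState.LOG2_NORMALIZED)
    truth = SyntheticTruth(tf_ids, tf_tissue, regulons, fc=fc, w=w,
                           beta=beta, seed=seed,
                           extras={"toi": toi, "shift": shift})
    return x, truth


# ---------------------------------------------------------------------------
# Single-cell generators
# ---------------------------------------------------------------------------

def logistic_dropout_probability(x: np.ndarray, k: float = 1.5,
                                 x0: float = 1.0) -> np.ndarray:
    """Probability of a technical zero as a decreasing logistic function of
    underlying log2 expression: p = 1 / (1 + exp(k * (x - x0)))."""
    return 1.0 / (1.0 + np.exp(k * (np.asarray(x, dtype=float) - x0)))


def simulate_scrnaseq(net: RegulatoryNetwork,
                      activity_states: np.ndarray,
                      n_background: int = 400,
                      beta: float = 1.5, noise_sd: float = 0.5,
                      base_mean: float = 2.0,
                      tf_effect: float = 1.5,
                      dropout: tuple | None = (1.5, 1.0),
                      force_tf_dropout: bool = False,
                      seed=None
                      ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """scRNA-Seq expression driven by per-cell TF activity states.

    ``activity_states`` is (n_TFs x n_cells), aligned with ``net.tf_ids``.
    Regulon-gene expression is base + sum_f sign_gf * beta * state_fc +
    Gaussian noise on the log2 scale, floored at zero; the TF's own
    transcript tracks its state (so expression-based calls are possible in
    principle) unless ``force_tf_dropout`` zeroes it in every cell.
    ``dropout`` = (k, x0) parameterizes the logistic zero-injection model;
    None disables it.
    """
    rng = np.random.default_rng(seed)
    states = np.atleast_2d(np.asarray(activity_states, dtype=float))
    if states.shape[0] != net.n_tfs:
        raise ValueError("activity_states rows must match net TFs")
    n_cells = states.shape[1]
    tgt_ids = list(net.target_ids)
    tf_ids = list(net.tf_ids)
    bg_ids = [f"BG{i + 1:04d}" for i in range(n_background)]
    gene_ids = np.asarray(tgt_ids + tf_ids + bg_ids, dtype=object)
    n_genes = gene_ids.size

    signal = net.adjacency.astype(float) @ (beta * states)   # targets x cells
    values = np.empty((n_genes, n_cells))
    nt = len(tgt_ids)
    values[:nt] = (base_mean + signal
                   + rng.normal(0.0, noise_sd, (nt, n_cells)))
    values[nt:nt + len(tf_ids)] = (
        base_mean + tf_effect * states
        + rng.normal(0.0, noise_sd, (len(tf_ids), n_cells)))
    values[nt + len(tf_ids):] = base_mean + rng.normal(
        0.0, noise_sd, (n_background, n_cells))
    values = np.maximum(values, 0.0)

    if dropout is not None:
        k, x0 = dropout
        p = logistic_dropout_probability(values, k, x0)
        values = np.where(rng.random(values.shape) < p, 0.0, values)
    if force_tf_dropout:
        values[nt:nt + len(tf_ids)] = 0.0

    cell_ids = np.asarray([f"C{i + 1:04d}" for i in range(n_cells)],
                          dtype=object)
    x = ExpressionMatrix(values, gene_ids, cell_ids,
                         norm_state=NormState.LOG2_NORMALIZED)
    regulons = {tf: net.regulon(tf) for tf in net.tf_ids}
    truth = SyntheticTruth(tf_ids, {t: None for t in tf_ids}, regulons,
                           beta=beta, seed=seed, activity_states=states,
                           dropout=dropout,
                           extras={"force_tf_dropout": force_tf_dropout})
    return x, truth


def simulate_timecourse(net: RegulatoryNetwork, ramp_tfs,
                        n_stages: int = 5, cells_per_stage: int = 50,
                        dropout: tuple | None = (1.5, 1.0),
                        seed=None, **kwargs
                        ) -> tuple[ExpressionMatrix, np.ndarray,
                                   SyntheticTruth]:
    """Differentiation time course: ``ramp_tfs`` increase their activity
    linearly from 0 to 1 across stages, all other TFs stay flat at 0.5.

    Returns (expression, stage labels, truth); with an empty ramp set the
    data are null for the ordinal differential-activity test.
    """
    ramp_tfs = list(ramp_tfs)
    unknown = [t for t in ramp_tfs if t not in set(net.tf_ids)]
    if unknown:
        raise ValueError(f"ramp TFs not in network: {unknown}")
    n_cells = n_stages * cells_per_stage
    stages = np.repeat(np.arange(n_stages), cells_per_stage)
    states = np.full((net.n_tfs, n_cells), 0.5)
    ramp = stages / max(n_stages - 1, 1)
    for j, tf in enumerate(net.tf_ids):
        if tf in ramp_tfs:
            states[j] = ramp
    x, truth = simulate_scrnaseq(net, states, dropout=dropout, seed=seed,
                                 **kwargs)
    truth.extras.update(ramp_tfs=ramp_tfs, n_stages=n_stages,
                        cells_per_stage=cells_per_stage)
    return x, stages, truth
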