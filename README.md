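# scregact

Tissue-specific transcription-factor (TF) regulon inference from bulk
expression, and single-cell regulatory-activity estimation.

## The problem

Tissue-specific TFs are frequently silenced in cancer and in normal cells
exposed to risk factors, but detecting this at single-cell resolution is
hard: scRNA-Seq dropout means a TF's own transcript is often observed in
no cell at all, so differential expression of the TF is powerless.
`scregact` addresses this in two steps:

1. **Regulon inference from bulk data.**  From a large multi-tissue bulk
   compendium (genes × samples with tissue labels), each candidate TF's
   signed regulon is learned by a marginal Pearson screen (p ≤ 10⁻⁶,
   capped to the strongest 1% of pairs) followed by greedy partial
   correlations computed per target gene from the inverse covariance,

       ρ̃_gf = −Ω_gf / √(Ω_gg Ω_ff),   |ρ̃| ≥ 0.2 retained,

   and the network is restricted to TFs overexpressed in the tissue of
   interest (empirical-Bayes moderated t-test, adjusted p < 0.05 and
   log₂FC > log₂1.5, with an optional second comparison against
   confounding tissues such as blood/spleen to exclude immune-infiltration
   artifacts).
2. **Per-cell activity.**  Each cell's z-scored expression profile is
   regressed on the TF's signed target profile (+1 activating / −1
   inhibitory / 0 non-member); the TF's activity in that cell is the slope
   t-statistic.  Because the score pools the whole regulon, it survives
   100% dropout of the TF transcript itself.

Around this core the package provides the analytic power model for
detecting TFs expressed in a minor cell fraction *w* (non-central t with
effect e = log₂(FC·w + 1 − w)/σ and non-centrality μ = √(n₁n₂/(n₁+n₂))·e),
Wilcoxon/Spearman differential-activity tables with Bonferroni control and
signed-z conversion, exact binomial skew tests, Monte-Carlo regulon
randomization nulls, sensitivity/FDR benchmarking, a rank-based AUC
activity score, and seeded synthetic-data generators with ground truth.

## Worked example

```python
import scregact as sa

# bulk compendium with 8 planted tissue-specific TFs (+8 null TFs)
bulk, truth = sa.simulate_bulk_multitissue(
    n_tissues=5, n_per_tissue=150, n_genes=1500, targets_per_tf=20, seed=11)
net = sa.infer_network(bulk, truth.tf_ids, toi="Tissue1", spTH=0.05)
print(net.n_tfs, int((net.adjacency != 0).sum()))
```

prints `8 160`: the 8 planted tissue-specific TFs and all 8×20 planted
regulon edges, with no false TFs and no false edges (edge precision and
recall 1.0 on this fixture).  Continuing with activity scoring under total
TF dropout (`examples/02_activity_under_dropout.py`):

```text
matrix sparsity after dropout: 0.23
mean active-vs-inactive separation AUC of the activity score: 1.000
```

the regulon score separates planted-active from planted-inactive cells
perfectly even though the TF transcript is zero in every cell.  The power
example (`examples/03_power_analysis.py`) prints

```text
w=0.05: effect e=0.433, noncentrality mu=5.26, sensitivity=87.2%
w=0.20: effect e=1.263, noncentrality mu=15.33, sensitivity=100.0%
```

the probability of detecting a TF expressed at fold change 8 in 5% (20%)
of the cells of a 150-sample tissue within an 8555-sample compendium, at a
Bonferroni-corrected threshold over 1313 candidate TFs.

Each script in `examples/` is a short narrative of one capability:
network inference, activity under dropout, power analysis, and
differential activity with the Monte-Carlo regulon null.

A thin CLI mirrors the library (`scregact --help`): `normalize`, `qc`,
`infer-net`, `activity`, `diff`, `mc-null`, `power`, `simulate`,
`benchmark`; every run writes a provenance JSON with parameters and input
hashes.

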