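# Methods

## Overview

`scregact` estimates the regulatory activity of tissue-specific
transcription factors (TFs) in single cells.  Because scRNA-Seq suffers
high technical dropout, the expression of a TF's own transcript is an
unreliable readout of its activity — key TFs can show a 100% dropout rate
across an entire dataset.  The package instead (i) learns each TF's signed
*regulon* (downstream target genes, direct or indirect) from large
multi-tissue **bulk** expression data, where dropout is absent and power is
high, and (ii) scores each single cell by how strongly its expression
profile aligns with that regulon.

## Regulatory-network inference from bulk data

Input: a log2-scale bulk matrix (genes x samples) with a tissue label per
sample, and a list of genes annotated as TFs.  Genes not annotated as TFs
are candidate targets; TF-TF edges are not considered.

1. **Variance filter.** Genes with sample SD (denominator n-1) at or below
   `sdth` (default 0.25) are removed; they carry no usable variation.
2. **Marginal screen.** Pearson correlation of every TF against every
   target, with the two-sided p-value from the exact t transform
   `t = r*sqrt((n-2)/(1-r^2))`.  An edge is a candidate when
   p <= `sigth` (default 1e-6) *and* the pair ranks in the top `spTH`
   fraction (default 1%) of all TF-target pairs by |r| — the cap that
   bounds how many marginal edges feed the next stage.  The ranking key is
   |r|, which at fixed n orders pairs identically to p.  The cap is
   applied globally over all pairs, not per TF.  TFs keeping fewer than
   `minNtgts` (default 10) candidates are dropped.
3. **Greedy partial correlations.** For each target gene g with candidate
   regulators f_1..f_k, the (1+k)x(1+k) covariance block of
   (g, f_1..f_k) is inverted and

       rho_gf = -Omega_gf / sqrt(Omega_gg * Omega_ff)

   gives the partial correlation of g with each regulator given the
   others.  Working one target at a time keeps k far below the sample
   count, so the block is well conditioned (a condition number above 1e10
   raises a warning; a singular block is an error naming the target and
   its collinear regulators).  Edges with |rho| >= `pcorth` (default 0.2)
   are retained; the edge sign (activating +1 / inhibitory -1) is the sign
   of the retained partial correlation, which is the quantity the network
   stores.  Covariances are computed on centered but unstandardized
   log-scale data.
4. **Tissue-specificity selection.** An empirical-Bayes moderated t-test
   compares the tissue of interest (toi) against all other tissues;
   a TF passes with adjusted p < 0.05 and log2 fold change >
   log2(1.5) ~ 0.58.  When confounding tissues (`cft`, e.g. blood and
   spleen, whose immune cells infiltrate solid tissue) are named, a second
   comparison of toi against those tissues alone additionally requires
   adjusted p < 0.05 and log2 fold change strictly > 0 — this rejects TFs
   whose apparent tissue specificity merely tracks immune-cell content.
   The strictly-positive reading of the second fold-change threshold is a
   deliberate choice; a non-strict reading changes nothing in practice
   because a TF with exactly zero fold change never reaches significance.

### Moderated t-test

Gene-wise pooled variances s2_g (d_g = n1+n2-2 df) are shrunk toward a
prior (d0, s0^2) estimated by moment matching on log variances: under
s2_g ~ s0^2 * F(d_g, d0) the mean and variance of log s2_g are known in
terms of digamma/trigamma functions, and solving the two moment equations
(Newton inversion of the trigamma function) yields d0 and s0^2.  The
moderated statistic

    t_g = (mean1_g - mean2_g) / sqrt(s2_tilde_g * (1/n1 + 1/n2)),
    s2_tilde_g = (d0*s0^2 + d_g*s2_g) / (d0 + d_g)

is referred to a t distribution with d0 + d_g df (normal when d0 is
infinite, which the estimator returns when the spread of log variances
does not exceed pure sampling noise; the shared variance is then the plain
mean of s2_g).  d0 = 0 recovers the ordinary equal-variance t-test.  The
test suite verifies the estimator and the statistics against the
Bioconductor `limma` implementation.  Multiplicity adjustment is
Benjamini-Hochberg by default, Bonferroni on request.

## Per-cell activity estimation

The scRNA-Seq matrix is z-scored gene-wise (sample SD, constant genes
dropped and reported).  For each TF a signed target profile over the gene
universe holds +1 for activating regulon members, -1 for inhibitory
members and 0 elsewhere; the TF's own gene is always 0, gene matching is
exact after case folding, and fewer than 3 matched members makes the score
undefined (the TF is dropped with a warning).  The activity of TF f in
cell c is the slope t-statistic of the simple regression (with intercept)
of the cell's z-scored profile on the target profile, computed in closed
form as t = r*sqrt((n-2)/(1-r^2)) with r the Pearson correlation over the
n genes.  An exact fit (|r| = 1) is capped at +/-1e6 so downstream rank
statistics stay finite.  The regression runs over the full gene universe
(zeros included as non-members); including the intercept is harmless
because the z-scored response has near-zero mean, and the slope
t-statistic is invariant to it.  Cells are independent work units, so the
result is identical regardless of how the computation is parallelized or
batched.

A threshold-free rank alternative is provided: the Wilcoxon AUC comparing
the within-cell expression ranks of a regulon's positively-signed members
against all other genes (midranks at ties; an all-tied cell scores 0.5).

Z-scoring is performed across the whole dataset, not within phenotype
groups; with batch-confounded designs this couples the score to batch
structure and the user should split batches beforehand.

## Differential activity and the Monte-Carlo null

Binary phenotypes use a two-sided Wilcoxon rank-sum test per TF
(normal approximation with midranks, tie and continuity correction —
verified against `scipy.stats.mannwhitneyu`); ordinal phenotypes use
Spearman correlation with the t approximation, or the full permutation
null below 10 observations.  P-values are Bonferroni-corrected over the
TFs tested, and converted to signed z via the normal quantile
z = Phi^-1(1 - p/2), signed by AUC vs 0.5 or the sign of rho.  A skew
towards inactivation among significant calls is summarized by the exact
one-tailed binomial tail P(X >= n_down | n, 1/2).  Paired method
comparisons use the exact binomial on discordant pairs (McNemar-style)
with Fisher's chi-square combination across tissues.

The Monte-Carlo regulon null asks whether an observed fraction of
significantly inactivated TFs could arise with regulons that carry no
information: each of `n_runs` (default 1000) randomizations replaces every
TF's regulon by a uniformly random gene set of the same size and sign
composition (excluding the TF's own gene) and recomputes the fraction.
The empirical p-value is (1 + #{null >= observed}) / (1 + n_runs), which
is never exactly zero and decreases monotonically in the observed
fraction.

**Calibration design.**  The hypothesis this null tests is that regulons
are exchangeable with random gene sets — not that the two phenotype groups
are identical.  Under a fully structureless dataset the inactivation
fraction is almost surely zero and the empirical p-value sits at 1 (it is
super-uniform, i.e. valid but conservative — a property of the statistic,
not an implementation artifact).  The calibration experiments therefore
draw per-gene group shifts independently of regulon membership: regulons
are then uninformative while the fraction statistic is non-degenerate.
Because the fraction of m TFs lives on a grid of step 1/m, its discrete
atoms bound how closely the p-value can approach a continuous uniform;
the calibration uses many small regulons (200 TFs x 5 genes, shift SD 2 on
unit noise, 40+40 cells) so the atoms are small, with 200 outer datasets
and 100 inner randomizations.  At these sizes the Kolmogorov distance from
U(0,1) is dominated by sampling noise (~0.87/sqrt(200) ~ 0.062).

## Sensitivity / precision benchmarking

Against a gold standard of TFs with known expected direction, sensitivity
is the fraction of gold TFs significant in the expected direction and the
FDR is the fraction of significant gold-TF calls in the contrary
direction (undefined — reported as missing — when nothing is significant).
Wilson 95% intervals accompany both.

## Power model

A TF expressed at linear fold change FC in only a fraction w of a
tissue's cells has bulk log2 effect e = log2(FC*w + (1-w))/sigma (sigma is
the pooled log2-scale SD; all defaults use the scaled basis sigma = 1).
The two-group t-statistic is non-central t with df = n1+n2-2 and
non-centrality mu = sqrt(n1*n2/(n1+n2)) * e.  Sensitivity at a positive
threshold t is offered in two forms: the exact two-sided rejection
probability 1 - F_nct(t) + F_nct(-t) (default) and the doubled one-tail
form 2*(1 - F_nct(t)) clipped to 1.  The doubled form equals the exact one
at mu = 0 (symmetric tails) and overestimates by up to 2x for large mu —
both are kept so either convention can be reproduced, but the exact form
is the default and is the one validated against simulation.  The
threshold may be given directly or derived from a significance level with
a Bonferroni multiplicity (t is then the central-t quantile at
1 - alpha/(2m)).  scipy's non-central t CDF can return NaN at several
thousand df; the package falls back to quadrature over the defining
chi-mixture representation, accurate to ~1e-10.

The Monte-Carlo validator simulates the two-group t-test through its
sufficient statistics (group means Normal with variance 1/n_i; pooled
variance a scaled chi-square), which is exactly distributed as simulating
all n1+n2 unit-variance observations and avoids generating ~1e9 deviates.

## Synthetic-data generators

All generators are pure functions of configuration and seed.

* **Bulk multi-tissue** (default 5 tissues x 60 samples, 1500 genes):
  log2-scale Gaussian baseline with gene means ~ N(6,1) and unit noise,
  matching the power model's scaled basis.  8 planted tissue-specific TFs
  receive the mixture shift log2(FC*w+(1-w)) in the tissue of interest
  (default FC 4, w 1 — i.e. expressed tissue-wide; w < 1 emulates
  minor-cell-fraction dilution) and 8 null TFs have regulons but no
  tissue effect.  Each regulon target is sign*beta*(TF deviation) + noise
  (beta 1, ~30% inhibitory edges), so both the marginal screen and the
  partial-correlation pruning see the planted structure, and TFs sharing
  a tissue shift are correlated — the partial-correlation stage must
  remove those indirect edges, which the tests verify.
* **scRNA-Seq**: per-cell TF activity states drive regulon genes
  (base 2.0 + sign*1.5*state + N(0, 0.5) on the log2 scale, floored at 0).
  Dropout is logistic in underlying expression,
  p = 1/(1+exp(k*(x-x0))) with default (k, x0) = (1.5, 1.0) giving ~20-25%
  zeros at the default expression scale; the TF's own transcript can be
  forced to 100% dropout to reproduce the regime that motivates
  regulon-based scoring.
* **Time course**: designated TFs ramp their activity linearly from 0 to 1
  across stages (default 5 stages x 50 cells); all other TFs stay flat.

What the generators do **not** emulate: count-level sampling (negative
binomial library-size effects), batch effects, doublets, correlated
regulons, or cell-type mixtures beyond the activity states.  Passing the
benchmarks therefore demonstrates correctness of the estimators under the
stated generative model, not performance on any particular real dataset.

## Numerical and design notes

* Sample SD (n-1) everywhere; zero-variance genes are dropped at
  z-scoring rather than zero-filled.
* Wilcoxon p-values use the tie-corrected normal approximation with
  continuity correction; at the cell counts of interest (>= 40 per group)
  this is accurate to ~1e-3 in p.
* The exact one-tailed binomial tail for a 20-vs-3 inactivation skew is
  2048/2^23 ~ 2.4e-4.
* When many regulons change coherently between groups, the global
  z-scoring couples unchanged TFs' scores to the overall compositional
  shift (their profiles correlate with the cell-mean term); strongly
  imbalanced designs can therefore show mild contrary calls.  This is a
  property of whole-transcriptome z-scoring, shared with related activity
  estimators.
* Test and acceptance problem sizes (samples, cells, replicate counts)
  were chosen so each check's Monte-Carlo error is several times smaller
  than the margin it must resolve; the specific sizes appear in the
  calibration paragraphs above and in the test docstrings.
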