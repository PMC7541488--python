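"""Differential TF activity between normal and cancer-like cells, with the
Monte-Carlo regulon null.

Simulates 30 TFs of which 12 are switched off in the 'cancer' group,
scores activity per cell, tests each TF with a two-sided Wilcoxon
rank-sum test (Bonferroni over TFs), summarizes the skew towards
inactivation with an exact one-tailed binomial test, and checks the
observed inactivation fraction against 200 regulon randomizations.
"""

import numpy as np

import scregact as sa

net = sa.random_network(n_tfs=30, targets_per_tf=15, seed=7)
rng = np.random.default_rng(8)
n_per = 60
states = np.ones((30, 2 * n_per))
states[:12, n_per:] = 0.0          # 12 TFs inactivated in cancer cells
sc, _ = sa.simulate_scrnaseq(net, states, dropout=(1.5, 1.0), seed=9)
labels = np.array(["normal"] * n_per + ["tumor"] * n_per)

tfa = sa.estimate_tfa_matrix(sc, net)
table = sa.diff_activity_binary(tfa, labels, test="wilcoxon")
n_dn = int((table["direction"] == "DN").sum())
n_up = int((table["direction"] == "UP").sum())
skew_p = sa.binomial_skew_test(n_dn, n_up)
print(f"significant TFs: {n_dn} inactivated, {n_up} activated "
      f"(Bonferroni < 0.05); binomial skew p = {skew_p:.2e}")

mc = sa.montecarlo_regulon_null(sc, net, labels, n_runs=200, seed=10)
print(f"observed inactivation fraction {mc.observed_fraction:.2f}; "
      f"Monte-Carlo p = {mc.empirical_p:.4f} over {mc.n_runs} "
      f"size/sign-matched random regulons")
print("A small Monte-Carlo p means the real regulons are coherently "
      "inactivated, not an artifact of regulon size.")
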