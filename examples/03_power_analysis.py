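"""Sensitivity to detect a tissue-specific TF diluted by a minor cell
fraction.

A TF expressed at fold change FC in only a fraction w of a tissue's cells
shows a bulk log2 effect of log2(FC*w + (1-w)).  The two-group t-statistic
follows a non-central t distribution, giving an analytic sensitivity at
any significance threshold.
"""

import scregact as sa

n1, n2 = 150, 8555 - 150          # tissue of interest vs rest of compendium
t = sa.threshold_from_alpha(0.05, m=1313, df=n1 + n2 - 2)

for w in (0.05, 0.2):
    params = sa.PowerParams(n1=n1, n2=n2, FC=8.0, w=w, sigma=1.0, t=t)
    se = sa.sensitivity_at_threshold(params)
    e = sa.effect_size(8.0, w)
    mu = sa.noncentrality(n1, n2, e)
    print(f"w={w:.2f}: effect e={e:.3f}, noncentrality mu={mu:.2f}, "
          f"sensitivity={100 * se:.1f}%")

print("Even at a 5% minor cell fraction the Bonferroni-corrected test "
      "detects the TF well over half the time.")
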