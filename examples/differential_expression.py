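"""Negative-binomial differential expression with the fivefold TE rule.

Simulates a 1000-feature NB count matrix with strong effects planted in
a 10% minority, runs the method-of-moments NB Wald test, and applies
the TE-family decision rule: |log2FC| > 2.32 (fivefold) and BH-adjusted
p < 0.05.
"""

import numpy as np

from hspirna import destats

rng = np.random.default_rng(0)
disp, mu, reps = 0.1, 200.0, 4
n = 1.0 / disp
a = rng.negative_binomial(n, n / (n + mu), size=(1000, reps))
b = rng.negative_binomial(n, n / (n + mu), size=(1000, reps))
b[:100] = rng.negative_binomial(n, n / (n + 8 * mu), size=(100, reps))

res = destats.nb_test(a, b)
called = destats.classify_de(res, destats.FIVEFOLD_LOG2)
print(res.head()[["mean_expression", "log2_fold_change", "p_value", "p_adj"]].round(4))
print(f"\nplanted 8-fold features detected: {called[:100].mean():.0%} of 100")
print(f"false calls among 900 null features: {int(called[100:].sum())}")
print(f"null p < 0.05 rate (calibration): {(res['p_value'][100:] < 0.05).mean():.3f}")
print(
    "\nThe strict fivefold threshold means log2(5) = 2.3219 passes while\n"
    "2.32 exactly does not; significance additionally requires FDR < 0.05."
)
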