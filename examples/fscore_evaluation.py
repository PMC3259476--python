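"""Score deconvolved output against theoretical peptide fragments.

Generates the a/b/c/x/y/z fragment series (with neutral losses) of a
peptide, perturbs a copy to mimic imperfect deconvolution and traces
precision/recall/F-score over a grid of mass tolerances.
"""

import numpy as np

from deisograph import f_score_curve, theoretical_fragments

theo = theoretical_fragments("ELVISLIVESK")
print(f"theoretical spectrum: {len(theo)} fragment m/z values "
      f"for peptide {theo.peptide}")

rng = np.random.default_rng(0)
experimental = [f.mz + rng.normal(0, 0.15) for f in theo.fragments[:60]]
experimental += list(rng.uniform(100, 1200, size=15))  # spurious ions

print(f"\n{'tol (Da)':>8} {'TP':>4} {'FP':>4} {'FN':>4} "
      f"{'precision':>9} {'recall':>7} {'F':>6}")
for tol, c in f_score_curve(experimental, theo, [0.0, 0.05, 0.1, 0.2, 0.5, 1.0]):
    print(f"{tol:8.2f} {c.TP:4d} {c.FP:4d} {c.FN:4d} "
          f"{c.precision:9.3f} {c.recall:7.3f} {c.f_score:6.3f}")

print("\nwider tolerances match more peaks (TP never decreases); the F-score")
print("is the harmonic mean of precision and recall at each tolerance.")
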