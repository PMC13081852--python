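"""Certified genotype counts above a threshold, far beyond enumeration.

A landscape with L=100, C=4 has 4^100 ~ 1.6e60 sequences — hopeless to
enumerate.  The dynamic-programming bounds round per-position effects down
(lower pass) and up (upper pass) onto an integer grid and convolve exact
big-integer score distributions, yielding certified brackets on the number
of sequences at or above any fitness threshold.  Refining the grid tightens
the bracket.
"""

import numpy as np

import genodensity as gd

ls = gd.generate_iid(L=100, C=4, effect_dist="normal", seed=3)
s = gd.summarize(ls)
threshold = s.Fmean + 0.6 * (s.Fmax - s.Fmean)
print(f"threshold {threshold:.2f} (60% of the way from Fmean to Fmax)")

print(f"\n{'resolution':>11} {'lower':>12} {'upper':>12} {'rel gap':>9}")
for resolution in (8.0, 2.0, 0.5, 0.125):
    b = gd.dp_count_bounds(ls, threshold, resolution)
    print(f"{resolution:11.3f} {float(b.lower):12.4e} {float(b.upper):12.4e} "
          f"{b.rel_gap:9.2%}")

b = gd.refine_bounds(ls, threshold, rel_tol=0.05)
print(f"\nauto-refined toward a 5% gap (achieved {b.rel_gap:.2%} within the "
      f"default work budget):\n  [{b.lower}, {b.upper}]")
print(
    "\nBoth bounds are exact integers (arbitrary precision); the true\n"
    "count of sequences with fitness >= threshold is certified to lie\n"
    "between them, and halving the resolution never loosens either side."
)
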