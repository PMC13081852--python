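"""Compare the bulk Gaussian and saddle-point densities to exact counts.

Builds a small random additive landscape (L=10, C=4; ~10^6 sequences),
enumerates every fitness value, and evaluates both smooth approximations on
a shared grid.  The bulk Gaussian is fine near the middle of the range but
overshoots badly near the peak; the saddle-point stays accurate throughout.
"""

import numpy as np

import genodensity as gd

ls = gd.generate_iid(L=10, C=4, effect_dist="normal", seed=0)
s = gd.summarize(ls)
print(f"landscape: L={s.L} C={s.C}  Fmean={s.Fmean:.3f}  Fmax={s.Fmax:.3f}")

vals = gd.enumerate_fitnesses(ls)
grid = np.linspace(np.quantile(vals, 0.02), s.Fmax - 0.02 * (s.Fmax - s.Fmin), 9)
# kernel width chosen between the extremal fitness spacing and the range
exact = gd.enumerate_density(ls, F_grid=grid, kernel_sd=0.4)
bulk = gd.rho_bulk(ls, grid)
saddle = gd.rho_saddle(ls, grid)

print(f"\n{'F':>8} {'log rho exact':>14} {'log rho saddle':>15} {'log rho bulk':>13}")
for F, le, lsad, lb in zip(grid, exact.log_rho, saddle.log_rho, bulk.log_rho):
    print(f"{F:8.3f} {le:14.3f} {lsad:15.3f} {lb:13.3f}")

print(
    "\nEach column is the natural-log number of sequences per unit fitness.\n"
    "Note how the bulk column drifts above the exact one toward high F\n"
    "(the last rows) while the saddle-point column keeps tracking it."
)
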