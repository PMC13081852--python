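"""Near-peak power law: recover alpha = (1+gamma)/(2+gamma) from simulations.

Generates binary landscapes whose per-position fitness gaps follow
p_gap(Delta) ~ Delta^gamma, computes the saddle-point density on a
log-spaced near-peak grid, and fits (1/L) log rho = A + B eps^alpha.  The
fitted exponent matches the analytic prediction for each gamma; for the
regular case (gamma=0) the fitted B also matches the closed form
sqrt(pi^2 p_gap(0)/3).
"""

import numpy as np

import genodensity as gd

print(f"{'gamma':>6} {'alpha fit':>10} {'alpha theory':>13} {'B fit':>7}")
for gamma in (-0.5, 0.0, 1.0):
    ls = gd.generate_binary_from_gaps(
        L=2000, gap_spec={"kind": "power_law", "gamma": gamma, "scale": 1.0},
        seed=11,
    )
    s = gd.summarize(ls)
    eps = gd.near_peak_grid(s)
    curve = gd.rho_saddle(ls, (s.Fmax - s.L * eps)[::-1])
    fit = gd.fit_near_peak(curve)
    print(f"{gamma:6.1f} {fit.alpha:10.3f} {gd.alpha_from_gamma(gamma):13.3f} "
          f"{fit.B:7.3f}")

# closed-form B check: uniform gaps on (0, 1] have p_gap(0) = 1
print(f"\nclosed-form B for gamma=0, p_gap(0)=1: {gd.B_regular(1.0):.3f} "
      "(compare to the fitted B in the gamma=0.0 row)")
print(
    "\nSmaller alpha means a 'stubbier' peak: the number of genotypes\n"
    "explodes faster as fitness drops below its maximum.  Landscapes\n"
    "enriched for near-zero gaps (gamma<0) are stubbier; depleted ones\n"
    "(gamma>0) are sharper."
)
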