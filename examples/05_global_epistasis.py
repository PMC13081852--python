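"""Near-peak scaling transfers through a monotone nonlinearity.

Many measured landscapes are a sigmoidal readout F = g(phi) of an additive
trait phi (global epistasis).  If g has nonzero slope g'_max at the trait
optimum, the near-peak exponent alpha is preserved and the coefficients
transform analytically: A_F = A_phi - log(g'_max)/L, B_F = g'_max^-alpha
B_phi.  This script fits the trait-space law inside the linearization
validity window, transfers it with no additional fitting, and compares
against the exactly transformed density.
"""

import numpy as np

import genodensity as gd
from genodensity.epistasis import validity_window

ls = gd.generate_iid(L=100, C=4, effect_dist="normal", seed=2)
s = gd.summarize(ls)
sigma = np.sqrt(s.sigma_bulk2)

print(f"{'span':>6} {'g_max_prime':>12} {'B_F analytic':>13} {'B_F direct':>11} "
      f"{'mean |err|':>11}")
for span in (sigma, sigma / 2):
    g = gd.sigmoid_nonlinearity(s, span=float(span))
    gp = g.slope(s.Fmax)
    eF_max = validity_window(g, s.Fmax, s.L, trait_depth=0.5 * (s.Fmax - s.Fmean))
    eps_phi = np.geomspace(eF_max / gp * 1e-2, eF_max / gp, 120)
    sad = gd.rho_saddle(ls, (s.Fmax - s.L * eps_phi)[::-1])
    fit_phi = gd.fit_near_peak(sad)
    analytic = gd.transform_peak_fit(fit_phi, g, s.L, s.Fmax)
    transformed = gd.transform_density(sad, g)
    direct = gd.fit_near_peak(transformed, L=s.L, fix_alpha=fit_phi.alpha)
    err = np.mean(np.abs(analytic.A + analytic.B * transformed.eps**analytic.alpha
                         - transformed.log_rho / s.L))
    print(f"{span:6.2f} {gp:12.3e} {analytic.B:13.4g} {direct.B:11.4g} "
          f"{err:11.5f}")

print(
    "\n'mean |err|' is the misfit of the analytically transferred law\n"
    "against the exactly transformed density, in units of (1/L) log rho.\n"
    "Flatter sigmoids (smaller span => smaller slope at the optimum) give\n"
    "larger B_F and a narrower validity window, but the exponent alpha\n"
    "never changes."
)
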