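# Methods

## Model and scope

The package works with additive fitness landscapes
`f(x) = θ₀ + Σ_l θ_{l,x_l}` over fixed-length sequences (`L` positions,
alphabet size `C ≥ 2`), and with global-epistasis models `F = g(φ)` whose
trait(s) φ are additive.  Fitness units are arbitrary;
`zscore_normalize` rescales so that uniformly random sequences have zero
mean and unit fitness variance, the convention commonly used for
empirically inferred models.  Inference of θ from data, indels, and
specific (non-global) epistatic interactions are out of scope.

Gauge freedom: adding a constant to a row of θ and absorbing it into θ₀
changes nothing observable.  All derived quantities (per-position deficits
δ_lc, runner-up gaps Δ_l, σ²_bulk, Fmax − Fmean, densities, fitted
exponents, crossover ratio) are gauge-invariant; this is enforced by tests.

## Density approximations

**Bulk.** `log ρ_bulk(F) = L log C − ½ log 2πσ²_bulk − (F − Fmean)²/2σ²_bulk`,
with Fmean and σ²_bulk computed in closed form from θ (exact mean/variance
of fitness under uniform random sequences).  Valid within a few bulk
standard deviations of Fmean; badly inflated near Fmax, and it assigns mass
above Fmax where the true density is zero.

**Tilted / saddle-point.** The tilted ensemble `p_β(x) ∝ e^{βf(x)}`
factorizes over positions for additive f, so the free fitness
`Φ(β) = βθ₀ + Σ_l log Σ_c e^{βθ_lc}` and its derivatives
(μ_β = Φ′, σ²_β = Φ″) are evaluated exactly with per-position softmax
weights and max-subtraction; no quantity is ever exponentiated out of log
space (C^L overflows floats at modest L).  The saddle-point density solves
`μ_β = F` per grid point:

    log ρ_saddle(F) = Φ(β) − βF − ½ log 2πσ²_β.

The root solve is safeguarded Newton on the monotone map β ↦ μ_β:
geometric bracket expansion from the warm-started previous solution,
Newton steps clipped to the bracket with bisection fallback, convergence at
`|μ_β − F| ≤ 10⁻¹⁰ (Fmax − Fmean)`.  β is capped at `10⁶ / median(δ_lc > 0)`;
targets needing more (F essentially at the boundary) raise rather than
saturate silently.  Grids ascend and each solve warm-starts from the last.
Positions with all characters tied contribute `log C` to Φ and nothing to
σ²_β; they are fine as long as one position is informative.  The domain is
the open interval (Fmin, Fmax): the endpoints are delta functions whose
weights come from tie counting, not from a density.

**Multi-trait saddle.** For K additive traits the tilted exponent
`β⃗·φ⃗(x)` is itself additive with effective effects `Σ_k β_k θ^k_lc`, so
`Φ(β⃗)` factorizes and its gradient/Hessian are per-position tilted
moments.  `∇Φ(β⃗) = φ⃗` is solved by Newton with backtracking line search
on the convex dual `Φ − β⃗·φ⃗`.  Membership of φ⃗ in the achievable
region is checked only per component (each trait within its own open
range), which is conservative: corner targets inside every component range
can still lie outside the joint hull, in which case the dual has no
stationary point and the solver raises a domain error instead of returning
an unconverged value.

## Exact counts

**Enumeration** (up to 2²⁰ sequences by default) builds all fitness values
by per-position outer sums and returns a Gaussian kernel density estimate
of log ρ.  The kernel width defaults to (Fmax − Fmin)/1000 and stands in
for finite measurement precision; the estimate is insensitive to the width
provided it is much smaller than the fitness range and much larger than
the spacing between the extremal values and their neighbors.  A warning is
logged when the chosen width violates that window (unavoidable at very
small L, where no width satisfies both sides).

**Certified DP bounds.** For large landscapes, per-position effects are
rounded down (lower pass) and up (upper pass) onto an integer grid of
width `resolution/L`, so every sequence's total rounding error is below
`resolution`.  Exact integer score distributions are built by convolving
per-position count polynomials; counts are arbitrary-precision (at C=20,
L=55 they reach ~10⁷¹).  The convolution uses Kronecker substitution — the
whole count polynomial is packed into one big Python integer with a fixed
number of bits per coefficient (⌈L log₂C⌉ + 8, byte-aligned), so each
position costs C shift-and-adds on a single integer rather than a Python
loop over coefficients.  A common divisor of the integer offsets is
divided out first, which keeps lattice-valued landscapes (e.g. Hamming)
cheap at any resolution.  The lower bound counts only sequences whose
rounded-down total already clears the threshold; the upper bound counts
every sequence whose rounded-up total could.  `refine_bounds` halves the
resolution geometrically until the relative gap meets `rel_tol` or a total
DP-state budget (default 5·10⁷) is spent; because successive grids nest,
refinement never loosens either bound, and the last certified pair is
returned with a convergence flag.  Thresholds are compared after one
floating division by the grid width; ties within one part in 10¹⁵ of a
grid line may land on either side, an ambiguity far below the certified
discretization error.

## Near-peak scaling

Writing `Φ(β) = β Fmax + L·E(β)` defines the per-site deficit contribution
`E(β) = (1/L) Σ_l log(1 + Σ_{c≠max} e^{−βδ_lc})`.  For binary alphabets
`E` is an integral of the kernel `K(s) = log(1 + e^{−s})` (value log 2 at
0, area π²/12) against the gap density, giving, for `p_gap(Δ) ∼ cΔ^γ`
near zero, the law `(1/L) log ρ ≈ A + B ε^α` with `α = (1+γ)/(2+γ)`.  For
regular gap densities (γ = 0) the coefficient has the closed form
`B = √(π² p_gap(0)/3)`, which the package validates against fitting B with
α fixed at ½ on large simulated landscapes — the two agree to ~1%.  For
C ≥ 3 the sandwich bound `E_bin ≤ E ≤ (C−1)E_bin` (E_bin built from the
optimal and runner-up characters only) shows α carries over unchanged.
Fixed-gap (Hamming/Berg–von Hippel) landscapes have binomial genotype
counts; their log density is linear in ε tempered by a log-linear term, so
fitted exponents over any finite window sit below 1 — the local exponent is
approximately `(−ln ε)/(1 − ln ε)`, about 0.75–0.88 over the default
window — and approach 1 only as the window narrows toward the peak.

**Fitting.** `fit_near_peak` minimizes unweighted squared error in
`(1/L) log ρ` over a log-spaced ε grid; initialization uses α = ½ with B
from the endpoint slope against √ε, B is parameterized by its log to stay
positive, and α is constrained to (0, 1].  With `fix_alpha` the problem is
linear least squares.

**Fit window.** The default window is `ε ∈ [10⁻³, 10⁻¹] · (Fmax − Fmean)/L`
with 200 log-spaced points.  The upper edge keeps the window in the top
decile of the upper fitness range, where the power law is the operative
description.  The lower edge matters more than it looks: the continuum
law requires several positions to contribute gaps below the tilting scale
1/β, and for L ~ 100 that breaks down below ε of about 10⁻³ of the
per-site span — the density there reflects the discrete gap multiset and
fitted exponents inflate.  With this window, binary landscapes at L = 2000
recover α = ⅓, ½, ⅔ for γ = −½, 0, 1 within ±0.02, and i.i.d. Gaussian
landscapes at L = 100 (C = 4 and 20) give mean fitted α ≈ 0.52–0.57 across
seeds.  Fitted α shifts by a few hundredths with the window choice; that
sensitivity is inherent to fitting an asymptotic law over a finite window.

**Crossover.** With peak, bulk, and saddle curves on one grid spanning
(Fmean, Fmax), F_cross is the highest-F sign change of
`|log ρ_peak − log ρ_saddle| − |log ρ_bulk − log ρ_saddle|`, located by
linear interpolation; `r = (Fmax − F_cross)/(Fmax − Fmean)`.  The leading,
L-linear parts of both log densities make the crossover equation L-free,
so r is asymptotically independent of sequence length; at finite L the
saddle prefactor `−½ log 2πσ²_β` adds an O(log L / L) correction that
shifts r visibly for L ≲ 50 (measured seed means: 0.246 at L = 50, 0.276
at L = 100, 0.290 at L = 200 for C = 4 Gaussian landscapes).  Invariance
is therefore asserted between L = 100 and L = 200.  Simulated Gaussian
landscapes at L = 100 give r in the high 0.2s to low 0.3s — the near-peak
law governs roughly a quarter to a third of the upper fitness range.

**Gap-exponent diagnostic.** `estimate_gap_exponent` is a Hill-type
order-statistics estimator of γ (and the amplitude c) from the smallest
quartile of positive runner-up gaps.  It is a heuristic diagnostic, never
substituted for fitting α; a near-constant gap multiset is flagged as the
fixed-gap regime instead of yielding a spurious exponent.

## Global epistasis

For `F = g(φ)` with g strictly increasing and `g'_max = g'(φ_max) > 0`,
densities transform by change of variables
(`log ρ_F = log ρ_φ − log g'`, checked for monotonicity on the actual
grid), and peak fits transform analytically with α unchanged:
`A_F = A_φ − log(g'_max)/L`, `B_F = g'^{−α}_max B_φ`.  The sigmoid family
is the logistic `low + (high−low)/(1 + e^{−(φ−φ_½)/s_φ})` with the
midpoint defaulting to four bulk standard deviations below the trait peak
— the common situation of a measurement saturating well below the best
achievable trait value.  (No specific functional form is canonical for
such readouts; the logistic is this package's choice.)  The transfer is
exact only where the linearization of g is accurate; `validity_window`
computes the operational window — the largest deficit at which the
linearization error stays below 5% of the local fitness deficit — and
`transform_peak_fit` attaches a saturation warning when the slope at the
optimum is under 5% of the maximum slope near the peak.  The flatter g is
at the optimum, the larger B_F and the narrower that window.  Multi-trait
models `F = g(φ⃗)` with a boundary maximum and nonzero gradient are
linearized by projecting onto the effective additive trait
`Σ_k c_k φ_k, c⃗ = ∇g(φ⃗_max)` (gradient supplied or central differences
with step 10⁻⁶ of each trait's range); everything single-trait then
applies.  Interior maxima and zero-gradient plateaus raise errors — the
scaling genuinely does not transfer there.

## Simulated landscapes

Generators cover the landscape families used throughout: i.i.d. effects
(normal/uniform/exponential; standard normal is the default study
condition, L = 100 with C = 4 or 20 for general-alphabet experiments),
binary landscapes with gaps drawn from `p_gap(Δ) ∝ Δ^γ` on (0, scale] via
inverse-CDF sampling (γ > −1; L = 2000 is the default scale for exponent
recovery, balancing asymptotic depth against runtime), fixed-gap Hamming
landscapes, and explicit gap lists.  θ₀ is 0 in all generators; every
generator takes one integer seed and is deterministic given it (no global
RNG state).  These emulate the qualitative structure of empirical
landscapes — many near-zero effects, a few large ones, controlled gap
statistics — but not their correlation structure, measurement noise, or
inference artifacts; passing tests on them validates the mathematics of
the density machinery, not any claim about a particular biological
dataset.  Empirical landscapes can be analyzed by reading their effect
matrices from TSV (or MEME motifs via `θ_lc = log(p_lc + 10⁻⁴)`, a
read-only convenience; no canonical motif-to-energy map exists).

## Numerical choices and limitations

- Runner-up gaps use the multiset of row values: a tied optimum gives
  Δ_l = 0, consistent with tie counts feeding the constant A.
- Default fitness grids: 512 points on
  `[Fmin + 10⁻⁴R, Fmax − 10⁻⁴R], R = Fmax − Fmin`; near-peak analyses use
  the log-spaced ε grid above.
- Density curves store natural-log densities only; TSV serialization
  carries F, ε, log ρ, and the method tag with a provenance header.
- Higher cumulants beyond σ²_β are ignored (sub-leading in L); the
  population-genetic reading β = 2Nₑ is documented, not simulated.
- The crossover requires a sign change on the supplied grid; with multiple
  sign changes the one closest to the peak is reported.
- B has no closed form here for γ ≠ 0; it is obtained by fitting.
- Tests exercise exhaustive cross-checks at C^L ≤ 2¹⁶–2²⁰ and simulation
  sizes (L = 100–2000, ≤ 8 seeds) chosen so the whole suite runs in about
  a minute; the quantities tested are insensitive to further scale-up at
  the asserted tolerances.
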