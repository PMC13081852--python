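"""Near-peak scaling of the genotypic density.

Just below maximal fitness, the log genotypic density of an additive
landscape follows an exponentiated power law in the per-site fitness deficit
eps = (Fmax - F)/L:

    (1/L) log rho ~= A + B * eps**alpha.

The exponent alpha is set by the distribution of per-position runner-up gaps
Delta (best minus second-best effect): when p_gap(Delta) ~ c*Delta**gamma
near zero, alpha = (1+gamma)/(2+gamma).  A regular gap density (gamma = 0)
gives square-root scaling with the closed-form coefficient
B = sqrt(pi**2 * p_gap(0) / 3); an enrichment of small gaps (gamma < 0)
flattens the peak further (alpha < 1/2), while a deficit of small gaps
sharpens it.  The constant A absorbs positions with characters tied for the
optimum.  This module provides the analytic pieces (kernel K, alpha, B), an
empirical (A, B, alpha) fit against any density curve, the resulting peak
approximation, the crossover against the bulk Gaussian, and a gap-exponent
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .density import DensityCurve, _ref
from .landscape import LandscapeSummary

__all__ = [
    "PeakFit",
    "CrossoverResult",
    "GapExponent",
    "kernel_K",
    "alpha_from_gamma",
    "B_regular",
    "near_peak_grid",
    "fit_near_peak",
    "rho_peak",
    "crossover",
    "estimate_gap_exponent",
]


@dataclass(frozen=True)
class PeakFit:
    """Fitted exponentiated power law (1/L) log rho = A + B eps^alpha.

    ``fit_region`` records the (eps_min, eps_max) window used;
    ``residual_rms`` is the root-mean-square misfit of (1/L) log rho over
    that window.  ``gamma``/``c`` optionally carry the gap-exponent pair the
    fit corresponds to.  ``warnings`` holds qualitative caveats (e.g. a
    saturating nonlinearity upstream).
    """

    A: float
    B: float
    alpha: float
    fit_region: tuple[float, float]
    residual_rms: float
    gamma: float | None = None
    c: float | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha={self.alpha} outside (0, 1]")
        if self.B <= 0:
            raise ValueError("B must be positive")
        if not self.fit_region[0] < self.fit_region[1]:
            raise ValueError("empty fit region")


@dataclass(frozen=True)
class CrossoverResult:
    """Fitness below which the bulk Gaussian beats the near-peak law.

    ``r = (Fmax - F_cross)/(Fmax - Fmean)`` is the fraction of the upper
    fitness range governed by the near-peak scaling.
    """

    F_cross: float
    r: float


@dataclass(frozen=True)
class GapExponent:
    """Point estimates of p_gap(Delta) ~ c * Delta^gamma near zero."""

    gamma: float
    c: float
    fixed_gap: bool = False

    def __iter__(self):
        return iter((self.gamma, self.c))


def kernel_K(s) -> np.ndarray | float:
    """Smoothing kernel K(s) = log(1 + exp(-s)).

    Equals log 2 at the origin, decays as exp(-s), and has area pi^2/12.
    Stable for large s via log1p.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("kernel_K requires s >= 0")
    out = np.log1p(np.exp(-s))
    return float(out) if out.ndim == 0 else out


def alpha_from_gamma(gamma: float) -> float:
    """Near-peak exponent alpha = (1 + gamma)/(2 + gamma) for gamma > -1."""
    if gamma <= -1:
        raise ValueError("gamma must exceed -1 (normalizable gap density)")
    return (1.0 + gamma) / (2.0 + gamma)


def B_regular(pgap0: float) -> float:
    """Closed-form B for a regular gap density, paired with sqrt(eps) scaling.

    For p_gap regular at zero (0 < p_gap(0) < inf) the deficit contribution
    behaves as E(beta) ~= pi^2 p_gap(0)/(12 beta); inverting the saddle
    condition gives (1/L) log rho ~= B sqrt(eps) with

        B = sqrt(pi^2 * p_gap(0) / 3).

    Validated against fits of the saddle-point density of large binary
    landscapes with alpha fixed at 1/2.
    """
    if pgap0 <= 0:
        raise ValueError("p_gap(0) must be positive")
    return float(np.sqrt(np.pi**2 * pgap0 / 3.0))


def near_peak_grid(
    summary: LandscapeSummary,
    eps_min: float | None = None,
    eps_max: float | None = None,
    n: int = 200,
) -> np.ndarray:
    """Default log-spaced near-peak grid of per-site deficits eps.

    Spans 1e-3 to 0.1 of the per-site span (Fmax - Fmean)/L unless
    overridden; returned ascending.  The lower edge keeps the window inside
    the regime where many positions contribute gaps below the tilting scale
    1/beta; pushing eps much smaller at moderate L probes the discreteness
    of the finite gap multiset, which biases fitted exponents upward.
    """
    span = (summary.Fmax - summary.Fmean) / summary.L
    if eps_min is None:
        eps_min = 1e-3 * span
    if eps_max is None:
        eps_max = 0.1 * span
    if not 0 < eps_min < eps_max:
        raise ValueError("need 0 < eps_min < eps_max")
    return np.geomspace(eps_min, eps_max, n)


def fit_near_peak(
    curve: DensityCurve,
    L: int | None = None,
    region: tuple[float, float] | None = None,
    fix_alpha: float | None = None,
) -> PeakFit:
    """Fit (1/L) log rho = A + B eps^alpha to a density curve.

    Nonlinear least squares in (1/L) log rho, unweighted.  Initialization:
    alpha = 0.5, B from the endpoint slope against sqrt(eps), A from the
    intercept.  With ``fix_alpha`` the problem is linear in (A, B).  The
    region defaults to the full positive-eps extent of the curve; at least
    20 points are required.
    """
    if L is None:
        L = int(curve.landscape_ref["L"])
    eps = np.asarray(curve.eps, dtype=float)
    y = np.asarray(curve.log_rho, dtype=float) / L
    mask = eps > 0
    if region is not None:
        mask &= (eps >= region[0]) & (eps <= region[1])
    eps, y = eps[mask], y[mask]
    if eps.size < 20:
        raise ValueError(f"fit region contains {eps.size} points; need >= 20")
    order = np.argsort(eps)
    eps, y = eps[order], y[order]

    if fix_alpha is not None:
        if not (0 < fix_alpha <= 1):
            raise ValueError("fix_alpha must lie in (0, 1]")
        X = np.column_stack([np.ones_like(eps), eps**fix_alpha])
        (A, B), *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - (A + B * eps**fix_alpha)
        return PeakFit(
            A=float(A), B=float(B), alpha=float(fix_alpha),
            fit_region=(float(eps[0]), float(eps[-1])),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
        )

    r = np.sqrt(eps)
    B0 = (y[-1] - y[0]) / (r[-1] - r[0])
    B0 = max(B0, 1e-8)
    A0 = y[0] - B0 * r[0]

    def residuals(p):
        A, logB, alpha = p
        return A + np.exp(logB) * eps**alpha - y

    sol = least_squares(
        residuals,
        x0=[A0, np.log(B0), 0.5],
        bounds=([-np.inf, -np.inf, 1e-3], [np.inf, np.inf, 1.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"near-peak fit did not converge: {sol.message}")
    A, logB, alpha = sol.x
    return PeakFit(
        A=float(A), B=float(np.exp(logB)), alpha=float(alpha),
        fit_region=(float(eps[0]), float(eps[-1])),
        residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
    )


def rho_peak(
    fit: PeakFit, landscape_summary: LandscapeSummary, F_grid
) -> DensityCurve:
    """Evaluate the fitted near-peak law on a fitness grid below Fmax."""
    F = np.asarray(F_grid, dtype=float)
    if np.any(F >= landscape_summary.Fmax):
        raise ValueError("rho_peak requires F strictly below Fmax")
    L = landscape_summary.L
    eps = (landscape_summary.Fmax - F) / L
    log_rho = L * (fit.A + fit.B * eps**fit.alpha)
    return DensityCurve(F, log_rho, eps, "peak", _ref(landscape_summary))


def crossover(
    peak: DensityCurve, bulk: DensityCurve, saddle: DensityCurve
) -> CrossoverResult:
    """Locate where the near-peak law overtakes the bulk Gaussian.

    All three curves must share one F grid spanning (Fmean, Fmax).  F_cross
    is the largest F at which |log rho_peak - log rho_saddle| equals
    |log rho_bulk - log rho_saddle| (linear interpolation between grid
    points); above it the power law is the closer approximation to the
    saddle-point density.
    """
    F = saddle.F
    if not (np.array_equal(peak.F, F) and np.array_equal(bulk.F, F)):
        raise ValueError("curves must share a common fitness grid")
    d = np.abs(peak.log_rho - saddle.log_rho) - np.abs(bulk.log_rho - saddle.log_rho)
    sign = np.sign(d)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if flips.size == 0:
        raise ValueError("no crossover found on the supplied grid")
    i = flips[-1]  # highest-F sign change: the near-peak regime boundary
    F_cross = F[i] - d[i] * (F[i + 1] - F[i]) / (d[i + 1] - d[i])
    Fmax = saddle.landscape_ref["Fmax"]
    Fmean = saddle.landscape_ref["Fmean"]
    r = (Fmax - F_cross) / (Fmax - Fmean)
    if not (0 < r < 1):
        raise ValueError(f"crossover ratio r={r} outside (0, 1)")
    return CrossoverResult(F_cross=float(F_cross), r=float(r))


def estimate_gap_exponent(
    runner_up_gaps, tail_fraction: float = 0.25
) -> GapExponent:
    """Hill-type estimate of the small-gap exponent of p_gap(Delta).

    Uses the smallest ``tail_fraction`` of positive gaps: for a density
    ~ c*Delta^gamma near zero, the lower-tail CDF is a power law with index
    1 + gamma, whose Hill estimator over the k smallest order statistics is
    k / sum_i log(Delta_(k+1)/Delta_(i)).  The coefficient c is recovered
    from the empirical tail mass.  Heuristic point estimates only; a
    near-constant gap multiset is flagged as the fixed-gap (Hamming) regime,
    where log rho grows linearly in eps.
    """
    gaps = np.sort(np.asarray(runner_up_gaps, dtype=float))
    gaps = gaps[gaps > 0]
    n = gaps.size
    if n < 50:
        raise ValueError(f"need >= 50 positive gaps, got {n}")
    if gaps[-1] - gaps[0] <= 1e-12 * max(gaps[-1], 1.0):
        return GapExponent(gamma=np.inf, c=0.0, fixed_gap=True)
    k = max(10, int(tail_fraction * n))
    t = gaps[k]  # (k+1)-th order statistic
    logs = np.log(t / gaps[:k])
    a_hat = k / logs.sum()  # CDF index 1 + gamma
    gamma_hat = a_hat - 1.0
    # P(Delta <= t) ~= c * t^(1+gamma)/(1+gamma)  =>  c from tail mass k/n
    c_hat = (k / n) * a_hat / t**a_hat
    return GapExponent(gamma=float(gamma_hat), c=float(c_hat))
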