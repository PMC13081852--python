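"""Global epistasis: monotone nonlinear readouts of additive traits.

Many measured fitness landscapes take the form F = g(phi), where phi is an
additive trait and g a monotone nonlinearity (a "global epistasis" model).
When g attains its maximum at the trait optimum phi_max with nonzero slope
g'_max, the near-peak power law transfers from trait space to fitness space
with the exponent alpha unchanged:

    A_F = A_phi - (1/L) log g'_max,     B_F = (g'_max)**(-alpha) * B_phi.

The flatter g is at phi_max (stronger saturation), the larger B_F and the
narrower the fitness range over which the linearization — and hence the
transferred scaling — remains valid.  For multi-trait models F = g(phi_vec),
linearizing g at the trait-space optimum projects the K traits onto a single
effective additive trait whose near-peak behavior is analyzed with the
single-trait machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .density import DensityCurve
from .landscape import AdditiveLandscape
from .near_peak import PeakFit

__all__ = [
    "Nonlinearity",
    "sigmoid_nonlinearity",
    "transform_density",
    "transform_peak_fit",
    "validity_window",
    "linearize_multitrait",
]


class MonotonicityError(ValueError):
    """Nonlinearity is not strictly increasing on the required domain."""


@dataclass(frozen=True)
class Nonlinearity:
    """A scalar monotone readout g(phi) with analytic or tabulated slope.

    ``kind`` is one of ``identity``, ``linear`` (params: slope, intercept),
    ``sigmoid`` (params: midpoint, span, low, high — the logistic
    low + (high-low)/(1+exp(-(phi-midpoint)/span))), or ``table`` (params:
    phi_knots, g_knots; monotone interpolation with finite-difference
    slopes).
    """

    kind: str
    params: dict

    @classmethod
    def identity(cls) -> "Nonlinearity":
        return cls(kind="identity", params={})

    @classmethod
    def linear(cls, slope: float, intercept: float = 0.0) -> "Nonlinearity":
        if slope <= 0:
            raise MonotonicityError("linear slope must be positive")
        return cls(kind="linear", params={"slope": slope, "intercept": intercept})

    @classmethod
    def sigmoid(cls, midpoint: float, span: float, low: float = 0.0,
                high: float = 1.0) -> "Nonlinearity":
        if span <= 0 or high <= low:
            raise MonotonicityError("need span > 0 and high > low")
        return cls(kind="sigmoid", params={
            "midpoint": midpoint, "span": span, "low": low, "high": high})

    @classmethod
    def table(cls, phi_knots, g_knots) -> "Nonlinearity":
        phi_knots = np.asarray(phi_knots, dtype=float)
        g_knots = np.asarray(g_knots, dtype=float)
        if np.any(np.diff(phi_knots) <= 0) or np.any(np.diff(g_knots) <= 0):
            raise MonotonicityError("table knots must be strictly increasing")
        return cls(kind="table", params={"phi": phi_knots, "g": g_knots})

    def __call__(self, phi):
        phi = np.asarray(phi, dtype=float)
        p = self.params
        if self.kind == "identity":
            out = phi
        elif self.kind == "linear":
            out = p["slope"] * phi + p["intercept"]
        elif self.kind == "sigmoid":
            z = (phi - p["midpoint"]) / p["span"]
            out = p["low"] + (p["high"] - p["low"]) / (1.0 + np.exp(-z))
        elif self.kind == "table":
            out = np.interp(phi, p["phi"], p["g"])
        else:
            raise ValueError(f"unknown nonlinearity kind {self.kind!r}")
        return float(out) if out.ndim == 0 else out

    def slope(self, phi):
        """g'(phi); analytic where available, finite differences for tables."""
        phi = np.asarray(phi, dtype=float)
        p = self.params
        if self.kind == "identity":
            out = np.ones_like(phi)
        elif self.kind == "linear":
            out = np.full_like(phi, p["slope"])
        elif self.kind == "sigmoid":
            z = (phi - p["midpoint"]) / p["span"]
            sig = 1.0 / (1.0 + np.exp(-np.abs(z)))
            # stable logistic derivative: sig*(1-sig) is symmetric in z
            out = (p["high"] - p["low"]) * sig * (1.0 - sig) / p["span"]
        elif self.kind == "table":
            out = np.interp(phi, p["phi"], np.gradient(p["g"], p["phi"]))
        else:
            raise ValueError(f"unknown nonlinearity kind {self.kind!r}")
        return float(out) if out.ndim == 0 else out

    def check_monotone(self, lo: float, hi: float, n: int = 1001) -> None:
        grid = np.linspace(lo, hi, n)
        if np.any(np.diff(self(grid)) <= 0):
            raise MonotonicityError(
                f"{self.kind} nonlinearity is not strictly increasing on "
                f"[{lo}, {hi}]"
            )

    @classmethod
    def from_json_dict(cls, spec: dict) -> "Nonlinearity":
        spec = dict(spec)
        kind = spec.pop("kind")
        if kind == "identity":
            return cls.identity()
        if kind == "linear":
            return cls.linear(**spec)
        if kind == "sigmoid":
            return cls.sigmoid(**spec)
        if kind == "table":
            return cls.table(spec["phi"], spec["g"])
        raise ValueError(f"unknown nonlinearity kind {kind!r}")


def sigmoid_nonlinearity(trait_summary, span: float, low: float = 0.0,
                         high: float = 1.0, midpoint_offset_sd: float = 4.0
                         ) -> Nonlinearity:
    """Sigmoid with midpoint a fixed number of bulk SDs below the trait peak.

    Default midpoint phi_max - 4*sigma_bulk mirrors the common situation
    where the measurement saturates well below the best achievable trait
    value.
    """
    sd = float(np.sqrt(trait_summary.sigma_bulk2))
    return Nonlinearity.sigmoid(
        midpoint=trait_summary.Fmax - midpoint_offset_sd * sd,
        span=span, low=low, high=high,
    )


def transform_density(curve: DensityCurve, g: Nonlinearity) -> DensityCurve:
    """Push a trait-space density through F = g(phi) by change of variables.

    log rho_F(g(phi)) = log rho_phi(phi) - log g'(phi); the fitness grid is
    the image of the trait grid.  Total genotype count is conserved.
    """
    phi = curve.F
    g.check_monotone(float(phi[0]), float(phi[-1]))
    F = np.asarray(g(phi), dtype=float)
    slope = np.asarray(g.slope(phi), dtype=float)
    if np.any(slope <= 0):
        raise MonotonicityError("g has non-positive slope on the curve domain")
    log_rho = curve.log_rho - np.log(slope)
    ref = dict(curve.landscape_ref)
    phi_max = ref["Fmax"]
    ref["Fmax"] = float(g(phi_max))
    # Fmean in fitness space is not g(phi_mean) in general; keep the image
    # of the trait mean as a reference point for plotting/crossover use
    ref["Fmean"] = float(g(ref["Fmean"]))
    eps = (ref["Fmax"] - F) / ref["L"]
    return DensityCurve(F, log_rho, eps, "transformed-" + curve.method, ref)


def transform_peak_fit(
    fit_phi: PeakFit,
    g: Nonlinearity,
    L: int,
    phi_max: float,
    saturation_ratio: float = 0.05,
) -> PeakFit:
    """Analytic transfer of a trait-space peak fit to fitness space.

    Requires g'_max = g'(phi_max) > 0.  alpha is unchanged;
    A_F = A_phi - log(g'_max)/L and B_F = g'_max**(-alpha) * B_phi.  When
    g'_max falls below ``saturation_ratio`` times the maximum slope of g
    near the peak, a saturation warning is attached: the linearization (and
    hence the transferred scaling) then holds only over a compressed fitness
    range.
    """
    gp = float(g.slope(phi_max))
    if gp <= 0:
        raise MonotonicityError(
            "g has zero or negative slope at the trait optimum; near-peak "
            "scaling does not transfer (plateau case)"
        )
    warnings = fit_phi.warnings
    # compare the slope at the optimum to the steepest slope over the
    # near-peak trait window to flag saturation
    span_lo = phi_max - L * fit_phi.fit_region[1]
    probe = np.linspace(span_lo - (phi_max - span_lo) * 4.0, phi_max, 201)
    max_slope = float(np.max(g.slope(probe)))
    if gp < saturation_ratio * max_slope:
        warnings = warnings + (
            "nonlinearity saturates near the trait optimum; transferred "
            "scaling valid over a compressed fitness range",
        )
    eps_lo, eps_hi = fit_phi.fit_region
    return replace(
        fit_phi,
        A=fit_phi.A - np.log(gp) / L,
        B=gp ** (-fit_phi.alpha) * fit_phi.B,
        fit_region=(eps_lo * gp, eps_hi * gp),
        warnings=warnings,
    )


def validity_window(
    g: Nonlinearity,
    phi_max: float,
    L: int,
    trait_depth: float,
    rel_err: float = 0.05,
    n: int = 2000,
) -> float:
    """Largest per-site fitness deficit over which linearizing g is accurate.

    Scans trait deficits u = phi_max - phi up to ``trait_depth`` and returns
    the fitness-space eps_F = (g(phi_max) - g(phi))/L at the deepest u for
    which the linearization error |g(phi_max) - u*g'_max - g(phi)| stays
    below ``rel_err`` times the local fitness deficit.  The transferred
    near-peak law is only meaningful for eps_F inside this window.
    """
    gp = float(g.slope(phi_max))
    if gp <= 0:
        raise MonotonicityError("g has zero slope at the trait optimum")
    u = np.geomspace(trait_depth * 1e-6, trait_depth, n)
    phi = phi_max - u
    deficit = float(g(phi_max)) - np.asarray(g(phi), dtype=float)
    err = np.abs(gp * u - deficit)
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = err <= rel_err * np.maximum(deficit, 1e-300)
    bad = np.nonzero(~ok)[0]
    i = (bad[0] - 1) if bad.size else (n - 1)
    if i < 0:
        raise MonotonicityError(
            "linearization of g is inaccurate at every probed trait deficit"
        )
    return float(deficit[i] / L)


def linearize_multitrait(
    g,
    phi_max,
    trait_landscapes: list[AdditiveLandscape],
    grad=None,
    rel_step: float = 1e-6,
) -> AdditiveLandscape:
    """Project K traits onto one effective additive trait via grad g.

    ``g`` maps a K-vector of traits to fitness and must attain its maximum
    on the boundary of the achievable trait polytope with nonzero gradient
    there.  The effective landscape has theta~_lc = sum_k c_k theta^k_lc and
    theta~0 = sum_k c_k theta0^k with c = grad g(phi_max) (supplied, or
    central differences with a step of ``rel_step`` times each trait's
    range).  All single-trait near-peak machinery applies to the result.
    """
    phi_max = np.asarray(phi_max, dtype=float)
    K = len(trait_landscapes)
    if phi_max.shape != (K,):
        raise ValueError(f"phi_max must have shape ({K},)")
    if grad is None:
        grad = np.empty(K)
        for k, t in enumerate(trait_landscapes):
            rng = float(
                (t.theta.max(axis=1) - t.theta.min(axis=1)).sum() or 1.0
            )
            h = rel_step * rng
            e = np.zeros(K)
            e[k] = h
            grad[k] = (g(phi_max + e) - g(phi_max - e)) / (2 * h)
    else:
        grad = np.asarray(grad, dtype=float)
    if np.allclose(grad, 0.0):
        raise ValueError(
            "g has zero gradient at the trait optimum; linearization fails"
        )
    L = trait_landscapes[0].L
    alphabet = trait_landscapes[0].alphabet
    for t in trait_landscapes[1:]:
        if t.L != L or t.alphabet != alphabet:
            raise ValueError("traits must share L and alphabet")
    theta = sum(c * t.theta for c, t in zip(grad, trait_landscapes))
    theta0 = float(sum(c * t.theta0 for c, t in zip(grad, trait_landscapes)))
    return AdditiveLandscape(theta0=theta0, theta=np.asarray(theta),
                             alphabet=alphabet)
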