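"""Ground-truth genotypic counts: exhaustive enumeration and certified bounds.

Two routes to the true density are provided.  ``enumerate_density`` computes
all C^L fitness values directly (feasible up to ~10^6 sequences) and returns
a Gaussian-kernel-smoothed log density — the kernel width stands in for the
finite precision of any real fitness measurement.  For larger landscapes,
``dp_count_bounds`` discretizes the per-position effects onto an integer
grid, rounding down for one pass and up for the other, and convolves exact
integer score distributions across positions.  Every sequence's total
rounding error is at most L*(grid width), so the two passes certify
lower/upper bounds on the number of sequences at or above any threshold.
``refine_bounds`` halves the grid width geometrically until the bounds agree
to a requested relative tolerance.

Counts are exact arbitrary-precision integers (at C=20, L=55 they reach
~10^71).  The per-position convolution is carried out via Kronecker
substitution: the count polynomial is packed into a single Python integer
with a fixed number of bits per coefficient, so each position costs C
shift-and-add operations on one big integer rather than a per-coefficient
Python loop.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .density import DensityCurve, _ref
from .landscape import AdditiveLandscape, summarize

__all__ = [
    "CountBounds",
    "enumerate_fitnesses",
    "enumerate_density",
    "dp_count_bounds",
    "refine_bounds",
]

logger = logging.getLogger(__name__)

ENUMERATION_BUDGET = 2**20


class EnumerationBudgetError(ValueError):
    """Landscape too large to enumerate; use dp_count_bounds instead."""


@dataclass(frozen=True)
class CountBounds:
    """Certified integer bounds on the number of sequences with f >= threshold."""

    threshold: float
    lower: int
    upper: int
    resolution: float
    converged: bool

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    @property
    def rel_gap(self) -> float:
        return (self.upper - self.lower) / max(self.lower, 1)


def enumerate_fitnesses(
    landscape: AdditiveLandscape, budget: int = ENUMERATION_BUDGET
) -> np.ndarray:
    """All C^L fitness values, sorted ascending."""
    L, C = landscape.L, landscape.C
    if C**L > budget:
        raise EnumerationBudgetError(
            f"C^L = {C}^{L} exceeds enumeration budget {budget}; "
            "use dp_count_bounds for certified counts"
        )
    vals = np.array([landscape.theta0])
    for row in landscape.theta:
        vals = (vals[:, None] + row[None, :]).ravel()
    vals.sort()
    return vals


def enumerate_density(
    landscape: AdditiveLandscape,
    kernel_sd: float | None = None,
    F_grid=None,
    n_grid: int = 512,
    budget: int = ENUMERATION_BUDGET,
) -> DensityCurve:
    """Kernel density estimate of rho(F) from exhaustive enumeration.

    ``kernel_sd`` defaults to (Fmax - Fmin)/1000.  The smoothed density is
    essentially independent of the kernel width provided it is much smaller
    than the fitness range and much larger than the spacing between extremal
    fitness values and their nearest neighbors; a warning is logged when the
    chosen width violates this.
    """
    s = summarize(landscape)
    vals = enumerate_fitnesses(landscape, budget=budget)
    R = s.Fmax - s.Fmin
    if kernel_sd is None:
        kernel_sd = R / 1000.0
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be positive")
    uniq = np.unique(vals)
    if uniq.size > 1:
        edge_gap = max(uniq[1] - uniq[0], uniq[-1] - uniq[-2])
        if not (edge_gap < kernel_sd < 0.1 * R):
            logger.warning(
                "kernel_sd=%.3g outside validity window (extremal gap %.3g, "
                "range %.3g); smoothed density may depend on the width",
                kernel_sd, edge_gap, R,
            )
    if F_grid is None:
        F_grid = np.linspace(s.Fmin, s.Fmax, n_grid)
    F = np.asarray(F_grid, dtype=float)
    # log sum over data points of the Gaussian kernel, chunked over the grid
    log_norm = -0.5 * np.log(2 * np.pi * kernel_sd**2)
    log_rho = np.empty_like(F)
    chunk = max(1, int(4e6 // max(vals.size, 1)))
    for i in range(0, F.size, chunk):
        d = (F[i : i + chunk, None] - vals[None, :]) / kernel_sd
        log_rho[i : i + chunk] = logsumexp(-0.5 * d * d, axis=1) + log_norm
    return DensityCurve(F, log_rho, (s.Fmax - F) / s.L, "exact", _ref(s))


# -- certified DP bounds ----------------------------------------------------


def _pack_counts(offsets_list: list[np.ndarray], bits: int) -> int:
    """Product over positions of sum_c z^offset, packed via z = 2**bits."""
    acc = 1
    for offsets in offsets_list:
        # multiply by the sparse per-position polynomial: C shifted adds
        counts: dict[int, int] = {}
        for off in offsets:
            counts[int(off)] = counts.get(int(off), 0) + 1
        new = 0
        for off, mult in counts.items():
            new += (acc << (off * bits)) * mult
        acc = new
    return acc


def _counts_from_packed(packed: int, bits: int) -> list[int]:
    """Unpack coefficient list (index = integer score) from a packed big int."""
    nbytes = bits // 8
    raw = packed.to_bytes((packed.bit_length() + 7) // 8 + nbytes, "little")
    ncoef = len(raw) // nbytes
    return [
        int.from_bytes(raw[i * nbytes : (i + 1) * nbytes], "little")
        for i in range(ncoef)
    ]


def _dp_pass(scaled: np.ndarray, threshold_scaled: int, bits: int) -> int:
    """Count sequences whose summed integer scores are >= threshold_scaled."""
    # shift each row so offsets are non-negative; track the total shift
    mins = scaled.min(axis=1)
    offsets = scaled - mins[:, None]
    base = int(mins.sum())
    # lattice landscapes put all scores on multiples of a common divisor;
    # dividing it out keeps the packed polynomial dense
    g = int(np.gcd.reduce(offsets.ravel()))
    if g > 1:
        offsets = offsets // g
    else:
        g = 1
    packed = _pack_counts(list(offsets), bits)
    coefs = _counts_from_packed(packed, bits)
    total = 0
    for score, count in enumerate(coefs):
        if count and score * g + base >= threshold_scaled:
            total += count
    return total


def dp_count_bounds(
    landscape: AdditiveLandscape, threshold: float, resolution: float
) -> CountBounds:
    """Certified bounds on #{x : f(x) >= threshold} at a given resolution.

    Per position, effects are rounded down (lower-bound pass) and up
    (upper-bound pass) to a grid of width resolution/L, so each sequence's
    total rounding error is below ``resolution``.  The lower bound counts
    only sequences guaranteed >= threshold; the upper bound counts every
    sequence that could possibly be.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    L, C = landscape.L, landscape.C
    h = resolution / L
    t = (threshold - landscape.theta0) / h
    bits = _coef_bits(L, C)
    floor_scaled = np.floor(landscape.theta / h).astype(np.int64)
    ceil_scaled = np.ceil(landscape.theta / h).astype(np.int64)
    # lower: floored totals underestimate true fitness, so score >= ceil(t)
    # guarantees true >= threshold
    lower = _dp_pass(floor_scaled, math.ceil(t), bits)
    # upper: ceiled totals overestimate, so any sequence with true >=
    # threshold has score >= t; counting score >= floor(t) is conservative
    upper = _dp_pass(ceil_scaled, math.floor(t), bits)
    if upper < lower:  # threshold in a gap resolved identically by both passes
        upper = lower
    return CountBounds(
        threshold=float(threshold),
        lower=lower,
        upper=upper,
        resolution=float(resolution),
        converged=lower == upper,
    )


def _coef_bits(L: int, C: int) -> int:
    # coefficients are bounded by C^L; pad and round up to whole bytes
    need = int(math.ceil(L * math.log2(C))) + 8
    return ((need + 7) // 8) * 8


def _dp_states(landscape: AdditiveLandscape, resolution: float) -> float:
    """Predicted total DP table size (number of integer-score slots)."""
    h = resolution / landscape.L
    spans = (landscape.theta.max(axis=1) - landscape.theta.min(axis=1)) / h
    return float(np.cumsum(spans + 1).sum())


def refine_bounds(
    landscape: AdditiveLandscape,
    threshold: float,
    rel_tol: float = 0.01,
    budget: int = 50_000_000,
    initial_resolution: float | None = None,
) -> CountBounds:
    """Halve the DP resolution until the bounds agree to ``rel_tol``.

    ``budget`` caps the total number of DP states across all refinement
    levels; the last certified bounds are returned with ``converged``
    indicating whether the tolerance was reached.  Refinement never loosens
    either bound.
    """
    if rel_tol <= 0:
        raise ValueError("rel_tol must be positive")
    s = summarize(landscape)
    R = max(s.Fmax - s.Fmin, 1e-12)
    res = initial_resolution if initial_resolution is not None else R / 8
    best_lower, best_upper = 0, None
    out = None
    spent = 0.0
    while True:
        spent += _dp_states(landscape, res)
        if out is not None and spent > budget:
            break
        b = dp_count_bounds(landscape, threshold, res)
        # nested grids make the raw bounds monotone; enforce it regardless
        best_lower = max(best_lower, b.lower)
        best_upper = b.upper if best_upper is None else min(best_upper, b.upper)
        out = CountBounds(
            threshold=float(threshold),
            lower=best_lower,
            upper=best_upper,
            resolution=res,
            converged=(best_upper - best_lower) / max(best_lower, 1) <= rel_tol,
        )
        if out.converged:
            break
        res /= 2.0
    return out
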