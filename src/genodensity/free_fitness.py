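"""Free fitness, tilted ensembles, and the saddle-condition solver.

The exponentially tilted distribution p_beta(x) ∝ exp(beta * f(x)) plays the
role of a canonical ensemble over sequence space (beta is an inverse
temperature; in weak-mutation population genetics beta = 2Ne).  Its log
normalizer, the free fitness

    Phi(beta) = log sum_x exp(beta f(x))
              = beta*theta0 + sum_l log sum_c exp(beta theta_lc),

is the cumulant-generating function of the fitness distribution: its first
two derivatives give the tilted mean mu_beta and variance sigma_beta^2.  For
additive landscapes everything factorizes over positions, so Phi and its
derivatives have closed forms in terms of per-position softmax weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

from .landscape import AdditiveLandscape, summarize

__all__ = ["TiltedEnsemble", "free_fitness", "deficit_contribution", "solve_beta"]


class SaddleDomainError(ValueError):
    """Requested fitness outside the achievable open interval (Fmin, Fmax)."""


@dataclass(frozen=True)
class TiltedEnsemble:
    """The tilted ensemble at a given inverse temperature.

    ``site_probs[l, c]`` is the marginal probability of character ``c`` at
    position ``l`` under p_beta; ``mu`` and ``sigma2`` are the tilted mean and
    variance of fitness (Phi'(beta) and Phi''(beta)).
    """

    beta: float
    phi: float
    mu: float
    sigma2: float
    site_probs: np.ndarray


def free_fitness(landscape: AdditiveLandscape, beta: float) -> TiltedEnsemble:
    """Closed-form Phi(beta), mu_beta, sigma_beta^2 and site marginals.

    Uses max-subtraction (logsumexp / softmax) throughout, so large |beta|
    values are overflow-safe.
    """
    beta = float(beta)
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    theta = landscape.theta
    z = beta * theta
    phi = beta * landscape.theta0 + logsumexp(z, axis=1).sum()
    w = softmax(z, axis=1)
    row_mean = (theta * w).sum(axis=1)
    row_mean2 = (theta**2 * w).sum(axis=1)
    mu = landscape.theta0 + row_mean.sum()
    sigma2 = float(np.maximum(row_mean2 - row_mean**2, 0.0).sum())
    return TiltedEnsemble(
        beta=beta, phi=float(phi), mu=float(mu), sigma2=sigma2, site_probs=w
    )


def deficit_contribution(landscape: AdditiveLandscape, beta: float) -> float:
    """Per-site deficit contribution E(beta).

    E(beta) = (1/L) sum_l log(1 + sum_{c != c_l^max} exp(-beta * delta_lc))
    with delta_lc = theta_l^max - theta_lc, so that
    Phi(beta) = beta * Fmax + L * E(beta).  As beta -> infinity E(beta)
    approaches log(n_ties)/L (zero for a unique optimum).
    """
    theta = landscape.theta
    deltas = theta.max(axis=1, keepdims=True) - theta  # one zero per row
    # log(1 + sum_{c != cmax} e^{-beta delta}) == logsumexp over all c of
    # -beta*delta, since the optimal character contributes e^0 = 1.  With
    # ties, extra zero deltas are genuine terms of the sum.
    per_site = logsumexp(-beta * deltas, axis=1)
    return float(per_site.sum() / landscape.L)


def solve_beta(
    landscape: AdditiveLandscape,
    F: float,
    rtol: float = 1e-10,
    beta0: float = 0.0,
    max_iter: int = 200,
) -> TiltedEnsemble:
    """Solve the saddle condition mu_beta = F for beta.

    Safeguarded Newton on the monotone map beta -> Phi'(beta), started at
    ``beta0`` with geometric bracket expansion and bisection fallback.  The
    returned ensemble satisfies |mu - F| <= rtol * (Fmax - Fmean).

    Raises
    ------
    SaddleDomainError
        If F lies outside the open achievable interval (Fmin, Fmax), or the
        landscape is fully degenerate.
    """
    s = summarize(landscape)
    if s.sigma_bulk2 <= 0:
        raise SaddleDomainError("fully degenerate landscape: all positions flat")
    if not (s.Fmin < F < s.Fmax):
        raise SaddleDomainError(
            f"F={F} outside achievable open interval ({s.Fmin}, {s.Fmax})"
        )
    scale = s.Fmax - s.Fmean
    tol = rtol * scale

    pos_deltas = s.deltas[s.deltas > 0]
    beta_cap = 1e6 / np.median(pos_deltas) if pos_deltas.size else 1e6

    ens = free_fitness(landscape, beta0)
    if abs(ens.mu - F) <= tol:
        return ens

    # bracket the root by geometric expansion around beta0
    lo, hi = beta0, beta0
    ens_lo = ens_hi = ens
    step = 1.0
    while ens_hi.mu < F:
        lo, ens_lo = hi, ens_hi
        hi = hi + step
        step *= 2.0
        if hi > beta_cap:
            raise SaddleDomainError(
                f"F={F} too close to Fmax={s.Fmax}: required beta exceeds cap"
            )
        ens_hi = free_fitness(landscape, hi)
    while ens_lo.mu > F:
        hi, ens_hi = lo, ens_lo
        lo = lo - step
        step *= 2.0
        if lo < -beta_cap:
            raise SaddleDomainError(
                f"F={F} too close to Fmin={s.Fmin}: required beta exceeds cap"
            )
        ens_lo = free_fitness(landscape, lo)

    beta = ens.beta if lo <= ens.beta <= hi else 0.5 * (lo + hi)
    for _ in range(max_iter):
        ens = free_fitness(landscape, beta)
        err = ens.mu - F
        if abs(err) <= tol:
            return ens
        if err > 0:
            hi = beta
        else:
            lo = beta
        if ens.sigma2 > 0:
            beta_new = beta - err / ens.sigma2
        else:
            beta_new = np.nan
        if not np.isfinite(beta_new) or not (lo < beta_new < hi):
            beta_new = 0.5 * (lo + hi)  # bisection fallback
        beta = beta_new
    # monotone map + bisection fallback: reaching here means tol is at
    # floating-point resolution; return the best bracket midpoint
    return free_fitness(landscape, 0.5 * (lo + hi))
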