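"""Genotypic density approximations: bulk Gaussian, tilted, and saddle-point.

The genotypic density rho(F) counts sequences per unit fitness.  Three smooth
approximations are provided:

* ``rho_bulk`` — the central-limit Gaussian, accurate in the bulk of the
  fitness distribution but badly inflated near the peak;
* ``rho_tilted`` — the density implied by a fixed-beta tilted ensemble;
* ``rho_saddle`` — the saddle-point approximation, which re-solves beta at
  every target fitness so the tilted mean equals F.  It is accurate over
  essentially the whole achievable range.

All densities are computed and stored in natural-log space; C^L overflows
floats at modest L, so raw rho values are never formed internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .free_fitness import SaddleDomainError, free_fitness, solve_beta
from .landscape import AdditiveLandscape, summarize

__all__ = [
    "DensityCurve",
    "rho_bulk",
    "rho_tilted",
    "rho_saddle",
    "rho_saddle_multi",
    "default_grid",
]


@dataclass(frozen=True)
class DensityCurve:
    """Log genotypic density evaluated on an ascending fitness grid.

    ``eps`` is the per-site fitness deficit (Fmax - F)/L at each grid point.
    ``landscape_ref`` snapshots (L, C, Fmax, Fmean) of the source landscape.
    """

    F: np.ndarray
    log_rho: np.ndarray
    eps: np.ndarray
    method: str
    landscape_ref: dict

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        log_rho = np.asarray(self.log_rho, dtype=float)
        eps = np.asarray(self.eps, dtype=float)
        if not np.all(np.diff(F) > 0):
            raise ValueError("fitness grid must be strictly ascending")
        if not np.all(np.isfinite(log_rho)):
            raise ValueError("log_rho must be finite at every retained point")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "log_rho", log_rho)
        object.__setattr__(self, "eps", eps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"F": self.F, "eps": self.eps, "log_rho": self.log_rho,
             "method": self.method}
        )

    def to_tsv(self, path) -> None:
        ref = self.landscape_ref
        with open(path, "w") as fh:
            fh.write(
                "#landscape L={L} C={C} Fmax={Fmax!r} Fmean={Fmean!r}\n".format(**ref)
            )
            self.to_frame().to_csv(fh, sep="\t", index=False)


def _ref(summary) -> dict:
    return {
        "L": summary.L,
        "C": summary.C,
        "Fmax": summary.Fmax,
        "Fmean": summary.Fmean,
    }


def default_grid(landscape: AdditiveLandscape, n: int = 512,
                 margin: float = 1e-4) -> np.ndarray:
    """Default fitness grid: n points inside [Fmin + m*R, Fmax - m*R]."""
    s = summarize(landscape)
    R = s.Fmax - s.Fmin
    return np.linspace(s.Fmin + margin * R, s.Fmax - margin * R, n)


def rho_bulk(landscape: AdditiveLandscape, F_grid) -> DensityCurve:
    """Central-limit Gaussian density: C^L * Normal(Fmean, sigma_bulk2)."""
    s = summarize(landscape)
    if s.sigma_bulk2 <= 0:
        raise ValueError("degenerate landscape: sigma_bulk2 = 0")
    F = np.asarray(F_grid, dtype=float)
    log_rho = (
        s.L * np.log(s.C)
        - 0.5 * np.log(2 * np.pi * s.sigma_bulk2)
        - (F - s.Fmean) ** 2 / (2 * s.sigma_bulk2)
    )
    return DensityCurve(F, log_rho, (s.Fmax - F) / s.L, "bulk", _ref(s))


def rho_tilted(landscape: AdditiveLandscape, F_grid, beta: float) -> DensityCurve:
    """Density implied by the tilted Gaussian at one fixed beta."""
    ens = free_fitness(landscape, beta)
    if ens.sigma2 <= 0:
        raise ValueError("tilted variance is zero; landscape degenerate at this beta")
    s = summarize(landscape)
    F = np.asarray(F_grid, dtype=float)
    log_rho = (
        ens.phi - beta * F
        - 0.5 * np.log(2 * np.pi * ens.sigma2)
        - (F - ens.mu) ** 2 / (2 * ens.sigma2)
    )
    return DensityCurve(F, log_rho, (s.Fmax - F) / s.L, "tilted", _ref(s))


def rho_saddle(landscape: AdditiveLandscape, F_grid,
               rtol: float = 1e-10) -> DensityCurve:
    """Saddle-point density: beta chosen per grid point so mu_beta = F.

    Grid points are processed in ascending order and each beta solve is
    warm-started from the previous one.  All F must lie strictly inside
    (Fmin, Fmax).
    """
    s = summarize(landscape)
    F = np.asarray(F_grid, dtype=float)
    log_rho = np.empty_like(F)
    beta = 0.0
    for i, Fi in enumerate(F):
        ens = solve_beta(landscape, Fi, rtol=rtol, beta0=beta)
        beta = ens.beta
        log_rho[i] = ens.phi - beta * Fi - 0.5 * np.log(2 * np.pi * ens.sigma2)
    return DensityCurve(F, log_rho, (s.Fmax - F) / s.L, "saddle", _ref(s))


def rho_saddle_multi(
    traits: list[AdditiveLandscape],
    phi_target,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> float:
    """Joint saddle-point log density for K additive traits sharing positions.

    Solves grad Phi(beta_vec) = phi_target by Newton iteration.  The tilted
    exponent beta·phi(x) is itself additive with effective per-position
    effects theta~_lc = sum_k beta_k theta^k_lc, so Phi factorizes over
    positions; the Hessian is the summed per-position tilted covariance of
    the trait effects and is positive definite for non-degenerate traits.

    Returns the scalar log rho at ``phi_target``; reduces to the single-trait
    saddle-point density when K = 1.
    """
    K = len(traits)
    if K < 1:
        raise ValueError("need at least one trait")
    L, C = traits[0].L, traits[0].C
    alphabet = traits[0].alphabet
    for t in traits[1:]:
        if t.L != L or t.alphabet != alphabet:
            raise ValueError("traits must share L and alphabet")
    phi_target = np.asarray(phi_target, dtype=float)
    if phi_target.shape != (K,):
        raise ValueError(f"phi_target must have shape ({K},)")

    # conservative polytope check: each component within its own open range
    for k, t in enumerate(traits):
        sk = summarize(t)
        if not (sk.Fmin < phi_target[k] < sk.Fmax):
            raise SaddleDomainError(
                f"trait {k} target {phi_target[k]} outside ({sk.Fmin}, {sk.Fmax})"
            )

    th = np.stack([t.theta for t in traits])          # (K, L, C)
    th0 = np.array([t.theta0 for t in traits])        # (K,)

    def pieces(beta):
        z = np.tensordot(beta, th, axes=1)            # (L, C)
        zmax = z.max(axis=1, keepdims=True)
        ez = np.exp(z - zmax)
        w = ez / ez.sum(axis=1, keepdims=True)        # (L, C)
        phi_val = float(
            beta @ th0 + (np.log(ez.sum(axis=1)) + zmax[:, 0]).sum()
        )
        return phi_val, w

    # Newton with backtracking on the convex dual f(beta) = Phi - beta.phi,
    # whose unique minimum sits at the saddle condition grad Phi = phi
    beta = np.zeros(K)
    phi_val, w = pieces(beta)
    fval = phi_val - beta @ phi_target
    for _ in range(max_iter):
        mean_k = np.einsum("klc,lc->kl", th, w)       # (K, L)
        mu = th0 + mean_k.sum(axis=1)
        grad = mu - phi_target
        # per-position covariance of trait effects under w, summed over l
        cross = np.einsum("jlc,klc,lc->jk", th, th, w)
        hess = cross - np.einsum("jl,kl->jk", mean_k, mean_k)
        if np.max(np.abs(grad)) <= tol * max(1.0, np.max(np.abs(phi_target))):
            sign, logdet = np.linalg.slogdet(hess)
            if sign <= 0:
                raise np.linalg.LinAlgError("Hessian not positive definite")
            return float(
                phi_val - beta @ phi_target
                - 0.5 * K * np.log(2 * np.pi) - 0.5 * logdet
            )
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular Hessian in multi-trait Newton; trait targets may be "
                "too close to the polytope boundary"
            ) from exc
        slope = -float(grad @ step)
        t = 1.0
        for _ in range(60):
            cand = beta - t * step
            phi_cand, w_cand = pieces(cand)
            f_cand = phi_cand - cand @ phi_target
            if f_cand <= fval + 0.25 * t * slope:
                break
            t *= 0.5
        else:
            # the dual has no stationary point when the target lies outside
            # the joint achievable region (the per-component check is only
            # conservative); beta then diverges and descent stalls
            raise SaddleDomainError(
                "multi-trait Newton stalled: phi_target appears to lie "
                "outside the jointly achievable trait region"
            )
        beta, phi_val, w, fval = cand, phi_cand, w_cand, f_cand
    raise RuntimeError(
        f"multi-trait Newton failed to converge in {max_iter} iterations"
    )
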