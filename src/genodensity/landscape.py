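"""Additive (Mount Fuji) fitness landscapes: data model, summaries, generators, I/O.

An additive landscape assigns to each sequence x of length ``L`` over an
alphabet of ``C`` characters the fitness

    f(x) = theta0 + sum_l theta[l, x_l],

where ``theta[l, c]`` is the effect of character ``c`` at position ``l``.
All downstream machinery (free fitness, saddle-point densities, near-peak
scaling) operates on this model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AdditiveLandscape",
    "LandscapeSummary",
    "summarize",
    "zscore_normalize",
    "generate_iid",
    "generate_binary_from_gaps",
    "read_matrix",
    "write_matrix",
]


class LandscapeError(ValueError):
    """Invalid landscape, sequence, or matrix-file input."""


@dataclass(frozen=True)
class AdditiveLandscape:
    """Additive fitness landscape parameters.

    Parameters
    ----------
    theta0
        Baseline fitness (arbitrary units).
    theta
        ``(L, C)`` matrix of additive effects, one row per position.
    alphabet
        Ordered character labels, one per column of ``theta``.
    """

    theta0: float
    theta: np.ndarray
    alphabet: tuple[str, ...]

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.ndim != 2:
            raise LandscapeError("theta must be a 2-D (L x C) matrix")
        if not np.all(np.isfinite(theta)):
            raise LandscapeError("theta contains non-finite values")
        alphabet = tuple(str(a) for a in self.alphabet)
        if theta.shape[1] != len(alphabet):
            raise LandscapeError(
                f"theta has {theta.shape[1]} columns but alphabet has "
                f"{len(alphabet)} characters"
            )
        if len(set(alphabet)) != len(alphabet):
            raise LandscapeError("alphabet labels must be unique")
        if theta.shape[0] < 1 or theta.shape[1] < 2:
            raise LandscapeError("need L >= 1 positions and C >= 2 characters")
        theta.setflags(write=False)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "alphabet", alphabet)
        object.__setattr__(self, "theta0", float(self.theta0))

    @property
    def L(self) -> int:
        return self.theta.shape[0]

    @property
    def C(self) -> int:
        return self.theta.shape[1]

    @property
    def char_index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.alphabet)}

    # -- evaluation ---------------------------------------------------------

    def encode(self, sequence: str) -> np.ndarray:
        """Map a sequence to its per-position column indices."""
        seq = list(sequence)
        if len(seq) != self.L:
            raise LandscapeError(
                f"sequence has length {len(seq)}, expected L={self.L}"
            )
        idx = self.char_index
        out = np.empty(self.L, dtype=np.intp)
        for l, ch in enumerate(seq):
            try:
                out[l] = idx[ch]
            except KeyError:
                raise LandscapeError(
                    f"unknown character {ch!r} at position {l}"
                ) from None
        return out

    def fitness(self, sequence) -> float:
        """Fitness of a single sequence (string or index array)."""
        if isinstance(sequence, str) or (
            len(sequence) > 0 and isinstance(sequence[0], str)
        ):
            idx = self.encode(sequence)
        else:
            idx = np.asarray(sequence, dtype=np.intp)
            if idx.shape != (self.L,):
                raise LandscapeError(
                    f"index sequence has shape {idx.shape}, expected ({self.L},)"
                )
        return float(self.theta0 + self.theta[np.arange(self.L), idx].sum())


def fitness(landscape: AdditiveLandscape, sequence) -> float:
    return landscape.fitness(sequence)


@dataclass(frozen=True)
class LandscapeSummary:
    """Derived summary quantities of an additive landscape.

    ``deltas[l, c]`` is the per-position deficit ``theta_l^max - theta_lc``
    (zero for each position's optimal character); ``runner_up_gaps[l]`` is the
    gap between the best and second-best effect at position ``l`` (zero when
    the top two tie).  ``sigma_bulk2`` is the fitness variance under uniform
    random sequences.
    """

    Fmax: float
    Fmin: float
    Fmean: float
    sigma_bulk2: float
    deltas: np.ndarray
    runner_up_gaps: np.ndarray
    xmax: str
    n_ties: int
    L: int
    C: int


def summarize(landscape: AdditiveLandscape, tie_tol: float = 0.0) -> LandscapeSummary:
    """Compute max/min/mean fitness, bulk variance, deficits and gaps.

    ``tie_tol`` is the absolute tolerance for counting characters tied for a
    position's maximum (used only for ``n_ties`` and ``xmax``).
    """
    theta = landscape.theta
    row_max = theta.max(axis=1)
    row_min = theta.min(axis=1)
    deltas = row_max[:, None] - theta
    # second-largest per row (ties for the top give a zero gap)
    part = np.partition(theta, theta.shape[1] - 2, axis=1)
    second = part[:, -2]
    gaps = row_max - second
    Fmax = landscape.theta0 + row_max.sum()
    Fmin = landscape.theta0 + row_min.sum()
    Fmean = landscape.theta0 + theta.mean(axis=1).sum()
    sigma_bulk2 = theta.var(axis=1).sum()
    ties_per_pos = (deltas <= tie_tol).sum(axis=1)
    n_ties = int(np.prod(ties_per_pos.astype(object)))
    xmax = "".join(landscape.alphabet[c] for c in theta.argmax(axis=1))
    return LandscapeSummary(
        Fmax=float(Fmax),
        Fmin=float(Fmin),
        Fmean=float(Fmean),
        sigma_bulk2=float(sigma_bulk2),
        deltas=deltas,
        runner_up_gaps=gaps,
        xmax=xmax,
        n_ties=n_ties,
        L=landscape.L,
        C=landscape.C,
    )


def zscore_normalize(landscape: AdditiveLandscape) -> AdditiveLandscape:
    """Affinely rescale so random sequences have zero mean and unit variance.

    Shifts ``theta0`` and uniformly scales all effects; fitness ranks of all
    sequences are preserved.
    """
    s = summarize(landscape)
    if s.sigma_bulk2 <= 0:
        raise LandscapeError("degenerate landscape: sigma_bulk2 = 0")
    # fitness maps as (f - Fmean)/sd; theta0 absorbs the shift
    scale = 1.0 / np.sqrt(s.sigma_bulk2)
    theta = landscape.theta * scale
    theta0 = (landscape.theta0 - s.Fmean) * scale
    return AdditiveLandscape(theta0=theta0, theta=theta, alphabet=landscape.alphabet)


# -- generators -------------------------------------------------------------

_DNA = ("A", "C", "G", "T")
_PROTEIN = tuple("ACDEFGHIKLMNPQRSTVWY")


def default_alphabet(C: int) -> tuple[str, ...]:
    if C == 4:
        return _DNA
    if C == 20:
        return _PROTEIN
    if C <= 26:
        return tuple(chr(ord("a") + i) for i in range(C))
    return tuple(f"c{i}" for i in range(C))


def generate_iid(
    L: int,
    C: int,
    effect_dist: str = "normal",
    params: tuple[float, ...] = (0.0, 1.0),
    seed: int = 0,
) -> AdditiveLandscape:
    """Landscape with i.i.d. per-position effects.

    ``effect_dist`` is one of ``normal`` (loc, scale), ``uniform`` (low, high)
    or ``exponential`` (scale).  ``theta0`` is zero; results are reproducible
    for a given ``seed``.
    """
    if L < 1 or C < 2:
        raise LandscapeError("need L >= 1 and C >= 2")
    rng = np.random.default_rng(seed)
    if effect_dist == "normal":
        loc, scale = params
        theta = rng.normal(loc, scale, size=(L, C))
    elif effect_dist == "uniform":
        low, high = params
        theta = rng.uniform(low, high, size=(L, C))
    elif effect_dist == "exponential":
        (scale,) = params
        theta = rng.exponential(scale, size=(L, C))
    else:
        raise LandscapeError(f"unsupported effect distribution {effect_dist!r}")
    return AdditiveLandscape(theta0=0.0, theta=theta, alphabet=default_alphabet(C))


def generate_binary_from_gaps(
    L: int,
    gap_spec: dict | None = None,
    seed: int = 0,
) -> AdditiveLandscape:
    """Binary landscape with per-position gaps from a specified distribution.

    Position ``l`` gets effects ``[0, -Delta_l]``.  ``gap_spec`` is one of::

        {"kind": "power_law", "gamma": g, "scale": s}   # p(D) ~ D^g on (0, s]
        {"kind": "fixed", "delta0": d}                  # Hamming landscape
        {"kind": "explicit", "gaps": [...]}

    Power-law gaps use inverse-CDF sampling ``Delta = s * U**(1/(1+g))``;
    ``gamma`` must exceed -1 for the density to be normalizable.  The fixed
    spec reproduces the Berg–von Hippel Hamming-distance landscape, where
    every mutation off the optimum costs the same deficit.
    """
    gap_spec = dict(gap_spec or {"kind": "power_law", "gamma": 0.0, "scale": 1.0})
    kind = gap_spec.pop("kind")
    if kind == "power_law":
        gamma = float(gap_spec["gamma"])
        scale = float(gap_spec.get("scale", 1.0))
        if gamma <= -1.0:
            raise LandscapeError(
                f"gap density ~ Delta^{gamma} is not normalizable (need gamma > -1)"
            )
        rng = np.random.default_rng(seed)
        u = rng.random(L)
        gaps = scale * u ** (1.0 / (1.0 + gamma))
    elif kind == "fixed":
        delta0 = float(gap_spec["delta0"])
        if delta0 <= 0:
            raise LandscapeError("fixed gap delta0 must be positive")
        gaps = np.full(L, delta0)
    elif kind == "explicit":
        gaps = np.asarray(gap_spec["gaps"], dtype=float)
        if gaps.shape != (L,):
            raise LandscapeError("explicit gap list must have length L")
    else:
        raise LandscapeError(f"unknown gap spec kind {kind!r}")
    theta = np.zeros((L, 2))
    theta[:, 1] = -gaps
    return AdditiveLandscape(theta0=0.0, theta=theta, alphabet=("0", "1"))


# -- I/O --------------------------------------------------------------------


def write_matrix(landscape: AdditiveLandscape, path, format: str = "tsv") -> None:
    """Write a landscape matrix; TSV is the canonical interchange format."""
    if format != "tsv":
        raise LandscapeError(f"unsupported write format {format!r}")
    with open(path, "w") as fh:
        fh.write(f"#theta0={landscape.theta0!r}\n")
        fh.write("\t".join(landscape.alphabet) + "\n")
        for row in landscape.theta:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix(path, format: str = "tsv", pseudocount: float = 1e-4) -> AdditiveLandscape:
    """Read a landscape from TSV or a minimal MEME motif file.

    MEME letter probabilities are converted to effects via
    ``theta_lc = log(p_lc + pseudocount)``.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "meme":
        return _read_meme(path, pseudocount)
    raise LandscapeError(f"unknown format {format!r}")


def _read_tsv(path) -> AdditiveLandscape:
    theta0 = 0.0
    alphabet: tuple[str, ...] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#theta0="):
                    try:
                        theta0 = float(line.split("=", 1)[1])
                    except ValueError:
                        raise LandscapeError(
                            f"{path}:{lineno}: bad theta0 value"
                        ) from None
                continue
            cells = line.split("\t")
            if alphabet is None:
                alphabet = tuple(cells)
                continue
            if len(cells) != len(alphabet):
                raise LandscapeError(
                    f"{path}:{lineno}: row has {len(cells)} cells, "
                    f"expected {len(alphabet)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                raise LandscapeError(
                    f"{path}:{lineno}: non-numeric cell"
                ) from None
    if alphabet is None or not rows:
        raise LandscapeError(f"{path}: no matrix data found")
    return AdditiveLandscape(theta0=theta0, theta=np.array(rows), alphabet=alphabet)


def _read_meme(path, pseudocount: float) -> AdditiveLandscape:
    alphabet: tuple[str, ...] | None = None
    rows: list[list[float]] = []
    in_matrix = False
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("ALPHABET="):
                alphabet = tuple(stripped.split("=", 1)[1].strip())
            elif stripped.startswith("letter-probability matrix"):
                in_matrix = True
                if "alength=" in stripped:
                    ncols = int(stripped.split("alength=")[1].split()[0])
            elif in_matrix:
                if not stripped:
                    in_matrix = False
                    continue
                try:
                    vals = [float(v) for v in stripped.split()]
                except ValueError:
                    in_matrix = False
                    continue
                if ncols is not None and len(vals) != ncols:
                    raise LandscapeError(
                        f"{path}:{lineno}: matrix row has {len(vals)} values, "
                        f"expected alength={ncols}"
                    )
                rows.append(vals)
    if not rows:
        raise LandscapeError(f"{path}: no letter-probability matrix found")
    probs = np.array(rows)
    if alphabet is None:
        alphabet = default_alphabet(probs.shape[1])
    theta = np.log(probs + pseudocount)
    return AdditiveLandscape(theta0=0.0, theta=theta, alphabet=alphabet)
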