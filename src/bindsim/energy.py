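"""Additive binding-energy models and Fermi-Dirac occupancy.

A transcription factor's intrinsic specificity is represented by an additive
energy matrix: each base ``b`` at each position ``j`` of an ``m``-long site
contributes an energy ``eps(b, j)`` (in units of kT), and the total binding
energy of a site is the sum over positions plus a scalar offset.  Columns are
kept in the Berg-von-Hippel zero gauge (the preferred base of every column has
energy 0), so the preferred site has energy equal to the offset.

Occupancy follows the two-state equilibrium: a site with energy ``E`` is bound
with probability ``1 / (1 + exp(E - mu))`` where ``mu = ln[TF]`` is the
chemical potential of the free protein.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: largest motif length for which the full 4**m landscape is enumerated
MAX_ENUM_LENGTH = 12

#: absolute tolerance for the per-column zero-gauge check
GAUGE_TOL = 1e-9


class InvalidConfigError(ValueError):
    """Raised for generator configurations that cannot be sampled."""


def seq_to_indices(seq) -> np.ndarray:
    """Convert a DNA string (or index array) to a base-index array.

    A=0, C=1, G=2, T=3.  Index arrays are validated and passed through.
    """
    if isinstance(seq, str):
        try:
            return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.uint8)
        except KeyError as exc:
            raise ValueError(f"invalid base {exc.args[0]!r} in sequence {seq!r}") from exc
    arr = np.asarray(seq)
    if arr.ndim != 1 or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("sequence must be a DNA string or 1-D integer array")
    if arr.size and (arr.min() < 0 or arr.max() > 3):
        raise ValueError("base indices must lie in 0..3 (A,C,G,T)")
    return arr.astype(np.uint8)


def indices_to_seq(idx: np.ndarray) -> str:
    """Inverse of :func:`seq_to_indices`."""
    return "".join(BASES[i] for i in np.asarray(idx))


@dataclass(frozen=True)
class EnergyMatrix:
    """Per-base, per-position binding-energy contributions in kT.

    Parameters
    ----------
    eps
        Array of shape ``(4, m)``; rows are A, C, G, T.  Every column must
        have minimum 0 (zero gauge).
    offset
        Scalar energy E0 added to every sequence energy; the energy of the
        per-column preferred sequence.
    """

    eps: np.ndarray
    offset: float = 0.0

    def __post_init__(self):
        eps = np.asarray(self.eps, dtype=float)
        if eps.ndim != 2 or eps.shape[0] != 4 or eps.shape[1] < 1:
            raise ValueError("energy matrix must have shape (4, m) with m >= 1")
        if not np.all(np.isfinite(eps)) or not np.isfinite(self.offset):
            raise ValueError("energy matrix entries and offset must be finite")
        if np.any(np.abs(eps.min(axis=0)) > GAUGE_TOL):
            raise ValueError(
                "energy matrix violates the zero gauge (some column minimum != 0); "
                "use EnergyMatrix.from_array(..., regauge=True)"
            )
        object.__setattr__(self, "eps", eps)
        object.__setattr__(self, "offset", float(self.offset))

    @classmethod
    def from_array(cls, eps, offset: float = 0.0, regauge: bool = False) -> "EnergyMatrix":
        """Build a matrix, optionally shifting column minima into the offset."""
        eps = np.asarray(eps, dtype=float)
        if regauge:
            mins = eps.min(axis=0)
            eps = eps - mins
            offset = float(offset + mins.sum())
        return cls(eps, offset)

    @property
    def m(self) -> int:
        return self.eps.shape[1]

    def preferred_sequence(self) -> str:
        """Lowest-energy site; per-column ties resolved by alphabet order."""
        return indices_to_seq(self.eps.argmin(axis=0))

    def energies(self, seqs: np.ndarray) -> np.ndarray:
        """Vectorized total energies for an ``(n, m)`` array of base indices."""
        seqs = np.atleast_2d(np.asarray(seqs))
        if seqs.shape[1] != self.m:
            raise ValueError(f"sequences have length {seqs.shape[1]}, model expects {self.m}")
        return self.offset + self.eps[seqs, np.arange(self.m)].sum(axis=1)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random energy-matrix generator.

    Non-preferred bases draw energies from a normal distribution with the
    given mean and sd (kT), truncated to strictly positive values so the
    randomly chosen preferred base (energy 0) stays the column minimum.
    """

    m: int
    energy_mean: float = 2.5
    energy_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if int(self.m) < 1:
            raise InvalidConfigError(f"motif length m must be >= 1, got {self.m}")
        if self.energy_sd < 0:
            raise InvalidConfigError(f"energy_sd must be >= 0, got {self.energy_sd}")


def random_energy_matrix(config: GeneratorConfig, rng: np.random.Generator | None = None) -> EnergyMatrix:
    """Draw a random zero-gauge energy matrix.

    One base per column is chosen uniformly as the preferred base (energy 0);
    the other three draw independently from N(mean, sd) truncated to positive
    values (negative/zero draws are redrawn).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = int(config.m)
    eps = np.zeros((4, m))
    preferred = rng.integers(0, 4, size=m)
    mask = np.ones((4, m), dtype=bool)
    mask[preferred, np.arange(m)] = False
    n_draw = int(mask.sum())
    draws = rng.normal(config.energy_mean, config.energy_sd, size=n_draw)
    if config.energy_sd > 0:
        bad = draws <= 0
        while bad.any():
            draws[bad] = rng.normal(config.energy_mean, config.energy_sd, size=int(bad.sum()))
            bad = draws <= 0
    elif config.energy_mean <= 0:
        raise InvalidConfigError("energy_mean must be positive when energy_sd is 0")
    eps[mask] = draws
    return EnergyMatrix(eps)


def sequence_energy(model: EnergyMatrix, seq) -> float:
    """Total binding energy of one site: ``E0 + sum_j eps(seq[j], j)``."""
    idx = seq_to_indices(seq)
    if idx.size != model.m:
        raise ValueError(f"sequence length {idx.size} does not match model length {model.m}")
    return float(model.offset + model.eps[idx, np.arange(model.m)].sum())


def occupancy(E, mu):
    """Equilibrium binding probability ``1 / (1 + exp(E - mu))``.

    Accepts scalars or arrays; strictly decreasing in E, increasing in mu.
    """
    E = np.asarray(E, dtype=float)
    out = expit(np.asarray(mu, dtype=float) - E)
    return float(out) if out.ndim == 0 else out


def mutate_probability(p, dE, mu=0.0):
    """Binding probability after changing a site's energy by ``dE`` kT.

    Inverts the occupancy relation at chemical potential ``mu`` to recover the
    site energy, adds ``dE``, and re-applies it.  The chemical potential
    cancels exactly: the result equals ``expit(logit(p) - dE)`` for any mu.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("binding probability must lie strictly in (0, 1)")
    E = np.asarray(mu, dtype=float) - logit(p)
    return occupancy(E + dE, mu)


@dataclass(frozen=True)
class BindingLandscape:
    """All ``4**m`` sites of a model with energies and occupancies at one mu."""

    model: EnergyMatrix
    mu: float
    seqs: np.ndarray = field(repr=False)      # (4**m, m) uint8, lexicographic
    energies: np.ndarray = field(repr=False)  # kT
    occupancies: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.seqs.shape[0]

    @property
    def affinities(self) -> np.ndarray:
        return np.exp(-self.energies)

    def sequence_strings(self) -> list[str]:
        return [indices_to_seq(row) for row in self.seqs]

    def with_mu(self, mu: float) -> "BindingLandscape":
        """Same energies re-occupied at a different chemical potential."""
        return dataclasses.replace(self, mu=float(mu), occupancies=occupancy(self.energies, mu))


def all_sequences(m: int) -> np.ndarray:
    """All 4**m base-index rows in lexicographic order (A<C<G<T)."""
    if m > MAX_ENUM_LENGTH:
        raise ValueError(
            f"refusing to enumerate 4**{m} sequences; the enumeration guard is m <= {MAX_ENUM_LENGTH}"
        )
    idx = np.arange(4**m)
    shifts = 2 * np.arange(m - 1, -1, -1)  # leftmost position most significant
    return ((idx[:, None] >> shifts) & 3).astype(np.uint8)


def enumerate_landscape(model: EnergyMatrix, mu: float) -> BindingLandscape:
    """Enumerate every site of the model with its energy and occupancy."""
    seqs = all_sequences(model.m)
    E = model.energies(seqs)
    return BindingLandscape(model=model, mu=float(mu), seqs=seqs, energies=E, occupancies=occupancy(E, mu))
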