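"""Probabilistic (position-probability) models of binding specificity.

A probabilistic model PM(b, j) gives the probability of base b at position j
of a bound site, with positions assumed independent, so the model probability
of a site is the product of its per-position entries.  PMs are estimated from
samples of sites — optionally weighted by occupancy — and can be converted to
a log-odds weight matrix against a background base distribution, or
summarized by per-column information content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyMatrix, seq_to_indices

UNIFORM_BACKGROUND = np.full(4, 0.25)


class EstimationError(ValueError):
    """Raised when a probability matrix cannot be estimated from a sample."""


@dataclass(frozen=True)
class SiteSample:
    """A set of equal-length sites with optional nonnegative weights."""

    seqs: np.ndarray  # (n, m) uint8 base indices
    weights: np.ndarray | None = None

    def __post_init__(self):
        seqs = np.atleast_2d(np.asarray(self.seqs, dtype=np.uint8))
        object.__setattr__(self, "seqs", seqs)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (seqs.shape[0],):
                raise ValueError("weights must be one value per sequence")
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
            object.__setattr__(self, "weights", w)

    @classmethod
    def from_strings(cls, seqs, weights=None) -> "SiteSample":
        return cls(np.array([seq_to_indices(s) for s in seqs]), weights)

    @property
    def n(self) -> int:
        return self.seqs.shape[0]

    @property
    def m(self) -> int:
        return self.seqs.shape[1]

    def unweighted(self) -> "SiteSample":
        return SiteSample(self.seqs, None)


@dataclass(frozen=True)
class ProbabilityMatrix:
    """Per-position base probabilities with a background distribution."""

    probs: np.ndarray  # (4, m); rows A, C, G, T; columns sum to 1
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError("probability matrix must have shape (4, m)")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if np.any(np.abs(probs.sum(axis=0) - 1) > 1e-12):
            raise ValueError("probability-matrix columns must each sum to 1")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1) > 1e-12:
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    @property
    def m(self) -> int:
        return self.probs.shape[1]


def estimate_pm(sample: SiteSample, pseudoweight: float = 0.0) -> ProbabilityMatrix:
    """Estimate a probability matrix from a (possibly weighted) site sample.

    ``PM(b, j) = [pseudoweight/4 + sum_i w_i S_i(b, j)] / [pseudoweight + sum_i w_i]``
    with uniform weights when the sample carries none.  The default
    pseudoweight of 0 reflects estimation from complete landscapes, where no
    base is ever absent; a positive value guards small user samples.
    """
    if pseudoweight < 0:
        raise ValueError("pseudoweight must be nonnegative")
    if sample.n == 0:
        raise EstimationError("cannot estimate a probability matrix from an empty sample")
    w = sample.weights if sample.weights is not None else np.ones(sample.n)
    total = w.sum()
    if total <= 0:
        raise EstimationError("sample weights are all zero")
    counts = np.empty((4, sample.m))
    for j in range(sample.m):
        counts[:, j] = np.bincount(sample.seqs[:, j], weights=w, minlength=4)
    probs = (pseudoweight / 4 + counts) / (pseudoweight + total)
    return ProbabilityMatrix(probs)


def pm_log_scores(pm: ProbabilityMatrix, seqs: np.ndarray) -> np.ndarray:
    """Natural-log model probabilities for an ``(n, m)`` index array.

    Zero PM entries contribute ``-inf`` (site probability 0); no error is
    raised, matching the convention that impossible sites score zero.
    """
    seqs = np.atleast_2d(np.asarray(seqs))
    if seqs.shape[1] != pm.m:
        raise ValueError(f"sequences have length {seqs.shape[1]}, PM expects {pm.m}")
    with np.errstate(divide="ignore"):
        logp = np.log(pm.probs)
    return logp[seqs, np.arange(pm.m)].sum(axis=1)


def pm_sequence_probability(pm: ProbabilityMatrix, seq) -> float:
    """Model probability of one site: product of its per-position entries."""
    idx = seq_to_indices(seq)
    if idx.size != pm.m:
        raise ValueError(f"sequence length {idx.size} does not match PM length {pm.m}")
    return float(np.exp(pm_log_scores(pm, idx[None, :])[0]))


def log_odds(pm: ProbabilityMatrix, background: np.ndarray | None = None) -> np.ndarray:
    """Log-odds weight matrix ``WM(b, j) = ln[PM(b, j) / P(b)]``.

    Zero probabilities map to ``-inf``.  Summing WM entries over a site's
    bases ranks sites identically to the product of PM entries.
    """
    bg = np.asarray(background if background is not None else pm.background, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background probabilities must be strictly positive")
    with np.errstate(divide="ignore"):
        return np.log(pm.probs) - np.log(bg)[:, None]


@dataclass(frozen=True)
class LogoStats:
    """Column-wise logo statistics: information content and/or energy heights."""

    ic: np.ndarray          # bits per column
    mcic: float             # mean column information content, bits
    energy_heights: np.ndarray | None = None  # (4, m) mean-centered, kT


def information_stats(pm: ProbabilityMatrix) -> LogoStats:
    """Per-column Schneider information content against a uniform background.

    ``IC_j = 2 + sum_b PM(b,j) log2 PM(b,j)`` (with 0 log 0 = 0), in bits.
    """
    p = pm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    return LogoStats(ic=ic, mcic=float(ic.mean()))


def energy_logo_values(model: EnergyMatrix) -> LogoStats:
    """Energy-logo heights: negated energies, mean-centered per column.

    Each column is shifted so its mean is 0 and negated so lower-energy
    (higher-affinity) bases sit on top; information fields are set from the
    Boltzmann PM of the matrix.
    """
    heights = -(model.eps - model.eps.mean(axis=0))
    stats = information_stats(boltzmann_pm(model))
    return LogoStats(ic=stats.ic, mcic=stats.mcic, energy_heights=heights)


def boltzmann_pm(model: EnergyMatrix) -> ProbabilityMatrix:
    """Column-factorized Boltzmann probabilities ``e^-eps / sum_b e^-eps``.

    This is the low-concentration (mu -> -inf) limit of the PM estimated from
    a full occupancy-weighted landscape.
    """
    w = np.exp(-model.eps)
    return ProbabilityMatrix(w / w.sum(axis=0))
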