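"""Site-subset selection and rank-agreement statistics.

The accuracy measure throughout is the squared Spearman rank correlation
(r²) between model-predicted scores and true occupancies, either over the
full landscape or restricted to the true top fraction of sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .energy import BindingLandscape
from .pm import ProbabilityMatrix, SiteSample, pm_log_scores

SUBSET_ALL = "all"
SUBSET_TOP = "true-top-q"


class UndefinedCorrelationError(ValueError):
    """Raised when a rank correlation is undefined (zero rank variance)."""


@dataclass(frozen=True)
class CorrelationResult:
    """Squared Spearman rank correlation over ``n`` compared sites."""

    r2: float
    rho: float  # signed coefficient, for diagnostics
    n: int
    subset_label: str = SUBSET_ALL


def spearman_r2(scores_pred, scores_true, subset_label: str = SUBSET_ALL) -> CorrelationResult:
    """Squared Spearman coefficient with midrank tie handling.

    Raises :class:`UndefinedCorrelationError` when either side has zero rank
    variance (all values tied), where the coefficient is undefined.
    """
    pred = np.asarray(scores_pred, dtype=float)
    true = np.asarray(scores_true, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1 or pred.size < 2:
        raise ValueError("need two equal-length 1-D score vectors with n >= 2")
    if np.all(pred == pred[0]) or np.all(true == true[0]):
        raise UndefinedCorrelationError(
            "rank correlation undefined: one score vector is constant (all ranks tied)"
        )
    rho = stats.spearmanr(pred, true).statistic
    if not math.isfinite(rho):
        raise UndefinedCorrelationError("rank correlation undefined for these scores")
    return CorrelationResult(r2=float(rho * rho), rho=float(rho), n=pred.size, subset_label=subset_label)


def restricted_rank_r2(scores_pred, scores_true, idx, subset_label: str = SUBSET_TOP) -> CorrelationResult:
    """Squared rank correlation over a subset, with ranks from the full vectors.

    Both score vectors are midranked over ALL sites first; the squared Pearson
    correlation of the two rank vectors is then taken over the subset ``idx``.
    A site that the model mis-ranks badly therefore carries its full
    landscape-scale rank error into the subset comparison, which is the
    relevant notion of accuracy for "how well are the top sites ranked within
    the model's overall prediction".
    """
    pred = np.asarray(scores_pred, dtype=float)
    true = np.asarray(scores_true, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("need two equal-length 1-D score vectors")
    idx = np.asarray(idx)
    if idx.size < 2:
        raise ValueError("subset must contain at least 2 sites")
    rp = stats.rankdata(pred)[idx]
    rt = stats.rankdata(true)[idx]
    if np.all(rp == rp[0]) or np.all(rt == rt[0]):
        raise UndefinedCorrelationError(
            "rank correlation undefined on subset: all ranks tied on one side"
        )
    rho = float(np.corrcoef(rp, rt)[0, 1])
    if not math.isfinite(rho):
        raise UndefinedCorrelationError("rank correlation undefined on this subset")
    return CorrelationResult(r2=rho * rho, rho=rho, n=idx.size, subset_label=subset_label)


def top_count(n: int, q: float) -> int:
    """Size of the top fraction: ``ceil(q * n)``."""
    if not 0 < q <= 1:
        raise ValueError("top fraction q must lie in (0, 1]")
    return math.ceil(q * n)


def top_indices(landscape: BindingLandscape, q: float) -> np.ndarray:
    """Indices of the true highest-occupancy (lowest-energy) sites.

    Ties in energy are broken by canonical lexicographic sequence order
    (stable sort over the lexicographically ordered landscape).
    """
    k = top_count(landscape.n, q)
    return np.argsort(landscape.energies, kind="stable")[:k]


def top_fraction(landscape: BindingLandscape, q: float) -> SiteSample:
    """The true top-``q`` sites, weighted by their true occupancies.

    Drop the weights (``.unweighted()``) for the unweighted estimation
    variant.
    """
    idx = top_indices(landscape, q)
    return SiteSample(landscape.seqs[idx], landscape.occupancies[idx])


def evaluate_pm(
    landscape: BindingLandscape,
    pm: ProbabilityMatrix,
    subset: str = SUBSET_ALL,
    top_q: float = 0.01,
) -> CorrelationResult:
    """Rank agreement between PM-predicted scores and true occupancies.

    ``subset='true-top-q'`` restricts the comparison to the true top
    fraction of sites (by true occupancy) — not the predicted top fraction,
    which may differ.  Ranks are always taken over the full landscape
    (:func:`restricted_rank_r2`), so subset results reflect how well the
    model places the top sites within its overall ranking.
    """
    if pm.m != landscape.model.m:
        raise ValueError("PM length does not match the landscape's motif length")
    pred = pm_log_scores(pm, landscape.seqs)
    return evaluate_scores(landscape, pred, subset=subset, top_q=top_q)


def evaluate_scores(
    landscape: BindingLandscape,
    scores: np.ndarray,
    subset: str = SUBSET_ALL,
    top_q: float = 0.01,
) -> CorrelationResult:
    """Rank agreement for arbitrary per-site predicted scores (e.g. a fitted
    energy model's predicted occupancies), against true occupancies."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (landscape.n,):
        raise ValueError("need one predicted score per landscape site")
    if subset == SUBSET_ALL:
        return spearman_r2(scores, landscape.occupancies, subset_label=subset)
    if subset == SUBSET_TOP:
        idx = top_indices(landscape, top_q)
        return restricted_rank_r2(scores, landscape.occupancies, idx)
    raise ValueError(f"unknown subset {subset!r}")
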