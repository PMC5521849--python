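"""Replicated simulation experiments comparing PMs with the energy model.

Each replicate draws one random energy matrix, enumerates its full binding
landscape, and — at each chemical potential — estimates three probability
matrices (from all sites weighted by occupancy, from the true top fraction
weighted, and from the true top fraction unweighted).  Each PM is scored by
the squared Spearman correlation against true occupancies over the full
landscape and over the true top fraction.  Means and standard deviations over
replicates summarize the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import (
    EnergyMatrix,
    GeneratorConfig,
    all_sequences,
    enumerate_landscape,
    mutate_probability,
    random_energy_matrix,
)
from .pm import SiteSample, estimate_pm, pm_log_scores
from .ranking import SUBSET_ALL, SUBSET_TOP, restricted_rank_r2, spearman_r2, top_count

#: PM estimation regimes, in the order the result tables list them
PM_METHODS = ("all-weighted", "top-weighted", "top-unweighted")

RESULT_COLUMNS = ("replicate", "mu", "pm_method", "subset", "r2", "n", "seed")


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of the replicated rank-correlation experiment."""

    m: int = 8
    mu_values: tuple[float, ...] = (-3.0, 0.0, 3.0)
    replicates: int = 100
    top_q: float = 0.01
    energy_mean: float = 2.5
    energy_sd: float = 1.0
    base_seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.mu_values:
            raise ValueError("mu_values must be nonempty")

    @property
    def generator(self) -> GeneratorConfig:
        return GeneratorConfig(m=self.m, energy_mean=self.energy_mean, energy_sd=self.energy_sd)

    def replicate_seed(self, replicate_index: int) -> int:
        return self.base_seed + replicate_index


@dataclass(frozen=True)
class ExperimentSummary:
    """Per-(mu, method, subset) mean and sd of r² plus the raw replicate rows."""

    rows: pd.DataFrame
    summary: pd.DataFrame  # columns: mu, pm_method, subset, mean_r2, sd_r2, n_replicates

    def cell(self, mu: float, pm_method: str, subset: str) -> tuple[float, float]:
        s = self.summary
        sel = s[(s.mu == mu) & (s.pm_method == pm_method) & (s.subset == subset)]
        if len(sel) != 1:
            raise KeyError(f"no unique summary cell for mu={mu}, {pm_method}, {subset}")
        row = sel.iloc[0]
        return float(row.mean_r2), float(row.sd_r2)

    def table(self, subset: str, decimals: int = 3) -> pd.DataFrame:
        """Formatted ``mean (sd)`` table: PM methods x mu values."""
        s = self.summary[self.summary.subset == subset]
        mus = sorted(s.mu.unique())
        methods = [m for m in PM_METHODS if m in set(s.pm_method)]
        methods += [m for m in sorted(set(s.pm_method)) if m not in methods]
        out = pd.DataFrame(index=methods, columns=[f"mu={mu:g}" for mu in mus], dtype=object)
        for method in methods:
            for mu in mus:
                mean, sd = self.cell(mu, method, subset)
                out.loc[method, f"mu={mu:g}"] = f"{mean:.{decimals}f} ({sd:.{decimals}f})"
        out.index.name = "pm_method"
        return out

    @classmethod
    def from_rows(cls, rows: pd.DataFrame) -> "ExperimentSummary":
        grouped = (
            rows.groupby(["mu", "pm_method", "subset"], as_index=False)
            .agg(mean_r2=("r2", "mean"), sd_r2=("r2", lambda x: float(np.std(x, ddof=0))), n_replicates=("r2", "size"))
        )
        return cls(rows=rows.reset_index(drop=True), summary=grouped)


def replicate_pms(seqs, occ, top_idx):
    """The three PM estimates for one (matrix, mu): see :data:`PM_METHODS`."""
    return {
        "all-weighted": estimate_pm(SiteSample(seqs, occ)),
        "top-weighted": estimate_pm(SiteSample(seqs[top_idx], occ[top_idx])),
        "top-unweighted": estimate_pm(SiteSample(seqs[top_idx])),
    }


def run_replicate(config: ExperimentConfig, replicate_index: int) -> list[dict]:
    """One replicate: one random matrix, evaluated at every mu.

    The matrix is shared across mu values so cross-mu contrasts are paired.
    Deterministic given (base_seed, replicate_index).
    """
    seed = config.replicate_seed(replicate_index)
    rng = np.random.default_rng(seed)
    model = random_energy_matrix(config.generator, rng)
    return _evaluate_model(config, model, replicate_index, seed)


def _evaluate_model(config: ExperimentConfig, model: EnergyMatrix, replicate_index: int, seed: int) -> list[dict]:
    seqs = all_sequences(config.m)
    energies = model.energies(seqs)
    order = np.argsort(energies, kind="stable")
    top_idx = order[: top_count(len(energies), config.top_q)]

    rows = []
    landscape = enumerate_landscape(model, config.mu_values[0])
    for mu in config.mu_values:
        landscape = landscape.with_mu(mu)
        occ = landscape.occupancies
        pms = replicate_pms(seqs, occ, top_idx)
        for method, pm in pms.items():
            pred = pm_log_scores(pm, seqs)
            for subset in (SUBSET_ALL, SUBSET_TOP):
                if subset == SUBSET_ALL:
                    res = spearman_r2(pred, occ, subset_label=subset)
                else:
                    res = restricted_rank_r2(pred, occ, top_idx)
                rows.append(
                    dict(replicate=replicate_index, mu=mu, pm_method=method, subset=subset,
                         r2=res.r2, n=res.n, seed=seed)
                )
    return rows


def run_experiment(config: ExperimentConfig, progress: bool = False) -> ExperimentSummary:
    """Aggregate :func:`run_replicate` over all replicates.

    With a single replicate the reported sd is 0 (degenerate aggregation).
    """
    import warnings

    all_rows: list[dict] = []
    for r in range(config.replicates):
        try:
            all_rows.extend(run_replicate(config, r))
        except Exception as exc:
            raise RuntimeError(
                f"replicate {r} (seed {config.replicate_seed(r)}) failed: {exc}"
            ) from exc
        if progress and (r + 1) % 10 == 0:
            print(f"  replicate {r + 1}/{config.replicates}", flush=True)
    if config.replicates == 1:
        warnings.warn("single replicate: standard deviations are reported as 0", stacklevel=2)
    rows = pd.DataFrame(all_rows, columns=list(RESULT_COLUMNS))
    return ExperimentSummary.from_rows(rows)


def mutation_effect(p_start: float, dE: float, mu: float = 3.0) -> tuple[float, float]:
    """Effect of a single mutation of energy cost ``dE`` on site occupancy.

    Returns the new binding probability and the percent decrease
    ``100 (p_start - p_end) / p_start``.  Because occupancy is nonlinear in
    energy, the same dE produces very different probability changes in
    different contexts — the mutation-context artifact of probabilistic
    models.
    """
    p_end = float(mutate_probability(p_start, dE, mu))
    return p_end, 100.0 * (p_start - p_end) / p_start
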