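"""Noisy-measurement simulation and energy-matrix recovery by regression.

Experimental occupancy measurements carry noise.  Here Gaussian noise (in kT)
is added to every sequence's energy before occupancies are generated, and two
kinds of model are recovered from the noisy occupancies: probability matrices
(as in the noiseless experiment) and an additive energy matrix fitted by
nonlinear least squares through the Fermi-Dirac occupancy link.  Because the
energy model has only 3m + 1 free parameters averaged over many sequences,
per-sequence noise largely averages out of the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .energy import BindingLandscape, EnergyMatrix, all_sequences, occupancy, random_energy_matrix
from .experiments import ExperimentConfig, ExperimentSummary, RESULT_COLUMNS, replicate_pms
from .pm import SiteSample, estimate_pm, pm_log_scores
from .ranking import SUBSET_ALL, SUBSET_TOP, restricted_rank_r2, spearman_r2, top_count

#: energy assigned to a base never observed at a position (unidentifiable)
UNOBSERVED_ENERGY = 20.0

#: model labels for the fitted-energy regimes in noise-experiment results
FIT_METHODS = ("fit-all", "fit-top")


@dataclass(frozen=True)
class NoiseConfig(ExperimentConfig):
    """Experiment parameters plus the energy-noise standard deviation (kT)."""

    noise_sd: float = 0.5
    fit_sources: tuple[str, ...] = ("all", "top")

    def __post_init__(self):
        super().__post_init__()
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for src in self.fit_sources:
            if src not in ("all", "top"):
                raise ValueError(f"unknown fit source {src!r}")


@dataclass(frozen=True)
class NoisyLandscape:
    """A true landscape plus its noisy observation at the same mu."""

    true: BindingLandscape
    observed: BindingLandscape


def noisy_landscape(
    model: EnergyMatrix, mu: float, noise_sd: float, rng: np.random.Generator
) -> NoisyLandscape:
    """Perturb each sequence energy with independent N(0, noise_sd²) noise.

    Observed occupancies come from the noisy energies; the noise-free
    landscape is retained alongside for evaluation.
    """
    from .energy import enumerate_landscape

    true = enumerate_landscape(model, mu)
    noise = rng.normal(0.0, noise_sd, size=true.n) if noise_sd > 0 else np.zeros(true.n)
    E_obs = true.energies + noise
    observed = BindingLandscape(
        model=model, mu=float(mu), seqs=true.seqs, energies=E_obs, occupancies=occupancy(E_obs, mu)
    )
    return NoisyLandscape(true=true, observed=observed)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a nonlinear energy-matrix regression."""

    fitted: EnergyMatrix
    objective: float  # sum of squared occupancy residuals at the optimum
    converged: bool
    iterations: int
    gradient_norm: float


def fit_energy_matrix(
    sample: SiteSample,
    mu: float,
    max_iter: int = 10_000,
    tol: float = 1e-12,
) -> FitResult:
    """Fit an additive energy matrix to observed occupancies by least squares.

    The sample's weights are the observed occupancies (the regression
    targets).  Minimizes ``sum_i (p_obs_i - 1/(1+exp(E(S_i)-mu)))²`` over the
    3m free column energies plus a scalar offset, with mu fixed and known.
    One base per column (the initialization's preferred base) is pinned at 0
    during optimization; the result is re-gauged to zero-minimum columns with
    the residual absorbed into the offset.  A base never observed at a
    position is unidentifiable and is pinned to ``UNOBSERVED_ENERGY`` with a
    warning.

    Initialization inverts the occupancy-weighted sample PM (Berg-von-Hippel:
    ``eps = -ln[PM(b,j)/max_b PM(b,j)]``) and sets the offset from the
    preferred site's observed occupancy, starting near the optimum.
    """
    if sample.n == 0:
        raise ValueError("cannot fit an energy matrix to an empty sample")
    if sample.weights is None:
        raise ValueError("sample must carry observed occupancies as weights")
    p_obs = np.clip(sample.weights, 1e-12, 1 - 1e-12)
    seqs = sample.seqs
    m = sample.m

    pm0 = estimate_pm(SiteSample(seqs, p_obs))
    with np.errstate(divide="ignore"):
        eps0 = -np.log(pm0.probs / pm0.probs.max(axis=0))

    observed = np.zeros((4, m), dtype=bool)
    for j in range(m):
        observed[np.unique(seqs[:, j]), j] = True
    if not observed.all():
        warnings.warn(
            f"{int((~observed).sum())} base/position combinations are absent from the "
            f"sample; their energies are pinned to {UNOBSERVED_ENERGY} kT",
            stacklevel=2,
        )
        eps0 = np.where(observed, eps0, UNOBSERVED_ENERGY)

    pinned_base = np.where(observed, np.where(np.isfinite(eps0), eps0, np.inf), np.inf).argmin(axis=0)
    free = observed.copy()
    free[pinned_base, np.arange(m)] = False
    free_b, free_j = np.nonzero(free)
    n_free = free_b.size

    # one-hot design for the free entries: X[i, k] = 1 if seq i has base free_b[k] at free_j[k]
    X = (seqs[:, free_j] == free_b[None, :]).astype(float)
    # pinned preferred bases contribute 0; unobserved bases contribute the ceiling
    fixed_energy = np.where(observed, 0.0, UNOBSERVED_ENERGY)[seqs, np.arange(m)].sum(axis=1)

    # offset init: match the preferred (lowest init-energy) site's observed occupancy
    init_site_energy = eps0[seqs, np.arange(m)].sum(axis=1)
    pref = int(np.argmin(init_site_energy))
    e0_init = float(mu - logit(p_obs[pref]) - init_site_energy[pref])

    x0 = np.concatenate([np.where(np.isfinite(eps0[free_b, free_j]), eps0[free_b, free_j], UNOBSERVED_ENERGY), [e0_init]])

    def site_energies(x):
        return X @ x[:n_free] + fixed_energy + x[-1]

    def residuals(x):
        return p_obs - expit(mu - site_energies(x))

    def jacobian(x):
        p = expit(mu - site_energies(x))
        w = p * (1.0 - p)
        J = np.empty((seqs.shape[0], n_free + 1))
        J[:, :n_free] = X * w[:, None]
        J[:, -1] = w
        return J

    sol = least_squares(
        residuals, x0, jac=jacobian, method="trf",
        xtol=tol, ftol=tol, gtol=tol, max_nfev=max_iter,
    )
    r = sol.fun
    grad = sol.jac.T @ r
    eps = np.where(observed, 0.0, UNOBSERVED_ENERGY)
    eps[free_b, free_j] = sol.x[:n_free]
    fitted = EnergyMatrix.from_array(eps, offset=float(sol.x[-1]), regauge=True)
    return FitResult(
        fitted=fitted,
        objective=float(r @ r),
        converged=bool(sol.status > 0),
        iterations=int(sol.nfev),
        gradient_norm=float(np.linalg.norm(grad)),
    )


def run_noise_experiment(config: NoiseConfig, progress: bool = False) -> ExperimentSummary:
    """Replicated noise experiment: PMs and fitted energy models side by side.

    Per replicate: draw a matrix, draw one energy-noise vector (shared across
    mu values, since energies are mu-independent); at each mu, estimate the
    three PM regimes from the noisy occupancies, fit energy matrices from the
    noisy occupancies of all sites and/or of the true top fraction, and score
    every model against the TRUE noise-free occupancies on the full landscape
    and on the true top fraction.
    """
    seqs = all_sequences(config.m)
    k = top_count(seqs.shape[0], config.top_q)

    all_rows: list[dict] = []
    for rep in range(config.replicates):
        seed = config.replicate_seed(rep)
        rng = np.random.default_rng(seed)
        model = random_energy_matrix(config.generator, rng)
        E_true = model.energies(seqs)
        noise = rng.normal(0.0, config.noise_sd, size=E_true.size) if config.noise_sd > 0 else np.zeros(E_true.size)
        E_obs = E_true + noise
        top_idx = np.argsort(E_true, kind="stable")[:k]  # true top fraction

        for mu in config.mu_values:
            occ_true = occupancy(E_true, mu)
            occ_obs = occupancy(E_obs, mu)

            preds: dict[str, np.ndarray] = {}
            for method, pm in replicate_pms(seqs, occ_obs, top_idx).items():
                preds[method] = pm_log_scores(pm, seqs)
            if "all" in config.fit_sources:
                fit = fit_energy_matrix(SiteSample(seqs, occ_obs), mu)
                preds["fit-all"] = occupancy(fit.fitted.energies(seqs), mu)
            if "top" in config.fit_sources:
                fit = fit_energy_matrix(SiteSample(seqs[top_idx], occ_obs[top_idx]), mu)
                preds["fit-top"] = occupancy(fit.fitted.energies(seqs), mu)

            for method, pred in preds.items():
                for subset in (SUBSET_ALL, SUBSET_TOP):
                    if subset == SUBSET_ALL:
                        res = spearman_r2(pred, occ_true, subset_label=subset)
                    else:
                        res = restricted_rank_r2(pred, occ_true, top_idx)
                    all_rows.append(
                        dict(replicate=rep, mu=mu, pm_method=method, subset=subset,
                             r2=res.r2, n=res.n, seed=seed)
                    )
        if progress and (rep + 1) % 10 == 0:
            print(f"  replicate {rep + 1}/{config.replicates}", flush=True)
    rows = pd.DataFrame(all_rows, columns=list(RESULT_COLUMNS))
    return ExperimentSummary.from_rows(rows)
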