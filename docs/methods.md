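# Methods

## Biophysical model

Binding specificity is represented by an additive energy matrix
`ε(b, j)` (4 bases × m positions, units kT) plus a scalar offset `E0`.
The total energy of a site `S` is `E(S) = E0 + Σ_j ε(S[j], j)`; additivity
(positional independence of the energy) is assumed exactly throughout.
Matrices are kept in the Berg–von Hippel zero gauge: the minimum of every
column is 0, so the per-column preferred sequence has energy `E0`.  Gauge
freedom (per-column constant shifts) is resolved on construction; reading a
file that violates the gauge re-gauges it and moves the residue into `E0`,
with a warning.

A site is bound at equilibrium with probability

    P(B|S) = 1 / (1 + exp(E(S) − μ))

where the chemical potential μ is the log of the effective free protein
concentration, in units where the association constant of a zero-energy site
times [TF] equals `e^μ`.  μ = −3, 0, 3 correspond to the preferred site
being bound at ≈ 0.05, 0.5 and 0.95.

## Random-matrix generator

The synthetic-data generator emulates a "typical TF" specificity: one base
per column is chosen uniformly as preferred and fixed at 0; the other three
draw i.i.d. from N(mean, sd) with defaults mean = 2.5 kT, sd = 1.0 kT.
Negative draws (≈ 0.6% of cells at the defaults) would contradict the
zero-gauge convention that the preferred base is the minimum, so draws are
rejected-and-redrawn until positive — i.e. the positive-truncated normal.
The truncation raises the mean of non-preferred energies from 2.5 to
≈ 2.544 kT; its effect on every statistic computed here is far below the
replicate-to-replicate spread.

What the generator does **not** emulate: non-additive (dinucleotide) energy
terms, reverse-complement symmetry, variable-length or gapped motifs, and
any in vivo confounders (chromatin, competition, cooperativity).  Passing
tests therefore demonstrate properties of the models under exact additivity
and a clean equilibrium readout, not performance on real genomic data.

## Landscape enumeration and PM estimation

All 4^m sites are enumerated in lexicographic order (A<C<G<T), guarded at
m ≤ 12 to keep the tool desk-scale.  Probability matrices are estimated as
(weighted) base frequencies per column:

    PM(b, j) = [pw/4 + Σ_i w_i · S_i(b, j)] / [pw + Σ_i w_i]

with pseudoweight `pw = 0` by default — complete landscapes leave no base
unobserved, so no regularization is needed; a positive `pw` is available
for user-supplied samples.  Three estimation regimes mirror common data
situations: all sites weighted by occupancy (a complete in vitro
experiment), the true top 1% of sites (⌈0.01·4^m⌉ = 656 at m = 8) weighted
by occupancy (a deep but truncated experiment), and the same top sites
unweighted (a curated list of known sites).  Energy ties in the top-site
selection are broken by the canonical sequence order; under continuous
energies they have probability zero but the rule keeps runs deterministic.

Site scores are computed in log space; a zero PM entry scores a sequence at
−∞ (probability 0), never raising.  Log-odds weight matrices use natural
log against a uniform 0.25 background; information content uses log2
(bits), `IC_j = 2 + Σ_b PM log2 PM`.  Energy-logo heights are the negated,
per-column mean-centered energies.

## Rank-agreement statistic

Accuracy is the squared Spearman rank correlation r² (midranks for ties;
Pearson correlation of the rank vectors, squared) between model scores and
true occupancies.  Since occupancy is strictly decreasing in energy, the
true ranking is μ-invariant.

Two evaluation scopes are reported:

- **all** — r² over all 4^m sites;
- **true-top-q** — the comparison is restricted to the true top fraction
  (default 1%) of sites, but both score vectors are ranked over the *full*
  landscape first and the squared Pearson correlation of those global ranks
  is taken over the subset.  This measures how well the model places the
  top sites within its overall prediction: a top site that the model
  demotes into the bulk carries its full, landscape-scale rank error into
  the statistic.  Re-ranking within the subset is deliberately not used; it
  would hide exactly the mis-placements the statistic is meant to expose.
  (The restriction is to the *true* top sites; evaluating on the
  model-predicted top set is possible via `top_indices` on predicted scores
  but is not the default.)

A constant score vector makes the correlation undefined; this is surfaced
as an error, never reported as 0.

## Replicated experiments

Each replicate draws one matrix (seed = base_seed + replicate index, a
single `numpy` Generator per replicate) and evaluates all μ values and all
PM regimes on it, so cross-μ contrasts are paired; means are unaffected by
the pairing.  Summaries report mean and population sd (divisor n) per
(μ, method, scope) cell, rounded to 3 decimals in the formatted tables; at
n = 100 the population-vs-sample sd difference is below the reporting
precision.  Defaults: m = 8, μ ∈ {−3, 0, 3}, 100 replicates, top fraction
0.01.

## Noise and energy-matrix regression

Measurement error is modeled as i.i.d. N(0, noise_sd²) energy noise
(default 0.5 kT, pessimistic relative to good in vitro data) added to every
sequence once per replicate — energies are μ-independent, so the same noise
serves all μ values, and noise_sd = 0 reproduces the noiseless experiment
bitwise.  Observed occupancies come from the noisy energies; evaluation is
always against the noise-free truth.

An energy matrix is recovered from observed occupancies by unweighted least
squares through the occupancy link:

    minimize  Σ_i ( p_obs,i − 1/(1+exp(E_θ(S_i) − μ)) )²

over the 3m free column energies plus `E0`, with μ fixed at its known
simulation value (estimating μ jointly is possible in principle but would
only trade off against `E0`, leaving rank predictions unchanged).  The
optimizer is a trust-region-reflective least-squares solver with the exact
analytic Jacobian (`∂residual/∂E = p(1−p)` times the one-hot design),
tolerances 1e−12 and a 10,000-evaluation cap.  Initialization inverts the
occupancy-weighted sample PM (`ε₀ = −ln[PM/colmax]`) and sets `E0` from the
preferred site's observed occupancy, which starts the search near the
optimum and avoids the flat tails of the link.  One base per column is
pinned at 0 during the fit and the result is re-gauged afterwards; a base
never observed in the sample is unidentifiable and is pinned to a 20 kT
ceiling with a warning.  With noiseless data the fit recovers the
generating matrix to ≲1e−4 kT per entry from the full landscape and ≲1e−3
from the top 1% alone; with noise, entry errors shrink as the training
sample grows, because each matrix parameter averages over all sequences
that carry it — the low-dimensionality advantage of matrix models.

## Numerical and interface choices

- Occupancies use the logistic `expit` for stability; PM products are
  summed in log space.
- All serialized numbers use full `repr` precision; the 3-decimal tables
  and the ×100 "percent" PM display are formatting only.
- Energy matrices travel as labeled TSV (rows matched by base label, any
  order); PMs as MEME minimal motif format or TSV.  Readers renormalize PM
  columns off by ≤ 1e−6 and reject worse.
- Every CLI run writes a metadata JSON (version, config echo, base and
  per-replicate seeds, output manifest) sufficient to reproduce outputs
  bitwise; stochastic subcommands require a seed.

## Problem sizes

The shipped experiments use the default conditions throughout: 65,536-site
landscapes, 100 replicates for both the noiseless grids and the noise
experiment (the supplementary-style noise run is reported at μ = 3, the
regime where concentration effects and the regression's advantage are
largest).  The acceptance script completes in well under a minute on a
single CPU.

## Known limitations

- Additivity is both the data-generating truth and the fitted model class;
  the framework quantifies PM distortion, not model mis-specification.
- The top-fraction definition uses the *true* ranking; real experiments
  truncate on noisy observed signals, which would add selection noise not
  modeled here.
- The regression assumes a known μ and a single-round equilibrium readout;
  count-based sequencing likelihoods and binding-site position inference
  within longer reads are out of scope.
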