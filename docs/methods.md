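# Methods

This note documents the models, numerical choices and known
limitations of `rotshift`. State indices follow the fixed six-state
order used everywhere in the package: (1) white rot / angiosperm
specialist, (2) brown rot / angiosperm specialist, (3) white rot /
gymnosperm specialist, (4) brown rot / gymnosperm specialist, (5)
white rot / generalist, (6) brown rot / generalist. Odd states are
white rot.

## Character coding

The gymnosperm association of a fungus species is g = N_G / (N_G +
N_A), the fraction of its woody host species that are gymnosperms.
Species with N_A = N_G = 0 carry no host information and are excluded.
Coding thresholds are inclusive: g ≥ 0.90 codes a gymnosperm
specialist and g ≤ 0.10 an angiosperm specialist under the default
"90–10" scheme; the "100–0" exclusivity scheme uses g = 1 and g = 0,
which lumps non-exclusive specialists with generalists. Host records
at infraspecific rank are collapsed to the binomial before counting,
so a species recorded on two subspecies of one host contributes one
host species.

Decay modes reported at genus level are extrapolated to all congeners.
Genera with more than one reported decay mode (by default
*Clitocybula*, *Mucronella*, *Hyphoderma*; configurable) are excluded
from extrapolation — their species are kept only with species-level
records. The genus is parsed as the first whitespace- or
underscore-delimited token of the species name.

The one-genus-subset resampler draws exactly one species per genus
uniformly at random (seeded), to measure how sensitive downstream rate
estimates are to the genus-level extrapolation.

## Tree handling

Trees are rooted `dendropy` trees with branch lengths in time units.
Support values are read from internal-node labels (the newick
convention; supports describe the edge above the labeled node).
`collapse_low_support` contracts edges whose child support is
*strictly below* the threshold, absorbing the contracted length into
the child edges so that all tip depths are preserved (the alternative
— discarding the length — would shrink the tree and distort rate
scales). `resolve_polytomies_random` replaces each polytomy by a
uniformly drawn rooted binary resolution, built by sequential
attachment of each child to a uniformly chosen edge (including the
root edge), which generates each labeled topology exactly once;
inserted edges have length 0, so path lengths and ultrametricity are
unchanged. Note that the simpler scheme of repeatedly pairing two
random children is *not* uniform over topologies (on a 4-tip star it
gives each balanced shape probability 1/9 and each caterpillar 1/18).

Ultrametricity is checked with a relative tolerance of 1e-6 of tree
height. The phylogenetic covariance matrix (MRCA depths) is computed
in a single O(n²) postorder pass; patristic distances follow from
d(i,j) = h_i + h_j − 2·vcv(i,j).

## Mk models

The six-state character evolves as a continuous-time Markov chain with
generator Q (rows sum to zero). Three transition structures are
supported; under ARD the free cells are (0-based indices, white =
{0,2,4}, generalists = {4,5}):

- **uncorrelated**: all 30 off-diagonal cells;
- **correlated_hosts**: specialist↔generalist moves within a decay
  mode (8 cells) plus decay-mode switches that keep the host state (6
  cells) = 14 cells — direct specialist→specialist jumps are zero;
- **correlated_hosts_norev**: the same minus the three brown→white
  cells = 11 cells.

ER shares a single rate across a structure's allowed cells, so k = 1
for every structure; ARD gives k = 30/14/11. These counts are the ones
that reproduce the published model-selection arithmetic, which is how
the masks were validated.

Transition probabilities P(t) = exp(Qt) are computed by
eigendecomposition of Q (one decomposition serves all branch lengths);
when the eigenvector matrix has condition number above 1e8 the code
falls back to scipy's scaling-and-squaring on each branch length.
Negative round-off entries are clipped at zero and rows renormalized.
P(0) = I, so zero-length branches are exact no-ops.

The likelihood is Felsenstein's pruning algorithm with per-node
rescaling (log-scale accumulation), scheduled level-by-level so that
each evaluation is a short sequence of batched matrix products —
roughly 3 ms per evaluation on a 700-tip tree. Tips may carry
ambiguity sets (partials of ones over the allowed states). The root is
combined with a *fixed* prior — flat (1/6 each) or "white rot equal"
(⅓ on each white-rot state) — not with likelihood-derived weights;
lnL = log Σ_i π_i L_i(root).

Fitting maximizes lnL over log-rates with L-BFGS-B, bounds [1e-9, 100]
per unit branch length. The tree is internally rescaled to unit height
(rates are reported back on the original scale), which keeps
absolute-time trees (heights of hundreds of MY) inside the same
bounds. Default 10 restarts: one neutral start (all rates 1 per tree
height) plus log-uniform draws on [1e-2, 20], seeded. Rates pinned at
the lower bound are reported as 0 in the rate table. AIC = 2k − 2 lnL;
Akaike weights are computed from ΔAIC in the standard way.

## Signal statistics

**Fritz–Purvis D** (binary traits). Nodal values are equal-weight
averages of daughter values on a tips-to-root pass; d is the sum over
internal nodes of |left − right|. The observed d is scaled between two
null means: tip shuffles (D = 1) and threshold-Brownian simulations
(D = 0). Prevalence matching for the Brownian null is done by order
statistic — each simulated replicate is split at the observed minority
count k, giving groups of exactly k and n−k tips. Because Brownian
motion is sign-symmetric this is equivalent in distribution to
thresholding at the prevalence quantile, and it makes D exactly
invariant to swapping the 0/1 labels. p_random is the fraction of
shuffle replicates with d ≤ d_obs (small = clumped); p_brownian the
fraction of Brownian replicates with d ≥ d_obs. Polytomies are
resolved randomly (seeded) first. Permutation p-values elsewhere use
the (1 + #extreme)/(1 + n) correction so they are never exactly zero;
the uncorrected fraction is reported alongside.

**Pagel's λ** (continuous traits). V(λ) keeps the diagonal of the
phylogenetic covariance and multiplies off-diagonals by λ ∈ [0, 1]
(upper bound 1 for ultrametric trees). The mean and σ² are profiled
out analytically; the 1-D optimization uses scipy's bounded
minimizer (tolerance 1e-6) and the optimum is compared against both
endpoints, so lnL(λ̂) ≥ max(lnL(0), lnL(1)) holds exactly.

**Correlogram.** The tree is rescaled to height 1. For each of
n_points lag means μ_m (equally spaced up to the maximum patristic
distance), weights are a Gaussian kernel in distance centered at μ_m
with sd = 2·d_max/n_points (a tunable; only the kernel family is fixed
by the method), zero on the diagonal and between zero-distance pairs,
row-normalized. Moran's I is computed per lag; the 95% envelope comes
from bootstrap resampling of tips. Under no signal I centers on
−1/(n−1), not 0.

**Parsimony randomization.** Fitch parsimony score of the (resolved)
six-state character versus scores after shuffling tip states; a score
below the whole null distribution indicates phylogenetic conservatism.

**Phylogenetic regression.** GLS with the λ error model, response
log10 host-species count (species with zero woody hosts are excluded
upstream, so the response is always finite), predictor the binary
decay mode; (β, σ², λ) by joint ML (λ profiled on [0, 1]), Wald tests
on β. λ = 0 reduces exactly to OLS.

## Synthetic data

The generator's defaults mirror the empirical study conditions: 1157
tips, tree height 282 (interpreted as MY), generating structure
correlated_hosts_norev/ARD with a white-rot root. Trees come from a
stop-at-n forward birth–death simulation (default pure birth)
conditioned on survival, with the final branch segment extended by the
waiting time to the next event — this avoids the zero-length cherry
that stopping exactly at the n-th birth produces. Tips are labeled in
genus blocks (geometric sizes, mean 3) so genus-level utilities are
exercised.

Characters are simulated by exact CTMC sampling along each branch
(exponential waiting times, competing transitions), returning a full
event log with per-state dwell times — counts/dwell give a
likelihood-free consistency check on the generator. Default generating
rates (per unit tree height) are well separated in [0.4, 4.0]:
specialist↔generalist rates 0.6–4.0 and white→brown switch rates
0.4–0.8, chosen so that every allowed transition accumulates enough
expected events on a ~10³-tip tree to be informative.

Host-count tables draw each species' total woody-host count from a
zero-truncated negative binomial (mean ≈ 8, shape 0.8 — long-tailed,
like real host-range distributions) and split it so the realized g
falls in the species' coding region (specialists at least as extreme
as the purity parameter, default 0.95; generalists strictly between
the thresholds). Re-coding the table therefore recovers the true
states exactly; this is a design guarantee, not an empirical claim
about database data, which carry misclassification the generator does
not emulate. Real data also violate other conveniences of the
generator: perfectly known decay modes, complete sampling, and a
correctly specified generating model. Passing tests show the
*machinery* is correct and well calibrated under the model, not that
the model is true of nature.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` use scaled-down problem
sizes chosen to keep full runs fast while leaving every check
informative: likelihood-oracle instances of 2–6 tips (enumeration is
exponential), model/rate recovery on 700-tip trees with 12 (tests) or
10 (script) replicates and 2 optimizer restarts, D calibration on a
500-tip tree with 100–200 replicates of 100 null simulations each, and
λ calibration with 30–50 replicates. Thresholds (80% model recovery,
25% median rate error, D means within ±0.1, 90% λ recovery) are
independent of these sizes.

## Known limitations

- Root treatment is a fixed prior; likelihood-weighted (FitzJohn-style)
  root handling is not implemented.
- No hidden-rate models, no three-binary-character correlated coding
  (unobserved states inflate rates as an artifact), no ancestral-state
  reconstruction plots, and no divergence-time estimation — trees are
  taken as given.
- The correlogram bootstrap resamples tips with replacement and zeroes
  weights between duplicate tips; other envelope constructions exist.
- Wald p-values in the regression use the normal reference
  distribution with the ML (not REML) σ².
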