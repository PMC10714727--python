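# Methods

This note documents the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical choices that matter when interpreting
output.

## Time-calibrated trees and coordinates

Trees are rooted Newick with decimal-year tip dates, parsed from a
`name_YYYY[.fraction]` label suffix or a sidecar TSV (the table wins for tips
it lists). For time trees, branch lengths are years and node heights are
measured back from the latest tip; for divergence trees (root-to-tip
regression input) branch lengths are substitutions/site and only the tip
dates carry time. Residue and site positions are reported 1-based inclusive
in all outputs; internal arrays are 0-based. DNA ambiguity codes are treated
as missing for counting estimators, and codon columns containing gaps or
ambiguity are excluded from codon likelihoods.

## Root-to-tip regression

Ordinary least squares of root-to-tip distance on tip date. The root is
placed at the optimum over every point of every branch: writing the tip
distances as d_i(x) = a_i ± x for a root x along a candidate edge, both
rooting criteria (maximal R², minimal residual mean square) have stationarity
conditions linear in x, so each branch's optimum is closed-form and the
global search is exact — no iterative optimization, which is what makes the
noise-free recovery exact to machine precision. Ties go to the smallest
preorder node id. The substitution rate is the slope, tMRCA the x-intercept.
Isochronous tips make the regression undefined and raise an error.

## Path sampling and stepping-stone sampling

Both estimators consume a power-posterior trace: log-likelihood samples at an
increasing ladder β ∈ [0, 1] (β = 0 the prior, β = 1 the posterior). Path
sampling integrates the per-rung mean log-likelihood over β by the trapezoid
rule; stepping-stone telescopes ratios between adjacent rungs using
log-sum-exp-stabilized importance weights from the lower rung. The default
ladder has K = 50 rungs at Beta(0.3, 1) quantiles, concentrating rungs near
β = 0 where the integrand changes fastest. Monte-Carlo standard errors come
from a block bootstrap (blocks of 50 consecutive samples, 200 resamples) to
respect within-chain autocorrelation.

Two built-in toy models exercise the whole chain:

* **Conjugate normal** (known variance, normal prior on the mean): the
  power posterior is itself conjugate, so exact samples are available at any
  β, and the marginal likelihood has a closed form — the oracle for
  estimator-consistency tests.
* **Clock regression**: root-to-tip distances d_i ~ N(slope·(t_i − t̄) +
  intercept, 1/τ) with a normal-gamma prior (τ ~ Gamma(2, 8·10⁻⁴), so
  E[σ] ≈ 0.02 substitutions/site; slope and intercept normal given τ with
  relative scales 0.01 and 25). The conjugate structure yields an analytic
  marginal likelihood (multivariate t) used to validate the MCMC path. The
  noise precision is a model parameter rather than fixed because the
  isochronous fit must be able to absorb the date-explained variance into σ;
  the Gamma prior on τ keeps E[1/σ²] finite, which keeps the β ≈ 0 integrand
  of path sampling well behaved (heavy-tailed σ priors make the PS variance
  explode).

`run_bets_toy` runs Metropolis-within-Gibbs at each rung (one coordinate at a
time, per-coordinate scales adapted during burn-in toward ~40% acceptance,
warm-started rung to rung, exact prior draws at β = 0), flags rungs with
effective sample size < 50, and reports the comparison under the plain
log-Bayes-factor orientation (positive favors heterochronous).

**Bayes-factor conventions.** The published model-comparison table prints
BF = log M(iso) − log M(het) while reading values above 3 as support for the
heterochronous model; `bets_compare(convention="table1")` reproduces exactly
that arithmetic, and `convention="log-bf"` gives the standard
het − iso orientation. Both interpret the reported value > 3 as favoring
heterochronous, < −3 as favoring isochronous, otherwise inconclusive.

## Epochs, κ_n and adaptive divergence

Epoch boundaries step back from the latest tip date in 50-year windows
(defaults: 3 epochs, 50 years); epoch 1 is the oldest and absorbs everything
beyond the last boundary. A branch belongs to the epoch of its temporal
midpoint; exact per-epoch time fractions are also computed and exposed for
sensitivity analysis, since midpoint assignment is a deterministic but
arbitrary rule for boundary-crossing branches.

κ per epoch is a joint maximum-likelihood fit of one HKY model in which κ
takes a free value per occupied epoch and a single free rate converts branch
years to substitutions; empirical base frequencies; likelihood by pruning;
standard errors from finite-difference curvature on the log-κ scale (delta
method). Epochs without branches report κ as missing with a warning. This is
the ML analogue of estimating per-epoch transition bias by Bayesian epoch
models: deterministic, fast, and testable against simulation truth.

The branch-site test follows the standard model-A construction: site classes
0 (ω₀ everywhere), 1 (neutral), 2a (ω₀ background / ω₂ foreground), 2b
(neutral background / ω₂ foreground) with weights (p₀, p₁, p₂p₀/(p₀+p₁),
p₂p₁/(p₀+p₁)); GY94 rate matrices share κ and F3×4 codon frequencies (F1×4
and equal-frequency options). All ω-class matrices are normalized by the
*neutral* (ω = 1) mean rate with the same κ, so one branch-length unit is one
expected neutral substitution per codon and ω > 1 classes genuinely evolve
faster — normalizing each class separately would cancel the very rate
contrast the test detects. The null (model A₁) pins ω₂ = 1; the LRT uses a
plain χ²₁ reference, which is conservative at the ω₂ = 1 boundary (observed
null rejection ≈ 0.025 at α = 0.05); the 50:50 mixture reference is not used
but the p-value convention is configurable upstream. Optimization works on
transformed parameters (log κ, logit ω₀, log scale, log(ω₂ − 1)); the class
weights are profiled out at every step by an inner optimizer with an analytic
gradient (they enter only through the per-class site likelihoods, so no extra
pruning is needed), and the alternative fit is warm-started from the null
optimum, which removes the ΔlnL < 0 failure mode of independent fits.
Site patterns are collapsed before fitting.

Adaptive divergence per 50-year window: AD = [Σ over branches with p < 0.05
and ω̂₂ > 1 whose midpoint falls in the window of ω̂₂] / κ(epoch of window).
Windows with no supported branch report AD = 0; a supported branch in an
epoch with missing κ is an error.

## Functional divergence

**Type I.** Substitution counts per column within each cluster's subtree are
Fitch parsimony minima (deterministic; gaps are missing and contribute no
changes; the generalization to multifurcations is the greedy set-union rule,
exact on binary trees). The model is a two-state column mixture: with
probability 1 − θ one Gamma(α, α/μ) rate drives Poisson counts in both
clusters (marginally a bivariate negative binomial with correlation); with
probability θ the clusters draw independent rates. The default ties the
Gamma hyperparameters across states and clusters (3 parameters: θ, α, μ) —
the free per-cluster variant (`per_cluster_rates=True`, 7 parameters) is
available but absorbs sampling noise as spurious divergence on null data, so
the tied model is the default. Q_k is the posterior probability of the
independent-rate state; the LRT against θ = 0 uses the boundary-aware 50:50
χ²₀/χ²₁ mixture; the SE comes from the observed curvature on the logit
scale.

**Type II.** Columns with a ≥ 60% majority consensus in both clusters are
classified as identical, conservative-different (same physicochemical class)
or radical-different under a 5-class property scheme (nonpolar GAVLIMPC,
polar STNQ, positive KRH, negative DE, aromatic FWY; configurable).
Conservative differences can only arise from ordinary substitution on the
connecting lineage, so the neutral substitution fraction is calibrated from
them — p̂·(1 − θ) = n_conservative / (n_conserved·(1 − r)), with r the
scheme's radical fraction over random replacements — and θ_II is the radical
excess: θ̂ = n_radical/n_conserved − p̂(1 − θ)·r, clipped to [0, 1]. This
self-calibration is preferred over an expectation from the tree's
between-cluster branch length (kept in the aux output) because it stays
correct when the alignment's realized divergence and the tree scale disagree.
The LRT is a binomial test of radical fraction among differing columns
against r.

## Coevolution

Residues are recoded into the 5-class property alphabet (identity and custom
schemes supported). A column's *block signature* is the set of maximal
monophyletic tip groups within which its class is uniform (missing residues
are compatible with anything); the pair score is the Jaccard agreement of the
two block sets — 1 exactly when the columns partition the tips identically.
Significance: the partner column's states are permuted across tips
(n seeded draws, default 1000) and p = (1 + #{null ≥ observed})/(n + 1).
Pairs with p ≤ α are retained and single-linkage clustered through shared
columns; Benjamini-Hochberg q-values over all pairs are reported alongside
(with 1000 permutations the achievable p floor of ~10⁻³ is coarser than the
BH rank-1 threshold, so q-values are informative but not used as the gate).
Because permutation p-values are discrete they are conservative
(P(p ≤ t) ≤ t), never anticonservative. Domain weights: each significant
pair adds its score to (domain_i, domain_j); within each cluster, every path
a–b–c through a shared member adds min(score(ab), score(bc)) to
(domain_a, domain_c), counted once per path; columns outside annotated
domains pool as "other". This scoring is inspired by blocks-in-sequences
coevolution analysis for small alignments but is an independent formulation;
equivalence with any external tool is not claimed.

## Shine-Dalgarno-like motifs

ORF annotations are validated (ATG start, stop end, length divisible by 3,
non-overlapping) and 5′UTR / intergenic / 3′UTR regions derived. The scanner
slides a 7-mer window ending s nucleotides before the ATG for
s ∈ center ± tol (default 5 ± 2, i.e. 3..7): *canonical* if the 7-mer equals
AGGAGGT (U ≡ T), *variant* if it matches the core xGGxGGx (positions 2, 3,
5, 6 = G; an optional mismatch budget loosens the core), *absent* if no
window matches, *NA* if the region is shorter than 7 + minimum spacer. When
several windows match, the spacer closest to the center wins, ties toward
the shorter spacer. Entropy is per-position Shannon entropy in bits over
observed bases (no pseudocounts, 0 ≤ H ≤ 2); a motif group is *stable* when
mean H ≤ 0.5 bits (configurable; the cutoff is a package default, not an
external standard). Logo matrices are column-stochastic 4×L tables.
Anti-SD pairing energies and UTR secondary structure are out of scope.

## Synthetic data

A single seed fans out to per-stage generators via CRC32-keyed
`SeedSequence`s, so stages are independently reproducible; identical
(config, seed) gives bit-identical output.

* **Trees**: heterochronous Kingman coalescent via msprime (haploid samples,
  population size in year units, tips spread evenly over the sampling
  window) and a forward birth-death sampler conditioned on the target tip
  count (isochronous, retried on extinction). Coalescent expectations
  (E[TMRCA] = 2N(1 − 1/n)) serve as oracles.
* **Sequences**: HKY with per-epoch κ and GY94 with model-A site classes,
  both simulated by exact per-branch transition matrices (eigendecomposition
  of the reversible generator), not Gillespie, for oracle comparability.
  Codon frequencies default to uniform over the 61 sense codons.
* **Divergent clusters**: type I draws per-column Gamma rates (shared or
  independent per cluster) under a 20-state equal-rates model; type II
  plants constant-but-different columns with residues from distinct property
  classes. A counts-level generator (`simulate_change_counts`) matches the
  θ_I estimator's model exactly for calibration experiments.
* **Coevolution**: planted pairs split jointly on an internal edge with at
  least 4 tips per side (smaller clades leave the permutation null too
  little entropy for the pair to reach small p); background columns are iid
  uniform residues — exactly the permutation null.
* **UTR sets**: canonical motifs planted at a given frequency with spacers
  from a given distribution into GG-free background (so zero-mutation
  recovery is exact by construction), then point-mutated per base.

What the generators do **not** emulate: among-site rate heterogeneity and
indels in the HKY/GY94 generators, selection on synonymous codon usage,
recombination/reassortment, non-clocklike rate variation beyond the injected
Gaussian distance noise, and real 5′UTR compositional structure. Passing
tests therefore demonstrate correctness of the estimators under their own
model assumptions and robustness to the planted-signal designs above — not
robustness to every misspecification found in real virus data.

## Problem sizes and defaults used in validation

Validation experiments run at desk scale: 8-taxon/100–300-codon branch-site
simulations (200 null replicates for error calibration, 50 for power),
500-column counts for θ_I (100 replicates), 12-taxon/32-column alignments
with 1000 permutations for coevolution (20 runs), 50 rungs × 1000 samples
for the estimator checks, and 200-strain UTR sets. The branch-site power
experiment uses a fixed balanced 8-taxon tree whose foreground is a long
(0.475 substitutions/codon) internal branch — the analogue of the long
host-jump lineages the method targets — with ω₂ = 6 on 20% of sites.

## Known limitations

* The branch-site implementation reproduces the model-A likelihood, not any
  specific external optimizer's heuristics; estimates at the ω₂ boundary can
  sit exactly at 1 with ΔlnL = 0.
* θ_II is a moment estimator; its SE is binomial and ignores consensus-call
  uncertainty.
* Fitch parsimony undercounts and saturates on deep subtrees, which
  compresses the overdispersion the θ_I mixture uses: on alignment-level
  (rather than counts-level) data the tied model can attribute decorrelation
  to a larger Gamma shape instead of to θ and is therefore conservative; the
  `per_cluster_rates=True` variant is more sensitive in that regime but
  noisier upward on null data. For planted-truth calibration use the
  counts-level generator, whose model matches the estimator exactly.
* The coevolution score is partition agreement, not an energy- or
  dimension-based score; weights are comparable within an analysis, not
  across tools.
* Root-to-tip regression assumes additive distances on the supplied
  topology; it does not re-estimate the tree.
* The toy BETS models operate on root-to-tip summaries, not full
  phylogenetic likelihoods over tree space.
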