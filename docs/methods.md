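# Methods

This note documents the models, numerical choices and known limitations of
famturnover, in the order the pipeline runs.

## Data model and units

A study consists of (i) a rooted, strictly binary, ultrametric chronogram
with branch lengths in million years (My); (ii) an integer family-by-species
copy-count table; (iii) optionally a family→term map and a species trait
table. All rates are per gene per My. Trees with polytomies or non-positive
branch lengths are rejected rather than repaired: both the parsimony branch
report and independent contrasts assume a binary tree, and silently
resolving a polytomy would fabricate branches on which events get placed.
Ultrametricity is checked to a relative tolerance of 1e-6 — exact for
integer-My fixtures while tolerating float noise in user trees. Whitespace
in species labels is normalized to underscores at ingestion so that tree
tips, table columns and trait rows match textually.

## Parsimony event mapping

A family's **origin** is fixed to the MRCA of the species with nonzero
counts before any reconstruction (orthologous-group semantics: the group is
defined at the taxonomic level of its ancestral gene, so losses cannot
predate the origin). Inside the origin subtree, ancestral copy numbers
minimize the total absolute change Σ|child − parent| over branches (Wagner
parsimony: per-copy duplications and losses cost 1 each), computed by
Sankoff dynamic programming over states 0..(max observed count + 1). The
state bound is sufficient because with linear cost no optimal ancestral
state exceeds the observed maximum by more than the headroom needed for
ties.

Ties are broken deterministically: at the origin, the smallest minimum-cost
state ≥ 1; below it, the minimum-cost state closest to the parent's chosen
state, then the smaller count. One consequence worth knowing: on the two
branches adjacent to the root, a one-step change can often be placed on
either side at equal cost, and the smallest-state rule then reconstructs a
stem **loss** on one side as a stem **gain** on the other. Branch tallies
adjacent to the root are therefore conservative about losses; this is why
planted-signal recovery in the synthetic studies is defined on true (not
reconstructed) contracting sets. A "gain" is tallied once per family on the
branch leading to its origin (at the root row if the origin is the root);
duplication/loss event tallies sum |Δ| within the subtree and therefore add
up exactly to the family's parsimony cost.

## Birth–death likelihood

Family size follows a linear birth–death process (per-copy gain rate λ,
loss rate μ, size 0 absorbing). Transition probabilities use the standard
extinction/growth parameterization α, β (see README) with the survivor-sum
closed form; the implementation evaluates the sum in linear space from
precomputed log-binomial tensors (all terms are positive, so there is no
cancellation; binomial magnitudes stay far below float64 overflow for the
state spaces in play, and the tensors are cached per state cap). The
critical case switches to α = β = λt/(1+λt) when |λ−μ|t < 1e-8.

The tree likelihood of a profile is computed by post-order pruning over
ancestral sizes 0..S with per-family rescaling. Defaults and choices:

* **State cap** S = max observed count + 10 (configurable). For the rates
  this package targets (λ, μ ≲ 0.01/gene/My on trees ≲ 100 My deep) the
  probability mass above the cap is far below the 1e-9 normalization
  tolerance asserted in the tests.
* **Root prior**: uniform on sizes 1..S, i.e. conditioned on the family
  existing at the root. A maximum-over-root-states alternative was
  considered and rejected: it is not a likelihood and breaks AIC
  comparisons.
* **Survivorship conditioning** (default on in `fit_model`): each family
  likelihood is divided by P(family observed at ≥ 1 tip), computed by one
  extra pruning pass on the all-zero profile. Families that die everywhere
  are never observed, and without this correction loss rates are biased
  downward by the ascertainment.
* **Annotation-error channel**: P(obs = true) = 1 − ε, ε/2 to each of
  true ± 1, with the inadmissible −1 mass at true = 0 reflected onto 0. At
  the truncation cap the +1 mass folds onto S, keeping rows stochastic.
* **Optimization**: Nelder–Mead in log-rate space (rates clipped to
  [1e-9, 10]), five restarts by default — the first from a method-of-moments
  start (median of per-family variance/(2·mean·depth)), the rest jittered by
  a uniform ±50% factor. A fit is flagged converged when the two best
  restarts agree in −lnL within 1e-4.
* **Error estimation**: profile likelihood over ε on the grid
  {0} ∪ {0.4126·2⁻ᵏ, k = 0..6} (rates refit at every candidate, warm-started),
  refined by a bounded scalar search between the best grid point's
  neighbours. Per-species mode starts all species at the global optimum and
  cycles species, optimizing each on the grid with the others fixed, until
  no ε moves by more than 1e-3. Because ε = 0 is on the grid, the returned
  fit can never be worse than the error-free fit.

Model classes are assigned by clade: a named clade claims its stem branch
and everything below it, so "bats" rates govern the branch into the bat MRCA
as well as all branches within bats.

### Known estimation bias

Simulation truth uses geometric(mean 2) root sizes while the fitting prior
is uniform on 1..S. In simulate-and-refit experiments this misspecification
leaves the loss rate nearly unbiased (≈ +5%) but depresses the gain rate by
roughly 10–20% at 2,000 families when λ ≪ μ — visible in, and tolerated by,
the ±25% recovery checks. Users fitting real data should treat small fitted
λ under strongly asymmetric models as a lower bound.

## Significance

**Per-family Monte-Carlo p.** For each family, root sizes are drawn from
its conditional root-size posterior under the fitted model, n_mc profiles
are simulated down the tree (through the error channel if one was fitted;
unobservable all-zero draws are redrawn), and
p = (1 + k)/(1 + n_mc) where k is the observed log-likelihood's rank from
below among the simulated ones. Count data make exact log-likelihood ties
common (many families show the modal, unchanged profile); with ties counted
conservatively the null p-value distribution would carry an atom of mass
equal to the modal profile's frequency and could not be uniform. The
default therefore breaks ties by a seeded uniform rank draw, which makes
null p-values exactly uniform on the achievable grid (the calibration the
tests assert, KS < 0.05 at 2,000 families); `tie_break="conservative"`
restores the strictly conservative estimator when preferred. The smallest
attainable p is 1/(1 + n_mc); the default n_mc = 1,000.

**Per-branch p.** Given jointly most-likely ancestral states (max-product
over the tree, ties to the smaller state), each branch gets a two-tailed
probability-ordering test: the summed probability of all child states no
more probable than the realised one given the parent state. This is a
repository convention — reasonable, exact, and deterministic — not an
attempt to reproduce any particular tool's internal test.

**Simulated LRT null.** For nested rate models (partition refinement
checked explicitly; free λμ nests tied), datasets are simulated under the
fitted null (root sizes from the fitting prior, so the simulated data match
the likelihood being refit), both models are refit to each — warm-started, with
the alternative started at the embedded null optimum so 2ΔlnL ≥ 0 up to
float noise — and the critical value is the ⌈0.95·n⌉-th order statistic of
the clipped sample. Defaults are 1,000 simulations; the calibration test
uses 300 to build the critical value, 500 held-out simulations of 60
families each to verify ≈5% type-I error, sizes chosen to make the check
statistically meaningful at desk scale.

## Enrichment

One-sided hypergeometric over-representation (P(X ≥ k)) per term, with the
population fixed to families present at the parent node of the tested
branch. Terms absent from the population are skipped rather than reported
at p = 1 — uninformative rows would only inflate the correction burden —
and the multiple-testing m is the number of terms actually tested.
Annotations are used as a flat family→term map: there is no ontology-graph
propagation of terms to ancestors, which can change counts relative to
DAG-aware tools; planted-signal tests are unaffected because the generator
plants flat terms.

## Comparative analysis

Independent contrasts follow Felsenstein's pruning recursion; the n−1
standardized contrasts of a binary n-tip tree are correlated **through the
origin** (contrast signs are arbitrary, so an intercept is meaningless) and
tested with t on n−2+1 = n−1 df. Raw associations use Spearman's ρ with a
seeded two-sided permutation p (default 10,000 permutations) — appropriate
because typical species samples here are small (n = 18). C-values missing
for a species are imputed as the arithmetic mean over congeners (genus =
first underscore-delimited label token), with a provenance flag.

## Synthetic studies

The generator simulates each family by exact per-copy exponential event
times down every branch (not transition-matrix sampling), so a complete
true event log exists — this is what makes the parsimony-lower-bound and
population-size tests possible. Defaults emulate the target study design:
the 18-taxon, 80-My fixture tree; 2,000 families; tied turnover
0.0008 changes/gene/My; geometric root sizes with mean 2 (conditioned ≥ 1);
global annotation error ε = 0.0635; a planted term ("OR-like") on 60% of
families truly contracting on the bat stem vs 10% elsewhere over 20
background terms at 5% incidence; Brownian traits with σ² = 0.005 Gb²/My
from a 3.0 Gb root, optionally mixed with standardized per-tip loss counts
to hit a target trait–turnover correlation (0 by default, giving pure
Brownian motion).

What the generator does **not** emulate: orthology-inference noise beyond
the ±1 error channel (no fragmented assemblies, no clustering artifacts),
rate heterogeneity across families, gene conversion, or correlated family
sizes. Passing tests therefore demonstrate correctness of the inference
machinery under its own model class, not robustness to every artifact of
real proteome data.

## Problem sizes used in checks

Recovery checks run at 2,000 families on the 18-taxon fixture; p-value
calibration at 2,000 families with n_mc = 200; LRT calibration at 60
families per simulated dataset. These sizes give the assertions enough
statistical resolution (binomial/KS error well inside the asserted bands)
while keeping the whole suite runnable on a single core in minutes.

## Degenerate inputs and failure contracts

All-zero family profiles are rejected everywhere (an unobserved family has
no likelihood and no origin). ε ≥ 1, negative rates, non-positive branch
durations, study sets outside their population, missing tip traits, and
non-nesting model pairs raise immediately with the offending item named.
Empty p-value vectors adjust to empty vectors; an empty family set yields
an all-zero branch summary.
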