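# Methods

This note documents the models, algorithms and numerical choices behind
`ontopart`, and what its synthetic-data calibrations do and do not show.

## The problem

Morphological character matrices for phylogenetics — here the running
example is a dung-beetle (Scarabaeinae) matrix of 110 taxa and 205
discrete characters scored 0/1/2 with `?` for missing — are usually
analysed either under parsimony or under the Mk family of likelihood
models. Characters from the same anatomical region plausibly share
evolutionary dynamics, which suggests partitioning the matrix by
anatomy and giving partitions separate rates. `ontopart` implements
that whole programme: an anatomy ontology drives the generation of
partition schemes, a space of parameter–partition models is enumerated
over those schemes, models are ranked by marginal likelihood
(stepping-stone and harmonic mean) via Bayes factors, and a parallel
parsimony suite (equal and implied weights, consensus, rogue-taxon
profiling) covers the non-probabilistic side.

## Ontology and partition schemes

The anatomy ontology is a table of *part_of* relations `(entity,
parent)`. Characters (`c<ID>`, 1-based) sit at the tips; regions are
internal nodes; there is a single root. **Elementary categories** are
the regions whose children are all characters — the Scarabaeinae
fixture has eleven (ES, SG, GC, AS, E, W, Pt, M, H, Pr, L; 205
characters in total, sizes 41/4/19/13/31/21/10/30/10/10/16).

A **hierarchical cut** is a partition of the characters in which every
block is the complete tip set of one node. Regions may have more than
one parent: the fixture needs both a "wing apparatus + pterothorax"
supercategory (E+W+Pt) and a "thorax + legs" supercategory (Pt+Pr+L),
which overlap in Pt, so the graph is a rooted DAG rather than a strict
tree. `enumerate_schemes(graph, policy="all")` enumerates every
hierarchical cut by exact-cover search over the elementary categories;
this is oracle-tested against brute-force set-partition enumeration
filtered by `validate_scheme`.

The fixture graph licenses 31 hierarchical cuts. The nine-scheme
selection used throughout the model comparison is a curated subset of
those cuts (the full cross-product of per-region coarsenings is larger
than any study would run); the fixture designates the nine published
block patterns on the graph, each validated as a cut at build time, and
the default enumeration policy returns a graph's designated selection
when one is present. Nothing in the enumerator depends on the selection
being nine: a graph without designated schemes yields all cuts.

## The model space

A model is a scheme plus a linkage specification: branch lengths linked
(one relative set) or unlinked (one per partition); a per-partition
rate multiplier absent or present (constrained to character-weighted
mean one); among-character rate variation equal, shared gamma, or
per-partition gamma. Parameter counts follow `B + R + G` with branch
lengths counted as one block per partition — the convention that
reproduces the published per-model counts (1 to 33 over the nine
schemes). The twelve linkage combinations are numbered by fixed slots;
multi-partition schemes drop the two fully linked no-multiplier slots
(observationally identical to the unpartitioned models), leaving ten,
and the single-partition scheme keeps exactly those two. Over the nine
schemes this gives 8×10 + 2 = 82 models, or 164 analyses across the
with/without-autapomorphy dataset variants.

## Mkv likelihood

Characters evolve by the k-state Mk chain (equal frequencies, equal
exchange rates) with the closed-form transition probabilities

    P_same(t) = 1/k + (k-1)/k · exp(-k t/(k-1))
    P_diff(t) = 1/k - 1/k · exp(-k t/(k-1)).

Because only variable characters are scored, each character's
likelihood is conditioned on variability: `lnL_i - ln(1 - Σ_s Pr(all
taxa = s))`, with the constant-pattern probabilities computed under the
same tree, gamma mixture, multiplier and (when unlinked) partition
branch lengths as the character itself.

Numerical choices:

* **Per-character k.** A character's state count is its number of
  distinct observed states (states relabelled 0..k-1); the
  ascertainment denominator uses the same k. How mixed 2- and 3-state
  characters were grouped by existing programs is not documented, so
  the per-character convention is ours and is what the tests verify.
* **Discrete gamma.** Four equal-probability categories represented by
  their conditional means (the standard discretisation), renormalised
  to exact mean one.
* **Missing and polymorphic cells.** Missing cells contribute a vector
  of ones in the pruning pass (full uncertainty), including inside the
  ascertainment denominator, where a constant pattern forces *all*
  taxa — missing ones included — to state s. Polymorphic cells `{01}`
  are treated as missing for likelihood (and as Fitch-ambiguous for
  parsimony); the source convention is unstated, and this choice keeps
  the likelihood well-normalised.
* **Pruning.** Felsenstein pruning vectorised over the characters of a
  partition (grouped by k), with per-node max-scaling accumulated in
  log space. The k constant patterns of each group are appended as
  pseudo-columns so the data and the ascertainment denominator share
  one pass. Correctness is tested against exhaustive summation over
  internal-node states for ≤5 taxa and against the exact normalisation
  Σ(variable patterns) = 1 for ≤4 taxa.
* **Rooting.** The likelihood is computed on the rooted structure with
  uniform root frequencies; the chain is reversible, so the value is
  invariant under re-rooting (tested).
* **Degenerate inputs.** A constant character raises immediately
  (inconsistent with variable-only coding). If the constant-pattern
  mass reaches 1 (e.g. an all-zero tree), the corrected log-likelihood
  is clamped to a large negative guard value instead of -inf.

## MCMC

Single-chain Metropolis–Hastings per run, two independent runs by
default. Priors: Exponential(10) branch lengths (mean 0.1),
Exponential(1) gamma shapes, flat Dirichlet on the weighted rate
multipliers, uniform topology. Proposals: branch-length scale moves
(multiplier `exp(λ(u-½))`), NNI, an optional SPR whose edge-split uses
a uniform fraction with the split–merge Jacobian `t_split/t_merged` in
the acceptance ratio (pruning a child of a two-child root is excluded
because it would drop an edge dimension), a 50/50 mixture of log-scale
random walks and independence draws from the prior for gamma shapes
(the likelihood is often nearly flat in the shape, where an
independence proposal mixes far better than a random walk — measured
as a several-fold gain in effective sample size), and mass-transfer
moves between two multipliers on the weighted simplex. Tuning constants are fixed — no adaptation — so a seed fully
determines the run. When the topology is held fixed, the proposal mass
freed from tree moves is reassigned to the continuous parameters.
Metropolis-coupled ensembles (heated chains with swap proposals) are
available behind `heating_temperature`/`n_chains` but are off by
default: desk-scale data does not need them and the ASDSF contract is
between independent runs either way.

Correctness checks: prior-only sampling recovers the Exponential(10)
branch-length mean; on the three-taxon tree with one variable character
the posterior mean of a terminal branch matches direct numerical
integration (the rooted posterior collapses to three effective lengths,
so the oracle is a 3-D quadrature); the recorded log-likelihood and
log-prior of every retained sample re-derive exactly.

Convergence is diagnosed by the **average standard deviation of split
frequencies** (ASDSF) between runs: splits reaching frequency 0.10 in
at least one run contribute the sample standard deviation of their
per-run frequencies, and a mean of 0.01 or lower counts as converged.
Consensus trees (strict, or majority with frequency > threshold) carry
split supports, which for posterior samples are posterior
probabilities.

## Marginal likelihoods and Bayes factors

The harmonic-mean estimator is `-logmeanexp(-lnL)` over the
post-burn-in trace. Stepping-stone sampling uses powers
`β_j = (j/K)^(1/α)` (Beta(α,1) quantiles; defaults K=50, α=0.4 at full
scale), annealed from the posterior to the prior; step s samples the
power posterior at the lower power and contributes
`logmeanexp[(β_{s-1}-β_s)·lnL]`, each step inheriting its start state
from the previous one, with the first 25% of each step discarded. The
contributions telescope: a constant likelihood is recovered exactly,
K=1 reduces to importance sampling from the prior, and conjugate toys
(Beta–Bernoulli, normal mean) agree with their analytic marginals
within Monte-Carlo error. Three independent ladders are run and their
range reported as the spread; at equal sampling effort this spread is
smaller than the harmonic mean's (tested).

Bayes factors are reported as `2lnBF = 2(lnML₁ - lnML₀)` with the
conventional bands (|2lnBF| < 2 negligible, 2–6 positive, 6–10 strong,
≥10 very strong). Estimates from the with- and without-autapomorphy
dataset variants are never comparable and mixing them raises an error.

## Parsimony

Fitch counting is vectorised over characters with state bitmasks
(missing = all states, polymorphic = its listed states) and tested
against exhaustive minimisation over internal labelings. Implied
weighting uses the Goloboff cost `Σ es_i/(es_i + k)`; as k grows the
ranking converges to equal weights. The search is random-addition
Wagner construction followed by SPR swapping to a local optimum,
pooling all distinct best topologies up to a buffer limit (the buffer
overflow is flagged, mirroring how full tree buffers are reported in
practice); on seven-taxon matrices it recovers the exhaustive-search
optimum. CI (= m/L) and RI (= (g-L)/(g-m)) are reported both over all
characters and over parsimony-informative characters only, because the
convention differs between programs.

The rogue-taxon analysis is a simplified positional-congruence
protocol. Leaf stability is the mean, over tree pairs, of the fraction
of rooted triplets containing the leaf that resolve identically (trees
are first rerooted on a common reference leaf — the lexicographically
smallest — because triplets are unresolvable on unrooted trees). The
least stable leaf below the threshold (default 0.9) is pruned from all
trees, stabilities are recomputed, and the loop repeats. A character
supports a flagged leaf's instability when its Fitch length differs
between at least one pair of trees that disagree on that leaf's
placement yet agree once it is pruned; the output table counts, per
character, how many unstable leaves implicate it. The exact published
congruence index is not re-derived; the iteration count of any
particular historical run is not a target.

## Synthetic data

The generator emulates exactly the process the inference assumes:
random topologies (uniform edge-attachment, or Yule via a birth–death
simulator) with iid Exponential(10) branch lengths drawn *after* the
topology is fixed (drawing-then-splitting would produce artificially
short internal edges); characters evolved under k-state Mk with
discrete-gamma category rates, per-partition multipliers (weighted mean
one) and optional per-partition branch scalings; rejection resampling
of constant characters, so the variability conditioning matches the
Mkv ascertainment assumption exactly rather than approximately; and
post-hoc autapomorphy injection (all carriers of a character's rarest
state but one are recoded to the majority state).

A "study-shaped" stand-in matrix reproduces the summary shape of the
real supplementary matrix — 110 taxa, 205 characters, exactly 29
parsimony-uninformative characters, characters 181/182 three-state,
~5% missing cells — with simulated cell values. It exercises the
loaders, classifiers and exclusion bookkeeping at full size; it does
not reproduce the real matrix's phylogenetic signal, so search lengths
and marginal likelihoods on it are not comparable to published values.

What passing the synthetic calibrations shows: the samplers target the
stated posteriors, the estimators are consistent on well-specified
data, and partition heterogeneity of the simulated magnitude is
detectable by stepping-stone Bayes factors. What they do not show:
robustness to model misspecification (correlated characters, ordered
states, asymmetric frequencies), performance on matrices with real
missing-data structure, or search adequacy on 100+-taxon datasets.

## Desk-scale problem sizes

The published analyses ran tens of millions of generations; this
package's default budgets are sized for a desktop. The test-suite
calibrations use: parameter recovery at 8 taxa, 500 characters (two
partitions of 250, multipliers (1.6, 0.4) — the 4:1 heterogeneity ratio
expressed on the weighted-mean-one scale — shared gamma shape 0.5),
20 replicates, with 95% central credible intervals checked against a
90% coverage requirement; model-selection closure at 8 taxa, 300
characters, three partitions with multipliers in ratio 9:3:1, 20
replicates, stepping-stone ladders of 8 steps; and the full-scale
profile (30 M generations, 50 steps) is preserved as a named budget for
reproduction attempts. The topology is held at the truth in the
recovery replicates: the claims under test concern the continuous
parameters and the partition-model preference, not tree search.

## Known limitations

* The SPR split–merge ratio treats per-partition branch-length vectors
  as a single scaled length; with unlinked branch lengths the NNI move
  carries the topology mixing burden.
* The "meaningful" scheme selection is fixture data, not a derived
  rule; the enumerator itself exposes every hierarchical cut.
* The heuristic parsimony search is not a reimplementation of any
  specific program's engine; equal scores, not equal tree pools, are
  the contract.
* Bremer support, ordered characters, asymmetric state frequencies and
  covarion-style models are out of scope.
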