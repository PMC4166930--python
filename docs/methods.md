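# Methods

This note documents the model, the sampler, the numerical choices and the
limits of what the package's synthetic-data experiments demonstrate.

## Substitution model and likelihood

Each partition evolves under a reversible Markov substitution process.
For DNA this is GTR: `Q_ij = r_ij π_j` (i ≠ j) with exchangeabilities
`r = (r_AC, r_AG, r_AT, r_CG, r_CT, r_GT)` and stationary frequencies π.
Exchangeabilities are kept on the simplex (they are only identified up to
scale once Q is normalized), which makes the flat Dirichlet prior on them
proper. Q is rescaled so that `−Σ π_i Q_ii = 1`; branch lengths are then
expected substitutions per site. Protein partitions use named empirical
matrices (JTT, WAG, LG, Dayhoff are shipped; the registry in
`_aa_data.py` is a plain table and extensible). Transition probabilities
come from the symmetrized eigendecomposition
`P(t) = D^{-1/2} V exp(Λt) V^T D^{1/2}` with `D = diag(π)`, which is
numerically stable for reversible Q; entries are clipped to [0, 1]
(roundoff at the 1e-16 level only).

Rate heterogeneity is the discrete-Γ model: k = 4 equally probable
categories (k configurable), category rates equal to the analytic means
of the equal-probability bins of Gamma(α, α) via regularized incomplete
gamma functions, renormalized to mean exactly 1.

The likelihood is Felsenstein pruning over site patterns (identical
columns are collapsed with integer weights per partition; the collapse is
exactly likelihood-neutral). Conditional likelihood vectors (CLVs) are
`(categories × patterns × states)` arrays. Underflow protection is
per-pattern: when a pattern's largest CLV entry drops below 2⁻²⁵⁶ the
pattern column is multiplied by 2²⁵⁶ and a counter incremented; the root
log-likelihood subtracts `256·ln 2` per count. The check is gated behind
a cheap whole-array minimum so the common no-rescale case costs one
contiguous reduction. This keeps 1,000-taxon caterpillar trees with
10⁻⁹-length branches finite.

### Cache invalidation

CLV validity is signature-based rather than flag-based: each stored CLV
remembers the (child id, branch length) pairs and model/Γ objects it was
computed from. At evaluation time a post-order sweep marks a node
"changed" when its signature differs or any child changed; exactly the
path from an edit to the evaluation root (the internal node adjacent to
the first taxon) is recomputed. Rejected proposals restore the previous
CLVs from an undo buffer, so a reject is bitwise state-neutral. An audit
(every 1,000 generations by default) recomputes the likelihood from
scratch and aborts on divergence > 10⁻⁶.

### Memory saving

Two orthogonal mechanisms, both exact:

* **Bounded-memory recomputation.** Modes cap resident CLVs per
  partition: `full` = all n−2 internal nodes, `economy` = ⌈(n−2)/2⌉,
  `minimal` = 2⌈log₂ n⌉ + 2. Eviction is deterministic,
  farthest-from-the-evaluation-root first (ties by node id). Children
  are evaluated taller-subtree-first, so a single pruning pass fits the
  logarithmic budget (the pebbling argument for binary trees); a budget
  below the single-pass floor raises an error. Because every node's CLV
  is computed by the same operations in the same order, all modes return
  bitwise-identical log-likelihoods and differ only in recomputation.

* **Missing-data shortcut (SEV-style).** For a pattern whose characters
  are missing in every taxon below a node, the CLV column is exactly 1
  (rows of P sum to 1), so those columns are never stored or multiplied;
  each node keeps CLVs only for its "active" patterns, with index maps
  into the parent's active set. Storage shrinks roughly in proportion to
  the missing fraction in block-structured (patchy-ortholog) matrices.
  The implemented case is the memory-dominant all-missing one;
  aliasing of partially identical subtree patterns is not implemented.

## Priors

Defaults (all configurable): uniform over unrooted topologies,
independent Exp(λ=10) per branch length (mean 0.1), Dirichlet(1,…,1) on
frequencies and on exchangeabilities, Exp(1) on α. Out-of-support
parameters short-circuit to −∞ before any likelihood work.

## Proposals

Topology-heavy default menu (relative weights in parentheses): stochastic
NNI (5), extended SPR (15, stop probability 0.5), branch-length
multiplier (30, θ = 2·ln 1.6), node slider (10), frequency-Dirichlet (2),
exchangeability-Dirichlet (2), α-multiplier (2). Multiplier moves use
`b' = b·exp(θ(u−½))` with log Hastings `log(b'/b)`; Dirichlet moves draw
from a Dirichlet centered at the current value (α = θ·current, components
floored at 10⁻⁶) with exact forward/reverse densities.

The extended SPR prunes a uniformly chosen subtree (directed edges with
internal tail; the count 3(n−2) is topology-invariant), joins the two
orphaned branches, and walks the regraft point by a non-backtracking
random walk that stops with probability `p_stop` per step (a trapped walk
regrafts where it stands; a prune that leaves a bare cherry is a null
move). The regraft splits the target branch at a uniform position. The
Hastings ratio multiplies (i) the exact forward/reverse walk
probabilities — these differ from 1 only near leaves, where the number of
non-backtracking extensions drops — and (ii) the length-split Jacobian
`L_target / L_joined` from the dimension-matching map
`(L1, L2, Lf, u) → (L1+L2, Lf·u, Lf(1−u), L1/(L1+L2))`. Move-level
validity is tested by uniform-stationarity of always-accept eSPR on the
15-topology 5-taxon space, and sampler-level validity by exact agreement
with enumerated posteriors.

Autotuning multiplies θ by `exp(δ(acc − 0.25))` per 100-attempt window
during burn-in only (frozen afterwards so the sampled chain is
Markovian). Dirichlet concentrations tune with the opposite sign, since
for them larger θ means smaller steps.

## Metropolis coupling and the nonblocking swap contract

Chain i targets `L(x)^{β_i}·prior(x)` with incremental heating
`β_i = 1/(1 + iΔ)`, Δ = 0.1 by default. Tempering the likelihood only —
rather than the full posterior — keeps every heated target proper under
the unbounded branch-length prior, and the MH ratio is
`exp(β·Δℓ + Δ(log prior) + log Hastings)`. A state swap between chains a
and b is accepted with `min(1, exp((β_a−β_b)(ℓ_b−ℓ_a)))`; the shared,
untempered prior cancels from the ratio. On acceptance the chains trade
states; each chain keeps its heat and RNG stream, so the cold chain's
identity is stable for sampling.

Swaps are organized by tickets: every swap interval one uniformly random
adjacent-heat pair without a pending ticket is ticketed; the ticket
resolves a configurable lag later with the chains' states at resolution
time, and no chain ever waits. Lag 0 reproduces the classic synchronous
schedule. Correctness is lag-independent because a swap between two
chains is a valid move of the joint kernel at whatever generation it is
applied; the tests verify that cold-chain occupancy under lags 0 and 2 is
statistically indistinguishable from an independently coded blocking
reference on an enumerable target.

Reproducibility: every run derives decorrelated streams from
`SeedSequence(seed, spawn_key=(run,))` — one stream per chain plus
streams for the starting tree and the scheduler — so identical
(config, seed, data) give bitwise-identical traces, and independent runs
share no randomness.

## Starting trees

Greedy Fitch-parsimony stepwise addition: taxa in seeded random order,
each inserted on the branch minimizing the parsimony score (ties: lowest
branch index), branch lengths initialized to 0.1 and left to burn-in.
Fitch state sets are bitmasks, so IUPAC ambiguity and gaps are free.
Stepwise addition is a heuristic: on random data it occasionally (a few
percent of instances) scores slightly worse than a random topology, and
the tests treat it as such.

## Postprocessing

Splits are canonical bitmasks (the side not containing the first taxon).
Majority-rule consensus includes splits with frequency > threshold
(threshold ≥ 0.5 guarantees pairwise compatibility); extended mode adds
remaining splits greedily by descending frequency (ties by bitmask) when
compatible. Branch lengths on the consensus are per-split means over the
samples containing the branch (pendant lengths tracked separately from
topology frequencies). ASDSF uses the population-SD convention across
runs over splits reaching 10% in at least one run, with 0.01 reported as
the conventional convergence rule of thumb. Credible intervals are
equal-tailed (2.5%/97.5%); ESS is `n/(1 + 2Σρ_k)` with autocorrelations
summed to the first non-positive term; constant traces report ESS = n
with a degeneracy flag. RF distance is the symmetric difference of
nontrivial split sets. Tree-space maps use classical MDS
(double-centering + top-2 spectral coordinates), with a deterministic,
seeded jitter of radius 10⁻³·max(D) applied to exact duplicates so that
identical trees plot adjacently but never on top of each other.

## Synthetic data

`generate_bushy_tree` draws a uniform-at-small-n topology by sequential
random joins and assigns long pendant (default 0.3) and short internal
(default 0.03) branches — the bush-like regime where internal branches
are hard to resolve — optionally jittered ±20%. `simulate_alignment`
draws root states from π and evolves each site down the tree with a
uniformly drawn Γ category. `apply_missingness` removes whole
(taxon × partition) blocks until the target fraction (±1%) is reached,
never silencing a taxon entirely. The default replay profile is 20 taxa
and 10 partitions × 1,000 sites, a 1%-scale model of a 200-taxon,
100-partition whole-genome design.

What these experiments show: that the sampler, started from a parsimony
tree, concentrates the posterior on the generating topology when data are
abundant, with every true split at full support after 33% burn-in; and
that the memory-saving paths are exact. What they do not show: behavior
under model misspecification (real data are not GTR+Γ), alignment error,
deep recombination/ILS conflicts between loci, or performance at
genome-scale character counts — the simulator draws i.i.d. sites from
the inference model's own family, which is the favorable case.

## Problem sizes and runtimes

The shipped experiment sizes are chosen to run on a single CPU in
minutes: the headline replay uses 20 taxa × 20,000 sites × two runs of
20,000 generations (about 4–5 minutes); likelihood oracles use 5-taxon,
20-site instances where exhaustive enumeration over ancestral states is
feasible; sampler-correctness checks use targets small enough to
normalize directly (3 discrete states; the 3 topologies of 4 taxa).
Statistical assertions use 3 standard errors with ESS-based error
estimates for autocorrelated chains, and χ² homogeneity at the 0.01
level with the expected false-positive allowance across replicates.

## Known limitations

* Branch-length proposals act on one linkage group at a time; with many
  unlinked branch-length groups mixing is slow.
* The eSPR length-split convention uses the group-0 branch length in its
  Jacobian; with unlinked branch lengths the correction is approximate
  (linked lengths — the default — are exact).
* No checkpoint/restart; runs are cheap enough at desk scale to redo.
* No invariant-sites category and no codon models.
* The SEV path is a whole-tree evaluation (no incremental updates); it
  is intended for static-tree evaluation and engine cross-checks, while
  MCMC uses the full/economy/minimal cached engine.
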