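# bayestree

Desk-scale Bayesian phylogenetic tree inference: Metropolis-coupled MCMC
(MC³) over tree topologies and substitution-model parameters for
partitioned DNA/protein alignments, with memory-saving likelihood
evaluation, parsimony starting trees, a synthetic-data simulator and a
full postprocessing kit (consensus trees, convergence diagnostics, sample
statistics, tree-space maps).

It is written for people who want a complete, transparent, testable
Bayesian tree-inference stack in pure scientific Python — for teaching,
for method experiments (new proposals, swap schedules, memory policies),
and for small-to-moderate analyses — not as a competitor to
production C++ samplers on genome-scale supermatrices.

## The model

Given an alignment partitioned into loci, each partition evolves under a
reversible substitution model: the general time-reversible (GTR) model for
DNA — rate matrix `Q_ij = r_ij π_j` with six exchangeabilities `r` on the
simplex and stationary frequencies `π`, normalized to one expected
substitution per site — or a named empirical amino-acid matrix (JTT, WAG,
LG, Dayhoff shipped). Across-site rate variation follows the discrete-Γ
model: four equally probable categories whose rates are the means of the
equal-probability bins of a Gamma(α, α) density. All parameters, including
branch lengths, can be linked or unlinked across partitions.

The posterior `p(T, b, θ | X) ∝ L(X | T, b, θ) · p(T) p(b) p(θ)` combines
the Felsenstein-pruning likelihood with priors: uniform on topologies,
independent Exp(10) on branch lengths, flat Dirichlet on frequencies and
exchangeabilities, Exp(1) on α (all configurable). Sampling uses
Metropolis–Hastings with a topology-heavy move set (stochastic NNI,
extended SPR with an exact Hastings correction, branch multipliers, node
sliders, Dirichlet parameter moves) and Metropolis coupling: heated chains
target `L^β · prior` with `β_i = 1/(1 + iΔ)`, and a nonblocking, ticketed
scheduler exchanges states between adjacent heats. Runs are seeded by
greedy Fitch-parsimony stepwise-addition trees.

## A worked example

```python
from bayestree import (RunConfig, build_model, compress_patterns,
                       discretize_gamma, generate_bushy_tree, run,
                       simulate_alignment, split_frequencies, asdsf)

true_tree = generate_bushy_tree(8, outer_len=0.3, inner_len=0.05, seed=7)
aln, _ = simulate_alignment(true_tree, build_model("DNA"),
                            discretize_gamma(0.5), 1500, seed=8)
patterns = compress_patterns(aln)
results = run(RunConfig(n_runs=2, n_generations=4000, sample_every=40,
                        seed=9), patterns)
tables = [split_frequencies(r.topologies, burnin_fraction=0.33,
                            taxon_names=aln.taxon_names) for r in results]
print(round(asdsf(tables), 4))
```

Running `examples/01_simulate_and_infer.py` (this example plus a
consensus) prints:

```
ASDSF across runs: 0.0015  (< 0.01 ~ converged)
true split supports: [1.0, 1.0, 1.0, 1.0, 0.99]
```

meaning the two independent runs agree topologically (average SD of split
frequencies 0.0015, far under the 0.01 rule of thumb) and every branch of
the generating tree is recovered with posterior support ≥ 0.99. The
`examples/` directory holds one short script per capability: inference,
memory-saving likelihood (bounded-memory recomputation and the
missing-data SEV path), parsimony starting trees, coupled chains on an
enumerable toy target, and MDS tree-space maps.

## Command line

```bash
bayestree simulate --taxa 20 --partitions 10 --sites 1000 --missing 0.75 -o sim
bayestree run -f sim.phy --format phylip -q sim.parts -s 1 -n myrun -r 2 -g 10000
bayestree sdsf myrun.topologies.*.nex        # convergence across runs
bayestree consense myrun.topologies.*.nex    # majority-rule consensus
bayestree stats myrun.parameters.0.tsv       # mean / CI / ESS per parameter
bayestree treespace myrun.topologies.*.nex   # 2D RF-distance map
```

Trace files are Tracer-compatible TSV; topology samples are Nexus trees
blocks with a translate table (FigTree-compatible).

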