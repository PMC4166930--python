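"""Tree-space map: classical MDS of Robinson–Foulds distances.

Samples topologies from a short run on weak data (so the chain genuinely
wanders), embeds the pairwise RF distances into the plane, and prints the
first coordinates.  Identical trees receive a small deterministic jitter,
so repeated topologies show up as tight clusters of distinct points
rather than a single dot.
"""

import numpy as np

from bayestree import (RunConfig, build_model, compress_patterns,
                       discretize_gamma, generate_bushy_tree, mds_embed,
                       parse_newick, rf_distance, run, simulate_alignment)

true_tree = generate_bushy_tree(8, 0.3, 0.01, seed=11)    # hard: tiny inner
aln, _ = simulate_alignment(true_tree, build_model("DNA"),
                            discretize_gamma(0.5), 150, seed=12)
pm = compress_patterns(aln)
res = run(RunConfig(n_runs=1, n_generations=2000, sample_every=50, seed=13),
          pm)[0]

trees = [parse_newick(s, aln.taxon_names) for s in res.topologies[13:]]
m = len(trees)
D = np.zeros((m, m))
for i in range(m):
    for j in range(i + 1, m):
        D[i, j] = D[j, i] = rf_distance(trees[i], trees[j])
coords = mds_embed(D, jitter_seed=14)
n_distinct = len({tuple(sorted(t.splits())) for t in trees})
print(f"{m} post-burn-in samples, {n_distinct} distinct topologies, "
      f"RF range 0..{int(D.max())}")
print("first five 2D coordinates (identical trees get jittered apart):")
for row in coords[:5]:
    print(f"  ({row[0]: .3f}, {row[1]: .3f})")
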