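"""Fitch parsimony and stepwise-addition starting trees.

Scores a couple of topologies on a toy alignment, then builds a greedy
stepwise-addition tree on simulated data and compares it (Robinson–Foulds
distance) to the generating topology.  With informative data the starting
tree usually lands on or next to the truth — the point of seeding MCMC
with "reasonable (non-random)" topologies is a shorter burn-in.
"""

import numpy as np

from bayestree import (Alignment, build_model, compress_patterns,
                       discretize_gamma, fitch_score, generate_bushy_tree,
                       parse_newick, rf_distance, simulate_alignment,
                       stepwise_addition_tree)

names = ["t1", "t2", "t3", "t4"]
aln = Alignment(names, np.array([["A"], ["A"], ["C"], ["C"]]))
pm = compress_patterns(aln)
for nwk in ("((t1:1,t2:1):1,t3:1,t4:1);", "((t1:1,t3:1):1,t2:1,t4:1);"):
    print(f"fitch score of {nwk}: {fitch_score(parse_newick(nwk, names), pm)}"
          " (changes needed for the A/A/C/C column)")

true_tree = generate_bushy_tree(12, 0.3, 0.05, seed=4)
aln2, _ = simulate_alignment(true_tree, build_model("DNA"),
                             discretize_gamma(0.5), 800, seed=5)
start = stepwise_addition_tree(aln2, seed=6)
print(f"stepwise-addition tree vs truth: RF = "
      f"{rf_distance(start, true_tree)} (0 = identical topology; "
      f"max {2 * (12 - 3)})")
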