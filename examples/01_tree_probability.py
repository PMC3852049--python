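"""Probability of a gene-tree topology given a species tree.

A three-taxon species tree with an internal branch of T = 1 coalescent unit.
The gene tree matching the species tree has probability 1 - (2/3)e^{-T}
(incomplete lineage sorting fails with probability e^{-T}, and then only one
of the three root resolutions matches); each discordant topology has
probability (1/3)e^{-T}.
"""

from netcoal import parse_gene_tree, parse_species_tree, prob_exact, prob_heuristic

S = parse_species_tree("((A:1,B:1):1,C:2);")

for newick in ("((A,B),C);", "((A,C),B);", "((B,C),A);"):
    g = parse_gene_tree(newick)
    exact = prob_exact(S, g)
    approx = prob_heuristic(S, g, seed=0)
    print(f"{newick:15s}  exact={exact:.6f}  heuristic={approx:.6f}")

# The three probabilities sum to 1; the heuristic sums only the most probable
# coalescent histories, so it is a lower bound on each exact value.
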