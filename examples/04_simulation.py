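"""Simulating gene trees within a species network and checking frequencies.

Gene trees are generated backward in time: lineages coalesce at rate 1 per
pair per coalescent unit within each branch, choose a parent branch at each
hybridization node according to its inheritance probability, and finish
coalescing above the root.  Observed topology frequencies converge to the
probabilities computed by the configuration algorithm.
"""

from collections import Counter

from netcoal import SimConfig, all_rooted_topologies, cal_prob, parse_gene_tree, parse_network, simulate_gene_trees

N = parse_network("((A:1,(X:0.5)#H1:0.5::0.3):1,(#H1:0.5::0.7,C:1):1);")

n = 20_000
freq = Counter(
    g.canonical_newick() for g, _ in simulate_gene_trees(N, n, SimConfig(seed=1))
)
print(f"{n} simulated gene trees:")
for newick in all_rooted_topologies(["A", "C", "X"]):
    g = parse_gene_tree(newick)
    key = g.canonical_newick()
    print(
        f"  {key:15s} observed={freq[key] / n:.4f}  expected={cal_prob(N, g):.4f}"
    )
# Observed and expected frequencies agree to sampling error (~1/sqrt(n)).
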