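"""Gene-tree probabilities on a species network with one hybridization.

Species X arose by hybridization: with inheritance probability 0.3 its
lineages trace toward A's ancestor, with 0.7 toward C's.  The probability of
each gene-tree topology is computed exactly with weighted ancestral
configurations and cross-checked by brute-force enumeration of coalescent
histories.
"""

from netcoal import all_rooted_topologies, brute_prob, cal_prob, parse_gene_tree, parse_network

N = parse_network("((A:1,(X:0.5)#H1:0.5::0.3):1,(#H1:0.5::0.7,C:1):1);")

total = 0.0
for newick in all_rooted_topologies(["A", "C", "X"]):
    g = parse_gene_tree(newick)
    p = cal_prob(N, g)
    oracle = brute_prob(N, g)
    total += p
    print(f"{newick:15s}  P={p:.6f}  (history-enumeration oracle: {oracle:.6f})")
print(f"sum over all rooted topologies = {total:.12f}")

# ((A,X),C) is likelier than under either parental tree alone would suggest at
# gamma near 0 or 1: the network mixes the two displayed trees.
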