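"""Deep-coalescence parsimony: minimum extra lineages on trees and networks.

The cost of reconciling a gene tree with a species phylogeny is the number of
"extra" lineages forced through its branches: for each branch, (lineages
leaving it) - 1, summed and minimized over all coalescent histories.  Branch
lengths and inheritance probabilities play no role — this is a purely
topological criterion.  A network can only lower the cost relative to the
trees it displays, since every displayed tree's reconciliation is available.
"""

from netcoal import (
    brute_xl,
    count_xl,
    displayed_trees,
    parse_gene_tree,
    parse_network,
    parse_species_tree,
    xl_tree,
)

S = parse_species_tree("((A:1,B:1):1,C:2);")
for newick in ("((A,B),C);", "((A,C),B);"):
    g = parse_gene_tree(newick)
    print(f"tree vs {newick:13s} XL = {xl_tree(S, g)}")

N = parse_network("((A:1,(X:0.5)#H1:0.5::0.3):1,(#H1:0.5::0.7,C:1):1);")
for newick in ("((A,X),C);", "((X,C),A);", "((A,C),X);"):
    g = parse_gene_tree(newick)
    net_cost = count_xl(N, g)
    tree_costs = [xl_tree(t, g) for t in displayed_trees(N)]
    print(
        f"network vs {newick:12s} XL = {net_cost} "
        f"(displayed trees: {tree_costs}, oracle: {brute_xl(N, g)})"
    )

# ((A,X),C) and ((X,C),A) both cost 0 on the network (each is displayed);
# on a single parental tree one of them would cost 1.
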