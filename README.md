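# netcoal

Gene trees on species trees and species networks under the multispecies
coalescent — probabilities, parsimony, simulation, and inference.

## The problem

In phylogenomics, trees estimated from individual loci routinely disagree with
each other and with the species phylogeny.  Two biological processes drive
this incongruence: **incomplete lineage sorting** (ILS — gene lineages fail to
coalesce in their own ancestral population and sort at random deeper in the
phylogeny) and **hybridization** (a species inherits genetic material from two
parental lineages, so the species phylogeny is a rooted network rather than a
tree).  `netcoal` computes the two central quantities for analyzing such data:

- **P(g | N)** — the probability of observing a rooted gene-tree *topology*
  `g` given a species phylogeny `N` (tree or network) with branch lengths in
  coalescent units and inheritance probabilities γ on reticulation edges.
  Writing `H_N(g)` for the set of coalescent histories of `g` in `N`,

      P(g|N) = Σ_{h ∈ H_N(g)}  (w(h)/d(h)) Π_b (w_b/d_b) γ(b)^{u_b(h)} p_{u_b v_b}(λ_b),

  where `p_{u,v}(λ)` is the standard coalescent probability that `u` lineages
  become `v` within `λ` coalescent units, and `w_b/d_b` is the fraction of
  event orderings on branch `b` consistent with `g`.

- **XL(N, g)** — the *minimum number of extra lineages* over all
  reconciliations of `g` with `N` (deep-coalescence parsimony):
  `min_h Σ_b max{v_b(h) − 1, 0}`, a topology-only criterion.

Both are computed exactly with **weighted ancestral configurations**: sets of
gene lineages propagated bottom-up through the network that split at
reticulations (with per-reticulation bookkeeping indices), merge at tree
nodes, and collapse at articulation nodes.  A brute-force enumeration of
coalescent histories is included as an independent correctness oracle, along
with a fast **limiting-coalescent-history (LCH) heuristic** for trees that
sums only the most probable histories, an MSC **simulator** (gene trees within
trees/networks, random trees, random networks by midpoint attachment), and a
small **maximum-likelihood species-tree inference** driver with normalized
Robinson-Foulds evaluation.

Intended users: researchers and method developers in phylogenetics who need
exact small-to-moderate-scale coalescent computations on networks, reference
values for testing other software, or a compact simulation/inference sandbox.

## A worked example

```python
from netcoal import parse_network, parse_gene_tree, cal_prob, count_xl

# species X arose by hybridization; 30% of its genome traces toward A
N = parse_network("((A:1,(X:0.5)#H1:0.5::0.3):1,(#H1:0.5::0.7,C:1):1);")

for nwk in ("((A,X),C);", "(A,(X,C));", "((A,C),X);"):
    g = parse_gene_tree(nwk)
    print(nwk, round(cal_prob(N, g), 6), count_xl(N, g))
```

prints

```
((A,X),C); 0.312263 0
(A,(X,C)); 0.565111 0
((A,C),X); 0.122626 1
```

The two gene trees displayed by the network need no extra lineages; the third
groups the two non-hybrid species and costs one.  The probabilities sum to 1
over the three rooted topologies and mix the two parental histories in
proportion to γ = 0.3/0.7 (plus ILS).  See `examples/` for one short script
per capability (tree probabilities and the LCH heuristic, network
probabilities, parsimony, simulation, inference) and run them with
`python examples/01_tree_probability.py` etc.  A thin command-line interface
exposes the same operations (`netcoal --help`).

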