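"""Species-tree computations: exact probability, the LCH heuristic, and parsimony.

The exact gene-tree topology probability is the reticulation-free special case
of the network algorithm.  The heuristic first builds a *limiting coalescent
history* (LCH): a single greedy history that, branch by branch in post-order,
commits the number of coalescences with the highest marginal probability for
that branch length.  The probability is then approximated by summing only the
coalescent histories lying at or below the LCH — every gene-tree clade must
coalesce no higher than where the LCH placed it.  The result is a lower bound
on the exact probability and equals it when the LCH leaves everything at the
root.

Parsimony on trees reduces to least-common-ancestor mapping: coalescing every
clade as low as the topology permits minimizes the number of extra lineages.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .coalescent import coalesce_count_prob, max_coalesced
from .configurations import ConfigSet, Mode
from .model import AlleleMap, GeneTree, MissingLengthError, SpeciesTree, resolve_allele_map
from .reconcile import cal_prob

__all__ = ["LCH", "prob_exact", "compute_lch", "prob_heuristic", "xl_tree"]


@dataclass
class LCH:
    """A limiting coalescent history for a (species tree, gene tree) pair.

    ``assignment[i]`` is the species-tree node on whose parent branch gene-tree
    clade ``i`` coalesces; clades absent from the mapping coalesce above the
    root.  ``numL``/``minL`` record, per species-tree node, the lineage count
    entering its parent branch and the fewest lineages that could leave it.
    """

    assignment: dict[int, int] = field(default_factory=dict)
    numL: dict[int, int] = field(default_factory=dict)
    minL: dict[int, int] = field(default_factory=dict)

    def all_root(self) -> bool:
        return not self.assignment


def prob_exact(S: SpeciesTree, g: GeneTree, mu: AlleleMap | None = None) -> float:
    """Exact probability of gene-tree topology ``g`` given species tree ``S``."""
    return cal_prob(S, g, mu)


def compute_lch(
    S: SpeciesTree, g: GeneTree, mu: AlleleMap | None = None, seed: int = 0
) -> LCH:
    """Greedy per-branch most-probable coalescent history (random tie-breaks).

    Walks the species tree in post-order; on each branch of length ``lam`` with
    ``u`` lineages entering, commits ``u - x`` topology-consistent coalescences
    where ``x`` maximizes ``p_{u,x}(lam)``.  Which events are committed, when
    more are eligible than needed, is decided uniformly at random with the
    given seed.
    """
    if not S.has_lengths:
        raise MissingLengthError("ComputeLCH requires branch lengths")
    mu = resolve_allele_map(g, S, mu)
    rng = random.Random(seed)
    lch = LCH()
    exiting: dict[int, frozenset[int]] = {}
    for v in S.postorder():
        if v == S.root:
            continue
        if S.is_leaf(v):
            sp = S.leaf_label[v]
            entering = frozenset(x for x in g.leaves if mu[g.labels[x]] == sp)
        else:
            entering = frozenset().union(*(exiting[c] for c in S.children[v]))
        (u,) = S.parents[v]
        lam = S.length[(u, v)]
        numL = len(entering)
        minL = len(max_coalesced(entering, g)) if entering else 0
        lch.numL[v], lch.minL[v] = numL, minL
        cur = set(entering)
        if numL != minL:
            best_x, best_p = numL, -1.0
            for x in range(minL, numL + 1):
                p = coalesce_count_prob(numL, x, lam)
                if p >= best_p:
                    best_p, best_x = p, x
            for _ in range(numL - best_x):
                eligible = sorted(
                    {
                        g.parent[x]
                        for x in cur
                        if g.parent[x] is not None
                        and all(c in cur for c in g.children[g.parent[x]])
                    }
                )
                y = rng.choice(eligible)
                cur -= set(g.children[y])
                cur.add(y)
                lch.assignment[y] = v
        exiting[v] = frozenset(cur)
    return lch


def prob_heuristic(
    S: SpeciesTree, g: GeneTree, mu: AlleleMap | None = None, seed: int = 0
) -> float:
    """Approximate P(g|S) by summing only histories at or below the LCH.

    Implemented on ancestral configurations: when configurations leave the
    branch above the node the LCH assigned to clade ``i``, any configuration in
    which clade ``i`` has not yet formed is discarded.  Always in
    ``(0, prob_exact]``; equals the exact value when the LCH keeps every clade
    at the root.  Deterministic for fixed inputs and seed.
    """
    mu = resolve_allele_map(g, S, mu)
    lch = compute_lch(S, g, mu, seed=seed)
    if lch.all_root():
        return cal_prob(S, g, mu)
    deadline: dict[int, list[int]] = {}
    for clade, v in lch.assignment.items():
        deadline.setdefault(v, []).append(clade)

    def edge_filter(v: int, cs: ConfigSet) -> ConfigSet:
        clades = deadline.get(v)
        if not clades:
            return cs
        strict_desc = [
            g.descendants(i) - {i} for i in clades
        ]
        out = ConfigSet(Mode.PROB)
        for (B, a), w in cs.items():
            if any(B & d for d in strict_desc):
                continue
            out.add(B, a, w)
        return out

    return cal_prob(S, g, mu, edge_filter=edge_filter)


def xl_tree(S: SpeciesTree, g: GeneTree, mu: AlleleMap | None = None) -> int:
    """Minimum extra lineages on a species tree (coalesce-as-early-as-possible).

    Equivalent to the least-common-ancestor reconciliation: on trees, greedily
    coalescing on every branch is optimal, so the cost is the sum over branches
    of (lineages leaving the branch - 1).
    """
    mu = resolve_allele_map(g, S, mu)
    total = 0
    exiting: dict[int, frozenset[int]] = {}
    for v in S.postorder():
        if S.is_leaf(v):
            sp = S.leaf_label[v]
            entering = frozenset(x for x in g.leaves if mu[g.labels[x]] == sp)
        else:
            entering = frozenset().union(*(exiting[c] for c in S.children[v]))
        out = max_coalesced(entering, g) if entering else frozenset()
        exiting[v] = out
        if v != S.root:
            total += max(len(out) - 1, 0)
    return total
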