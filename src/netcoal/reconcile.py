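"""Exact network algorithms over weighted ancestral configurations.

``count_xl`` computes the minimum number of extra lineages needed to
reconcile a gene tree with a species network (the deep-coalescence parsimony
cost); ``cal_prob`` computes the probability of observing the gene-tree
topology given the network under the multispecies coalescent with
hybridization.  Both traverse the network bottom-up, maintaining a set of
weighted ancestral configurations per edge: configurations split at
reticulations, merge at tree nodes, coalesce along edges, and collapse at
articulation nodes.

The two weight semantics differ only in a handful of local rules (neutral
element, split/merge weights, per-edge update), so both algorithms share one
traversal.
"""

from __future__ import annotations

import math
from typing import Callable

from .coalescent import coal_set, max_coalesced, transition_prob
from .configurations import (
    ConfigSet,
    Mode,
    SplitCounters,
    find_articulation_nodes,
    reduce_at_articulation,
    _vector_max,
    _vectors_compatible,
)
from .model import (
    AlleleMap,
    CapacityError,
    GeneTree,
    MissingLengthError,
    SpeciesNetwork,
    resolve_allele_map,
)

__all__ = [
    "create_cacs_for_xl",
    "create_cacs_for_prob",
    "count_xl",
    "cal_prob",
    "displayed_trees",
]

#: Default ceiling on the number of configurations alive on any one edge.
MAX_CONFIGS = 500_000

EdgeFilter = Callable[[int, ConfigSet], ConfigSet]


def create_cacs_for_xl(g: GeneTree, entering: ConfigSet) -> ConfigSet:
    """Configurations exiting an edge under parsimony.

    Each entering configuration coalesces maximally (under parsimony nothing
    is gained by stopping early) and pays ``max(|B+| - 1, 0)`` extra lineages
    for the edge; identical survivors keep the minimum weight.
    """
    out = ConfigSet(Mode.XL)
    for (B, a), w in entering.items():
        B_plus = max_coalesced(B, g)
        out.add(B_plus, a, w + max(len(B_plus) - 1, 0))
    return out


def create_cacs_for_prob(g: GeneTree, branch_length: float, entering: ConfigSet) -> ConfigSet:
    """Configurations exiting an edge of the given length, with probabilities.

    Every entering configuration fans out over everything its lineage set can
    coalesce into along the edge; weights of identical outcomes add.
    """
    if branch_length is None:
        raise MissingLengthError("probability computation requires branch lengths")
    out = ConfigSet(Mode.PROB)
    for (B, a), w in entering.items():
        for B_plus in coal_set(B, g):
            out.add(B_plus, a, w * transition_prob(B, B_plus, branch_length, g))
    return out


def _merge_sets(s1: ConfigSet, s2: ConfigSet, mode: Mode) -> ConfigSet:
    """All pairwise merges of compatible configurations from two child edges."""
    out = ConfigSet(mode)
    for (B1, a1), w1 in s1.items():
        for (B2, a2), w2 in s2.items():
            if not _vectors_compatible(a1, a2):
                continue
            B = B1 | B2
            if len(B) != len(B1) + len(B2):  # pragma: no cover - defensive
                raise AssertionError("compatible configurations overlap in lineages")
            out.add(B, _vector_max(a1, a2), mode.merge_weights(w1, w2))
    return out


def _traverse(
    N: SpeciesNetwork,
    g: GeneTree,
    mu: AlleleMap,
    mode: Mode,
    use_reduction: bool = True,
    edge_filter: EdgeFilter | None = None,
    max_configs: int = MAX_CONFIGS,
) -> float:
    q = N.q
    zeros = (0,) * q
    counters = SplitCounters(q)
    articulations = find_articulation_nodes(N) if use_reduction else set()
    alleles_of = {
        sp: frozenset(
            v for v in g.leaves if mu[g.labels[v]] == sp
        )
        for sp in N.leaf_label.values()
    }

    def process_edge(e: tuple[int, int], cs: ConfigSet) -> ConfigSet:
        if mode is Mode.XL:
            out = create_cacs_for_xl(g, cs)
        else:
            out = create_cacs_for_prob(g, N.length.get(e), cs)
        if edge_filter is not None:
            out = edge_filter(e[1], out)
        if len(out) > max_configs:
            raise CapacityError(
                f"{len(out)} configurations on edge {e} exceed the cap {max_configs}"
            )
        return out

    edge_acs: dict[tuple[int, int], ConfigSet] = {}
    for v in N.postorder():
        if N.is_leaf(v):
            cs = ConfigSet(mode)
            cs.add(alleles_of[N.leaf_label[v]], zeros, mode.neutral)
            (u,) = N.parents[v]
            edge_acs[(u, v)] = process_edge((u, v), cs)
        elif N.is_reticulation(v):
            (w,) = N.children[v]
            cs = edge_acs.pop((v, w))
            k = N.reticulation_index[v]
            u1, u2 = N.parents[v]
            sides = (ConfigSet(mode), ConfigSet(mode))
            for (B, a), wt in cs.sorted_items():
                members = sorted(B)
                for mask in range(1 << len(members)):
                    # one fresh split index per bipartition: only the two
                    # halves of the same bipartition may merge back later
                    idx = counters.fresh(k)
                    a_new = a[: k - 1] + (idx,) + a[k:]
                    B1 = frozenset(m for i, m in enumerate(members) if mask >> i & 1)
                    B2 = B - B1
                    sides[0].add(B1, a_new, wt)
                    sides[1].add(B2, a_new, mode.neutral)
            for u, side in zip((u1, u2), sides):
                if mode is Mode.PROB:
                    gam = N.gamma[(u, v)]
                    weighted = ConfigSet(mode)
                    for (B, a), wt in side.items():
                        weighted.add(B, a, wt * gam ** len(B))
                    side = weighted
                edge_acs[(u, v)] = process_edge((u, v), side)
        else:  # internal tree node or root
            kids = N.children[v]
            cs = edge_acs.pop((v, kids[0]))
            for w in kids[1:]:
                cs = _merge_sets(cs, edge_acs.pop((v, w)), mode)
                if len(cs) > max_configs:
                    raise CapacityError(
                        f"{len(cs)} configurations at node {v} exceed the cap"
                    )
            if v in articulations and q:
                cs = reduce_at_articulation(cs, mode)
            if v == N.root:
                return _finalize(cs, g, mode)
            (u,) = N.parents[v]
            edge_acs[(u, v)] = process_edge((u, v), cs)
    raise AssertionError("traversal ended without reaching the root")


def _finalize(cs: ConfigSet, g: GeneTree, mode: Mode) -> float:
    if mode is Mode.XL:
        return min(w for _, w in cs.items())
    root_set = frozenset({g.root})
    return math.fsum(
        w * transition_prob(B, root_set, math.inf, g) for (B, _), w in cs.items()
    )


def count_xl(
    N: SpeciesNetwork,
    g: GeneTree,
    mu: AlleleMap | None = None,
    use_reduction: bool = True,
    max_configs: int = MAX_CONFIGS,
) -> int:
    """Minimum number of extra lineages reconciling ``g`` with the network.

    Topology-only: branch lengths and inheritance probabilities are ignored.
    """
    mu = resolve_allele_map(g, N, mu)
    return int(
        _traverse(N, g, mu, Mode.XL, use_reduction=use_reduction, max_configs=max_configs)
    )


def cal_prob(
    N: SpeciesNetwork,
    g: GeneTree,
    mu: AlleleMap | None = None,
    use_reduction: bool = True,
    edge_filter: EdgeFilter | None = None,
    max_configs: int = MAX_CONFIGS,
) -> float:
    """Probability of observing gene-tree topology ``g`` given the network.

    Requires branch lengths (coalescent units) on all edges and inheritance
    probabilities on reticulation in-edges.
    """
    mu = resolve_allele_map(g, N, mu)
    return _traverse(
        N,
        g,
        mu,
        Mode.PROB,
        use_reduction=use_reduction,
        edge_filter=edge_filter,
        max_configs=max_configs,
    )


# ---------------------------------------------------------------------------
# Displayed trees
# ---------------------------------------------------------------------------


def displayed_trees(N: SpeciesNetwork) -> list["SpeciesNetwork"]:
    """All trees displayed in ``N``: one in-edge kept per reticulation.

    Suppressed degree-two nodes have their branch lengths added.  Returned as
    :class:`SpeciesTree` objects (lengths preserved, gammas all 1).
    """
    from itertools import product as _product

    choices = list(_product(*[range(2) for _ in N.reticulations]))
    out = []
    for choice in choices:
        keep_parent = {
            r: N.parents[r][c] for r, c in zip(N.reticulations, choice)
        }
        children: dict[int, list[int]] = {v: [] for v in N.nodes}
        length: dict[tuple[int, int], float | None] = {}
        for (u, v) in N.edges:
            if N.is_reticulation(v) and keep_parent[v] != u:
                continue
            children[u].append(v)
            length[(u, v)] = N.length.get((u, v))
        # drop nodes no longer reachable from the root, then suppress
        # in-1/out-1 nodes and out-degree-1 roots
        reachable: set[int] = set()
        stack = [N.root]
        while stack:
            x = stack.pop()
            if x in reachable:
                continue
            reachable.add(x)
            stack.extend(children[x])
        children = {v: [c for c in kids] for v, kids in children.items() if v in reachable}
        parents: dict[int, list[int]] = {v: [] for v in children}
        for u, kids in children.items():
            for v in kids:
                parents[v].append(u)
        changed = True
        while changed:
            changed = False
            for v in list(children):
                if v not in children:
                    continue
                if len(parents[v]) == 1 and len(children[v]) == 1:
                    (u,), (c,) = parents[v], children[v]
                    lu, lc = length.pop((u, v)), length.pop((v, c))
                    newlen = None if lu is None or lc is None else lu + lc
                    children[u][children[u].index(v)] = c
                    parents[c] = [u]
                    length[(u, c)] = newlen
                    del children[v], parents[v]
                    changed = True
                elif len(parents[v]) == 0 and len(children[v]) == 1:
                    (c,) = children[v]
                    length.pop((v, c), None)
                    del children[v], parents[v]
                    parents[c] = []
                    changed = True
        root = next(v for v in children if not parents[v])
        gamma = {e: 1.0 for e in length}
        labels = {v: N.leaf_label[v] for v in children if not children[v]}
        from .model import SpeciesTree

        out.append(SpeciesTree(children, length, gamma, labels))
    return out
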