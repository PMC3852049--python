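"""Brute-force enumeration of coalescent histories.

A coalescent history maps every gene-tree node to the species-network edge on
which that coalescence (or, for leaves, sampling) occurs, respecting the
species assignment of the alleles and ancestry: a node must map at or below
wherever its ancestors map.  On a network a history additionally fixes, for
every gene lineage and every reticulation it crosses, which parent edge the
lineage follows; these routings are enumerated explicitly here.

Summing per-history probabilities yields the exact gene-tree topology
probability; minimizing per-history extra-lineage counts yields the parsimony
reconciliation cost.  Both are exponential-time reference computations meant
for small instances; the fast configuration-based algorithms are checked
against them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import product

from .coalescent import transition_prob
from .model import AlleleMap, CapacityError, GeneTree, MissingLengthError, SpeciesNetwork
from .model import resolve_allele_map

__all__ = [
    "ROOT_EDGE",
    "CoalescentHistory",
    "enumerate_histories",
    "history_prob",
    "history_xl",
    "brute_prob",
    "brute_xl",
]

#: Sentinel for the implicit infinite branch above the network root.
ROOT_EDGE = (-1, -1)

Edge = tuple[int, int]


@dataclass
class CoalescentHistory:
    """One coalescent history with its derived per-edge lineage sets.

    ``node_edge`` maps every gene-tree node to a network edge (``ROOT_EDGE``
    for coalescences above the root).  ``entering[b]`` is the set of lineages
    entering edge ``b`` from below (``u_b``), ``exiting[b]`` the set leaving it
    at the top (``v_b``); only touched edges are listed.
    """

    node_edge: dict[int, Edge]
    entering: dict[Edge, frozenset[int]]
    exiting: dict[Edge, frozenset[int]]

    def u(self, b: Edge) -> int:
        return len(self.entering.get(b, ()))

    def v(self, b: Edge) -> int:
        return len(self.exiting.get(b, ()))


def _edge_top(e: Edge) -> int:
    return e[0]


def _edge_bottom(e: Edge, N: SpeciesNetwork) -> int:
    return N.root if e == ROOT_EDGE else e[1]


def enumerate_histories(
    N: SpeciesNetwork,
    g: GeneTree,
    mu: AlleleMap | None = None,
    max_histories: int = 2_000_000,
) -> list[CoalescentHistory]:
    """Exhaustive, duplicate-free enumeration of coalescent histories.

    Intended for small instances; raises :class:`CapacityError` beyond
    ``max_histories``.
    """
    mu = resolve_allele_map(g, N, mu)
    anc = N.ancestors()  # node -> nodes at or above it
    edges = N.edges

    # -- upward routes between network nodes (sequences of edges climbed) ---
    @lru_cache(maxsize=None)
    def routes(a: int, d: int) -> tuple[tuple[Edge, ...], ...]:
        """All directed upward edge-paths from node ``a`` to ancestor ``d``."""
        if a == d:
            return ((),)
        out = []
        for p in N.parents[a]:
            if d in anc[p]:
                for rest in routes(p, d):
                    out.append(((p, a),) + rest)
        return tuple(out)

    # -- candidate edges per gene-tree node, assigned in post-order ---------
    leaf_edge = {v: N.leaf_edge(mu[g.labels[v]]) for v in g.leaves}

    assignments: list[dict[int, Edge]] = [dict(leaf_edge)]
    for y in range(g.n_nodes):
        if g.is_leaf(y):
            continue
        new_assignments = []
        for asg in assignments:
            child_edges = [asg[c] for c in g.children[y]]
            if any(e == ROOT_EDGE for e in child_edges):
                candidates: list[Edge] = [ROOT_EDGE]
            else:
                candidates = [ROOT_EDGE]
                for e in edges:
                    ok = all(
                        e == ce or _edge_bottom(e, N) in anc[_edge_top(ce)]
                        for ce in child_edges
                    )
                    if ok:
                        candidates.append(e)
            for e in candidates:
                nxt = dict(asg)
                nxt[y] = e
                new_assignments.append(nxt)
        if len(new_assignments) > max_histories:
            raise CapacityError("too many coalescent histories to enumerate")
        assignments = new_assignments

    # -- expand every assignment over lineage routings ----------------------
    histories: list[CoalescentHistory] = []
    for asg in assignments:
        lineages = [x for x in range(g.n_nodes) if x != g.root]
        per_lineage_routes: list[list[tuple[Edge, ...]]] = []
        feasible = True
        for x in lineages:
            e_lo, e_hi = asg[x], asg[g.parent[x]]
            if e_lo == e_hi:
                rs = [()]
            elif e_hi == ROOT_EDGE:
                rs = [r + (ROOT_EDGE,) for r in routes(_edge_top(e_lo), N.root)]
            else:
                rs = [
                    r + (e_hi,)
                    for r in routes(_edge_top(e_lo), _edge_bottom(e_hi, N))
                ]
            if not rs:
                feasible = False
                break
            per_lineage_routes.append(rs)
        if not feasible:
            continue
        total = math.prod(len(r) for r in per_lineage_routes)
        if len(histories) + total > max_histories:
            raise CapacityError("too many coalescent histories to enumerate")
        for combo in product(*per_lineage_routes):
            entering: dict[Edge, set[int]] = {}
            for x, path in zip(lineages, combo):
                entered = path if not g.is_leaf(x) else (asg[x],) + path
                for b in entered:
                    entering.setdefault(b, set()).add(x)
            histories.append(_finish_history(asg, entering, g))
    return histories


def _finish_history(
    asg: dict[int, Edge], entering: dict[Edge, set[int]], g: GeneTree
) -> CoalescentHistory:
    events: dict[Edge, list[int]] = {}
    for y in g.internal_nodes():
        events.setdefault(asg[y], []).append(y)
    exiting: dict[Edge, frozenset[int]] = {}
    entering_f: dict[Edge, frozenset[int]] = {}
    for b in set(entering) | set(events):
        S = set(entering.get(b, ()))
        entering_f[b] = frozenset(S)
        for y in sorted(events.get(b, ())):  # post-order ids: children first
            S -= set(g.children[y])
            S.add(y)
        exiting[b] = frozenset(S)
    return CoalescentHistory(dict(asg), entering_f, exiting)


def history_prob(hist: CoalescentHistory, N: SpeciesNetwork, g: GeneTree) -> float:
    """Probability contribution of one coalescent history (one term of the sum).

    The product over touched edges of
    ``(w_b/d_b) * gamma(b)^{u_b} * p_{u_b, v_b}(lambda_b)``, with the implicit
    root branch contributing its ordering fraction at infinite length.
    """
    p = 1.0
    for b, U in hist.entering.items():
        V = hist.exiting[b]
        if b == ROOT_EDGE:
            t = math.inf
        else:
            t = N.length.get(b)
            if t is None:
                raise MissingLengthError(f"edge {b} has no branch length")
        factor = transition_prob(U, V, t, g)
        if b != ROOT_EDGE:
            gam = N.gamma[b]
            if gam != 1.0:
                factor *= gam ** len(U)
        p *= factor
        if p == 0.0:
            break
    return p


def history_xl(hist: CoalescentHistory, N: SpeciesNetwork) -> int:
    """Extra lineages of one history: sum over explicit edges of max(v_b - 1, 0)."""
    return sum(
        max(len(V) - 1, 0) for b, V in hist.exiting.items() if b != ROOT_EDGE
    )


def brute_prob(
    N: SpeciesNetwork,
    g: GeneTree,
    mu: AlleleMap | None = None,
    max_histories: int = 2_000_000,
) -> float:
    """Exact gene-tree topology probability by summation over all histories."""
    hists = enumerate_histories(N, g, mu, max_histories=max_histories)
    return math.fsum(history_prob(h, N, g) for h in hists)


def brute_xl(
    N: SpeciesNetwork,
    g: GeneTree,
    mu: AlleleMap | None = None,
    max_histories: int = 2_000_000,
) -> int:
    """Minimum extra lineages over all coalescent histories."""
    hists = enumerate_histories(N, g, mu, max_histories=max_histories)
    return min(history_xl(h, N) for h in hists)
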