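"""Scalar coalescent primitives shared by every algorithm in the package.

The central quantity is ``p_{u,v}(t)``: under the standard coalescent, the
probability that ``u`` lineages are reduced to ``v`` lineages after ``t``
coalescent units (Tavare's alternating sum).  On top of it sit the
combinatorial pieces needed for gene-tree topologies: the number of orderings
of a fixed number of coalescent events, the number of those orderings that
respect a gene tree (a linear-extension count of the required-event forest),
and the closure ``Coal(B, g)`` of a lineage set under topology-consistent
merges.

Lineage sets are frozensets of gene-tree node ids forming an antichain of the
gene tree: the lineages that coexist at one point of the species phylogeny.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

from .model import CapacityError, GeneTree

__all__ = [
    "MAX_LINEAGES",
    "coalesce_count_prob",
    "total_orderings",
    "consistent_orderings",
    "transition_prob",
    "coal_set",
    "max_coalesced",
]

#: Largest lineage count for which the alternating sum is evaluated; the
#: coefficients are exact rationals, so this is a capacity choice, not a
#: stability one.
MAX_LINEAGES = 30


@lru_cache(maxsize=None)
def _tavare_coefficients(u: int, v: int) -> tuple[tuple[int, float], ...]:
    """Exact coefficients c_k of p_{u,v}(t) = sum_k c_k * exp(-k(k-1)t/2)."""
    out = []
    for k in range(v, u + 1):
        c = Fraction((2 * k - 1) * (-1) ** (k - v))
        c /= Fraction(math.factorial(v) * math.factorial(k - v) * (v + k - 1))
        for y in range(k):
            c *= Fraction((v + y) * (u - y), (u + y))
        out.append((k, float(c)))
    return tuple(out)


def coalesce_count_prob(u: int, v: int, t: float) -> float:
    """Probability that ``u`` lineages coalesce into ``v`` within time ``t``.

    ``t`` is in coalescent units and may be ``math.inf`` (then the answer is 1
    iff ``v == 1``).  Requires ``1 <= v <= u <= MAX_LINEAGES``.
    """
    if not 1 <= v <= u:
        raise ValueError(f"need 1 <= v <= u, got u={u}, v={v}")
    if u > MAX_LINEAGES:
        raise CapacityError(f"lineage count {u} exceeds the cap of {MAX_LINEAGES}")
    if t < 0:
        raise ValueError("negative time")
    if u == v == 1:
        return 1.0
    if math.isinf(t):
        return 1.0 if v == 1 else 0.0
    if t == 0.0:
        return 1.0 if u == v else 0.0
    p = math.fsum(
        c * math.exp(-0.5 * k * (k - 1) * t) for k, c in _tavare_coefficients(u, v)
    )
    return max(p, 0.0)


def total_orderings(u: int, v: int) -> int:
    """Number of orderings of ``u - v`` unconstrained pairwise coalescences."""
    if not 1 <= v <= u:
        raise ValueError(f"need 1 <= v <= u, got u={u}, v={v}")
    d = 1
    for k in range(v + 1, u + 1):
        d *= k * (k - 1) // 2
    return d


def _required_events(
    B: frozenset[int], B_plus: frozenset[int], g: GeneTree
) -> list[int]:
    """Gene-tree nodes created in coalescing ``B`` into ``B_plus``.

    Raises ``ValueError`` when ``B_plus`` is not reachable from ``B``.
    """
    events: list[int] = []

    def gather(y: int) -> None:
        if y in B:
            return
        if g.is_leaf(y):
            raise ValueError("target set not reachable from source set")
        events.append(y)
        for c in g.children[y]:
            gather(c)

    for tgt in B_plus:
        gather(tgt)
    covered = set(B_plus)
    for y in events:
        covered.update(g.children[y])
    if not B <= covered or len(events) != len(B) - len(B_plus):
        raise ValueError("target set not reachable from source set")
    return events


def consistent_orderings(
    B: frozenset[int], B_plus: frozenset[int], g: GeneTree
) -> int:
    """Number of event orderings turning ``B`` into ``B_plus`` that respect ``g``.

    A merge creating gene-tree node ``x`` may only occur once both children of
    ``x`` are present, so the admissible orderings are the linear extensions of
    the forest of required events; counted with the forest hook-length formula
    ``r! / prod(subtree sizes)``.
    """
    key = (B, B_plus)
    cached = g._orderings_cache.get(key)
    if cached is not None:
        return cached
    events = _required_events(B, B_plus, g)
    ev = set(events)
    sizes: dict[int, int] = {}
    for y in sorted(events):  # post-order ids: children before parents
        sizes[y] = 1 + sum(sizes[c] for c in g.children[y] if c in ev)
    # children of an event inside the event set are direct; deeper events hang
    # below those, so summing immediate event-children sizes is exact because
    # ids increase toward the root and each event's event-descendants form its
    # subtree within the forest.
    w = math.factorial(len(events))
    for s in sizes.values():
        w //= s
    g._orderings_cache[key] = w
    return w


def coal_set(B: frozenset[int], g: GeneTree) -> frozenset[frozenset[int]]:
    """``Coal(B, g)``: every lineage set ``B`` can coalesce into, including ``B``."""
    B = frozenset(B)
    cached = g._coal_cache.get(B)
    if cached is not None:
        return cached
    out = {B}
    for y in _mergeable(B, g):
        merged = (B - frozenset(g.children[y])) | {y}
        out |= coal_set(merged, g)
    res = frozenset(out)
    g._coal_cache[B] = res
    return res


def _mergeable(B: frozenset[int], g: GeneTree) -> list[int]:
    seen: set[int] = set()
    out = []
    for x in B:
        p = g.parent[x]
        if p is None or p in seen:
            continue
        seen.add(p)
        if all(c in B for c in g.children[p]):
            out.append(p)
    return out


def max_coalesced(B: frozenset[int], g: GeneTree) -> frozenset[int]:
    """The unique minimum-cardinality element of ``Coal(B, g)`` (greedy merging)."""
    B = frozenset(B)
    cached = g._maxcoal_cache.get(B)
    if cached is not None:
        return cached
    cur = B
    while True:
        ms = _mergeable(cur, g)
        if not ms:
            break
        y = ms[0]
        cur = (cur - frozenset(g.children[y])) | {y}
    g._maxcoal_cache[B] = cur
    return cur


def transition_prob(
    B: frozenset[int], B_plus: frozenset[int], t: float, g: GeneTree
) -> float:
    """Probability that lineage set ``B`` leaves a branch of length ``t`` as ``B_plus``.

    The product ``p_{|B|,|B+|}(t) * w / d`` where ``w`` counts event orderings
    consistent with ``g`` and ``d`` counts all orderings.  ``t = inf`` encodes
    the implicit branch above the root.
    """
    B, B_plus = frozenset(B), frozenset(B_plus)
    if len(B) <= 1:
        if B_plus != B:
            raise ValueError("a lone lineage cannot change")
        return 1.0
    if B == B_plus:
        return coalesce_count_prob(len(B), len(B), t)
    w = consistent_orderings(B, B_plus, g)  # validates reachability
    d = total_orderings(len(B), len(B_plus))
    p = coalesce_count_prob(len(B), len(B_plus), t)
    return p * w / d
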