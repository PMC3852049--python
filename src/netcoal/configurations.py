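"""Weighted ancestral configurations and their algebra.

An ancestral configuration (AC) records the gene lineages present at a point
of the species network together with bookkeeping for reticulations: a vector
of split indices (entry ``i`` is nonzero iff the lineage set was produced by a
particular split at reticulation ``i``; 0 means "did not pass through that
split") and a weight.  The weight is an extra-lineage count in parsimony mode
(``Mode.XL``) or a cumulative probability in probability mode (``Mode.PROB``).

Two configurations are *compatible* when their vectors agree wherever both are
nonzero; only compatible configurations may merge at a tree node.  At a
reticulation, a configuration splits into all ``2^|B|`` ordered bipartitions of
its lineage set, every pair stamped with one fresh split index.  At an
articulation node (a node whose removal disconnects the network) the vectors
can be reset to zero, collapsing configurations that differ only in
reticulation bookkeeping that is already fully resolved.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Iterator

from .model import SpeciesNetwork

__all__ = [
    "Mode",
    "Config",
    "SplitCounters",
    "ConfigSet",
    "compatible",
    "split",
    "merge",
    "find_articulation_nodes",
    "reduce_at_articulation",
]


class Mode(enum.Enum):
    """Weight semantics: extra-lineage counts (XL) or probabilities (PROB)."""

    XL = "xl"
    PROB = "prob"

    @property
    def neutral(self) -> float:
        """Weight of the merge-neutral (empty) configuration."""
        return 0 if self is Mode.XL else 1.0

    def combine(self, w1: float, w2: float) -> float:
        """Consolidation rule for identical configurations within one set."""
        return min(w1, w2) if self is Mode.XL else w1 + w2

    def merge_weights(self, w1: float, w2: float) -> float:
        return w1 + w2 if self is Mode.XL else w1 * w2


@dataclass(frozen=True)
class Config:
    """One weighted ancestral configuration ``(B, a, w)``."""

    B: frozenset[int]
    a: tuple[int, ...]
    w: float

    def key(self) -> tuple[frozenset[int], tuple[int, ...]]:
        return (self.B, self.a)


class SplitCounters:
    """Per-reticulation counters of splits performed so far (``o_i`` in the text)."""

    def __init__(self, q: int):
        self.counts = [0] * q

    def fresh(self, k: int) -> int:
        """Consume and return the next split index at reticulation ``k`` (1-based)."""
        self.counts[k - 1] += 1
        return self.counts[k - 1]


class ConfigSet:
    """A set of configurations attached to a node or edge.

    Internally a dict ``(B, a) -> w``; adding a configuration whose ``(B, a)``
    already exists consolidates weights by the mode rule (minimum for XL,
    sum for PROB).
    """

    __slots__ = ("mode", "_d")

    def __init__(self, mode: Mode, items: Iterable[Config] = ()):
        self.mode = mode
        self._d: dict[tuple[frozenset[int], tuple[int, ...]], float] = {}
        for c in items:
            self.add(c.B, c.a, c.w)

    def add(self, B: frozenset[int], a: tuple[int, ...], w: float) -> None:
        key = (B, a)
        old = self._d.get(key)
        self._d[key] = w if old is None else self.mode.combine(old, w)

    def __len__(self) -> int:
        return len(self._d)

    def __iter__(self) -> Iterator[Config]:
        for (B, a), w in self._d.items():
            yield Config(B, a, w)

    def items(self):
        return self._d.items()

    def sorted_items(self):
        """Deterministic iteration order: canonical by sorted lineage ids then vector."""
        return sorted(self._d.items(), key=lambda kv: (sorted(kv[0][0]), kv[0][1]))

    def __contains__(self, key) -> bool:
        return key in self._d


def compatible(c1: Config, c2: Config) -> bool:
    """True when the split-index vectors agree wherever both are nonzero."""
    if len(c1.a) != len(c2.a):
        raise ValueError("split-index vectors of different lengths")
    return _vectors_compatible(c1.a, c2.a)


def _vectors_compatible(a1: tuple[int, ...], a2: tuple[int, ...]) -> bool:
    for x, y in zip(a1, a2):
        if x != y and x != 0 and y != 0:
            return False
    return True


def _vector_max(a1: tuple[int, ...], a2: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(x if x >= y else y for x, y in zip(a1, a2))


def split(
    c: Config, k: int, counters: SplitCounters, mode: Mode
) -> list[tuple[Config, Config]]:
    """All ``2^|B|`` ordered bipartitions of ``c`` at reticulation ``k`` (1-based).

    Each bipartition consumes its own fresh split index, stamped on both of
    its members: the two halves of one bipartition can later merge back (equal
    indices), while halves of different bipartitions — which would double- or
    zero-count lineages — are incompatible.  The first member keeps the weight
    of ``c``; the second gets the neutral weight (0 for XL, 1 for PROB).
    """
    if not 1 <= k <= len(c.a):
        raise ValueError(f"reticulation index {k} out of range")
    members = sorted(c.B)
    pairs: list[tuple[Config, Config]] = []
    for mask in range(1 << len(members)):
        idx = counters.fresh(k)
        a_new = c.a[: k - 1] + (idx,) + c.a[k:]
        B1 = frozenset(m for i, m in enumerate(members) if mask >> i & 1)
        B2 = c.B - B1
        pairs.append(
            (Config(B1, a_new, c.w), Config(B2, a_new, mode.neutral))
        )
    return pairs


def merge(c1: Config, c2: Config, mode: Mode) -> Config:
    """Merge two compatible configurations from disjoint subtrees at a tree node."""
    if not compatible(c1, c2):
        raise ValueError("cannot merge incompatible configurations")
    if c1.B & c2.B:
        raise ValueError("lineage sets to merge must be disjoint")
    return Config(
        c1.B | c2.B, _vector_max(c1.a, c2.a), mode.merge_weights(c1.w, c2.w)
    )


def find_articulation_nodes(N: SpeciesNetwork) -> set[int]:
    """Nodes whose removal disconnects their rooted subnetwork from the rest.

    A non-leaf node qualifies when every in-edge of each of its strict
    descendants originates inside its descendant set: then all reticulation
    bookkeeping below it is resolved and split-index vectors can be reset.
    The root always qualifies (the implicit branch above it separates it), and
    on a species tree every internal node does.  Note this is stricter than an
    undirected cut vertex: the flank of a reticulation "diamond" separates its
    pendant leaves but not its subnetwork, and must not reset vectors.
    """
    desc: dict[int, set[int]] = {v: {v} for v in N.nodes}
    for v in N.postorder():
        for c in N.children[v]:
            desc[v] |= desc[c]
    out = set()
    for v in N.nodes:
        if N.is_leaf(v):
            continue
        dv = desc[v]
        if all(p in dv for c in dv if c != v for p in N.parents[c]):
            out.add(v)
    return out


def reduce_at_articulation(cs: ConfigSet, mode: Mode) -> ConfigSet:
    """Reset split-index vectors to zero at an articulation node.

    Everything below an articulation node is resolved, so configurations that
    differ only in their vectors are interchangeable: in XL mode the
    minimum-weight configuration per distinct lineage set survives, in PROB
    mode weights of identical lineage sets are summed.
    """
    out = ConfigSet(mode)
    q = 0
    for (B, a), w in cs.items():
        q = len(a)
        out.add(B, (0,) * q, w)
    return out
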