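"""Data model for species networks, species trees, gene trees and allele maps.

A species network is a rooted directed acyclic graph whose nodes partition into
a root (in-degree 0, out-degree >= 2), internal tree nodes (in 1, out >= 2),
reticulation nodes (in 2, out 1) and leaves (in 1, out 0).  Edges carry branch
lengths in coalescent units and, on reticulation in-edges, inheritance
probabilities gamma that sum to 1 over the in-edges of each node.  A species
tree is the reticulation-free special case.  Gene trees are rooted binary trees
on allele labels; an allele map sends allele names to species names and need be
neither injective nor surjective.

Networks are read and written in the rich-Newick dialect: hybrid nodes are
tagged ``#Hk`` and edge annotations are ``:length:support:gamma`` with the
support field left empty.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PhyloError",
    "ParseError",
    "ValidationError",
    "MissingLengthError",
    "CapacityError",
    "GeneTree",
    "SpeciesNetwork",
    "SpeciesTree",
    "AlleleMap",
    "parse_gene_tree",
    "parse_network",
    "parse_species_tree",
    "parse_allele_map",
    "write_network",
    "all_rooted_topologies",
]

GAMMA_TOL = 1e-9


class PhyloError(Exception):
    """Base class for errors raised by this package."""


class ParseError(PhyloError):
    pass


class ValidationError(PhyloError):
    pass


class MissingLengthError(PhyloError):
    """A computation that needs branch lengths met an edge without one."""


class CapacityError(PhyloError):
    """An instance exceeds a configured size ceiling."""


# ---------------------------------------------------------------------------
# Newick tokenizing (shared by gene trees and networks)
# ---------------------------------------------------------------------------


@dataclass
class _RawNode:
    children: list["_RawNode"]
    label: str | None = None
    length: float | None = None
    gamma: float | None = None


def _parse_newick_string(text: str) -> _RawNode:
    s = text.strip()
    if not s.endswith(";"):
        raise ParseError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def error(msg: str) -> ParseError:
        return ParseError(f"{msg} (at position {pos})")

    def parse_subtree() -> _RawNode:
        nonlocal pos
        node = _RawNode(children=[])
        if pos < len(s) and s[pos] == "(":
            pos += 1
            node.children.append(parse_subtree())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                node.children.append(parse_subtree())
            if pos >= len(s) or s[pos] != ")":
                raise error("expected ')'")
            pos += 1
        # label (possibly containing a #H tag)
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        label = s[start:pos].strip()
        node.label = label or None
        # colon-separated fields: length[:support[:gamma]]
        fields: list[str] = []
        while pos < len(s) and s[pos] == ":":
            pos += 1
            fstart = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            fields.append(s[fstart:pos].strip())
            if len(fields) > 3:
                raise error("too many ':' fields on an edge")
        if fields:
            if fields[0]:
                try:
                    node.length = float(fields[0])
                except ValueError:
                    raise error(f"bad branch length {fields[0]!r}") from None
                if node.length < 0:
                    raise error("negative branch length")
        if len(fields) == 3 and fields[2]:
            try:
                node.gamma = float(fields[2])
            except ValueError:
                raise error(f"bad inheritance probability {fields[2]!r}") from None
        return node

    root = parse_subtree()
    if pos != len(s):
        raise error("trailing characters after tree")
    return root


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------


class GeneTree:
    """Rooted binary tree on alleles with a stable post-order node numbering.

    Nodes are integers ``0..2n-2`` in post-order; the root is the last id.
    Leaves carry allele labels.  Internal nodes identify clades; there are
    ``n - 1`` of them (including the root) for ``n`` leaves.
    """

    def __init__(self, children: Sequence[tuple[int, ...]], labels: Mapping[int, str]):
        self.children: list[tuple[int, ...]] = [tuple(c) for c in children]
        self.labels: dict[int, str] = dict(labels)
        self.n_nodes = len(self.children)
        self.root = self.n_nodes - 1
        self.parent: list[int | None] = [None] * self.n_nodes
        for v, kids in enumerate(self.children):
            for c in kids:
                self.parent[c] = v
        self.leaves: tuple[int, ...] = tuple(
            v for v in range(self.n_nodes) if not self.children[v]
        )
        self._validate()
        # descendant sets (inclusive) for fast ancestry queries
        self._desc: list[frozenset[int]] = [frozenset()] * self.n_nodes
        for v in range(self.n_nodes):  # post-order: children first
            acc = {v}
            for c in self.children[v]:
                acc |= self._desc[c]
            self._desc[v] = frozenset(acc)
        self.leaf_by_label: dict[str, int] = {self.labels[v]: v for v in self.leaves}
        # caches used by the coalescent machinery
        self._coal_cache: dict[frozenset[int], frozenset[frozenset[int]]] = {}
        self._maxcoal_cache: dict[frozenset[int], frozenset[int]] = {}
        self._orderings_cache: dict[tuple[frozenset[int], frozenset[int]], int] = {}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "GeneTree":
        raw = _parse_newick_string(text)
        children: list[tuple[int, ...]] = []
        labels: dict[int, str] = {}

        def build(node: _RawNode) -> int:
            if node.children:
                if len(node.children) != 2:
                    raise ParseError(
                        f"gene trees must be binary; found a node with "
                        f"{len(node.children)} children"
                    )
                kid_ids = tuple(build(c) for c in node.children)
                children.append(kid_ids)
                return len(children) - 1
            if not node.label:
                raise ParseError("gene tree leaf without a label")
            children.append(())
            labels[len(children) - 1] = node.label
            return len(children) - 1

        build(raw)
        return cls(children, labels)

    def _validate(self) -> None:
        if self.n_nodes < 1:
            raise ValidationError("empty gene tree")
        for v, kids in enumerate(self.children):
            if kids and len(kids) != 2:
                raise ValidationError("gene trees must be binary")
        names = [self.labels[v] for v in self.leaves]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate allele labels in gene tree")
        n = len(self.leaves)
        if self.n_nodes != 2 * n - 1:
            raise ValidationError("malformed gene tree topology")

    # -- queries ------------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def internal_nodes(self, include_root: bool = True) -> list[int]:
        out = [v for v in range(self.n_nodes) if self.children[v]]
        if not include_root:
            out = [v for v in out if v != self.root]
        return out

    def descendants(self, v: int) -> frozenset[int]:
        """Nodes at or below ``v`` (inclusive)."""
        return self._desc[v]

    def is_strict_descendant(self, x: int, v: int) -> bool:
        return x != v and x in self._desc[v]

    def clade_labels(self, v: int) -> frozenset[str]:
        return frozenset(self.labels[u] for u in self._desc[v] if self.is_leaf(u))

    def is_antichain(self, B: Iterable[int]) -> bool:
        B = list(B)
        return not any(
            a != b and a in self._desc[b] for a in B for b in B
        )

    # -- output -------------------------------------------------------------

    def newick(self, v: int | None = None) -> str:
        if v is None:
            return self.newick(self.root) + ";"
        if self.is_leaf(v):
            return self.labels[v]
        return "(" + ",".join(self.newick(c) for c in self.children[v]) + ")"

    def canonical_newick(self) -> str:
        """Topology-only Newick with children sorted by smallest leaf label."""

        def rec(v: int) -> tuple[str, str]:
            if self.is_leaf(v):
                return self.labels[v], self.labels[v]
            parts = sorted(rec(c) for c in self.children[v])
            key = min(p[0] for p in parts)
            return key, "(" + ",".join(p[1] for p in parts) + ")"

        return rec(self.root)[1] + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneTree({self.newick()!r})"


def parse_gene_tree(text: str) -> GeneTree:
    """Parse a rooted binary Newick gene tree (branch lengths ignored)."""
    return GeneTree.from_newick(text)


# ---------------------------------------------------------------------------
# Species networks
# ---------------------------------------------------------------------------


class SpeciesNetwork:
    """Rooted phylogenetic network with branch lengths and inheritance probabilities.

    Nodes are integers.  ``length[(u, v)]`` is the branch length in coalescent
    units of edge ``(u, v)`` (``None`` when absent: allowed for parsimony use,
    an error for probability use).  ``gamma[(u, v)]`` is the inheritance
    probability (1.0 on every non-reticulation edge).  Reticulation nodes are
    numbered ``1..q`` in order of first appearance of their hybrid tags, and
    that numbering is what split-index vectors of ancestral configurations
    refer to.
    """

    def __init__(
        self,
        children: Mapping[int, Sequence[int]],
        length: Mapping[tuple[int, int], float | None],
        gamma: Mapping[tuple[int, int], float],
        leaf_label: Mapping[int, str],
        reticulation_order: Sequence[int] = (),
    ):
        self.children: dict[int, tuple[int, ...]] = {
            v: tuple(c) for v, c in children.items()
        }
        self.nodes: tuple[int, ...] = tuple(sorted(self.children))
        self.length: dict[tuple[int, int], float | None] = dict(length)
        self.gamma: dict[tuple[int, int], float] = dict(gamma)
        self.leaf_label: dict[int, str] = dict(leaf_label)
        self.parents: dict[int, tuple[int, ...]] = {v: () for v in self.nodes}
        for u, kids in self.children.items():
            for v in kids:
                self.parents[v] = self.parents[v] + (u,)
        roots = [v for v in self.nodes if not self.parents[v]]
        if len(roots) != 1:
            raise ValidationError(f"network must have exactly one root, found {len(roots)}")
        self.root: int = roots[0]
        retics = [v for v in self.nodes if len(self.parents[v]) == 2]
        if reticulation_order:
            if set(reticulation_order) != set(retics):
                raise ValidationError("reticulation_order does not match in-degree-2 nodes")
            self.reticulations: tuple[int, ...] = tuple(reticulation_order)
        else:
            self.reticulations = tuple(sorted(retics))
        self.reticulation_index: dict[int, int] = {
            v: i + 1 for i, v in enumerate(self.reticulations)
        }
        self.label_to_leaf: dict[str, int] = {}
        self.validate()
        for v, name in self.leaf_label.items():
            self.label_to_leaf[name] = v

    # -- structure ----------------------------------------------------------

    @property
    def q(self) -> int:
        return len(self.reticulations)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in self.nodes for v in self.children[u]]

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def is_reticulation(self, v: int) -> bool:
        return v in self.reticulation_index

    @property
    def leaves(self) -> list[int]:
        return [v for v in self.nodes if self.is_leaf(v)]

    @property
    def has_lengths(self) -> bool:
        return all(self.length.get(e) is not None for e in self.edges)

    def validate(self) -> None:
        seen_edges = set()
        for u in self.nodes:
            for v in self.children[u]:
                if v not in self.children:
                    raise ValidationError(f"edge to unknown node {v}")
                if (u, v) in seen_edges:
                    raise ValidationError(f"parallel edges between {u} and {v}")
                seen_edges.add((u, v))
        # degree constraints
        for v in self.nodes:
            din, dout = len(self.parents[v]), len(self.children[v])
            if v == self.root:
                if din != 0 or dout < 2:
                    raise ValidationError("root must have in-degree 0 and out-degree >= 2")
            elif dout == 0:
                if din != 1:
                    raise ValidationError(f"leaf {v} must have in-degree 1")
                if v not in self.leaf_label:
                    raise ValidationError(f"leaf {v} has no species label")
            elif din == 1:
                if dout < 2:
                    raise ValidationError(
                        f"internal tree node {v} must have out-degree >= 2"
                    )
            elif din == 2:
                if dout != 1:
                    raise ValidationError(
                        f"reticulation node {v} must have out-degree 1"
                    )
            else:
                raise ValidationError(f"node {v} has illegal in-degree {din}")
        labels = list(self.leaf_label.values())
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate leaf labels")
        if set(self.leaf_label) != set(self.leaves):
            raise ValidationError("leaf labels must be attached to leaves exactly")
        # acyclicity via DFS
        state: dict[int, int] = {}

        def dfs(v: int) -> None:
            state[v] = 1
            for c in self.children[v]:
                if state.get(c) == 1:
                    raise ValidationError("cycle detected in network")
                if state.get(c, 0) == 0:
                    dfs(c)
            state[v] = 2

        dfs(self.root)
        if len(state) != len(self.nodes):
            raise ValidationError("network has nodes unreachable from the root")
        # edge parameters
        for e in self.edges:
            g = self.gamma.get(e)
            if g is None:
                raise ValidationError(f"edge {e} has no inheritance probability")
            if not (0.0 <= g <= 1.0):
                raise ValidationError(f"inheritance probability {g} outside [0, 1]")
            ln = self.length.get(e, None)
            if ln is not None and ln < 0:
                raise ValidationError("negative branch length")
        for v in self.nodes:
            if v == self.root:
                continue
            tot = sum(self.gamma[(u, v)] for u in self.parents[v])
            if abs(tot - 1.0) > GAMMA_TOL:
                raise ValidationError(
                    f"inheritance probabilities into node {v} sum to {tot}, not 1"
                )

    def postorder(self) -> list[int]:
        """Topological order in which every node follows all of its descendants."""
        order: list[int] = []
        pending = {v: len(self.children[v]) for v in self.nodes}
        stack = [v for v in self.nodes if pending[v] == 0]
        stack.sort()
        while stack:
            v = stack.pop()
            order.append(v)
            for u in self.parents[v]:
                pending[u] -= 1
                if pending[u] == 0:
                    stack.append(u)
        if len(order) != len(self.nodes):  # pragma: no cover - guarded by validate
            raise ValidationError("cycle detected in network")
        return order

    def ancestors(self) -> dict[int, frozenset[int]]:
        """For each node, the set of nodes at or above it (inclusive)."""
        anc: dict[int, set[int]] = {v: {v} for v in self.nodes}
        for v in reversed(self.postorder()):  # root first
            for c in self.children[v]:
                anc[c] |= anc[v]
        return {v: frozenset(s) for v, s in anc.items()}

    def leaf_edge(self, species: str) -> tuple[int, int]:
        v = self.label_to_leaf[species]
        (u,) = self.parents[v]
        return (u, v)

    # -- output -------------------------------------------------------------

    def newick(self) -> str:
        return write_network(self)

    def copy(self) -> "SpeciesNetwork":
        return parse_network(self.newick())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.newick()!r})"


class SpeciesTree(SpeciesNetwork):
    """A species network without reticulation nodes (all gamma equal to 1)."""

    def validate(self) -> None:
        super().validate()
        if self.reticulations:
            raise ValidationError("species tree may not contain reticulation nodes")


def _fmt(x: float) -> str:
    return repr(round(x, 12)) if x == x else "nan"


def write_network(N: SpeciesNetwork) -> str:
    """Serialize to (rich) Newick; reticulation in-edges carry ``:len::gamma``.

    The full subtree below a reticulation is written at its first in-edge in
    traversal order; the other in-edge gets the bare ``#Hk`` tag.  Tags are
    numbered by first appearance in the output, so parsing the result assigns
    the same numbering and writing is idempotent.
    """
    written: dict[int, int] = {}

    def annot(e: tuple[int, int]) -> str:
        ln = N.length.get(e)
        out = ""
        if N.is_reticulation(e[1]):
            out = (":" + _fmt(ln) if ln is not None else ":") + "::" + _fmt(N.gamma[e])
        elif ln is not None:
            out = ":" + _fmt(ln)
        return out

    def rec(v: int, in_edge: tuple[int, int] | None) -> str:
        tag = ""
        if N.is_reticulation(v):
            if v in written:
                return f"#H{written[v]}" + annot(in_edge)  # type: ignore[arg-type]
            written[v] = len(written) + 1
            tag = f"#H{written[v]}"
        if N.is_leaf(v):
            body = N.leaf_label[v]
        else:
            body = "(" + ",".join(rec(c, (v, c)) for c in N.children[v]) + ")" + tag
        return body + (annot(in_edge) if in_edge is not None else "")

    return rec(N.root, None) + ";"


def parse_network(text: str) -> SpeciesNetwork:
    """Parse a species network from (rich) Newick.

    Reticulations are encoded with ``#H`` hybrid tags; the inheritance
    probability is the third colon field on at least one in-edge of each
    reticulation (the sibling in-edge defaults to its complement).  Returns a
    :class:`SpeciesTree` when the result has no reticulations.
    """
    raw = _parse_newick_string(text)
    children: dict[int, list[int]] = {}
    length: dict[tuple[int, int], float | None] = {}
    gamma_given: dict[tuple[int, int], float | None] = {}
    leaf_label: dict[int, str] = {}
    hybrid_node: dict[str, int] = {}
    hybrid_order: list[int] = []
    counter = itertools.count()

    def build(node: _RawNode, parent: int | None) -> None:
        label = node.label or ""
        tag = None
        if "#" in label:
            species_part, _, tagpart = label.partition("#")
            tag = tagpart
            label = species_part
        if tag is not None:
            if tag in hybrid_node:
                v = hybrid_node[tag]
            else:
                v = next(counter)
                children[v] = []
                hybrid_node[tag] = v
                hybrid_order.append(v)
        else:
            v = next(counter)
            children[v] = []
        if parent is None:
            if tag is not None:
                raise ParseError("root may not be a hybrid node")
        else:
            e = (parent, v)
            if v in children[parent]:
                raise ParseError("parallel edges between the same node pair")
            children[parent].append(v)
            length[e] = node.length
            gamma_given[e] = node.gamma
        for c in node.children:
            build(c, v)
        if not node.children and tag is None:
            if not label:
                raise ParseError("leaf without a label")
            if v in leaf_label and leaf_label[v] != label:
                raise ParseError("conflicting labels for one node")
            leaf_label[v] = label
        elif label and tag is not None and node.children:
            # named hybrid interior node: name ignored (topology carries it)
            pass

    build(raw, None)

    labels = list(leaf_label.values())
    if len(set(labels)) != len(labels):
        raise ParseError(f"duplicate leaf label in {sorted(labels)}")

    # resolve inheritance probabilities
    gamma: dict[tuple[int, int], float] = {}
    parents: dict[int, list[int]] = {v: [] for v in children}
    for u, kids in children.items():
        for v in kids:
            parents[v].append(u)
    for v in children:
        ps = parents[v]
        if len(ps) <= 1:
            for u in ps:
                g = gamma_given.get((u, v))
                if g is not None and abs(g - 1.0) > GAMMA_TOL:
                    raise ParseError(
                        "inheritance probability on a non-reticulation edge must be 1"
                    )
                gamma[(u, v)] = 1.0
        elif len(ps) == 2:
            e1, e2 = (ps[0], v), (ps[1], v)
            g1, g2 = gamma_given.get(e1), gamma_given.get(e2)
            if g1 is None and g2 is None:
                raise ParseError(
                    f"no inheritance probability given on the in-edges of hybrid node {v}"
                )
            if g1 is None:
                g1 = 1.0 - g2  # type: ignore[operator]
            if g2 is None:
                g2 = 1.0 - g1
            for g in (g1, g2):
                if not (0.0 <= g <= 1.0):
                    raise ParseError(f"inheritance probability {g} outside [0, 1]")
            if abs(g1 + g2 - 1.0) > GAMMA_TOL:
                raise ParseError(
                    f"inheritance probabilities {g1} + {g2} on hybrid node {v} "
                    "do not sum to 1"
                )
            gamma[e1], gamma[e2] = g1, g2
        else:
            raise ParseError(f"hybrid node {v} appears {len(ps)} times")

    cls = SpeciesTree if not hybrid_order else SpeciesNetwork
    try:
        return cls(children, length, gamma, leaf_label, reticulation_order=hybrid_order)
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc


def parse_species_tree(text: str) -> SpeciesTree:
    """Parse a plain-Newick species tree; rejects networks."""
    net = parse_network(text)
    if not isinstance(net, SpeciesTree):
        raise ParseError("expected a species tree, found reticulation nodes")
    return net


# ---------------------------------------------------------------------------
# Allele maps
# ---------------------------------------------------------------------------


@dataclass
class AlleleMap:
    """Mapping from allele names (gene-tree leaves) to species names."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, allele: str) -> str:
        return self.mapping[allele]

    def __contains__(self, allele: str) -> bool:
        return allele in self.mapping

    def species(self) -> set[str]:
        return set(self.mapping.values())

    @classmethod
    def identity(cls, g: GeneTree) -> "AlleleMap":
        return cls({g.labels[v]: g.labels[v] for v in g.leaves})

    def check(self, g: GeneTree, N: SpeciesNetwork) -> None:
        net_species = set(N.leaf_label.values())
        for v in g.leaves:
            allele = g.labels[v]
            if allele not in self.mapping:
                raise ValidationError(f"allele {allele!r} missing from the allele map")
            sp = self.mapping[allele]
            if sp not in net_species:
                raise ValidationError(
                    f"allele {allele!r} maps to species {sp!r} absent from the network"
                )


def parse_allele_map(text: str) -> AlleleMap:
    """Parse a two-column ``allele<TAB>species`` table."""
    mapping: dict[str, str] = {}
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"line {ln}: expected 'allele<TAB>species'")
        allele, sp = parts
        if allele in mapping and mapping[allele] != sp:
            raise ParseError(f"allele {allele!r} mapped to both {mapping[allele]!r} and {sp!r}")
        mapping[allele] = sp
    return AlleleMap(mapping)


def resolve_allele_map(
    g: GeneTree, N: SpeciesNetwork, mu: AlleleMap | None
) -> AlleleMap:
    """Return ``mu`` checked against the instance, or the identity map if omitted."""
    if mu is None:
        mu = AlleleMap.identity(g)
    mu.check(g, N)
    return mu


# ---------------------------------------------------------------------------
# Topology enumeration
# ---------------------------------------------------------------------------


def all_rooted_topologies(labels: Sequence[str]) -> list[str]:
    """All rooted binary labeled topologies on ``labels``, as Newick strings.

    There are ``(2n-3)!!`` of them: 3 for three labels, 15 for four.  Built by
    attaching each successive leaf to every edge (including the root edge) of
    every smaller topology.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    trees: list[object] = [(labels[0], labels[1])]
    for name in labels[2:]:
        nxt: list[object] = []
        for t in trees:
            nxt.extend(_attach_everywhere(t, name))
        trees = nxt

    def to_newick(t: object) -> str:
        if isinstance(t, str):
            return t
        a, b = t  # type: ignore[misc]
        return f"({to_newick(a)},{to_newick(b)})"

    return [to_newick(t) + ";" for t in trees]


def _attach_everywhere(t: object, name: str) -> list[object]:
    out: list[object] = [(t, name)]  # attach on the root edge
    if isinstance(t, str):
        return out
    a, b = t  # type: ignore[misc]
    out.extend((sub, b) for sub in _attach_everywhere(a, name))
    out.extend((a, sub) for sub in _attach_everywhere(b, name))
    return out
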