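"""Maximum-likelihood species-tree inference from gene-tree topologies.

The likelihood of a candidate species tree is the product over loci of the
probability of each observed gene-tree topology, computed by either the exact
configuration algorithm or the LCH heuristic.  The search is a hill climb over
the rooted nearest-neighbor-interchange (NNI) neighborhood with per-branch
coordinate ascent for branch lengths, started from a greedy clade-frequency
consensus of the input gene trees; optional restarts perturb the start with
random NNI moves.  Accuracy is evaluated with the normalized rooted
Robinson-Foulds distance (symmetric difference of internal clades divided by
its maximum, ``2(n - 2)``).

This is a compact inference driver for moderate numbers of taxa, not an
optimized search engine.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from scipy.optimize import minimize_scalar

from .model import AlleleMap, GeneTree, SpeciesTree, ValidationError, parse_species_tree
from .treeprob import prob_exact, prob_heuristic

__all__ = [
    "SearchState",
    "loglik",
    "optimize_branch_lengths",
    "infer_species_tree",
    "rf_distance",
    "tree_clades",
    "tree_from_clades",
    "greedy_consensus",
]

Clade = frozenset

_MIN_PROB = 1e-300


@dataclass
class SearchState:
    """Bookkeeping of one hill-climb: current tree, score and counters."""

    tree: SpeciesTree
    loglik: float
    iterations: int = 0
    evaluations: int = 0
    seed: int = 0


def _normalize_genes(genes) -> list[tuple[GeneTree, AlleleMap]]:
    out = []
    for item in genes:
        if isinstance(item, GeneTree):
            out.append((item, AlleleMap.identity(item)))
        else:
            g, mu = item
            out.append((g, mu if mu is not None else AlleleMap.identity(g)))
    if not out:
        raise ValidationError("need at least one gene tree")
    return out


def _dedup(genes: list[tuple[GeneTree, AlleleMap]]):
    """Group identical (topology, map) inputs; probability is computed once."""
    groups: dict[tuple[str, tuple], tuple[GeneTree, AlleleMap, int]] = {}
    for g, mu in genes:
        key = (g.canonical_newick(), tuple(sorted(mu.mapping.items())))
        if key in groups:
            gg, mm, c = groups[key]
            groups[key] = (gg, mm, c + 1)
        else:
            groups[key] = (g, mu, 1)
    return list(groups.values())


def loglik(
    S: SpeciesTree,
    genes,
    method: str = "exact",
    seed: int = 0,
) -> float:
    """Sum of log gene-tree-topology probabilities under ``S``.

    ``method`` is ``"exact"`` or ``"heuristic"`` (the LCH-bounded sum, a lower
    bound on the exact log-likelihood term by term).
    """
    if method not in ("exact", "heuristic"):
        raise ValueError(f"unknown method {method!r}")
    total = 0.0
    for g, mu, count in _dedup(_normalize_genes(genes)):
        if method == "exact":
            p = prob_exact(S, g, mu)
        else:
            p = prob_heuristic(S, g, mu, seed=seed)
        total += count * math.log(max(p, _MIN_PROB))
    return total


# ---------------------------------------------------------------------------
# Clade representation of rooted trees
# ---------------------------------------------------------------------------


def tree_clades(S: SpeciesTree, with_lengths: bool = False):
    """Internal non-root clades of ``S`` as frozensets of species names.

    With ``with_lengths=True``, returns a dict clade -> branch length for
    every non-root clade including the singletons (terminal branches).
    """
    clades: dict[Clade, float | None] = {}
    below: dict[int, frozenset[str]] = {}
    for v in S.postorder():
        if S.is_leaf(v):
            below[v] = frozenset({S.leaf_label[v]})
        else:
            below[v] = frozenset().union(*(below[c] for c in S.children[v]))
        if v != S.root:
            (u,) = S.parents[v]
            clades[below[v]] = S.length.get((u, v))
    if with_lengths:
        return clades
    return {c for c in clades if 1 < len(c) < len(below[S.root])}


def tree_from_clades(lengths: dict[Clade, float]) -> SpeciesTree:
    """Build the rooted binary species tree realizing a laminar clade family.

    ``lengths`` maps every non-root clade (internal and singleton) to its
    branch length.
    """
    leafset = frozenset().union(*lengths)
    fam = sorted(lengths, key=len)

    def rec(clade: Clade) -> str:
        if len(clade) == 1:
            (sp,) = clade
            return f"{sp}:{lengths[clade]!r}"
        kids: list[Clade] = []
        covered: set[str] = set()
        for c in sorted((c for c in fam if c < clade), key=len, reverse=True):
            if not (c & covered):
                kids.append(c)
                covered |= c
        if covered != set(clade) or len(kids) != 2:
            raise ValidationError("clade family is not a resolved rooted tree")
        inner = ",".join(rec(c) for c in sorted(kids, key=lambda c: sorted(c)[0]))
        if clade == leafset:
            return f"({inner})"
        return f"({inner}):{lengths[clade]!r}"

    return parse_species_tree(rec(leafset) + ";")


def rf_distance(t1: SpeciesTree, t2: SpeciesTree) -> float:
    """Normalized rooted Robinson-Foulds distance in ``[0, 1]``.

    Symmetric difference of the internal non-root clade sets divided by
    ``2(n - 2)``; 0 for identical topologies, 1 when no clade is shared.
    """
    l1 = frozenset(t1.leaf_label.values())
    l2 = frozenset(t2.leaf_label.values())
    if l1 != l2:
        raise ValidationError("trees are on different leaf sets")
    c1, c2 = tree_clades(t1), tree_clades(t2)
    denom = 2 * (len(l1) - 2)
    if denom == 0:
        return 0.0
    return len(c1 ^ c2) / denom


# ---------------------------------------------------------------------------
# Branch-length optimization and search
# ---------------------------------------------------------------------------

_BOUNDS = (1e-3, 15.0)


def _multi_allele(genes: list[tuple[GeneTree, AlleleMap]]) -> bool:
    return any(
        len(set(mu.mapping.values())) < len(mu.mapping) for _, mu in genes
    )


def optimize_branch_lengths(
    S: SpeciesTree,
    genes,
    method: str = "exact",
    tol: float = 1e-4,
    seed: int = 0,
    max_sweeps: int = 6,
    bounds: tuple[float, float] = _BOUNDS,
) -> SpeciesTree:
    """Coordinate ascent on branch lengths (bounded scalar search per branch).

    Sweeps the branches until one full sweep improves the log-likelihood by
    less than ``tol``.  Terminal branches are only optimized when some locus
    samples more than one allele from a species (otherwise they cannot affect
    the topology probability).  The log-likelihood never decreases.
    """
    genes = _normalize_genes(genes)
    S = S.copy()
    internal_edges = [
        (u, v) for (u, v) in S.edges if not S.is_leaf(v)
    ]
    edges = list(internal_edges)
    if _multi_allele(genes):
        edges = S.edges
    if not edges:
        return S

    def ll() -> float:
        return loglik(S, genes, method=method, seed=seed)

    cur = ll()
    for _ in range(max_sweeps):
        start = cur
        for e in edges:
            orig = S.length[e]

            def neg(x: float, e=e) -> float:
                S.length[e] = float(x)
                return -ll()

            res = minimize_scalar(
                neg, bounds=bounds, method="bounded", options={"xatol": 1e-2}
            )
            if -res.fun >= cur:
                S.length[e] = float(res.x)
                cur = -res.fun
            else:  # scalar search found nothing better; keep the previous value
                S.length[e] = orig
        if cur - start < tol:
            break
    return S


def _nni_neighbors(lengths: dict[Clade, float]) -> list[dict[Clade, float]]:
    """Rooted NNI moves in clade space: swap a clade's child with its sibling."""
    leafset = frozenset().union(*lengths)
    internal = [c for c in lengths if 1 < len(c) < len(leafset)]
    fam = set(lengths) | {leafset}
    out = []
    for C in internal:
        parent = min((p for p in fam if C < p), key=len)
        sib_members = parent - C
        # the sibling subtree is itself a clade (or singleton) of the family
        kids = _children_of(C, fam)
        for keep in kids:
            newC = keep | sib_members
            new_lengths = dict(lengths)
            del new_lengths[C]
            new_lengths[newC] = lengths[C]
            out.append(new_lengths)
    return out


def _children_of(clade: Clade, fam: set[Clade]) -> list[Clade]:
    kids: list[Clade] = []
    covered: set[str] = set()
    for c in sorted((c for c in fam if c < clade), key=len, reverse=True):
        if not (c & covered):
            kids.append(c)
            covered |= c
    return kids


def greedy_consensus(genes, default_length: float = 1.0) -> SpeciesTree:
    """Greedy clade-frequency consensus of the input gene trees.

    Species-image clades are ranked by frequency and added when compatible
    (laminar) with everything already accepted; the result is completed to a
    fully resolved rooted binary tree deterministically.  All branch lengths
    are initialized to ``default_length``.
    """
    genes = _normalize_genes(genes)
    leafset = frozenset().union(
        *(frozenset(mu.mapping.values()) for _, mu in genes)
    )
    counts: dict[Clade, int] = {}
    for g, mu in genes:
        for v in g.internal_nodes(include_root=False):
            img = frozenset(mu[lb] for lb in g.clade_labels(v))
            if 1 < len(img) < len(leafset):
                counts[img] = counts.get(img, 0) + 1
    chosen: list[Clade] = []
    for clade in sorted(
        counts, key=lambda c: (-counts[c], len(c), tuple(sorted(c)))
    ):
        if all(not (clade & d) or clade <= d or d <= clade for d in chosen):
            chosen.append(clade)
    # complete to a binary tree
    fam = set(chosen) | {frozenset({sp}) for sp in leafset} | {leafset}
    full = set(fam)
    for clade in sorted(fam, key=len, reverse=True):
        if len(clade) == 1:
            continue
        kids = _children_of(clade, full - {clade})
        while len(kids) > 2:
            kids.sort(key=lambda c: (len(c), tuple(sorted(c))))
            joined = kids[0] | kids[1]
            full.add(joined)
            kids = [joined] + kids[2:]
    lengths = {c: default_length for c in full if c != leafset}
    return tree_from_clades(lengths)


def infer_species_tree(
    genes,
    method: str = "heuristic",
    seed: int = 0,
    restarts: int = 0,
    tol: float = 1e-4,
    max_iterations: int = 25,
) -> SpeciesTree:
    """Hill-climbing ML species-tree search over the rooted NNI neighborhood.

    Starts from the greedy consensus of the gene trees (restarts perturb it
    with random NNI moves), screens neighbors with inherited branch lengths,
    and re-optimizes branch lengths on accepted candidates.  Deterministic for
    fixed inputs and seed; the returned tree's log-likelihood is at least the
    starting tree's.
    """
    genes = _normalize_genes(genes)
    rng = random.Random(seed)

    def score(lengths: dict[Clade, float]) -> float:
        return loglik(tree_from_clades(lengths), genes, method=method, seed=seed)

    def climb(lengths: dict[Clade, float]) -> tuple[dict[Clade, float], float]:
        tree = optimize_branch_lengths(
            tree_from_clades(lengths), genes, method=method, tol=tol, seed=seed
        )
        lengths = dict(tree_clades(tree, with_lengths=True))
        cur = score(lengths)
        for _ in range(max_iterations):
            neighbors = _nni_neighbors(lengths)
            scored = sorted(
                ((score(nb), i) for i, nb in enumerate(neighbors)), reverse=True
            )
            improved = False
            for s, i in scored[:2]:
                cand_tree = optimize_branch_lengths(
                    tree_from_clades(neighbors[i]),
                    genes,
                    method=method,
                    tol=tol,
                    seed=seed,
                    max_sweeps=2,
                )
                cand_lengths = dict(tree_clades(cand_tree, with_lengths=True))
                cand = score(cand_lengths)
                if cand > cur + tol:
                    lengths, cur = cand_lengths, cand
                    improved = True
                    break
            if not improved:
                break
        return lengths, cur

    start = dict(tree_clades(greedy_consensus(genes), with_lengths=True))
    best_lengths, best = climb(start)
    for _ in range(restarts):
        pert = dict(start)
        for _ in range(2):
            nbs = _nni_neighbors(pert)
            if not nbs:
                break
            pert = nbs[rng.randrange(len(nbs))]
        cand_lengths, cand = climb(pert)
        if cand > best:
            best_lengths, best = cand_lengths, cand
    return tree_from_clades(best_lengths)
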