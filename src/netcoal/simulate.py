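"""Simulation of gene trees within species phylogenies, and random phylogenies.

The gene-tree simulator runs the multispecies coalescent backward in time
within the edges of a species tree or network: within an edge, each pair of
lineages coalesces at rate 1 per coalescent unit (so ``k`` lineages wait an
exponential with rate ``k(k-1)/2``); at a reticulation node every lineage
independently follows a parent edge with that edge's inheritance probability;
above the root coalescence continues until one lineage remains.  Only the
realized topology is returned — branch lengths of the gene tree play no role
in any computation here.

Random ultrametric species trees come from uniformly random sequential joins
with internal-node times spread uniformly up to the requested height.  Random
networks grow from a tree by repeated midpoint attachment: two edges are
drawn, their midpoints connected from the one nearer the root to the one
farther, and the lower midpoint becomes a reticulation with a uniform
inheritance probability.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from .model import (
    AlleleMap,
    GeneTree,
    MissingLengthError,
    SpeciesNetwork,
    SpeciesTree,
    ValidationError,
    parse_gene_tree,
)

__all__ = [
    "SimConfig",
    "simulate_gene_tree",
    "simulate_gene_trees",
    "random_species_tree",
    "random_network",
]


@dataclass
class SimConfig:
    """Sampling design for the gene-tree simulator.

    ``alleles_per_species`` is either one count for every species or a mapping
    species name -> count (0 allowed; at least two alleles in total).  Alleles
    of species ``X`` are named ``X`` when singletons and ``X_1, X_2, ...``
    otherwise.
    """

    alleles_per_species: int | dict[str, int] = 1
    seed: int = 0
    replicates: int = 1

    def counts(self, species: list[str]) -> dict[str, int]:
        if isinstance(self.alleles_per_species, int):
            out = {sp: self.alleles_per_species for sp in species}
        else:
            out = {sp: self.alleles_per_species.get(sp, 0) for sp in species}
        if any(c < 0 for c in out.values()):
            raise ValidationError("allele counts must be non-negative")
        if sum(out.values()) < 2:
            raise ValidationError("need at least two alleles in total")
        return out


def _coalesce_in_edge(
    lineages: list[str], t_max: float, rng: random.Random
) -> list[str]:
    lineages = list(lineages)
    t = 0.0
    while len(lineages) >= 2:
        k = len(lineages)
        rate = k * (k - 1) / 2.0
        if math.isfinite(t_max):
            t += rng.expovariate(rate)
            if t > t_max:
                break
        i, j = rng.sample(range(k), 2)
        if i > j:
            i, j = j, i
        merged = f"({lineages[i]},{lineages[j]})"
        lineages[i] = merged
        del lineages[j]
    return lineages


def simulate_gene_tree(
    N: SpeciesNetwork,
    cfg: SimConfig | None = None,
    rng: random.Random | None = None,
) -> tuple[GeneTree, AlleleMap]:
    """Simulate one gene-tree topology within the edges of ``N``.

    Returns the gene tree and the allele-to-species map of its leaves.
    """
    cfg = cfg or SimConfig()
    if rng is None:
        rng = random.Random(cfg.seed)
    if not N.has_lengths:
        raise MissingLengthError("simulation requires branch lengths")
    species = sorted(N.leaf_label.values())
    counts = cfg.counts(species)
    mapping: dict[str, str] = {}
    at_node: dict[int, list[str]] = {}
    for sp in species:
        names = (
            [sp]
            if counts[sp] == 1
            else [f"{sp}_{i + 1}" for i in range(counts[sp])]
        )
        for nm in names:
            mapping[nm] = sp
        at_node[N.label_to_leaf[sp]] = list(names)

    exiting_edge: dict[tuple[int, int], list[str]] = {}
    for v in N.postorder():
        if N.is_leaf(v):
            lineages = at_node.get(v, [])
        else:
            lineages = []
            for c in N.children[v]:
                lineages.extend(exiting_edge.pop((v, c)))
        if v == N.root:
            (root_lineage,) = _coalesce_in_edge(lineages, math.inf, rng)
            g = parse_gene_tree(root_lineage + ";")
            return g, AlleleMap(dict(mapping))
        if N.is_reticulation(v):
            u1, u2 = N.parents[v]
            g1 = N.gamma[(u1, v)]
            sides: dict[int, list[str]] = {u1: [], u2: []}
            for ln in lineages:
                sides[u1 if rng.random() < g1 else u2].append(ln)
            for u in (u1, u2):
                exiting_edge[(u, v)] = _coalesce_in_edge(
                    sides[u], N.length[(u, v)], rng
                )
        else:
            (u,) = N.parents[v]
            exiting_edge[(u, v)] = _coalesce_in_edge(lineages, N.length[(u, v)], rng)
    raise AssertionError("unreachable")  # pragma: no cover


def simulate_gene_trees(
    N: SpeciesNetwork, n: int, cfg: SimConfig | None = None
) -> list[tuple[GeneTree, AlleleMap]]:
    """Simulate ``n`` independent gene trees (one shared seeded RNG)."""
    cfg = cfg or SimConfig()
    rng = random.Random(cfg.seed)
    return [simulate_gene_tree(N, cfg, rng) for _ in range(n)]


def random_species_tree(
    n: int, height: float, seed: int | random.Random = 0
) -> SpeciesTree:
    """Random ultrametric species tree on ``n`` taxa with the given root height.

    Topology from uniformly random sequential joins; the ``n - 2`` non-root
    join times are uniform on ``(0, height)`` and the root sits at ``height``,
    so every root-to-leaf path length equals ``height`` in coalescent units.
    """
    if n < 2 or height <= 0:
        raise ValidationError("need n >= 2 taxa and positive height")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    labels = [f"t{i + 1}" for i in range(n)]
    times = sorted(rng.uniform(0.0, height) for _ in range(n - 2)) + [height]
    active: list[tuple[str, float]] = [(lb, 0.0) for lb in labels]
    for t in times:
        i, j = rng.sample(range(len(active)), 2)
        if i > j:
            i, j = j, i
        (s1, t1), (s2, t2) = active[i], active[j]
        joined = f"({s1}:{t - t1!r},{s2}:{t - t2!r})"
        active[i] = (joined, t)
        del active[j]
    from .model import parse_species_tree

    return parse_species_tree(active[0][0] + ";")


def random_network(
    S: SpeciesTree, k: int, seed: int | random.Random = 0, max_redraws: int = 100
) -> SpeciesNetwork:
    """Grow a random network from ``S`` by ``k`` midpoint attachments.

    Each step draws two distinct edges, connects their midpoints from the one
    nearer the root ("higher") to the one farther ("lower"), and turns the
    lower midpoint into a reticulation with inheritance probability drawn
    uniformly.  Midpoint depths are measured from the root along branch
    lengths, so every edge runs from a shallower to a deeper node and the
    result is always acyclic.  Ties in midpoint depth are redrawn.
    """
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    if not S.has_lengths:
        raise MissingLengthError("midpoint attachment requires branch lengths")
    children: dict[int, list[int]] = {v: list(S.children[v]) for v in S.nodes}
    length: dict[tuple[int, int], float] = {e: S.length[e] for e in S.edges}
    gamma: dict[tuple[int, int], float] = {e: 1.0 for e in S.edges}
    labels = dict(S.leaf_label)
    retic_order: list[int] = []
    depth: dict[int, float] = {S.root: 0.0}
    for v in S.postorder()[::-1]:
        for c in S.children[v]:
            depth[c] = depth[v] + S.length[(v, c)]
    next_id = max(S.nodes) + 1

    def split_edge(e: tuple[int, int], d: float) -> int:
        nonlocal next_id
        u, v = e
        m = next_id
        next_id += 1
        children[m] = [v]
        children[u][children[u].index(v)] = m
        g_old = gamma.pop(e)
        ln = length.pop(e)
        frac = (d - depth[u]) / ln if ln > 0 else 0.5
        length[(u, m)], length[(m, v)] = ln * frac, ln * (1 - frac)
        # an inheritance probability belongs to the in-edge of the reticulation
        # below it, which is now the lower half
        gamma[(u, m)], gamma[(m, v)] = 1.0, g_old
        depth[m] = d
        return m

    for _ in range(k):
        for _attempt in range(max_redraws):
            edges = [(u, v) for u, kids in children.items() for v in kids]
            e1, e2 = rng.sample(edges, 2)
            d1 = (depth[e1[0]] + depth[e1[1]]) / 2.0
            d2 = (depth[e2[0]] + depth[e2[1]]) / 2.0
            if d1 == d2:
                continue
            if d1 > d2:
                e1, e2, d1, d2 = e2, e1, d2, d1
            m_high = split_edge(e1, d1)
            m_low = split_edge(e2, d2)
            children[m_high].append(m_low)
            g = rng.uniform(0.0, 1.0)
            # the retained in-edge of the lower midpoint keeps 1 - g
            (u_low,) = [u for u, kids in children.items() if m_low in kids and u != m_high]
            gamma[(m_high, m_low)] = g
            length[(m_high, m_low)] = d2 - d1
            gamma[(u_low, m_low)] = 1.0 - g
            retic_order.append(m_low)
            break
        else:
            raise ValidationError(
                f"could not place reticulation after {max_redraws} draws"
            )
    net = SpeciesNetwork(children, length, gamma, labels, reticulation_order=retic_order)
    return net
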