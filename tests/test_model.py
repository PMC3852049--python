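"""Parsing, writing and validation of trees, networks and allele maps."""

import random

import pytest

import netcoal.model as m
from netcoal import (
    ParseError,
    ValidationError,
    all_rooted_topologies,
    parse_allele_map,
    parse_gene_tree,
    parse_network,
    parse_species_tree,
    random_network,
    random_species_tree,
    write_network,
)


class TestGeneTree:
    def test_three_leaves(self):
        g = parse_gene_tree("((a,b),c);")
        assert g.n_leaves == 3
        assert len(g.internal_nodes()) == 2
        assert g.newick() == "((a,b),c);"

    def test_nonbinary_rejected(self):
        with pytest.raises(ParseError):
            parse_gene_tree("(a,b,c);")

    def test_duplicate_alleles_rejected(self):
        with pytest.raises(ValidationError):
            parse_gene_tree("((a,b),a);")

    def test_multi_allele_instance(self):
        g = parse_gene_tree("((a1,a2),b);")
        mu = parse_allele_map("a1\tA\na2\tA\nb\tB\n")
        S = parse_species_tree("(A:1,B:1);")
        mu.check(g, S)  # no error: non-injective map is legal

    def test_canonical_newick_is_order_invariant(self):
        g1 = parse_gene_tree("((a,b),c);")
        g2 = parse_gene_tree("(c,(b,a));")
        assert g1.canonical_newick() == g2.canonical_newick()


class TestNetworkParsing:
    def test_plain_tree(self):
        S = parse_network("((A:1,B:1):1,C:2);")
        assert isinstance(S, m.SpeciesTree)
        assert S.q == 0
        assert sorted(S.leaf_label.values()) == ["A", "B", "C"]

    def test_one_reticulation(self, diamond):
        assert diamond.q == 1
        r = diamond.reticulations[0]
        gammas = sorted(diamond.gamma[(u, r)] for u in diamond.parents[r])
        assert gammas == [0.3, 0.7]

    def test_gamma_complement_synthesized(self):
        net = parse_network("((A:1,(X:0.5)#H1:0.5::0.3):1,(#H1:0.5,C:1):1);")
        r = net.reticulations[0]
        assert sorted(net.gamma[(u, r)] for u in net.parents[r]) == [0.3, 0.7]

    def test_duplicate_leaf_label_rejected(self):
        with pytest.raises(ParseError):
            parse_network("((A:1,B:1):1,A:2);")

    def test_missing_gamma_rejected(self):
        with pytest.raises(ParseError):
            parse_network("((A:1,(X:0.5)#H1:0.5):1,(#H1:0.5,C:1):1);")

    def test_gamma_out_of_range_rejected(self):
        with pytest.raises(ParseError):
            parse_network("((A:1,(X:0.5)#H1:0.5::1.3):1,(#H1:0.5,C:1):1);")

    def test_lengths_optional_for_parsimony(self):
        net = parse_network("((A,(X)#H1:::0.3),(#H1:::0.7,C));")
        assert not net.has_lengths
        assert net.q == 1


class TestRoundTrip:
    def test_diamond_round_trip(self, diamond):
        s1 = write_network(diamond)
        s2 = write_network(parse_network(s1))
        assert s1 == s2

    def test_species_tree_has_no_hybrid_tags(self, tree3):
        assert "#" not in write_network(tree3)

    def test_even_gamma_written_on_both_edges(self):
        net = parse_network("((A:1,(X:0.5)#H1:0.5::0.5):1,(#H1:0.5,C:1):1);")
        assert write_network(net).count("::0.5") == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_random_network_round_trip(self, seed):
        rng = random.Random(seed)
        S = random_species_tree(rng.randint(4, 10), 5.0, seed)
        N = random_network(S, rng.randint(0, min(4, 8)), seed + 1)
        s1 = write_network(N)
        N2 = parse_network(s1)
        assert write_network(N2) == s1
        assert N2.q == N.q
        assert sorted(N2.leaf_label.values()) == sorted(N.leaf_label.values())
        assert sorted(map(round8, N2.length.values())) == sorted(
            map(round8, N.length.values())
        )
        assert sorted(map(round8, N2.gamma.values())) == sorted(
            map(round8, N.gamma.values())
        )


def round8(x):
    return None if x is None else round(x, 8)


class TestValidation:
    """Every mutation breaking a degree constraint must be rejected."""

    def _parts(self, N):
        children = {v: list(N.children[v]) for v in N.nodes}
        return children, dict(N.length), dict(N.gamma), dict(N.leaf_label)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_edge_deletion_rejected(self, seed):
        rng = random.Random(seed)
        S = random_species_tree(5, 4.0, seed)
        N = random_network(S, rng.randint(1, 2), seed)
        children, length, gamma, labels = self._parts(N)
        edges = [(u, v) for u, kids in children.items() for v in kids]
        u, v = edges[rng.randrange(len(edges))]
        children[u].remove(v)
        with pytest.raises(ValidationError):
            m.SpeciesNetwork(children, length, gamma, labels)

    def test_cycle_rejected(self, tree3):
        children, length, gamma, labels = self._parts(tree3)
        # add an edge from a leaf back up to the root's child: cycle/degree break
        leaf = tree3.label_to_leaf["A"]
        inner = tree3.parents[leaf][0]
        children[leaf].append(inner)
        with pytest.raises(ValidationError):
            m.SpeciesNetwork(children, length, gamma, labels)

    def test_bad_gamma_sum_rejected(self, diamond):
        children, length, gamma, labels = self._parts(diamond)
        r = diamond.reticulations[0]
        u = diamond.parents[r][0]
        gamma[(u, r)] = 0.9  # sibling still 0.7
        with pytest.raises(ValidationError):
            m.SpeciesNetwork(children, length, gamma, labels)


class TestAlleleMap:
    def test_tsv(self):
        mu = parse_allele_map("a\tA\nb\tB\n")
        assert mu.mapping == {"a": "A", "b": "B"}

    def test_identity_synthesized(self, tree3, gene_match):
        mu = m.resolve_allele_map(gene_match, tree3, None)
        assert mu.mapping == {"A": "A", "B": "B", "C": "C"}

    def test_unknown_species_rejected(self, tree3):
        g = parse_gene_tree("((a,b),c);")
        mu = parse_allele_map("a\tZ\nb\tB\nc\tC\n")
        with pytest.raises(ValidationError):
            mu.check(g, tree3)

    def test_conflicting_rows_rejected(self):
        with pytest.raises(ParseError):
            parse_allele_map("a\tA\na\tB\n")


class TestTopologyEnumeration:
    @pytest.mark.parametrize("n,count", [(2, 1), (3, 3), (4, 15), (5, 105)])
    def test_counts(self, n, count):
        labels = [f"s{i}" for i in range(n)]
        tops = all_rooted_topologies(labels)
        assert len(tops) == count
        canon = {parse_gene_tree(t).canonical_newick() for t in tops}
        assert len(canon) == count  # all distinct


def test_plain_newick_agrees_with_dendropy():
    """Cross-check the hand-written parser against dendropy on plain trees."""
    dendropy = pytest.importorskip("dendropy")
    nwk = "((A:1.5,B:0.5):1,((C:1,D:1):0.25,E:2):1);"
    S = parse_species_tree(nwk)
    dt = dendropy.Tree.get(data=nwk, schema="newick")
    d_clades = {
        frozenset(lf.taxon.label for lf in nd.leaf_iter())
        for nd in dt.preorder_node_iter()
        if not nd.is_leaf() and nd.parent_node is not None
    }
    from netcoal.inference import tree_clades

    assert tree_clades(S) == d_clades
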