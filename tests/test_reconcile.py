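"""Network algorithms: CountXL and CalProb over weighted configurations."""

import math
import random

import pytest

from netcoal import (
    all_rooted_topologies,
    brute_prob,
    brute_xl,
    cal_prob,
    count_xl,
    displayed_trees,
    parse_gene_tree,
    prob_exact,
    xl_tree,
)
from netcoal.configurations import ConfigSet, Mode
from netcoal.reconcile import create_cacs_for_prob, create_cacs_for_xl

from conftest import random_instance


class TestCreateCacsForXL:
    def test_singleton_unchanged(self):
        g = parse_gene_tree("((a,b),c);")
        a = g.leaf_by_label["a"]
        cs = ConfigSet(Mode.XL)
        cs.add(frozenset({a}), (0,), 1)
        out = create_cacs_for_xl(g, cs)
        assert dict(out.items()) == {(frozenset({a}), (0,)): 1}

    def test_cherry_fully_coalesces_at_no_cost(self):
        g = parse_gene_tree("((a,b),c);")
        a, b = g.leaf_by_label["a"], g.leaf_by_label["b"]
        cs = ConfigSet(Mode.XL)
        cs.add(frozenset({a, b}), (), 0)
        ((B, _), w), = out = list(create_cacs_for_xl(g, cs).items())
        assert B == frozenset({g.parent[a]})
        assert w == 0

    def test_unmergeable_lineages_pay_extra(self):
        g = parse_gene_tree("((a,b),(c,d));")
        # three lineages a, b, c: only the ab cherry merges -> 2 exit, 1 extra
        B = frozenset([g.leaf_by_label[x] for x in "abc"])
        cs = ConfigSet(Mode.XL)
        cs.add(B, (), 1)
        ((Bp, _), w), = list(create_cacs_for_xl(g, cs).items())
        assert len(Bp) == 2
        assert w == 1 + 1
        # fully unmergeable: a, c with weight 1 -> 1 + (2-1)
        cs2 = ConfigSet(Mode.XL)
        cs2.add(frozenset([g.leaf_by_label["a"], g.leaf_by_label["c"]]), (), 1)
        ((Bp2, _), w2), = list(create_cacs_for_xl(g, cs2).items())
        assert Bp2 == frozenset([g.leaf_by_label["a"], g.leaf_by_label["c"]])
        assert w2 == 2


class TestCreateCacsForProb:
    def test_singleton_weight_preserved(self):
        g = parse_gene_tree("((a,b),c);")
        cs = ConfigSet(Mode.PROB)
        cs.add(frozenset({g.leaf_by_label["a"]}), (), 0.4)
        ((_, _), w), = list(create_cacs_for_prob(g, 2.0, cs).items())
        assert w == pytest.approx(0.4)

    def test_cherry_two_outcomes(self):
        g = parse_gene_tree("((a,b),c);")
        a, b = g.leaf_by_label["a"], g.leaf_by_label["b"]
        cs = ConfigSet(Mode.PROB)
        cs.add(frozenset({a, b}), (), 1.0)
        out = dict(create_cacs_for_prob(g, 0.7, cs).items())
        assert out[(frozenset({a, b}), ())] == pytest.approx(math.exp(-0.7))
        assert out[(frozenset({g.parent[a]}), ())] == pytest.approx(
            1 - math.exp(-0.7)
        )

    def test_identical_outcomes_consolidate_by_sum(self):
        g = parse_gene_tree("((a,b),c);")
        a, b = g.leaf_by_label["a"], g.leaf_by_label["b"]
        ab = g.parent[a]
        cs = ConfigSet(Mode.PROB)
        cs.add(frozenset({a, b}), (), 0.5)
        cs.add(frozenset({ab}), (), 0.25)
        out = dict(create_cacs_for_prob(g, 1.0, cs).items())
        assert out[(frozenset({ab}), ())] == pytest.approx(
            0.5 * (1 - math.exp(-1)) + 0.25
        )


class TestCountXL:
    def test_tree_specialization(self, tree3, gene_disc):
        assert count_xl(tree3, gene_disc) == xl_tree(tree3, gene_disc)

    def test_displayed_gene_tree_costs_nothing(self, diamond):
        import re

        for disp in displayed_trees(diamond):
            topo = re.sub(r":[0-9.eE+-]+", "", disp.newick())
            assert count_xl(diamond, parse_gene_tree(topo)) == 0

    def test_network_never_beats_its_displayed_trees(self, diamond):
        for t in all_rooted_topologies(sorted(diamond.leaf_label.values())):
            g = parse_gene_tree(t)
            best_tree = min(xl_tree(d, g) for d in displayed_trees(diamond))
            assert count_xl(diamond, g) <= best_tree

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_history_oracle(self, seed):
        rng = random.Random(seed * 31 + 7)
        ntaxa = rng.choice([3, 4, 5])
        q = rng.choice([0, 1, 2]) if ntaxa <= 4 else rng.choice([0, 1])
        N, g, mu = random_instance(rng, ntaxa, q)
        assert count_xl(N, g, mu) == brute_xl(N, g, mu)
        assert count_xl(N, g, mu, use_reduction=False) == brute_xl(N, g, mu)


class TestCalProb:
    def test_tree_specialization(self, tree3, gene_match):
        assert cal_prob(tree3, gene_match) == pytest.approx(
            prob_exact(tree3, gene_match), rel=1e-12
        )

    def test_degenerate_gamma_matches_displayed_tree(self, diamond):
        r = diamond.reticulations[0]
        u1, u2 = diamond.parents[r]
        for hot, disp_idx in ((u1, 0), (u2, 1)):
            diamond.gamma[(u1, r)] = 1.0 if hot == u1 else 0.0
            diamond.gamma[(u2, r)] = 1.0 if hot == u2 else 0.0
            disp = displayed_trees(diamond)[disp_idx]
            for t in all_rooted_topologies(sorted(diamond.leaf_label.values())):
                g = parse_gene_tree(t)
                assert cal_prob(diamond, g) == pytest.approx(
                    prob_exact(disp, g), abs=1e-9
                )

    def test_normalization_with_reticulation(self, diamond):
        tot = math.fsum(
            cal_prob(diamond, parse_gene_tree(t))
            for t in all_rooted_topologies(sorted(diamond.leaf_label.values()))
        )
        assert tot == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_history_oracle(self, seed):
        rng = random.Random(seed * 17 + 3)
        ntaxa = rng.choice([3, 4, 5])
        q = rng.choice([0, 1, 2]) if ntaxa <= 4 else rng.choice([0, 1])
        N, g, mu = random_instance(rng, ntaxa, q)
        expect = brute_prob(N, g, mu)
        assert cal_prob(N, g, mu) == pytest.approx(expect, rel=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_articulation_reduction_invariance(self, seed):
        rng = random.Random(seed * 101 + 13)
        N, g, mu = random_instance(rng, 4, rng.choice([1, 2]))
        on = cal_prob(N, g, mu, use_reduction=True)
        off = cal_prob(N, g, mu, use_reduction=False)
        assert abs(on - off) < 1e-12

    def test_interior_gamma_between_displayed_trees_mixture(self, diamond):
        """For one lineage crossing, P is the gamma-mixture of displayed trees."""
        disp = displayed_trees(diamond)
        g = parse_gene_tree("((A,X),C);")
        r = diamond.reticulations[0]
        u1, u2 = diamond.parents[r]
        gam = diamond.gamma[(u1, r)]
        mix = gam * prob_exact(disp[0], g) + (1 - gam) * prob_exact(disp[1], g)
        assert cal_prob(diamond, g) == pytest.approx(mix, rel=1e-9)
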