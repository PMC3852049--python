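"""Coalescent scalar primitives: probabilities, ordering counts, merge closures."""

import math
import random

import pytest

from netcoal import (
    coal_set,
    coalesce_count_prob,
    consistent_orderings,
    max_coalesced,
    parse_gene_tree,
    total_orderings,
    transition_prob,
)


def enumerate_orderings(B, B_plus, g):
    """Exhaustive oracle: count event sequences turning B into B_plus under g."""
    B, B_plus = frozenset(B), frozenset(B_plus)
    if B == B_plus:
        return 1
    eligible = {
        g.parent[x]
        for x in B
        if g.parent[x] is not None
        and all(c in B for c in g.children[g.parent[x]])
    }
    total = 0
    for p in eligible:
        merged = (B - frozenset(g.children[p])) | {p}
        total += enumerate_orderings(merged, B_plus, g)
    return total


@pytest.fixture
def cat3():
    return parse_gene_tree("((a,b),c);")


@pytest.fixture
def bal4():
    return parse_gene_tree("((a,b),(c,d));")


class TestCoalesceCountProb:
    def test_single_lineage(self):
        for t in (0.0, 1.0, math.inf):
            assert coalesce_count_prob(1, 1, t) == 1.0

    def test_two_lineage_closed_forms(self):
        assert coalesce_count_prob(2, 1, 0.5) == pytest.approx(
            1 - math.exp(-0.5), abs=1e-12
        )
        assert coalesce_count_prob(2, 2, 1.0) == pytest.approx(
            math.exp(-1), abs=1e-12
        )

    def test_zero_time_identity(self):
        assert coalesce_count_prob(4, 4, 0.0) == 1.0
        assert coalesce_count_prob(4, 2, 0.0) == 0.0

    def test_infinite_time_absorbs(self):
        assert coalesce_count_prob(5, 1, math.inf) == 1.0
        assert coalesce_count_prob(5, 3, math.inf) == 0.0

    @pytest.mark.parametrize("u", range(2, 9))
    @pytest.mark.parametrize("t", [0.1, 1.0, 10.0])
    def test_distribution_sums_to_one(self, u, t):
        assert math.fsum(
            coalesce_count_prob(u, v, t) for v in range(1, u + 1)
        ) == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_cross_check(self):
        """Pairwise coalescence times are Exp(1): simulate p_{2,1}(t)."""
        rng = random.Random(12345)
        n = 20000
        t = 0.7
        hits = sum(rng.expovariate(1.0) <= t for _ in range(n))
        se = math.sqrt(n * 0.25) / n * 3
        assert abs(hits / n - coalesce_count_prob(2, 1, t)) < 3 * se + 0.01

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            coalesce_count_prob(2, 3, 1.0)
        with pytest.raises(ValueError):
            coalesce_count_prob(2, 0, 1.0)


class TestOrderings:
    @pytest.mark.parametrize(
        "u,v,expected", [(2, 1, 1), (3, 1, 3), (5, 2, 180), (4, 4, 1)]
    )
    def test_total(self, u, v, expected):
        assert total_orderings(u, v) == expected

    def test_single_event(self, cat3):
        a, b = cat3.leaf_by_label["a"], cat3.leaf_by_label["b"]
        ab = cat3.parent[a]
        B = frozenset({a, b})
        assert consistent_orderings(B, frozenset({ab}), cat3) == 1

    def test_two_disjoint_cherries(self, bal4):
        g = bal4
        leaves = {g.labels[v]: v for v in g.leaves}
        B = frozenset(leaves.values())
        ab, cd = g.parent[leaves["a"]], g.parent[leaves["c"]]
        assert consistent_orderings(B, frozenset({ab, cd}), g) == 2

    def test_cherries_then_join(self, bal4):
        g = bal4
        B = frozenset(g.leaves)
        assert consistent_orderings(B, frozenset({g.root}), g) == 2  # 3!/(1*1*3)

    @pytest.mark.parametrize("newick", ["((a,b),c);", "((a,b),(c,d));", "(((a,b),c),d);"])
    def test_matches_enumeration_oracle(self, newick):
        g = parse_gene_tree(newick)
        B = frozenset(g.leaves)
        for B_plus in coal_set(B, g):
            assert consistent_orderings(B, B_plus, g) == enumerate_orderings(
                B, B_plus, g
            )
            assert consistent_orderings(B, B_plus, g) <= total_orderings(
                len(B), len(B_plus)
            )

    def test_unreachable_target_rejected(self, cat3):
        a, c = cat3.leaf_by_label["a"], cat3.leaf_by_label["c"]
        ab = cat3.parent[a]
        with pytest.raises(ValueError):
            consistent_orderings(frozenset({a, c}), frozenset({ab}), cat3)


class TestCoalSet:
    def test_cherry(self, cat3):
        a, b = cat3.leaf_by_label["a"], cat3.leaf_by_label["b"]
        ab = cat3.parent[a]
        B = frozenset({a, b})
        assert coal_set(B, cat3) == {B, frozenset({ab})}

    def test_no_merge_possible(self, cat3):
        a, c = cat3.leaf_by_label["a"], cat3.leaf_by_label["c"]
        B = frozenset({a, c})
        assert coal_set(B, cat3) == {B}

    def test_caterpillar_chain(self, cat3):
        B = frozenset(cat3.leaves)
        assert len(coal_set(B, cat3)) == 3  # {a,b,c}, {ab,c}, {abc}

    @pytest.mark.parametrize(
        "k,newick",
        [
            (1, "((x1,y1),z1);"),
            (2, "(((x1,y1),z1),(x2,y2));"),
            (3, "(((((x1,y1),z1),(x2,y2)),z2),(x3,y3));"),
            (4, "(((((((x1,y1),z1),(x2,y2)),z2),(x3,y3)),z3),(x4,y4));"),
        ],
    )
    def test_independent_events_give_power_of_two(self, k, newick):
        """Spacer leaves keep the k cherry merges mutually independent."""
        g = parse_gene_tree(newick)
        B = frozenset(
            v for v in g.leaves if not g.labels[v].startswith("z")
        )
        assert len(coal_set(B, g)) == 2 ** k

    def test_max_coalesced(self, cat3):
        B = frozenset(cat3.leaves)
        assert max_coalesced(B, cat3) == frozenset({cat3.root})
        a, c = cat3.leaf_by_label["a"], cat3.leaf_by_label["c"]
        assert max_coalesced(frozenset({a, c}), cat3) == frozenset({a, c})


class TestTransitionProb:
    def test_identity_set(self, cat3):
        B = frozenset({cat3.leaf_by_label["a"], cat3.leaf_by_label["b"]})
        assert transition_prob(B, B, 1.0, cat3) == pytest.approx(math.exp(-1))

    def test_cherry_coalesces(self, cat3):
        a, b = cat3.leaf_by_label["a"], cat3.leaf_by_label["b"]
        ab = cat3.parent[a]
        assert transition_prob(
            frozenset({a, b}), frozenset({ab}), 0.5, cat3
        ) == pytest.approx(1 - math.exp(-0.5))

    def test_root_fraction_caterpillar(self, cat3):
        B = frozenset(cat3.leaves)
        assert transition_prob(
            B, frozenset({cat3.root}), math.inf, cat3
        ) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("newick,t", [("((a,b),c);", 0.8), ("((a,b),(c,d));", 1.5)])
    def test_subdistribution(self, newick, t):
        """Sums to <= 1 over reachable sets; = 1 iff every merge is consistent."""
        g = parse_gene_tree(newick)
        B = frozenset(g.leaves)
        tot = math.fsum(transition_prob(B, Bp, t, g) for Bp in coal_set(B, g))
        # the caterpillar's first merge can be inconsistent (a with c), the
        # balanced tree's first merge can be inconsistent too: strictly < 1
        assert tot < 1.0
        # a pure cherry: every coalescence is consistent, total is exactly 1
        cherry = parse_gene_tree("(a,b);")
        Bc = frozenset(cherry.leaves)
        assert math.fsum(
            transition_prob(Bc, Bp, t, cherry) for Bp in coal_set(Bc, cherry)
        ) == pytest.approx(1.0, abs=1e-12)
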