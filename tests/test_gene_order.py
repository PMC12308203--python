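"""Circular signed gene-order comparison: canonical form, breakpoint
distance, cluster search, apomorphy scan, and the NJ plumbing."""

import numpy as np
import pytest

from mitoprof.annotation_io import extract_gene_order
from mitoprof.gene_order import (
    ANCESTRAL_ND2_CLUSTER,
    NEOCOCCOID_ND2_CLUSTERS,
    GeneOrder,
    adjacencies,
    apomorphy_scan,
    breakpoint_distance,
    canonicalize,
    find_cluster,
    nj_tree,
    order_distance_matrix,
)
from mitoprof.synthetic_data import perturb_gene_order


def _random_order(rng, n=12):
    labels = [f"g{i}" for i in range(n)]
    rng.shuffle(labels)
    return GeneOrder("r", tuple((l, int(rng.choice([-1, 1]))) for l in labels))


class TestCanonicalize:
    def test_anchored_order_unchanged(self):
        o = GeneOrder.parse("COI,trnA,-trnB,ND2", "t")
        assert canonicalize(o) == o

    def test_rotation_yields_same_canonical_form(self):
        o = GeneOrder.parse("COI,trnA,-trnB,ND2,trnC", "t")
        rotated = GeneOrder("t", o.genes[2:] + o.genes[:2])
        assert canonicalize(rotated) == canonicalize(o)

    def test_negative_anchor_flips_whole_order(self):
        o = GeneOrder.parse("trnA,-COI,trnB,-trnC", "t")
        canon = canonicalize(o)
        assert canon.genes[0] == ("COI", 1)
        # flip of (trnA,-COI,trnB,-trnC) is (trnC,-trnB,COI,-trnA), rotated to COI
        assert canon.genes == (("COI", 1), ("trnA", -1), ("trnC", 1), ("trnB", -1))

    def test_reflection_same_canonical_form(self):
        o = GeneOrder.parse("COI,trnA,-trnB,ND2", "t")
        flipped = GeneOrder("t", tuple((g, -s) for g, s in reversed(o.genes)))
        assert canonicalize(flipped) == canonicalize(o)


class TestBreakpointDistance:
    def test_identical_orders_distance_zero(self):
        o = GeneOrder.parse("COI,trnA,-trnB,ND2,trnC")
        assert breakpoint_distance(o, o) == 0

    def test_moving_one_gene_breaks_three_adjacencies(self):
        a = GeneOrder.parse("g1,g2,g3,g4,g5")
        b = GeneOrder.parse("g1,g3,g4,g2,g5")  # g2 moved between g4 and g5
        assert breakpoint_distance(a, b) == 3

    def test_pseudometric_axioms_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            a, b = _random_order(rng), _random_order(rng)
            d_ab = breakpoint_distance(a, b)
            assert d_ab >= 0
            assert d_ab == breakpoint_distance(b, a)
            assert breakpoint_distance(a, a) == 0

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(23)
        for _ in range(60):
            a, b, c = (_random_order(rng) for _ in range(3))
            assert (breakpoint_distance(a, c)
                    <= breakpoint_distance(a, b) + breakpoint_distance(b, c))

    def test_strand_flip_of_whole_order_is_distance_zero(self):
        o = GeneOrder.parse("COI,trnA,-trnB,ND2")
        flipped = GeneOrder("f", tuple((g, -s) for g, s in reversed(o.genes)))
        assert breakpoint_distance(o, flipped) == 0

    def test_differing_gene_content_warns_and_restricts(self):
        a = GeneOrder.parse("g1,g2,g3,g4")
        b = GeneOrder.parse("g1,g2,g3,g5")
        with pytest.warns(UserWarning, match="shared"):
            breakpoint_distance(a, b)


class TestFindCluster:
    def test_reference_order_retains_ancestral_nd2_cluster(
        self, reference_annotation
    ):
        order = extract_gene_order(reference_annotation, taxon="reference")
        matches = find_cluster(order, ANCESTRAL_ND2_CLUSTER)
        assert len(matches) == 1 and not matches[0].inverted

    def test_derived_neococcoid_cluster_absent_from_reference(
        self, reference_annotation
    ):
        order = extract_gene_order(reference_annotation)
        assert find_cluster(order, NEOCOCCOID_ND2_CLUSTERS["trnI-ND2-trnY"]) == []

    def test_match_across_circular_origin(self):
        o = GeneOrder.parse("ND2,trnW,g1,g2,g3,trnM")
        matches = find_cluster(o, GeneOrder.parse("trnM,ND2,trnW").genes)
        assert len(matches) == 1

    def test_inverted_occurrence_reported(self):
        # reverse complement of +a,+b is -b,-a
        o = GeneOrder.parse("g1,-trnB,-trnA,g2")
        matches = find_cluster(o, GeneOrder.parse("trnA,trnB").genes)
        assert len(matches) == 1 and matches[0].inverted

    def test_pattern_too_short_rejected(self):
        o = GeneOrder.parse("g1,g2,g3")
        with pytest.raises(ValueError):
            find_cluster(o, (("g1", 1),))


class TestApomorphyScan:
    def test_fixed_exclusive_pattern_flagged(self):
        g1 = [GeneOrder.parse("a,b,c,d", "t1"), GeneOrder.parse("a,b,c,d", "t2")]
        g2 = [GeneOrder.parse("a,c,b,d", "t3")]
        out = apomorphy_scan({"G1": g1, "G2": g2},
                             {"ab": GeneOrder.parse("a,b").genes})
        row = out[out.group == "G1"].iloc[0]
        assert row.diagnostic_for == "G1" and row.fixed_in == "G1"

    def test_shared_pattern_not_flagged(self):
        g1 = [GeneOrder.parse("a,b,c,d", "t1")]
        g2 = [GeneOrder.parse("a,b,d,c", "t2")]
        out = apomorphy_scan({"G1": g1, "G2": g2},
                             {"ab": GeneOrder.parse("a,b").genes})
        assert out.diagnostic_for.isna().all()

    def test_unknown_gene_label_in_pattern_named(self):
        g1 = [GeneOrder.parse("a,b", "t1")]
        g2 = [GeneOrder.parse("b,a", "t2")]
        with pytest.raises(ValueError, match="zz"):
            apomorphy_scan({"G1": g1, "G2": g2},
                           {"bad": GeneOrder.parse("a,zz").genes})

    def test_ancestral_cluster_in_all_non_neococcoids(self, reference_orders):
        orders, groups = reference_orders
        non_neo = [orders[t] for t in orders if groups[t] == "non_neococcoid"]
        assert len(non_neo) == 4
        for o in non_neo:
            assert find_cluster(o, ANCESTRAL_ND2_CLUSTER), o.taxon

    def test_neococcoid_patterns_group_diagnostic_on_fixture(self, reference_orders):
        orders, groups = reference_orders
        by_group = {}
        for taxon, o in orders.items():
            if groups[taxon] == "ancestor":
                continue
            by_group.setdefault(groups[taxon], []).append(o)
        out = apomorphy_scan(by_group, NEOCOCCOID_ND2_CLUSTERS)
        for pattern in NEOCOCCOID_ND2_CLUSTERS:
            rows = out[out.pattern == pattern]
            assert (rows.diagnostic_for == "neococcoid").all(), pattern
        anc = apomorphy_scan(by_group, {"ancestral": ANCESTRAL_ND2_CLUSTER})
        assert (anc.diagnostic_for == "non_neococcoid").all()
        assert (anc.fixed_in == "non_neococcoid").all()


class TestDistanceMatrixAndTree:
    def test_closest_pair_become_sisters(self):
        a = GeneOrder.parse("g1,g2,g3,g4,g5", "A")
        b = GeneOrder.parse("g1,g2,g3,g4,g5", "B")
        c = GeneOrder.parse("g1,g3,g5,g2,g4", "C")
        d = GeneOrder.parse("g1,g3,g5,g4,g2", "D")
        tree = nj_tree(order_distance_matrix([a, b, c, d]))
        import re
        # A and B (distance 0) must share a cherry
        assert re.search(r"\(A[^()]*,B[^()]*\)|\(B[^()]*,A[^()]*\)", tree)

    def test_nj_recovers_additive_four_taxon_topology(self):
        import pandas as pd
        ids = list("ABCD")
        # additive on ((A,B),(C,D)) with internal branch 2
        m = pd.DataFrame(
            [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]],
            index=ids, columns=ids, dtype=float,
        )
        tree = nj_tree(m)
        import re
        assert (re.search(r"\(A[^()]*,B[^()]*\)|\(B[^()]*,A[^()]*\)", tree)
                or re.search(r"\(C[^()]*,D[^()]*\)|\(D[^()]*,C[^()]*\)", tree))

    def test_all_equal_distances_still_give_valid_tree(self):
        orders = [GeneOrder.parse("g1,g2,g3,g4", t) for t in "ABC"]
        import pandas as pd
        m = pd.DataFrame([[0, 3, 3], [3, 0, 3], [3, 3, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        tree = nj_tree(m)
        assert tree.endswith(";") and all(t in tree for t in "ABC")


class TestPerturbation:
    def test_zero_events_is_identity(self, reference_orders):
        orders, _ = reference_orders
        anc = orders["ancestor"]
        out, log = perturb_gene_order(anc, 0, seed=1)
        assert out == anc and log == []

    def test_one_transposition_gives_distance_two_or_three(self, reference_orders):
        orders, _ = reference_orders
        anc = orders["ancestor"]
        for seed in range(8):
            out, log = perturb_gene_order(anc, 1, event_mix=(1.0, 0.0), seed=seed)
            d = breakpoint_distance(anc, out)
            assert d in (2, 3)

    def test_same_seed_reproducible(self, reference_orders):
        orders, _ = reference_orders
        anc = orders["ancestor"]
        a, _ = perturb_gene_order(anc, 4, seed=9)
        b, _ = perturb_gene_order(anc, 4, seed=9)
        assert a == b

    def test_median_distance_non_decreasing_in_event_count(self, reference_orders):
        orders, _ = reference_orders
        anc = orders["ancestor"]
        medians = []
        for k in range(1, 6):
            ds = [breakpoint_distance(
                anc, perturb_gene_order(anc, k, seed=100 * k + r)[0])
                for r in range(12)]
            medians.append(np.median(ds))
        assert all(m2 >= m1 for m1, m2 in zip(medians, medians[1:]))
        assert medians[0] > 0
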