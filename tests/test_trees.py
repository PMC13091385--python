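import io as _io
import itertools
import math

import numpy as np
import pytest
from skbio import TreeNode

from ssptrace.io import AlignedBlock, ProteinRecord
from ssptrace.synth import diverge_from_ancestor
from ssptrace.trees import (basal_placement_frequency, bootstrap_support,
                            bootstrap_trees, distance_matrix,
                            neighbor_joining, poisson_distance)


def _tree(newick):
    return TreeNode.read(_io.StringIO(newick))


class TestPoissonDistance:
    def test_identical_sequences_zero(self):
        assert poisson_distance("KRHA", "KRHA") == 0.0

    def test_closed_form(self):
        # p = 0.1 -> -ln(0.9)
        a = "A" * 9 + "K"
        b = "A" * 9 + "R"
        assert poisson_distance(a, b) == pytest.approx(-math.log(0.9))

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        alpha = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            a = "".join(rng.choice(alpha, 30))
            b = "".join(rng.choice(alpha, 30))
            assert poisson_distance(a, b) == poisson_distance(b, a)

    def test_saturation_capped(self):
        assert poisson_distance("AAAA", "VVVV") == 5.0

    def test_gap_only_overlap_raises(self):
        with pytest.raises(ValueError):
            poisson_distance("A--", "-AA")


def _additive_matrix_from_tree(tree, labels):
    d = tree.tip_tip_distances(list(labels))
    n = len(labels)
    m = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            m[i, j] = d[a, b]
    return m


def _all_quartet_trees():
    # the three unrooted 4-taxon topologies with integer branch lengths
    shapes = [
        "((A:{0},B:{1}):{4},C:{2},D:{3});",
        "((A:{0},C:{1}):{4},B:{2},D:{3});",
        "((A:{0},D:{1}):{4},B:{2},C:{3});",
    ]
    for shape in shapes:
        for lens in itertools.product((1, 2, 3), repeat=5):
            yield _tree(shape.format(*lens))


class TestNeighborJoining:
    def test_worked_quartet_recovered_with_branch_lengths(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> additive distances
        ref = _tree("((A:1,B:2):1,(C:3,D:1):0);")
        labels = ["A", "B", "C", "D"]
        m = _additive_matrix_from_tree(ref, labels)
        t = neighbor_joining(m, labels)
        got = t.tip_tip_distances(labels)
        for a, b in itertools.combinations(labels, 2):
            assert got[a, b] == pytest.approx(m[labels.index(a), labels.index(b)])

    def test_recovers_all_quartet_topologies(self):
        labels = ["A", "B", "C", "D"]
        for ref in itertools.islice(_all_quartet_trees(), 0, None, 7):
            m = _additive_matrix_from_tree(ref, labels)
            t = neighbor_joining(m, labels)
            got = t.tip_tip_distances(labels)
            for i, j in itertools.combinations(range(4), 2):
                assert got[labels[i], labels[j]] == pytest.approx(m[i, j]), str(ref)

    def test_recovers_five_taxon_caterpillar_trees(self):
        labels = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(0)
        for _ in range(30):
            lens = rng.integers(1, 4, size=7)
            ref = _tree(
                "((A:{0},B:{1}):{5},(C:{2},(D:{3},E:{4}):{6}):0);".format(*lens)
            )
            m = _additive_matrix_from_tree(ref, labels)
            t = neighbor_joining(m, labels)
            got = t.tip_tip_distances(labels)
            for i, j in itertools.combinations(range(5), 2):
                assert got[labels[i], labels[j]] == pytest.approx(m[i, j])

    def test_taxon_order_invariance(self):
        labels = ["A", "B", "C", "D", "E"]
        ref = _tree("((A:1,B:2):1,(C:3,(D:1,E:2):1):0);")
        m = _additive_matrix_from_tree(ref, labels)
        t1 = neighbor_joining(m, labels)
        perm = [3, 1, 4, 0, 2]
        m2 = m[np.ix_(perm, perm)]
        t2 = neighbor_joining(m2, [labels[i] for i in perm])
        d1 = t1.tip_tip_distances(labels)
        d2 = t2.tip_tip_distances(labels)
        for a, b in itertools.combinations(labels, 2):
            assert d1[a, b] == pytest.approx(d2[a, b])

    def test_star_matrix_yields_tree_without_crash(self):
        m = np.full((4, 4), 2.0)
        np.fill_diagonal(m, 0.0)
        t = neighbor_joining(m, ["A", "B", "C", "D"])
        assert {x.name for x in t.tips()} == {"A", "B", "C", "D"}
        assert all((n.length or 0) >= 0 for n in t.traverse())

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((4, 4))
        m[0, 1] = 1.0
        with pytest.raises(ValueError):
            neighbor_joining(m, list("ABCD"))


def _two_clade_block(rng=None):
    rng = rng or np.random.default_rng(3)
    return diverge_from_ancestor(rng, length=120, n_plants=6, n_protists=4)


class TestBootstrap:
    def test_fixed_seed_reproducible(self):
        block = _two_clade_block()
        t1 = bootstrap_trees(block, reps=10, rng=np.random.default_rng(1))
        t2 = bootstrap_trees(block, reps=10, rng=np.random.default_rng(1))
        for a, b in zip(t1, t2):
            assert str(a) == str(b)

    def test_clean_deep_split_has_high_support(self):
        block = _two_clade_block()
        ref = neighbor_joining(distance_matrix(block))
        boots = bootstrap_trees(block, reps=50, rng=np.random.default_rng(2))
        support = bootstrap_support(ref, boots)
        plants = frozenset(r.id for r in block.records if r.group == "land_plant")
        all_tips = frozenset(r.id for r in block.records)
        key = min(plants, all_tips - plants, key=sorted)
        assert support.get(key, 0.0) >= 0.95

    def test_zero_divergence_alignment_does_not_crash(self):
        recs = tuple(
            ProteinRecord(id=f"t{i}", seq="KRHAKRHA", group="unassigned")
            for i in range(5)
        )
        block = AlignedBlock(records=recs, width=8)
        trees = bootstrap_trees(block, reps=5, rng=np.random.default_rng(0))
        assert len(trees) == 5


class TestBasalPlacement:
    def test_plants_monophyletic_with_protists_outside_is_one(self):
        t = _tree("(((p1:0.1,p2:0.1):0.5,(x1:0.4,x2:0.5):0.1):0.2,x3:0.9);")
        f = basal_placement_frequency([t], ["p1", "p2"], ["x1", "x2", "x3"])
        assert f == 1.0

    def test_protist_nested_inside_plants_is_zero(self):
        t = _tree("(((p1:0.1,x1:0.1):0.1,p2:0.1):0.5,(x2:0.4,x3:0.5):0.2);")
        f = basal_placement_frequency([t], ["p1", "p2"], ["x1", "x2", "x3"])
        assert f == 0.0

    def test_missing_label_raises(self):
        t = _tree("((a:1,b:1):1,(c:1,d:1):0);")
        with pytest.raises(ValueError, match="missing"):
            basal_placement_frequency([t], ["a", "zz"], ["c"])

    def test_invariant_under_consistent_renaming(self):
        block = _two_clade_block()
        boots = bootstrap_trees(block, reps=20, rng=np.random.default_rng(9))
        l = [r.id for r in block.records if r.group == "land_plant"]
        p = [r.id for r in block.records if r.group == "protist"]
        f1 = basal_placement_frequency(boots, l, p)
        renamed = []
        for t in boots:
            c = t.copy()
            for tip in c.tips():
                tip.name = "X" + tip.name
            renamed.append(c)
        f2 = basal_placement_frequency(renamed, ["X" + x for x in l], ["X" + x for x in p])
        assert f1 == f2
        assert 0.0 <= f1 <= 1.0

    def test_early_diverging_protists_place_basally(self):
        block = diverge_from_ancestor(np.random.default_rng(5))
        boots = bootstrap_trees(block, reps=30, rng=np.random.default_rng(6))
        l = [r.id for r in block.records if r.group == "land_plant"]
        p = [r.id for r in block.records if r.group == "protist"]
        assert basal_placement_frequency(boots, l, p) >= 0.8
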