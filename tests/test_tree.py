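"""Distances, neighbor-joining, Newick round trips, bootstrap."""

import math

import numpy as np
import pytest

from evokit.tree import (
    Alignment,
    DistanceMatrix,
    SaturationError,
    bootstrap_support,
    neighbor_joining,
    pairwise_distance,
    parse_newick,
    random_additive_tree,
    write_newick,
)


def path_matrix(tree, labels):
    """Leaf-to-leaf path lengths of a tree, in the given label order."""
    idx = {l: i for i, l in enumerate(labels)}
    d = np.zeros((len(labels), len(labels)))

    def below(node):
        if node.is_leaf:
            return {node.label: 0.0}
        groups, out = [], {}
        for c in node.children:
            g = {l: x + c.length for l, x in below(c).items()}
            groups.append(g)
            out.update(g)
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for la, da in groups[a].items():
                    for lb, db in groups[b].items():
                        d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da + db
        return out

    below(tree.root)
    return d


class TestDistances:
    def test_identical_sequences_are_zero_under_all_models(self):
        aln = Alignment([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        for model in ("p", "jc69", "k2p"):
            assert pairwise_distance(aln, model).matrix[0, 1] == 0.0

    def test_jc69_worked_example(self):
        aln = Alignment([("a", "ACGT"), ("b", "ACGA")])
        dm_p = pairwise_distance(aln, "p")
        assert dm_p.matrix[0, 1] == pytest.approx(0.25)
        dm = pairwise_distance(aln, "jc69")
        assert dm.matrix[0, 1] == pytest.approx(-0.75 * math.log(2 / 3), abs=1e-9)
        assert dm.matrix[0, 1] == pytest.approx(0.304099, abs=1e-6)

    def test_jc69_agrees_with_p_at_small_divergence(self):
        # 1 mismatch in 10,000 sites: correction is first-order negligible
        s1 = "A" * 10000
        s2 = "C" + "A" * 9999
        aln = Alignment([("a", s1), ("b", s2)])
        p = pairwise_distance(aln, "p").matrix[0, 1]
        jc = pairwise_distance(aln, "jc69").matrix[0, 1]
        assert abs(jc - p) < 1e-6

    def test_k2p_separates_transitions_from_transversions(self):
        # one transition (A<->G), one transversion (A<->C), 8 sites
        aln = Alignment([("a", "AAAAAAAA"), ("b", "GCAAAAAA")])
        P, Q = 1 / 8, 1 / 8
        expect = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert pairwise_distance(aln, "k2p").matrix[0, 1] == pytest.approx(expect)

    def test_saturation_error_names_the_pair(self):
        aln = Alignment([("x1", "ACGT"), ("y1", "CATG")])  # p = 1
        with pytest.raises(SaturationError, match="x1"):
            pairwise_distance(aln, "jc69")

    def test_pairwise_deletion_and_no_comparable_sites(self):
        aln = Alignment([("a", "AC-T"), ("b", "ACG-")])
        # comparable columns: positions 0,1 only -> p = 0
        assert pairwise_distance(aln, "p").matrix[0, 1] == 0.0
        bad = Alignment([("a", "--AA"), ("b", "GG--")])
        with pytest.raises(ValueError, match="no comparable sites"):
            pairwise_distance(bad, "p")


class TestNeighborJoining:
    def test_three_taxon_worked_example(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        )
        tree = neighbor_joining(dm)
        lengths = {c.label: c.length for c in tree.root.children}
        assert lengths == {
            "A": pytest.approx(1.0),
            "B": pytest.approx(1.0),
            "C": pytest.approx(3.0),
        }

    def test_two_taxon_tree_splits_distance_evenly(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 3.0], [3.0, 0]]))
        tree = neighbor_joining(dm)
        assert {c.length for c in tree.root.children} == {1.5}

    def test_consistency_on_additive_matrices(self):
        for seed in range(30):
            true_tree, dm = random_additive_tree(8, seed=seed)
            rec = neighbor_joining(dm)
            assert rec.bipartitions().keys() == true_tree.bipartitions().keys()
            err = np.abs(path_matrix(rec, dm.labels) - dm.matrix).max()
            assert err < 1e-8

    def test_label_permutation_invariance(self):
        _, dm = random_additive_tree(7, seed=3)
        perm = np.random.default_rng(0).permutation(len(dm.labels))
        dm2 = DistanceMatrix(
            [dm.labels[i] for i in perm], dm.matrix[np.ix_(perm, perm)]
        )
        assert neighbor_joining(dm).bipartitions().keys() == \
            neighbor_joining(dm2).bipartitions().keys()

    def test_clamped_negative_branches_preserve_pair_path_length(self):
        # a matrix violating additivity enough to force a negative branch
        d = np.array(
            [[0, 5, 9, 9, 8],
             [5, 0, 10, 10, 9],
             [9, 10, 0, 8, 7],
             [9, 10, 8, 0, 3],
             [8, 9, 7, 3, 0]], float)
        # perturb to create a negative NJ branch
        d[0, 1] = d[1, 0] = 0.1
        dm = DistanceMatrix(list("ABCDE"), d)
        plain = neighbor_joining(dm)
        clamped = neighbor_joining(dm, clamp_negative=True)

        def lengths(tree):
            out = []

            def walk(n):
                for c in n.children:
                    out.append(c.length)
                    walk(c)

            walk(tree.root)
            return out

        assert min(lengths(plain)) < 0  # faithful default keeps it
        assert min(lengths(clamped)) >= 0
        # the clamp moves length to the sibling: joined-pair path preserved
        pm_p, pm_c = path_matrix(plain, dm.labels), path_matrix(clamped, dm.labels)
        assert pm_c[0, 1] == pytest.approx(pm_p[0, 1])

    def test_complete_deletion_drops_columns_globally(self):
        aln = Alignment([("a", "ACGTA"), ("b", "ACGTA"), ("c", "TC-TA")])
        pw = pairwise_distance(aln, "p", deletion="pairwise")
        comp = pairwise_distance(aln, "p", deletion="complete")
        # pairwise: a-b compare all 5 columns; complete: column 2 dropped
        assert pw.matrix[0, 1] == 0.0
        assert comp.matrix[0, 2] == pytest.approx(1 / 4)

    def test_four_point_condition_on_random_additive_matrix(self):
        from itertools import combinations

        _, dm = random_additive_tree(7, seed=9)
        d = dm.matrix
        for i, j, k, l in combinations(range(7), 4):
            sums = sorted([d[i, j] + d[k, l], d[i, k] + d[j, l], d[i, l] + d[j, k]])
            assert sums[2] - sums[1] < 1e-9  # two largest are equal


class TestNewick:
    def test_writer_simple_and_roundtrip(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 1.0], [1.0, 0]]))
        tree = neighbor_joining(dm)
        assert write_newick(tree) == "(A:0.5,B:0.5);"

    def test_parse_four_leaf_tree(self):
        tree = parse_newick("(A:1,B:2,(C:3,D:4):5);")
        assert sorted(tree.leaf_labels) == ["A", "B", "C", "D"]
        internal = [c for c in tree.root.children if not c.is_leaf]
        assert len(internal) == 1 and internal[0].length == pytest.approx(5.0)

    def test_redundant_nesting_collapsed(self):
        tree = parse_newick("((A,B));")
        assert sorted(tree.leaf_labels) == ["A", "B"]
        assert len(tree.root.children) == 2

    def test_parse_errors_report_position(self):
        with pytest.raises(ValueError, match="position"):
            parse_newick("(A,B")
        with pytest.raises(ValueError, match="position"):
            parse_newick("(A,B);extra(")
        with pytest.raises(ValueError, match="position"):
            parse_newick("(A,B")

    def test_quoted_labels_roundtrip(self):
        text = "('taxon one':1,'it''s':2,C:3);"
        tree = parse_newick(text)
        assert "taxon one" in tree.leaf_labels and "it's" in tree.leaf_labels
        assert write_newick(parse_newick(write_newick(tree))) == write_newick(tree)

    def test_roundtrip_fixed_point_on_random_trees(self):
        for seed in range(100):
            tree, _ = random_additive_tree(int(3 + seed % 8), seed=seed)
            s1 = write_newick(tree)
            s2 = write_newick(parse_newick(s1))
            assert s1 == s2

    def test_support_values_serialize_as_internal_labels(self):
        tree = parse_newick("((A:1,B:1)87:0.1,C:2,D:2);")
        node = [c for c in tree.root.children if not c.is_leaf][0]
        assert node.support == 87
        assert ")87:" in write_newick(tree)


def make_two_clade_alignment(n_sites=1000, seed=0):
    """Two 2-taxon clades separated by many substitutions."""
    rng = np.random.default_rng(seed)
    anc = rng.choice(list("ACGT"), size=n_sites)

    def mutate(seq, rate):
        out = seq.copy()
        hit = rng.random(n_sites) < rate
        for i in np.where(hit)[0]:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
        return out

    left = mutate(anc, 0.3)  # long internal edge
    a = mutate(left, 0.02)
    b = mutate(left, 0.02)
    c = mutate(anc, 0.02)
    d = mutate(anc, 0.02)
    return Alignment(
        [("a", "".join(a)), ("b", "".join(b)), ("c", "".join(c)), ("d", "".join(d))]
    )


class TestBootstrap:
    def test_central_split_is_strongly_supported(self):
        aln = make_two_clade_alignment()
        tree, skipped = bootstrap_support(aln, "jc69", B=100, seed=4)
        assert skipped == 0
        (split_node,) = tree.bipartitions().values()
        assert split_node.support >= 95

    def test_single_replicate_support_is_binary(self):
        aln = make_two_clade_alignment(seed=1)
        tree, _ = bootstrap_support(aln, "p", B=1, seed=2)
        for node in tree.bipartitions().values():
            assert node.support in (0, 1)

    def test_identical_seed_identical_supports(self):
        aln = make_two_clade_alignment(seed=2)
        t1, _ = bootstrap_support(aln, "jc69", B=50, seed=8)
        t2, _ = bootstrap_support(aln, "jc69", B=50, seed=8)
        assert write_newick(t1) == write_newick(t2)


def test_random_additive_tree_determinism():
    t1, d1 = random_additive_tree(6, seed=5)
    t2, d2 = random_additive_tree(6, seed=5)
    assert write_newick(t1) == write_newick(t2)
    assert np.array_equal(d1.matrix, d2.matrix)
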