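"""Column filtering, distances, NJ, patristic and RF comparisons."""
import math

import dendropy
import numpy as np
import pytest

from thermoshuffle.phylo import (
    Alignment,
    DistanceMatrix,
    conserved_block_filter,
    consensus_distances,
    majority_topology,
    neighbor_joining,
    patristic_matrix,
    patristic_normalized,
    protein_distance,
    rf_distance,
    topology_signature,
    total_branch_length,
)
from conftest import random_additive_tree


def naive_patristic(tree, a, b):
    """Independent oracle: BFS over the node graph summing edge lengths."""
    adj = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            w = child.edge.length or 0.0
            adj.setdefault(id(node), []).append((id(child), w))
            adj.setdefault(id(child), []).append((id(node), w))
    leaves = {
        lf.taxon.label: id(lf) for lf in tree.leaf_node_iter()
    }
    start, goal = leaves[a], leaves[b]
    frontier = [(start, 0.0)]
    seen = {start}
    while frontier:
        node, dist = frontier.pop()
        if node == goal:
            return dist
        for nxt, w in adj[node]:
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, dist + w))
    raise AssertionError("disconnected tree")


class TestConservedBlockFilter:
    def _aln(self, rows):
        return Alignment([f"t{i}" for i in range(len(rows))], rows)

    def test_identical_gapfree_keeps_everything(self):
        res = conserved_block_filter(self._aln(["MKV" * 10] * 4))
        assert res.retained_fraction == 1.0
        assert res.passes_gate

    @pytest.mark.parametrize(
        "n_gapped,fraction,passes", [(24, 0.76, True), (26, 0.74, False)]
    )
    def test_seventy_five_percent_gate(self, n_gapped, fraction, passes):
        good = "A" * (100 - n_gapped)
        row1 = good + "C" * n_gapped
        row2 = good + "-" * n_gapped
        res = conserved_block_filter(self._aln([row1, row2]))
        assert res.retained_fraction == pytest.approx(fraction)
        assert res.passes_gate is passes

    def test_low_conservation_columns_dropped(self):
        rows = ["AAAA", "AAAC", "AAGG", "AATT"]  # col conservation 1,.75,.5,.25
        res = conserved_block_filter(
            self._aln(rows), min_conservation=0.5
        )
        assert list(res.alignment.mask) == [True, True, True, False]

    def test_all_columns_dropped_flagged_not_crashed(self):
        res = conserved_block_filter(self._aln(["A-", "-A"]))
        assert res.retained_fraction == 0.0
        assert not res.passes_gate

    def test_never_lengthens(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            rows = [
                "".join(rng.choice(list("ACDE-"), size=30))
                for _ in range(4)
            ]
            res = conserved_block_filter(self._aln(rows))
            assert 0.0 <= res.retained_fraction <= 1.0


class TestProteinDistance:
    def test_identical_rows_zero(self):
        dm = protein_distance(Alignment(["a", "b"], ["MKV" * 20] * 2))
        assert dm.matrix[0, 1] == 0.0

    def test_poisson_correction_closed_form(self):
        row1 = "A" * 100
        row2 = "C" * 10 + "A" * 90
        dm = protein_distance(Alignment(["a", "b"], [row1, row2]))
        assert dm.matrix[0, 1] == pytest.approx(-math.log(0.9), abs=1e-9)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(3)
        aa = list("ACDEFGHIKL")
        rows = ["".join(rng.choice(aa, size=60)) for _ in range(5)]
        dm = protein_distance(Alignment([f"t{i}" for i in range(5)], rows))
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)

    def test_no_comparable_columns_raises(self):
        with pytest.raises(ValueError, match="no comparable"):
            protein_distance(Alignment(["a", "b"], ["A-", "-A"]))


class TestNeighborJoining:
    def test_three_taxon_branch_lengths(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        )
        tree = neighbor_joining(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_recovers_known_additive_tree(self):
        true = dendropy.Tree.get(
            data="((A:1,B:2):1,(C:3,D:4):1);", schema="newick"
        )
        dm = patristic_matrix(true)
        # sanity: the four-point condition holds for the generating tree
        d = dm.matrix
        sums = sorted([d[0, 1] + d[2, 3], d[0, 2] + d[1, 3], d[0, 3] + d[1, 2]])
        assert sums[1] == pytest.approx(sums[2])
        rec = neighbor_joining(dm)
        assert rf_distance(rec, true) == 0
        back = patristic_matrix(rec).reordered(dm.taxa)
        assert np.allclose(back.matrix, dm.matrix, atol=1e-9)

    def test_q_tie_broken_deterministically(self):
        # fully symmetric matrix: every pair ties on Q
        dm = DistanceMatrix(
            ["A", "B", "C", "D"], np.ones((4, 4)) - np.eye(4)
        )
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(dm)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]], float))

    def test_matches_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(5)
        for _ in range(5):
            tree = random_additive_tree(6, rng)
            dm = patristic_matrix(tree)
            mine = neighbor_joining(dm)
            theirs_nwk = sk_nj(
                SkDM(dm.matrix, ids=dm.taxa), result_constructor=str
            )
            theirs = dendropy.Tree.get(
                data=theirs_nwk, schema="newick", preserve_underscores=True
            )
            assert rf_distance(mine, theirs) == 0


class TestPatristic:
    def test_normalized_example(self):
        tree = dendropy.Tree.get(data="((A:1,B:2):1,C:3);", schema="newick")
        nd = patristic_normalized(tree)
        assert nd.get("A", "B") == pytest.approx(3 / 7)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        tree = random_additive_tree(6, rng)
        nd1 = patristic_normalized(tree)
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= 10
        nd2 = patristic_normalized(tree)
        assert np.allclose(nd1.matrix, nd2.matrix)

    def test_entries_at_most_one(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            nd = patristic_normalized(random_additive_tree(8, rng))
            assert nd.matrix.max() <= 1.0 + 1e-12

    def test_matches_bfs_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            tree = random_additive_tree(8, rng)
            pm = patristic_matrix(tree)
            for a in pm.taxa[:4]:
                for b in pm.taxa[4:]:
                    assert pm.get(a, b) == pytest.approx(
                        naive_patristic(tree, a, b), abs=1e-9
                    )

    def test_zero_length_tree_rejected(self):
        tree = dendropy.Tree.get(data="((A:0,B:0):0,C:0);", schema="newick")
        with pytest.raises(ValueError):
            patristic_normalized(tree)


class TestRFDistance:
    def test_identical_zero(self):
        t = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
        assert rf_distance(t, t) == 0

    def test_alternative_quartet_is_four(self):
        t1 = dendropy.Tree.get(
            data="((A:1,B:1):1,(C:1,D:1):1,E:1);", schema="newick"
        )
        t2 = dendropy.Tree.get(
            data="((A:1,C:1):1,(B:1,D:1):1,E:1);", schema="newick"
        )
        assert rf_distance(t1, t2) == 4

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            t1 = random_additive_tree(7, rng)
            t2 = random_additive_tree(7, rng)
            assert rf_distance(t1, t2) == rf_distance(t2, t1)

    def test_leaf_mismatch_raises(self):
        t1 = dendropy.Tree.get(data="((A:1,B:1):1,C:1);", schema="newick")
        t2 = dendropy.Tree.get(data="((A:1,B:1):1,D:1);", schema="newick")
        with pytest.raises(ValueError, match="leaf"):
            rf_distance(t1, t2)


class TestConsensusDistances:
    def _dm(self, v):
        return DistanceMatrix(
            ["A", "B"], np.array([[0.0, v], [v, 0.0]])
        )

    def test_mean_of_two(self):
        cons = consensus_distances([self._dm(0.2), self._dm(0.4)])
        assert cons.get("A", "B") == pytest.approx(0.3)

    def test_single_tree_identity(self):
        cons = consensus_distances([self._dm(0.25)])
        assert cons.get("A", "B") == pytest.approx(0.25)

    def test_idempotent_on_identical(self):
        cons = consensus_distances([self._dm(0.4)] * 5)
        assert cons.get("A", "B") == pytest.approx(0.4)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            consensus_distances([])


class TestMajorityTopology:
    def test_plurality_wins(self):
        t_major = "((A:1,B:1):1,(C:1,D:1):1);"
        t_minor = "((A:1,C:1):1,(B:1,D:1):1);"
        trees = [
            dendropy.Tree.get(data=s, schema="newick")
            for s in [t_major, t_major, t_minor]
        ]
        cons = majority_topology(trees)
        assert topology_signature(cons) == topology_signature(trees[0])

    def test_tie_broken_toward_reference(self):
        t1 = "((A:1,B:1):1,(C:1,D:1):1);"
        t2 = "((A:1,C:1):1,(B:1,D:1):1);"
        trees = [
            dendropy.Tree.get(data=s, schema="newick") for s in [t1, t2]
        ]
        ref = dendropy.Tree.get(data=t2, schema="newick")
        cons = majority_topology(trees, reference=ref)
        assert topology_signature(cons) == topology_signature(ref)
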