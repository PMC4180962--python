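"""Movement scores, transfer calls, topology census and OU stratigraphy."""
import dendropy
import numpy as np
import pytest

from thermoshuffle.hgt import (
    UNKNOWN,
    OUPattern,
    call_transfer,
    donor_recipient_summary,
    movement_scores,
    ou_distance,
    ou_pattern,
    rank_relative_age,
    topology_census,
)
from thermoshuffle.phylo import (
    DistanceMatrix,
    consensus_distances,
    majority_topology,
    patristic_normalized,
)
from thermoshuffle.simulate import (
    default_species_tree,
    random_sequence,
    simulate_gene_trees,
)


def tree(s):
    return dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)


class TestTopologyCensus:
    CONS = "((A:1,B:1):1,(C:1,D:1):1,E:1);"
    ALT1 = "((A:1,C:1):1,(B:1,D:1):1,E:1);"
    ALT2 = "((A:1,D:1):1,(B:1,C:1):1,E:1);"

    def test_all_congruent(self):
        trees = [(f"t{i}", tree(self.CONS)) for i in range(5)]
        census = topology_census(trees, tree(self.CONS))
        assert census.n_congruent == 5
        assert census.incongruent_groups == {}

    def test_one_swapped_tree(self):
        trees = [(f"t{i}", tree(self.CONS)) for i in range(9)]
        trees.append(("alt", tree(self.ALT1)))
        census = topology_census(trees, tree(self.CONS))
        assert census.n_congruent == 9
        assert census.group_sizes == [1]

    def test_alternative_groups_recovered(self):
        trees = (
            [(f"c{i}", tree(self.CONS)) for i in range(10)]
            + [(f"a{i}", tree(self.ALT1)) for i in range(3)]
            + [(f"b{i}", tree(self.ALT2)) for i in range(2)]
        )
        census = topology_census(trees, tree(self.CONS))
        assert census.n_congruent == 10
        assert census.group_sizes == [3, 2]

    def test_leaf_mismatch_skipped_with_log(self):
        trees = [
            ("good", tree(self.CONS)),
            ("bad", tree("((A:1,B:1):1,C:1);")),
        ]
        census = topology_census(trees, tree(self.CONS))
        assert census.skipped == ["bad"]
        assert census.n_congruent == 1


class TestMovementScores:
    def test_zero_when_equal(self):
        m = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.1], [0.3, 0.1, 0]]),
        )
        scores = movement_scores(m, m)
        assert all(v == 0 for v in scores.values())

    def test_absolute_deviation_arithmetic(self):
        cons = DistanceMatrix(
            ["J", "K", "L", "M"],
            np.array(
                [
                    [0, 0.20, 0.30, 0.10],
                    [0.20, 0, 0.0, 0.0],
                    [0.30, 0.0, 0, 0.0],
                    [0.10, 0.0, 0.0, 0],
                ]
            ),
        )
        gene = DistanceMatrix(
            ["J", "K", "L", "M"],
            np.array(
                [
                    [0, 0.25, 0.35, 0.15],
                    [0.25, 0, 0.0, 0.0],
                    [0.35, 0.0, 0, 0.0],
                    [0.15, 0.0, 0.0, 0],
                ]
            ),
        )
        scores = movement_scores(gene, cons)
        assert scores["J"] == pytest.approx(0.15)

    def test_squared_form(self):
        a = DistanceMatrix(["A", "B"], np.array([[0, 0.3], [0.3, 0]]))
        b = DistanceMatrix(["A", "B"], np.array([[0, 0.1], [0.1, 0]]))
        assert movement_scores(a, b, form="sq")["A"] == pytest.approx(0.04)

    def test_scale_invariance_through_normalization(self):
        """Scores built from normalized matrices ignore global tree scaling."""
        sp = default_species_tree()
        n1 = patristic_normalized(sp)
        for e in sp.preorder_edge_iter():
            if e.length is not None:
                e.length *= 7.5
        n2 = patristic_normalized(sp)
        assert np.allclose(n1.matrix, n2.reordered(n1.taxa).matrix)


class TestCallTransfer:
    def test_simulated_transfer_called_exactly(self):
        trees, truth = simulate_gene_trees(
            n_congruent=10,
            transfers=[("M_silvanus", "T_scotoductus")],
            noise_sd=0.0,
            shrink=0.2,
            seed=2,
        )
        by_id = dict(trees)
        cons_topo = majority_topology([t for _, t in trees])
        from thermoshuffle.hgt import topology_census as census_fn

        census = census_fn(trees, cons_topo)
        cons = consensus_distances(
            [patristic_normalized(by_id[i]) for i in census.congruent_ids]
        )
        (tid, donor, recipient) = truth.transfer_events[0]
        call = call_transfer(tid, patristic_normalized(by_id[tid]), cons)
        assert call.recipient == recipient
        assert call.donor == donor

    def test_all_distances_increase_unknown_donor(self):
        taxa = ["A", "B", "C"]
        cons = DistanceMatrix(
            taxa,
            np.array([[0, 0.2, 0.2], [0.2, 0, 0.2], [0.2, 0.2, 0]]),
        )
        gene = DistanceMatrix(
            taxa,
            np.array([[0, 0.4, 0.4], [0.4, 0, 0.2], [0.4, 0.2, 0]]),
        )
        call = call_transfer("t", gene, cons)
        assert call.recipient == "A"
        assert call.donor == UNKNOWN

    def test_tied_maxima_flagged_ambiguous(self):
        taxa = ["A", "B", "C"]
        cons = DistanceMatrix(
            taxa, np.array([[0, 0.2, 0.3], [0.2, 0, 0.3], [0.3, 0.3, 0]])
        )
        gene = DistanceMatrix(
            taxa, np.array([[0, 0.1, 0.3], [0.1, 0, 0.3], [0.3, 0.3, 0]])
        )
        call = call_transfer("t", gene, cons)
        assert call.ambiguous
        assert call.tied_recipients == ("A", "B")


class TestDonorRecipientSummary:
    def _call(self, donor, recipient):
        from thermoshuffle.hgt import TransferCall

        return TransferCall(
            tree_id="t", recipient=recipient, donor=donor, scores={},
            deltas_to_recipient={},
        )

    def test_empty(self):
        assert len(donor_recipient_summary([])) == 0

    def test_counts(self):
        calls = [
            self._call("B", "D"),
            self._call("B", "D"),
            self._call(UNKNOWN, "D"),
        ]
        df = donor_recipient_summary(calls)
        assert (
            df.set_index(["donor", "recipient"])["count"].to_dict()
            == {("B", "D"): 2, (UNKNOWN, "D"): 1}
        )

    def test_totals_conserved(self):
        rng = np.random.default_rng(5)
        taxa = ["A", "B", "C", "D"]
        calls = [
            self._call(taxa[rng.integers(4)], taxa[rng.integers(4)])
            for _ in range(20)
        ]
        assert donor_recipient_summary(calls)["count"].sum() == 20


class TestOUStratigraphy:
    def test_identical_sequences_distance_zero(self):
        seq = random_sequence(20_000, gc=0.6, seed=1)
        a = ou_pattern(seq, "a")
        b = ou_pattern(seq, "b")
        assert ou_distance(a, b) == 0.0
        assert a.frequencies.sum() == pytest.approx(1.0)

    def test_gc_shifted_island_distant(self):
        host = ou_pattern(random_sequence(50_000, gc=0.65, seed=2), "host")
        island = ou_pattern(random_sequence(20_000, gc=0.35, seed=3), "isl")
        assert ou_distance(island, host) > 0.1

    def test_k_mismatch_raises(self):
        a = ou_pattern(random_sequence(5000, seed=1), "a", k=3)
        b = ou_pattern(random_sequence(5000, seed=2), "b", k=4)
        with pytest.raises(ValueError):
            ou_distance(a, b)

    def test_amelioration_series_monotone(self):
        """Mixing island composition toward the host shrinks the distance."""
        rng = np.random.default_rng(9)
        host_seq = random_sequence(50_000, gc=0.68, seed=4)
        host = ou_pattern(host_seq, "host")
        n = 15_000
        dists = []
        for frac_host, seed in [(0.0, 10), (0.5, 11), (0.9, 12)]:
            h = random_sequence(n, gc=0.68, seed=seed)
            d = random_sequence(n, gc=0.35, seed=seed + 50)
            take = rng.random(n) < frac_host
            mix = "".join(h[i] if take[i] else d[i] for i in range(n))
            dists.append(ou_distance(ou_pattern(mix, "m"), host))
        assert dists[0] > dists[1] > dists[2]

    def test_ranking_most_recent_first(self):
        host = ou_pattern(random_sequence(30_000, gc=0.65, seed=5), "host")
        recent = ou_pattern(random_sequence(10_000, gc=0.3, seed=6), "recent")
        old = ou_pattern(random_sequence(10_000, gc=0.64, seed=7), "old")
        ranked = rank_relative_age([old, recent], host)
        assert [r[0] for r in ranked] == ["recent", "old"]

    def test_n_windows_skipped(self):
        pat = ou_pattern("ACGT" * 100 + "N" * 50 + "ACGT" * 100, "x", k=2)
        assert pat.frequencies.sum() == pytest.approx(1.0)
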