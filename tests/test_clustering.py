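import numpy as np
import pandas as pd
import pytest

from baitnet import clustering
from baitnet.clustering import BaitPreyMatrix
from baitnet.types import BIOID, PreyCluster, ValidationError
from conftest import make_table


def matrix_from_rows(baits, preys, rows):
    return BaitPreyMatrix(baits=list(baits), preys=list(preys),
                          values=np.array(rows, dtype=float))


class TestBuildMatrix:
    def test_two_baits_sharing_one_of_three_preys(self):
        table = pd.DataFrame(
            [("B1", "P1", BIOID, 4.0, 0.9), ("B1", "P2", BIOID, 2.0, 0.9),
             ("B2", "P2", BIOID, 5.0, 0.9), ("B2", "P3", BIOID, 1.0, 0.9)],
            columns=["bait", "prey", "method", "avg_spec", "score"])
        m = clustering.build_bait_prey_matrix(table)
        assert m.values.shape == (2, 3)
        assert (m.values > 0).sum() == 4

    def test_empty_table_gives_empty_matrix(self):
        m = clustering.build_bait_prey_matrix(make_table([]))
        assert m.values.shape == (0, 0)

    def test_row_sums_conserve_per_bait_totals(self):
        table = make_table([("B1", "P1"), ("B1", "P2"), ("B2", "P1")],
                           avg_spec=3.0)
        m = clustering.build_bait_prey_matrix(table)
        frame = m.to_frame()
        assert frame.loc["B1"].sum() == pytest.approx(6.0)
        assert frame.loc["B2"].sum() == pytest.approx(3.0)


class TestHierarchical:
    def test_identical_rows_merge_first_at_zero_distance(self):
        m = matrix_from_rows(["B1", "B2", "B3"], ["P1", "P2"],
                             [[5, 1], [5, 1], [0, 9]])
        tree = clustering.hierarchical_cluster(m, axis="bait")
        first = tree.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0)

    def test_collinear_points_merge_nearest_pair_first(self):
        # 1-d profiles at 0, 1 and 10: (0, 1) must merge first
        m = matrix_from_rows(["B1", "B2", "B3"], ["P1"], [[0], [1], [10]])
        tree = clustering.hierarchical_cluster(m, axis="bait",
                                               metric="euclidean")
        assert {int(tree.linkage[0][0]), int(tree.linkage[0][1])} == {0, 1}

    def test_permutation_invariant_topology(self):
        rng = np.random.default_rng(5)
        values = rng.poisson(6, size=(6, 10)).astype(float)
        baits = [f"B{i}" for i in range(6)]
        m1 = matrix_from_rows(baits, [f"P{j}" for j in range(10)], values)
        perm = rng.permutation(6)
        m2 = matrix_from_rows([baits[i] for i in perm],
                              [f"P{j}" for j in range(10)], values[perm])
        t1 = clustering.hierarchical_cluster(m1, axis="bait")
        t2 = clustering.hierarchical_cluster(m2, axis="bait")
        parts1 = {frozenset(c.members) for c in
                  clustering.extract_clusters(t1, k=3)}
        parts2 = {frozenset(c.members) for c in
                  clustering.extract_clusters(t2, k=3)}
        assert parts1 == parts2

    def test_single_item_axis_rejected(self):
        m = matrix_from_rows(["B1"], ["P1", "P2"], [[1, 2]])
        with pytest.raises(ValidationError):
            clustering.hierarchical_cluster(m, axis="bait")


class TestPreyCorrelation:
    def test_identical_profiles_correlate_perfectly(self):
        m = matrix_from_rows(["B1", "B2", "B3"], ["P1", "P2"],
                             [[4, 4], [1, 1], [7, 7]])
        corr, excluded = clustering.prey_correlation_matrix(m)
        assert corr.loc["P1", "P2"] == pytest.approx(1.0)
        assert excluded == []

    def test_closed_form_anticorrelation(self):
        # profiles (1,0,0) and (0,1,0) across three baits: r = -1/2
        m = matrix_from_rows(["B1", "B2", "B3"], ["P1", "P2"],
                             [[1, 0], [0, 1], [0, 0]])
        corr, _ = clustering.prey_correlation_matrix(m)
        assert corr.loc["P1", "P2"] == pytest.approx(-0.5)

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(3)
        m = matrix_from_rows([f"B{i}" for i in range(5)],
                             [f"P{j}" for j in range(8)],
                             rng.poisson(5, size=(5, 8)).astype(float))
        corr, _ = clustering.prey_correlation_matrix(m)
        assert np.allclose(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values), 1.0)
        assert ((corr.values >= -1 - 1e-12) & (corr.values <= 1 + 1e-12)).all()

    def test_constant_profile_flagged_and_excluded(self):
        m = matrix_from_rows(["B1", "B2"], ["P1", "P2"], [[3, 1], [3, 5]])
        corr, excluded = clustering.prey_correlation_matrix(m)
        assert excluded == ["P1"]
        assert list(corr.index) == ["P2"]


class TestExtractClusters:
    def tree(self):
        m = matrix_from_rows(["B1", "B2"], ["P1", "P2", "P3", "P4"],
                             [[9, 8, 0, 1], [1, 0, 9, 8]])
        return clustering.hierarchical_cluster(m, axis="prey")

    def test_k_equal_items_gives_singletons(self):
        clusters = clustering.extract_clusters(self.tree(), k=4)
        assert sorted(len(c.members) for c in clusters) == [1, 1, 1, 1]

    def test_k_one_gives_everything(self):
        (cluster,) = clustering.extract_clusters(self.tree(), k=1)
        assert sorted(cluster.members) == ["P1", "P2", "P3", "P4"]
        assert cluster.cluster_id == "A"

    def test_two_planted_blocks_recovered(self):
        clusters = clustering.extract_clusters(self.tree(), k=2)
        parts = {frozenset(c.members) for c in clusters}
        assert parts == {frozenset({"P1", "P2"}), frozenset({"P3", "P4"})}

    def test_letters_follow_leaf_order(self):
        clusters = clustering.extract_clusters(self.tree(), k=2)
        assert [c.cluster_id for c in clusters] == ["A", "B"]

    def test_exactly_one_of_k_or_height(self):
        with pytest.raises(ValidationError):
            clustering.extract_clusters(self.tree())
        with pytest.raises(ValidationError):
            clustering.extract_clusters(self.tree(), k=2, height=1.0)

    def test_label_generator_rolls_over_alphabet(self):
        assert clustering._letters(0) == "A"
        assert clustering._letters(25) == "Z"
        assert clustering._letters(26) == "AA"


class TestDrivingBaits:
    def test_counts_and_ranking(self):
        cluster = PreyCluster("A", ["P1", "P2", "P3"])
        table = make_table([("B1", "P1"), ("B1", "P2"), ("B2", "P3"),
                            ("B2", "X")])
        assert clustering.driving_baits(cluster, table) == [("B1", 2), ("B2", 1)]

    def test_ties_broken_alphabetically(self):
        cluster = PreyCluster("A", ["P1", "P2"])
        table = make_table([("B2", "P1"), ("B1", "P2")])
        assert clustering.driving_baits(cluster, table) == [("B1", 1), ("B2", 1)]

    def test_zero_count_baits_omitted_unless_flagged(self):
        cluster = PreyCluster("A", ["P1"])
        table = make_table([("B1", "P1"), ("B2", "X")])
        assert clustering.driving_baits(cluster, table) == [("B1", 1)]
        with_zero = clustering.driving_baits(cluster, table, include_zero=True)
        assert with_zero == [("B1", 1), ("B2", 0)]
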