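import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methyloscan.mtase_repertoire import (
    DistanceMatrix,
    PresenceAbsenceMatrix,
    build_presence_absence,
    cluster_species,
    jaccard_distance,
    nj_tree,
    persistent_mtases,
    profile_distance_matrix,
    upgma,
)

from ._oracles import random_additive_tree


class TestPresenceAbsence:
    HITS = [
        ("dam", "gA", 99.0), ("dam", "gB", 95.0), ("dam", "gC", 88.0),
        ("mtx", "gA", 99.0), ("mtx", "gB", 70.0),
        ("mty", "gC", 70.1),
    ]

    def test_strict_threshold(self):
        matrix = build_presence_absence(self.HITS)
        frame = matrix.to_frame()
        assert not frame.loc["mtx", "gB"]   # 70.0 is absent (strict >)
        assert frame.loc["mty", "gC"]       # 70.1 is present

    def test_source_genome_always_present(self):
        matrix = build_presence_absence(
            [("dam", "gB", 50.0)], source_genomes={"dam": "gA"}
        )
        frame = matrix.to_frame()
        assert frame.loc["dam", "gA"]
        assert not frame.loc["dam", "gB"]

    def test_no_hits_row_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            matrix = build_presence_absence(
                self.HITS + [("ghost", "gA", 10.0)]
            )
        assert "ghost" not in matrix.mtase_ids
        assert "ghost" in caplog.text

    def test_identity_out_of_range(self):
        with pytest.raises(ValueError):
            build_presence_absence([("dam", "gA", 120.0)])

    def test_ortholog_group_merge(self):
        hits = [("m1", "gA", 99.0), ("m2", "gB", 99.0)]
        matrix = build_presence_absence(
            hits, ortholog_groups={"m1": "m1", "m2": "m1"}
        )
        assert matrix.mtase_ids == ["m1"]
        assert matrix.to_frame().loc["m1"].all()


class TestPersistent:
    def test_single_persistent_row(self):
        matrix = build_presence_absence(self.hits_with_one_persistent())
        assert persistent_mtases(matrix) == ["dam"]

    @staticmethod
    def hits_with_one_persistent():
        hits = [("dam", g, 95.0) for g in ("gA", "gB", "gC")]
        hits += [("mtx", "gA", 95.0), ("mty", "gB", 95.0)]
        return hits

    def test_identity_matrix_no_persistent(self):
        matrix = PresenceAbsenceMatrix(
            ["m1", "m2"], ["gA", "gB"], np.eye(2, dtype=bool)
        )
        assert persistent_mtases(matrix) == []

    def test_single_genome_all_persistent(self):
        matrix = PresenceAbsenceMatrix(
            ["m1", "m2"], ["gA"], np.ones((2, 1), dtype=bool)
        )
        assert persistent_mtases(matrix) == ["m1", "m2"]

    def test_oracle_identity(self):
        """persistent == intersection of per-genome presence sets."""
        rng = np.random.default_rng(5)
        cells = rng.random((12, 6)) < 0.6
        cells[:, 0] |= ~cells.any(axis=1)  # no all-absent rows
        matrix = PresenceAbsenceMatrix(
            [f"m{i}" for i in range(12)], [f"g{j}" for j in range(6)], cells
        )
        per_genome = [
            {m for m, row in zip(matrix.mtase_ids, cells) if row[j]}
            for j in range(6)
        ]
        assert set(persistent_mtases(matrix)) == set.intersection(*per_genome)


class TestJaccard:
    def test_direct_count(self):
        assert jaccard_distance([1, 1, 0], [1, 0, 1]) == pytest.approx(2 / 3)

    def test_identical(self):
        assert jaccard_distance([1, 0, 1], [1, 0, 1]) == 0.0

    def test_disjoint(self):
        assert jaccard_distance([1, 0], [0, 1]) == 1.0

    def test_both_empty_convention(self):
        assert jaccard_distance([0, 0], [0, 0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            jaccard_distance([1], [1, 0])

    def test_metric_on_length6_vectors(self):
        """Triangle inequality, exhaustively, over non-empty profiles."""
        vectors = [v for v in itertools.product([0, 1], repeat=6) if any(v)]
        d = {
            (a, b): jaccard_distance(a, b)
            for a in vectors for b in vectors
        }
        for a in vectors:
            for b in vectors:
                assert d[a, b] == pytest.approx(d[b, a])
                for c in vectors:
                    assert d[a, c] <= d[a, b] + d[b, c] + 1e-12


class TestUpgma:
    def test_two_ids_closed_form(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        tree = upgma(d)
        assert tree.leaf_depths() == {"A": 0.2, "B": 0.2}

    def test_three_ids_hand_computed(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]]),
        )
        tree = upgma(d)
        depths = tree.leaf_depths()
        assert depths == pytest.approx({"A": 0.3, "B": 0.3, "C": 0.3})
        # (A,B) joined first at height 0.1
        inner = [child for child, _bl in tree.children if not child.is_leaf][0]
        assert sorted(inner.leaf_names()) == ["A", "B"]

    def test_duplicate_profiles_join_at_zero(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.0, 0.5], [0.0, 0, 0.5], [0.5, 0.5, 0]]),
        )
        tree = upgma(d)
        inner = [child for child, _bl in tree.children if not child.is_leaf][0]
        assert sorted(inner.leaf_names()) == ["A", "B"]

    def test_single_id_rejected(self):
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(["A"], np.zeros((1, 1))))

    @given(st.integers(2, 10), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_ultrametric_on_random_matrices(self, n, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((n, n))
        d = np.triu(m, 1)
        d = d + d.T
        tree = upgma(DistanceMatrix([f"x{i}" for i in range(n)], d))
        depths = list(tree.leaf_depths().values())
        assert len(depths) == n
        assert max(depths) - min(depths) < 1e-9

    def test_jaccard_pipeline(self):
        matrix = build_presence_absence(TestPersistent.hits_with_one_persistent())
        tree = upgma(profile_distance_matrix(matrix, axis="mtase"))
        assert sorted(tree.leaf_names()) == ["dam", "mtx", "mty"]


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = nj_tree(d)
        lengths = {child.name: bl for child, bl in tree.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_fewer_than_three_rejected(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError, match="upgma"):
            nj_tree(d)

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 8])
    def test_additive_matrices_reconstructed_exactly(self, n_leaves):
        for seed in range(5):
            d = random_additive_tree(n_leaves, random.Random(seed))
            tree = nj_tree(d)
            paths = tree.path_lengths()
            for i, a in enumerate(d.ids):
                for j in range(i + 1, len(d.ids)):
                    b = d.ids[j]
                    assert paths[(a, b) if a < b else (b, a)] == pytest.approx(
                        d.d[i, j], abs=1e-9
                    )

    def test_ultrametric_input_matches_upgma_topology(self):
        # build an ultrametric matrix from a known UPGMA shape
        d = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array([
                [0.0, 0.2, 0.8, 0.8],
                [0.2, 0.0, 0.8, 0.8],
                [0.8, 0.8, 0.0, 0.4],
                [0.8, 0.8, 0.4, 0.0],
            ]),
        )
        # unrooted NJ: the AB|CD split shows up as one of the two clades
        nj_clades = _leaf_bipartitions(nj_tree(d))
        assert {"A", "B"} in nj_clades or {"C", "D"} in nj_clades
        up_clades = _leaf_bipartitions(upgma(d))
        assert {"A", "B"} in up_clades and {"C", "D"} in up_clades

    def test_negative_lengths_clamped(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            m = rng.random((5, 5))
            d = np.triu(m, 1)
            d = d + d.T
            tree = nj_tree(DistanceMatrix([f"x{i}" for i in range(5)], d))

            def walk(node):
                for child, bl in node.children:
                    assert bl >= 0.0
                    walk(child)

            walk(tree)


def _leaf_bipartitions(tree):
    clades = []

    def walk(node):
        names = set(node.leaf_names())
        if 1 < len(names):
            clades.append(names)
        for child, _bl in node.children:
            walk(child)

    walk(tree)
    return clades


class TestClusterSpecies:
    def test_single_linkage_closure(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.05, 0.09], [0.05, 0, 0.05], [0.09, 0.05, 0]]),
        )
        assert cluster_species(d) == [{"A", "B", "C"}]

    def test_all_far_apart(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]),
        )
        assert cluster_species(d) == [{"A"}, {"B"}, {"C"}]

    def test_threshold_inclusive(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 0.06], [0.06, 0]]))
        assert cluster_species(d) == [{"A", "B"}]
        d2 = DistanceMatrix(["A", "B"], np.array([[0, 0.061], [0.061, 0]]))
        assert cluster_species(d2) == [{"A"}, {"B"}]


class TestDistanceMatrix:
    def test_csv_round_trip(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(",A,B\nA,0,0.3\nB,0.3,0\n")
        d = DistanceMatrix.from_csv(p)
        assert d.ids == ["A", "B"]
        assert d.get("A", "B") == 0.3

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]], float))

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, np.nan], [np.nan, 0]]))
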