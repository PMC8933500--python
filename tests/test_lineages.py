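"""Hamming distances, PCoA, lineage clustering, neighbor joining, trajectories."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa
from skbio.tree import nj as skbio_nj

from replinet import genotyping as gt
from replinet import lineages as ln


class TestHamming:
    def test_counts_differing_positions(self):
        mat = pd.DataFrame(
            [[1, 0, 1, 1, 0], [1, 0, 0, 1, 1]], index=["a", "b"]
        )
        dm = ln.hamming_matrix(mat)
        assert dm["a", "b"] == 2

    def test_symmetric_zero_diagonal(self, rng):
        mat = rng.integers(0, 2, size=(6, 12))
        dm = ln.hamming_matrix(mat)
        np.testing.assert_array_equal(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0)

    def test_identical_vectors_distance_zero(self):
        dm = ln.hamming_matrix(np.array([[1, 1, 0], [1, 1, 0]]))
        assert dm.data[0, 1] == 0


class TestPCoA:
    def test_two_points_embed_at_half_distance(self):
        dm = DistanceMatrix(np.array([[0.0, 6.0], [6.0, 0.0]]), ids=["a", "b"])
        result = ln.pcoa_embed(dm, dims=2)
        coords = result.coordinates["axis1"].to_numpy()
        assert sorted(coords) == pytest.approx([-3.0, 3.0])
        assert result.coordinates["axis2"].to_numpy() == pytest.approx([0.0, 0.0])

    def test_right_triangle_distances_preserved(self):
        # 3-4-5 triangle is planar: 2-D embedding must be exact
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        dm = DistanceMatrix(d, ids=list("abc"))
        coords = ln.pcoa_embed(dm, dims=2).coordinates.to_numpy()
        for i in range(3):
            for j in range(3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
                    d[i, j], abs=1e-9
                )

    def test_identical_points_embed_at_origin(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        result = ln.pcoa_embed(dm, dims=2)
        assert np.allclose(result.coordinates.to_numpy(), 0.0)

    def test_sqrt_hamming_has_nonnegative_spectrum(self, rng):
        # Hamming distance between binary vectors equals squared Euclidean
        # distance, so sqrt(Hamming) is exactly Euclidean-embeddable and its
        # classical-scaling spectrum is non-negative; raw Hamming input may
        # carry negative eigenvalues, which must be reported, not dropped.
        mat = rng.integers(0, 2, size=(8, 20))
        dm = ln.hamming_matrix(mat)
        sqrt_dm = DistanceMatrix(np.sqrt(dm.data), ids=dm.ids)
        result = ln.pcoa_embed(sqrt_dm, dims=2)
        assert result.eigenvalues.min() > -1e-9 * max(1.0, result.eigenvalues.max())
        assert result.negative_eigenvalues.size == 0

    def test_negative_eigenvalues_reported_for_raw_hamming(self, rng):
        mat = rng.integers(0, 2, size=(8, 20))
        result = ln.pcoa_embed(ln.hamming_matrix(mat), dims=2)
        negatives = result.eigenvalues[result.eigenvalues < -1e-9]
        np.testing.assert_array_equal(result.negative_eigenvalues, negatives)

    def test_agrees_with_skbio_up_to_sign(self, rng):
        mat = rng.integers(0, 2, size=(7, 15))
        dm = ln.hamming_matrix(mat)
        ours = ln.pcoa_embed(dm, dims=2).coordinates.to_numpy()
        theirs = skbio_pcoa(dm, number_of_dimensions=2).samples.to_numpy()
        for axis in range(2):
            assert np.allclose(np.abs(ours[:, axis]), np.abs(theirs[:, axis]), atol=1e-8)

    def test_orientation_deterministic(self, rng):
        mat = rng.integers(0, 2, size=(6, 10))
        dm = ln.hamming_matrix(mat)
        a = ln.pcoa_embed(dm).coordinates
        b = ln.pcoa_embed(dm).coordinates
        pd.testing.assert_frame_equal(a, b)
        for axis in a.columns:  # largest-magnitude loading positive
            col = a[axis].to_numpy()
            if np.abs(col).max() > 0:
                assert col[np.argmax(np.abs(col))] > 0


class TestClusterLineages:
    def test_single_genotype_single_lineage(self):
        dm = DistanceMatrix(np.zeros((1, 1)), ids=["g"])
        assignment = ln.cluster_lineages(dm, cutoff=1)
        assert assignment.mapping == {"g": "L1"}

    def test_two_separated_clusters(self):
        d = np.array(
            [
                [0, 2, 20, 21],
                [2, 0, 22, 20],
                [20, 22, 0, 1],
                [21, 20, 1, 0],
            ],
            dtype=float,
        )
        assignment = ln.cluster_lineages(DistanceMatrix(d, ids=list("abcd")), cutoff=5)
        assert len(assignment.labels) == 2
        assert assignment.mapping["a"] == assignment.mapping["b"]
        assert assignment.mapping["c"] == assignment.mapping["d"]
        assert assignment.mapping["a"] != assignment.mapping["c"]

    def test_chain_links_transitively(self):
        d = np.array([[0, 3, 6], [3, 0, 3], [6, 3, 0]], dtype=float)
        assignment = ln.cluster_lineages(DistanceMatrix(d, ids=list("abc")), cutoff=3)
        assert len(assignment.labels) == 1

    def test_labels_ordered_by_first_round(self):
        d = np.array([[0, 20], [20, 0]], dtype=float)
        dm = DistanceMatrix(d, ids=["late", "early"])
        assignment = ln.cluster_lineages(
            dm, cutoff=5, first_rounds={"late": 9, "early": 2}, prefix="HL"
        )
        assert assignment.mapping["early"] == "HL1"
        assert assignment.mapping["late"] == "HL2"

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            ln.cluster_lineages(DistanceMatrix(np.zeros((1, 1)), ids=["g"]), cutoff=-1)


def _tree_distances(newick_tree, ids):
    return {
        (a, b): newick_tree.find(a).distance(newick_tree.find(b))
        for a in ids
        for b in ids
        if a != b
    }


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        result = ln.nj_tree(DistanceMatrix(d, ids=list("abc")))
        # l_a = (d_ab + d_ac - d_bc)/2 = 2, l_b = 3, l_c = 7
        dist = {t.name: t.length for t in result.tree.tips()}
        assert dist == pytest.approx({"a": 2.0, "b": 3.0, "c": 7.0})
        assert result.clamped == 0.0

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) gives these path lengths
        ids = list("ABCD")
        d = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 0 + 9, 0],
            ],
            dtype=float,
        )
        d[3, 2] = 9
        d[2, 3] = 9
        result = ln.nj_tree(DistanceMatrix(d, ids=ids))
        paths = _tree_distances(result.tree, ids)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if a != b:
                    assert paths[(a, b)] == pytest.approx(d[i, j], abs=1e-9)
        assert result.clamped == 0.0

    def test_five_taxon_ultrametric_topology(self):
        # ultrametric tree: ((A,B),C) vs (D,E), heights 1/2/3
        ids = list("ABCDE")
        d = np.array(
            [
                [0, 2, 4, 6, 6],
                [2, 0, 4, 6, 6],
                [4, 4, 0, 6, 6],
                [6, 6, 6, 0, 2],
                [6, 6, 6, 2, 0],
            ],
            dtype=float,
        )
        result = ln.nj_tree(DistanceMatrix(d, ids=ids))
        tree = result.tree
        assert tree.find("A").parent is tree.find("B").parent
        assert tree.find("D").parent is tree.find("E").parent

    def test_matches_skbio_nj_path_lengths(self, rng):
        # random additive-ish matrix: compare against the reference NJ
        n = 6
        coords = rng.random((n, 4)) * 10
        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d, ids=[f"t{i}" for i in range(n)])
        ours = ln.nj_tree(dm).tree
        theirs = skbio_nj(dm)
        ours_d = _tree_distances(ours, list(dm.ids))
        theirs_d = {
            (a, b): theirs.find(a).distance(theirs.find(b))
            for a in dm.ids
            for b in dm.ids
            if a != b
        }
        for key in ours_d:
            assert ours_d[key] == pytest.approx(theirs_d[key], abs=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            ln.nj_tree(DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"]))

    def test_negative_branch_clamped_and_logged(self):
        # strongly non-additive matrix forces a negative NJ estimate
        d = np.array(
            [
                [0, 1, 10, 10],
                [1, 0, 1, 10],
                [10, 1, 0, 1],
                [10, 10, 1, 0],
            ],
            dtype=float,
        )
        result = ln.nj_tree(DistanceMatrix(d, ids=list("abcd")))
        for node in result.tree.traverse():
            if node.length is not None:
                assert node.length >= 0
        assert result.clamped > 0


class TestLineageFrequencies:
    def _table(self):
        m1 = gt.MutationCall(position=10, kind="substitution", ref="A", alt="G")
        m2 = gt.MutationCall(position=20, kind="substitution", ref="A", alt="G")
        panel = gt.MutationPanel(mutations=(m1, m2))
        reads = {1: [frozenset({m1})] * 6 + [frozenset({m2})] * 4}
        return gt.build_consensus_genotypes(reads, panel)

    def test_two_lineages_renormalized(self):
        table = self._table()
        assignment = ln.LineageAssignment(
            mapping={table.ids[0]: "L1", table.ids[1]: "L2"}, labels=("L1", "L2")
        )
        freq, presence = ln.lineage_frequencies(table, assignment)
        assert freq.loc["L1", 1] == pytest.approx(0.6)
        assert freq.loc["L2", 1] == pytest.approx(0.4)
        assert freq[1].sum() == pytest.approx(1.0, abs=1e-12)
        assert presence.loc["L1", 1] and presence.loc["L2", 1]

    def test_single_lineage_frequency_one(self):
        table = self._table()
        assignment = ln.LineageAssignment(
            mapping={gid: "L1" for gid in table.ids}, labels=("L1",)
        )
        freq, _ = ln.lineage_frequencies(table, assignment)
        assert freq.loc["L1", 1] == pytest.approx(1.0)

    def test_presence_flag_at_point_one_percent(self):
        m1 = gt.MutationCall(position=10, kind="substitution", ref="A", alt="G")
        panel = gt.MutationPanel(mutations=(m1,))
        # 0.0009 vs 0.0011 around the 0.1% rule
        reads = {1: [frozenset({m1})] * 9 + [frozenset()] * 9991}
        table = gt.build_consensus_genotypes(reads, panel)
        assignment = ln.LineageAssignment(
            mapping={table.ids[0]: "L1", table.ids[1]: "L2"}, labels=("L1", "L2")
        )
        _, presence = ln.lineage_frequencies(table, assignment)
        rare = "L1" if table.genotypes[0].bitstring == "1" else "L2"
        assert not presence.loc[rare, 1]  # 0.0009 <= 0.001

        reads = {1: [frozenset({m1})] * 11 + [frozenset()] * 9989}
        table = gt.build_consensus_genotypes(reads, panel)
        assignment = ln.LineageAssignment(
            mapping={table.ids[0]: "L1", table.ids[1]: "L2"}, labels=("L1", "L2")
        )
        _, presence = ln.lineage_frequencies(table, assignment)
        rare = "L1" if table.genotypes[0].bitstring == "1" else "L2"
        assert presence.loc[rare, 1]  # 0.0011 > 0.001

    def test_unassigned_genotype_rejected(self):
        table = self._table()
        assignment = ln.LineageAssignment(
            mapping={table.ids[0]: "L1"}, labels=("L1",)
        )
        with pytest.raises(ValueError):
            ln.lineage_frequencies(table, assignment)
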