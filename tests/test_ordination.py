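"""Simple-matching distances, PCoA round trips, NJ tree reconstruction."""

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa

from ssrpop.ordination import (
    neighbor_joining,
    pcoa,
    simple_matching_dissimilarity,
    tree_distance_matrix,
)
from tests.conftest import make_table


class TestSimpleMatching:
    def test_identical_profiles_have_zero_distance(self):
        row = [(100, 102), (110, 110)]
        dm = simple_matching_dissimilarity(make_table([row, list(row)]))
        assert dm.data[0, 1] == 0.0

    def test_fully_disjoint_profiles_have_distance_one(self):
        t = make_table([[(100, 102), (110, 112)], [(104, 106), (114, 116)]])
        assert simple_matching_dissimilarity(t).data[0, 1] == 1.0

    def test_half_sharing_gives_half(self):
        # share exactly 1 of 2 copies at each of 2 loci -> d = 0.5
        t = make_table([[(100, 102), (110, 112)], [(100, 104), (112, 116)]])
        assert simple_matching_dissimilarity(t).data[0, 1] == pytest.approx(0.5)

    def test_missing_loci_skipped_in_denominator(self):
        t = make_table([[(100, 102), (110, 112)], [(100, 102), ()]])
        assert simple_matching_dissimilarity(t).data[0, 1] == 0.0

    def test_incomparable_pair_is_an_error(self):
        t = make_table([[(100, 102), ()], [(), (110, 112)]])
        with pytest.raises(ValueError, match="no comparable locus"):
            simple_matching_dissimilarity(t)

    def test_pseudometric_properties(self, collection):
        _, table, _ = collection
        dm = simple_matching_dissimilarity(
            table.subset(table.accession_ids[:40]))
        m = dm.data
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0)
        assert (m >= 0).all() and (m <= 1).all()


class TestPcoa:
    def test_collinear_points_recovered_on_one_axis(self):
        dm = DistanceMatrix([[0, 1, 2], [1, 0, 1], [2, 1, 0]],
                            ids=["a", "b", "c"])
        res = pcoa(dm)
        assert res.proportion_explained[0] == pytest.approx(1.0)
        x = res.coordinates["PCo1"].to_numpy()
        assert abs(x[0] - x[2]) == pytest.approx(2.0)
        assert abs(x[0] - x[1]) == pytest.approx(1.0)

    def test_euclidean_configuration_round_trips(self, rng):
        pts = rng.normal(size=(12, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(12)]))
        assert (res.eigenvalues >= -1e-9).all()
        coords = res.coordinates.to_numpy()
        d_hat = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(d_hat, d, atol=1e-8)

    def test_duplicate_rows_are_coincident(self):
        dm = DistanceMatrix([[0, 0, 1], [0, 0, 1], [1, 1, 0]],
                            ids=["a", "b", "c"])
        coords = pcoa(dm).coordinates
        np.testing.assert_allclose(coords.loc["a"], coords.loc["b"],
                                   atol=1e-9)

    def test_agrees_with_skbio_reference(self, rng):
        pts = rng.normal(size=(10, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(10)])
        ours = pcoa(dm)
        ref = skbio_pcoa(dm)
        n_pos = len(ours.proportion_explained)
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues[:n_pos]),
            np.sort(ref.eigvals.to_numpy()[:n_pos]), atol=1e-8)

    def test_na_entries_are_an_error(self):
        class Fake:   # stand-in carrying a NaN past skbio's validation
            data = np.array([[0.0, np.nan], [np.nan, 0.0]])
            ids = ("a", "b")

        with pytest.raises(ValueError, match="NA"):
            pcoa(Fake())

    def test_groups_separate_on_first_axes(self, collection):
        _, table, truth = collection
        ids = [a for a in truth.group_labels.index
               if a in set(table.accession_ids)][:90]
        res = pcoa(simple_matching_dissimilarity(table.subset(ids)))
        coords = res.coordinates.iloc[:, :2].to_numpy()
        labels = truth.group_labels[ids].to_numpy()
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(len(ids), 1)
        assert d[iu][same[iu]].mean() < d[iu][~same[iu]].mean()


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix([[0, 0.4], [0.4, 0]], ids=["A", "B"])
        tree = neighbor_joining(dm)
        assert tree_distance_matrix(tree.tree, ["A", "B"])[0, 1] \
            == pytest.approx(0.4)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)); path lengths give the input matrix
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        dm = DistanceMatrix(d, ids=list("ABCD"))
        tree = neighbor_joining(dm)
        np.testing.assert_allclose(
            tree_distance_matrix(tree.tree, list("ABCD")), d, atol=1e-9)
        # topology: A+B form a cherry
        tips = {t.name for t in
                tree.tree.find("A").parent.children if t.is_tip()}
        assert tips == {"A", "B"}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_additive_matrices_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        dist = _random_additive_matrix(rng, n)
        ids = [f"T{i}" for i in range(n)]
        tree = neighbor_joining(DistanceMatrix(dist, ids=ids))
        np.testing.assert_allclose(tree_distance_matrix(tree.tree, ids),
                                   dist, atol=1e-9)

    def test_newick_branch_lengths_clamped_but_raw_kept(self):
        # non-additive noisy matrix can give negative NJ branches
        rng = np.random.default_rng(7)
        d = rng.random((6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = neighbor_joining(DistanceMatrix(d, ids=list("ABCDEF")))
        assert "-" not in tree.newick.replace("e-", "")
        for node in tree.tree.traverse():
            if node.length is not None:
                assert node.length >= 0


def _random_additive_matrix(rng, n):
    """Path-length matrix of a random binary tree with random edge lengths.

    Built bottom-up by repeatedly joining two active nodes; leaf-to-leaf
    distances accumulate edge lengths, independent of any NJ code.
    """
    dist = {i: {} for i in range(n)}
    members = {i: [i] for i in range(n)}
    depth = {i: {i: 0.0} for i in range(n)}   # node -> leaf -> distance
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        i, j = rng.choice(len(active), 2, replace=False)
        a, b = active[min(i, j)], active[max(i, j)]
        la, lb = rng.uniform(0.1, 2.0, 2)
        for u in members[a]:
            for v in members[b]:
                d = depth[a][u] + la + depth[b][v] + lb
                dist[u][v] = dist[v][u] = d
        new = next_id
        next_id += 1
        members[new] = members[a] + members[b]
        depth[new] = {u: depth[a][u] + la for u in members[a]}
        depth[new].update({v: depth[b][v] + lb for v in members[b]})
        active = [x for x in active if x not in (a, b)] + [new]
    out = np.zeros((n, n))
    for u in range(n):
        for v in range(n):
            if u != v:
                out[u, v] = dist[u][v]
    return out
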