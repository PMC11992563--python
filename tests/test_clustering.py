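import numpy as np
import pytest

from stormclust import (
    ClusterParams,
    FieldGeometry,
    LocalizationTable,
    cluster_hull_area,
    coarse_cluster,
    dbscan_core,
    developed_dbscan,
    hierarchical_split,
    refine_subcluster_count,
    select_oversized,
)
from stormclust.clustering import _renumber
from stormclust.errors import ParameterError, ValidationError

from oracles import check_dbscan_labels


def make_table(points, geometry=None):
    points = np.asarray(points, dtype=float)
    if geometry is None:
        geometry = FieldGeometry.from_bounding_box(points)
    return LocalizationTable.from_arrays(points[:, 0], points[:, 1], geometry=geometry)


class TestDbscanCore:
    def test_chain_joins_into_one_cluster(self):
        labels = dbscan_core(np.array([[0, 0], [5, 0], [10, 0]]), eps=10, minpts=3)
        assert labels.tolist() == [0, 0, 0]

    def test_isolated_point_is_noise(self):
        assert dbscan_core(np.array([[0.0, 0.0]]), eps=10, minpts=2).tolist() == [-1]

    def test_two_blobs_recovered(self, rng):
        a = rng.normal([0, 0], 5, (10, 2))
        b = rng.normal([500, 0], 5, (10, 2))
        pts = np.vstack([a, b])
        labels = dbscan_core(pts, eps=30, minpts=3)
        assert labels.max() == 1
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]
        check_dbscan_labels(pts, 30, 3, labels)

    def test_empty_input(self):
        assert dbscan_core(np.empty((0, 2)), eps=10, minpts=2).tolist() == []

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_brute_force_closure(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        kind = seed % 3
        if kind == 0:
            pts = rng.uniform(0, 500, (n, 2))
        elif kind == 1:
            centers = rng.uniform(0, 500, (max(n // 10, 1), 2))
            pts = centers[rng.integers(0, len(centers), n)] + rng.normal(0, 8, (n, 2))
        else:
            pts = rng.normal(250, 30, (n, 2))
        eps = float(rng.uniform(5, 60))
        minpts = int(rng.integers(2, 6))
        check_dbscan_labels(pts, eps, minpts, dbscan_core(pts, eps, minpts))

    def test_agrees_with_sklearn_on_a_dense_field(self):
        sklearn = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 2000, (2000, 2))
        mine = dbscan_core(pts, 30, 3)
        theirs = sklearn.DBSCAN(eps=30, min_samples=3).fit(pts).labels_

        def partition(l):
            return {frozenset(np.flatnonzero(l == k)) for k in np.unique(l[l != -1])}

        assert np.array_equal(mine == -1, theirs == -1)
        assert partition(mine) == partition(theirs)

    def test_labels_renumbered_by_first_occurrence(self):
        pts = np.array([[1000.0, 0], [1000.0, 5], [1000.0, 10], [0.0, 0], [0.0, 5], [0.0, 10]])
        labels = dbscan_core(pts, eps=10, minpts=3)
        assert labels.tolist() == [0, 0, 0, 1, 1, 1]

    def test_permutation_stability(self, rng):
        pts = rng.uniform(0, 800, (150, 2))
        labels = dbscan_core(pts, 40, 3)
        perm = rng.permutation(len(pts))
        labels_p = dbscan_core(pts[perm], 40, 3)

        def partition(l, idx):
            return {frozenset(idx[l == k]) for k in np.unique(l[l != -1])}

        assert partition(labels, np.arange(len(pts))) == partition(labels_p, perm)


class TestHullAndSelection:
    def test_right_triangle_area(self):
        assert cluster_hull_area(np.array([[0, 0], [100, 0], [0, 100]])) == pytest.approx(5000)

    def test_degenerate_clusters_have_zero_area(self):
        assert cluster_hull_area(np.array([[0, 0], [50, 50]])) == 0.0
        assert cluster_hull_area(np.array([[0, 0], [10, 10], [20, 20], [30, 30]])) == 0.0

    def test_unit_square_scaled(self):
        sq = np.array([[0, 0], [100, 0], [100, 100], [0, 100]])
        assert cluster_hull_area(sq) == pytest.approx(10_000)

    def _assignment_with_areas(self):
        # three triangles with areas 50, 50, 5000 -> mean 1700, select only the last
        tri = lambda ox, s: np.array([[ox, 0], [ox + s, 0], [ox, s]])
        pts = np.vstack([tri(0, 10), tri(5000, 10), tri(10_000, 100)])
        table = make_table(pts)
        params = ClusterParams(eps1=150, minpts=3, eps2=16)
        return coarse_cluster(table, params)

    def test_select_strictly_above_mean(self):
        assignment = self._assignment_with_areas()
        assert select_oversized(assignment) == [2]

    def test_single_cluster_never_selected(self):
        pts = np.array([[0, 0], [100, 0], [0, 100]], dtype=float)
        assignment = coarse_cluster(make_table(pts), ClusterParams(eps1=150, minpts=3))
        assert select_oversized(assignment) == []

    def test_equal_areas_select_nothing(self):
        # power-of-two offset keeps both hull areas bit-identical in floating point
        tri = lambda ox: np.array([[ox, 0], [ox + 10, 0], [ox, 10]])
        pts = np.vstack([tri(0), tri(4096)])
        assignment = coarse_cluster(make_table(pts), ClusterParams(eps1=100, minpts=3))
        assert select_oversized(assignment) == []


class TestRefinement:
    def test_two_tight_blobs_found_by_sweep(self, rng):
        pts = np.vstack([rng.normal([0, 0], 3, (10, 2)), rng.normal([200, 0], 3, (10, 2))])
        params = ClusterParams(eps1=100, minpts=3, eps2=20, n_eps_steps=9)
        assert refine_subcluster_count(pts, params) == 2

    def test_one_blob_keeps_intact(self, rng):
        pts = rng.normal([0, 0], 3, (15, 2))
        params = ClusterParams(eps1=100, minpts=3, eps2=20, n_eps_steps=9)
        assert refine_subcluster_count(pts, params) == 1

    def test_all_noise_falls_back_to_one(self):
        pts = np.array([[0.0, 0], [500, 0]])
        params = ClusterParams(eps1=50, minpts=5, eps2=16)
        assert refine_subcluster_count(pts, params) == 1


class TestHierarchicalSplit:
    def test_k_extremes(self, rng):
        pts = rng.uniform(0, 100, (7, 2))
        assert hierarchical_split(pts, 1).tolist() == [0] * 7
        assert sorted(hierarchical_split(pts, 7)) == list(range(7))

    def test_k_out_of_range(self, rng):
        with pytest.raises(ParameterError):
            hierarchical_split(rng.uniform(0, 10, (5, 2)), 6)

    def test_ward_separates_two_blobs(self, rng):
        a = rng.normal([0, 0], 10, (20, 2))
        b = rng.normal([300, 0], 10, (20, 2))
        pts = np.vstack([a, b])
        labels = hierarchical_split(pts, 2, "ward")
        # oracle: assign to nearest true center
        truth = (np.linalg.norm(pts - [300, 0], axis=1)
                 < np.linalg.norm(pts - [0, 0], axis=1)).astype(int)
        agreement = max((labels == truth).mean(), (labels != truth).mean())
        assert agreement == 1.0


class TestDevelopedDbscan:
    def test_empty_table(self):
        table = LocalizationTable.from_arrays([], [], geometry=FieldGeometry(1000, 1000))
        assignment = developed_dbscan(table, ClusterParams())
        assert len(assignment.final_label) == 0
        assert assignment.n_final_clusters == 0

    def test_merged_pair_is_split(self, rng):
        """Two molecules 60 nm apart merge under a large coarse radius but are
        recovered by refinement; isolated singles make the merge oversized."""
        blobs = [rng.normal([500, 500], 8, (20, 2)), rng.normal([560, 500], 8, (20, 2))]
        singles = [rng.normal([c, 3000], 8, (6, 2)) for c in (500, 1500, 2500, 3500)]
        pts = np.vstack(blobs + singles)
        table = make_table(pts, FieldGeometry(4000, 4000))
        params = ClusterParams(eps1=50, minpts=3, eps2=16, n_eps_steps=8)
        assignment = developed_dbscan(table, params)
        # the merged pair occupies rows 0..39: coarse together, final apart
        coarse = assignment.coarse_label[:40]
        final = assignment.final_label[:40]
        assert len(np.unique(coarse)) == 1
        assert len(np.unique(final)) == 2
        blob_id = np.repeat([0, 1], 20)
        first, second = final[:20], final[20:]
        assert len(np.unique(first)) == 1 and len(np.unique(second)) == 1

    def test_identical_points_single_cluster(self):
        pts = np.full((5, 2), 100.0)
        table = make_table(pts, FieldGeometry(1000, 1000))
        assignment = developed_dbscan(table, ClusterParams())
        assert assignment.n_final_clusters == 1
        assert (assignment.final_label == 0).all()

    def test_refinement_invariants_on_synthetic_field(self, sparse_monomer_field):
        table, truth = sparse_monomer_field
        assignment = developed_dbscan(table, ClusterParams())
        assignment.validate()  # split-only, noise unchanged, count monotone
        labs = assignment.final_label
        present = np.unique(labs[labs != -1])
        np.testing.assert_array_equal(present, np.arange(len(present)))  # label hygiene
        # recovery at 5 molecules/um^2: merging, 1-blink noise and occasional
        # oversplitting of a blink cloud each contribute a few percent either way
        n_true = len(truth.molecules)
        assert abs(assignment.n_final_clusters - n_true) / n_true < 0.10

    def test_determinism(self, sparse_monomer_field):
        table, _ = sparse_monomer_field
        a1 = developed_dbscan(table, ClusterParams())
        a2 = developed_dbscan(table, ClusterParams())
        np.testing.assert_array_equal(a1.final_label, a2.final_label)


def test_renumber_label_hygiene():
    labels = np.array([-1, 7, 7, 3, -1, 3, 9])
    out = _renumber(labels)
    assert out.tolist() == [-1, 0, 0, 1, -1, 1, 2]


def test_params_validation():
    with pytest.raises(ValidationError):
        ClusterParams(eps1=10, eps2=20)
    with pytest.raises(ValidationError):
        ClusterParams(minpts=1)
    with pytest.raises(ValidationError):
        ClusterParams(linkage="centroid")
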