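"""Cluster fixpoints against closure/BFS oracles; full-image segmentation."""

import numpy as np
import pytest

from conftest import box_closure_oracle, euclidean_bfs_oracle
from depthmask import (ContractError, Point3D, build_tree, cluster_euclidean,
                       cluster_expanding_box, cluster_fixed_box,
                       generate_random_cloud, partition_signature,
                       reset_removal, segment_all)


def ids(points):
    return {id(p) for p in points}


def chain(n, step, b=1.0):
    return [Point3D(i * step * b, 0.0, 0.0, i, 0) for i in range(n)]


class TestSeededClusters:
    def test_isolated_seed_singleton(self):
        pts = [Point3D(0, 0, 0, 0, 0), Point3D(10, 10, 10, 1, 0)]
        for fn in (cluster_expanding_box, cluster_fixed_box,
                   cluster_euclidean):
            tree = build_tree(pts)
            c = fn(tree, pts[0], 2.0)
            assert ids(c.points) == {id(pts[0])}

    def test_chain_within_reach_fully_clustered(self):
        pts = chain(10, 0.9)
        tree = build_tree(pts)
        c = cluster_expanding_box(tree, pts[0], 1.0)
        assert ids(c.points) == ids(pts)
        assert ids(c.points) == box_closure_oracle(pts, pts[0], 1.0)

    def test_box_fixpoint_no_active_point_in_final_box(self):
        pts = generate_random_cloud(200, (30, 30, 30), 77)
        tree = build_tree(pts)
        c = cluster_expanding_box(tree, pts[0], 3.0)
        outside = [p for p in pts if id(p) not in ids(c.points)]
        assert not any(c.bbox.contains(p) for p in outside)

    def test_removed_seed_rejected(self):
        pts = chain(3, 0.5)
        tree = build_tree(pts)
        cluster_expanding_box(tree, pts[0], 1.0)
        with pytest.raises(ContractError):
            cluster_expanding_box(tree, pts[0], 1.0)

    def test_nonmember_seed_rejected(self):
        tree = build_tree(chain(3, 0.5))
        with pytest.raises(ContractError):
            cluster_fixed_box(tree, Point3D(9, 9, 9, 9, 0), 1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_fixed_box_equals_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 250))
        b = float(rng.uniform(0.5, 4.0))
        pts = generate_random_cloud(n, (25, 25, 25), 1000 + seed)
        tree = build_tree(pts)
        seed_pt = pts[int(rng.integers(0, n))]
        c = cluster_fixed_box(tree, seed_pt, b)
        assert ids(c.points) == box_closure_oracle(pts, seed_pt, b)

    @pytest.mark.parametrize("seed", range(20))
    def test_expanding_equals_fixed_cluster(self, seed):
        rng = np.random.default_rng(500 + seed)
        n = int(rng.integers(30, 250))
        b = float(rng.uniform(0.5, 4.0))
        pts = generate_random_cloud(n, (25, 25, 25), 2000 + seed)
        seed_pt = pts[int(rng.integers(0, n))]
        te = build_tree(pts)
        tf = build_tree(pts)
        ce = cluster_expanding_box(te, seed_pt, b)
        cf = cluster_fixed_box(tf, seed_pt, b)
        assert ids(ce.points) == ids(cf.points)

    @pytest.mark.parametrize("seed", range(20))
    def test_euclidean_equals_bfs_oracle(self, seed):
        rng = np.random.default_rng(900 + seed)
        n = int(rng.integers(20, 150))
        b = float(rng.uniform(0.5, 4.0))
        pts = generate_random_cloud(n, (20, 20, 20), 3000 + seed)
        seed_pt = pts[int(rng.integers(0, n))]
        tree = build_tree(pts)
        c = cluster_euclidean(tree, seed_pt, b)
        assert ids(c.points) == euclidean_bfs_oracle(pts, seed_pt, b)

    def test_two_points_radius_semantics(self):
        close = [Point3D(0, 0, 0, 0, 0), Point3D(0.5, 0, 0, 1, 0)]
        tree = build_tree(close)
        assert len(cluster_euclidean(tree, close[0], 1.0)) == 2
        far = [Point3D(0, 0, 0, 0, 0), Point3D(2.0, 0, 0, 1, 0)]
        tree = build_tree(far)
        assert len(cluster_euclidean(tree, far[0], 1.0)) == 1

    def test_euclidean_subset_of_box_cluster(self):
        for seed in range(10):
            pts = generate_random_cloud(150, (20, 20, 20), 4000 + seed)
            b = 2.0
            te = build_tree(pts)
            tb = build_tree(pts)
            ce = cluster_euclidean(te, pts[0], b)
            cb = cluster_fixed_box(tb, pts[0], b)
            assert ids(ce.points) <= ids(cb.points)


class TestPassCounting:
    def test_cloud_inside_initial_box_one_productive_pass(self):
        pts = generate_random_cloud(50, (2, 2, 2), 8)
        for fn in (cluster_expanding_box, cluster_fixed_box):
            tree = build_tree(pts)
            c = fn(tree, pts[0], 5.0)
            assert len(c) == 50
            assert c.productive_passes == 1

    def test_stop_callback_caps_growth_with_overshoot(self):
        # chain where each pass adds one point: the cap triggers exactly
        # when the running size first reaches it
        pts = chain(20, 0.9)
        tree = build_tree(pts)
        cap = 0.9 * 20
        c = cluster_expanding_box(tree, pts[0], 1.0,
                                  stop=lambda size: size >= cap)
        assert cap <= len(c) < 20

    def test_stop_after_full_pass_may_overshoot_cap(self):
        # everything fits in the first box: the single pass overshoots a
        # 50% cap because passes are never split
        pts = generate_random_cloud(40, (2, 2, 2), 13)
        tree = build_tree(pts)
        c = cluster_expanding_box(tree, pts[0], 5.0,
                                  stop=lambda size: size >= 20)
        assert len(c) == 40


class TestSegmentAll:
    def test_one_big_cluster(self):
        pts = generate_random_cloud(50, (5, 5, 5), 17)
        tree = build_tree(pts)
        res = segment_all(tree, 10.0, "expanding")
        assert res.cluster_count == 1
        assert len(res.clusters[0]) == 50

    def test_all_singletons(self):
        pts = [Point3D(10.0 * i, 0, 0, i, 0) for i in range(50)]
        for algo in ("expanding", "fixed", "euclidean"):
            tree = build_tree(pts)
            res = segment_all(tree, 1.0, algo)
            assert res.cluster_count == 50
            assert all(len(c) == 1 for c in res.clusters)

    def test_two_separated_blobs(self, rng):
        blob_a = [Point3D(x, y, z, i, 0) for i, (x, y, z)
                  in enumerate(rng.uniform(0, 3, (40, 3)))]
        blob_b = [Point3D(x + 20, y, z, 100 + i, 0) for i, (x, y, z)
                  in enumerate(rng.uniform(0, 3, (40, 3)))]
        pts = blob_a + blob_b
        tree = build_tree(pts)
        res = segment_all(tree, 2.0, "expanding")
        assert res.cluster_count == 2
        assert {frozenset(ids(c.points)) for c in res.clusters} == \
            {frozenset(ids(blob_a)), frozenset(ids(blob_b))}

    @pytest.mark.parametrize("algo", ["expanding", "fixed", "euclidean"])
    def test_partition_invariant(self, algo):
        pts = generate_random_cloud(300, (25, 25, 25), 66)
        tree = build_tree(pts)
        res = segment_all(tree, 2.0, algo)
        seen = set()
        for c in res.clusters:
            assert not (ids(c.points) & seen)
            seen |= ids(c.points)
        assert seen == ids(pts)

    def test_fixed_and_expanding_same_partition(self):
        pts = generate_random_cloud(400, (30, 30, 30), 91)
        tree = build_tree(pts)
        rf = segment_all(tree, 2.5, "fixed")
        reset_removal(tree)
        re_ = segment_all(tree, 2.5, "expanding")
        assert partition_signature(rf) == partition_signature(re_)
        assert re_.total_node_visits <= rf.total_node_visits

    def test_cluster_fixpoint_idempotent_on_reseed(self):
        pts = generate_random_cloud(200, (20, 20, 20), 44)
        tree = build_tree(pts)
        res = segment_all(tree, 2.0, "expanding")
        target = max(res.clusters, key=len)
        # reactivate only this cluster's removal flags and re-seed from any
        # member (subtree_active is conservatively re-armed everywhere;
        # stale True never changes results, only visits)
        for p in target.points:
            tree.node_for(p).removed = False
        for p in pts:
            tree.node_for(p).subtree_active = True
        c2 = cluster_expanding_box(tree, target.points[-1], 2.0)
        assert ids(c2.points) == ids(target.points)

    def test_unknown_algorithm(self):
        tree = build_tree(chain(3, 0.5))
        with pytest.raises(ContractError):
            segment_all(tree, 1.0, "voronoi")

    def test_deterministic_repeat(self):
        pts = generate_random_cloud(250, (25, 25, 25), 10)
        tree = build_tree(pts)
        r1 = segment_all(tree, 2.0, "expanding")
        reset_removal(tree)
        r2 = segment_all(tree, 2.0, "expanding")
        assert [ids(c.points) for c in r1.clusters] == \
            [ids(c.points) for c in r2.clusters]
        assert r1.passes == r2.passes
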