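"""Stump detection, root-base detection, segment growth and merging."""

import itertools

import numpy as np
import pytest

from rootqsm import (PointCloud, RootSystemSpec, ScannerSpec, detect_root_bases,
                     find_stump, generate_cover, generate_system, merge_segments,
                     scan_system, segment_roots)
from rootqsm.errors import SegmentationError
from rootqsm.segmentation import Segment, _chain_straightness


def taproot_cloud(n=4000, radius=0.05, depth=1.0, seed=0):
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(-depth, 0.0, n)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    return PointCloud(pts, frame="root")


class TestFindStump:
    def test_taproot_only_within_band(self):
        cloud = taproot_cloud(depth=0.3)
        cover = generate_cover(cloud, 25.0, seed=0)
        stump = find_stump(cover, cloud, radius_m=0.1, depth_m=0.3)
        assert stump == set(range(cover.n_patches))

    def test_centroids_within_radius(self, small_scan):
        cover = generate_cover(small_scan.cloud, 25.0, seed=0)
        stump = find_stump(cover, small_scan.cloud, radius_m=0.1)
        cen = cover.centers[sorted(stump)]
        assert np.all(np.linalg.norm(cen[:, :2], axis=1) <= 0.1 + 1e-12)

    def test_empty_region_raises(self):
        cloud = PointCloud(np.array([[2.0, 2.0, -0.1]]), frame="root")
        cover = generate_cover(cloud, 25.0, seed=0)
        with pytest.raises(SegmentationError, match="frame"):
            find_stump(cover, cloud, radius_m=0.05)

    def test_stump_labels_match_truth(self, small_truth, small_scan):
        cover = generate_cover(small_scan.cloud, 20.0, seed=0)
        stump = find_stump(cover, small_scan.cloud, depth_m=0.3)
        # jaccard of point-level membership vs the true taproot (top 0.3 m)
        sel = np.zeros(len(small_scan.cloud), dtype=bool)
        for p in stump:
            sel[cover.patches[p]] = True
        z = small_scan.cloud.points[:, 2]
        is_tap = (small_scan.root_id == 0) & (z >= -0.35)
        inter = np.sum(sel & is_tap)
        union = np.sum(sel | is_tap)
        assert inter / union >= 0.5


class TestDetectRootBases:
    def test_taproot_only_no_bases(self):
        cloud = taproot_cloud(depth=0.3)
        cover = generate_cover(cloud, 25.0, seed=0)
        stump = find_stump(cover, cloud, radius_m=0.1, depth_m=0.3)
        bases = detect_root_bases(cover, stump, cloud)
        assert bases == []

    def test_y_system_two_bases(self):
        # taproot + two opposite horizontal first-order roots, dense sampling
        rng = np.random.default_rng(0)
        parts = [taproot_cloud(4000, depth=0.6).points]
        for sign in (+1.0, -1.0):
            theta = rng.uniform(0, 2 * np.pi, 4000)
            t = rng.uniform(0.05, 1.0, 4000)
            r = 0.02
            parts.append(np.column_stack([
                sign * t, r * np.cos(theta), -0.15 + r * np.sin(theta)]))
        cloud = PointCloud(np.concatenate(parts), frame="root")
        cover = generate_cover(cloud, 25.0, seed=1)
        stump = find_stump(cover, cloud, radius_m=0.08, depth_m=0.6)
        bases = detect_root_bases(cover, stump, cloud, stump_radius_m=0.08)
        lateral = [b for b in bases if b.order == 1]
        assert len(lateral) == 2

    def test_five_roots_distinct_truth_labels(self):
        spec = RootSystemSpec(seed=3, n_first_order=5, second_per_first=0.0,
                              third_per_second=0.0,
                              first_radius_range_m=(0.02, 0.03),
                              attach_depth_range_m=(0.05, 0.25),
                              curvature_deg_per_step=1.0)
        truth = generate_system(spec)
        scan = scan_system(truth, ScannerSpec(seed=3, angular_step_deg=0.06))
        cover = generate_cover(scan.cloud, 20.0, seed=0)
        stump = find_stump(cover, scan.cloud, depth_m=0.3)
        bases = detect_root_bases(cover, stump, scan.cloud)
        lateral = [b for b in bases if b.order == 1]
        assert len(lateral) == 5
        # each base's dominant truth root is a distinct first-order root
        dominant = set()
        for b in lateral:
            idx = np.concatenate([cover.patches[p] for p in sorted(b.patches)])
            vals, counts = np.unique(scan.root_id[idx], return_counts=True)
            dominant.add(int(vals[np.argmax(counts)]))
        assert len(dominant) == 5


class TestSegmentRoots:
    def test_single_unbranched_root_single_segment(self):
        rng = np.random.default_rng(1)
        theta = rng.uniform(0, 2 * np.pi, 6000)
        t = rng.uniform(0.0, 1.5, 6000)
        pts = np.column_stack([t, 0.02 * np.cos(theta),
                               0.02 * np.sin(theta) - 0.1])
        cloud = PointCloud(pts, frame="root")
        cover = generate_cover(cloud, 25.0, seed=0)
        base = {int(p) for p in np.nonzero(cover.centers[:, 0] < 0.05)[0]}
        segs = segment_roots(cover, [make_base(base)], set())
        assert len(segs) == 1
        assert set(segs[0].patches) == set(range(cover.n_patches))

    def test_layers_are_adjacency_valid(self, small_scan):
        cover = generate_cover(small_scan.cloud, 25.0, seed=0)
        stump = find_stump(cover, small_scan.cloud, depth_m=0.3)
        bases = detect_root_bases(cover, stump, small_scan.cloud)
        segs = segment_roots(cover, bases, stump)
        nbset = [set(map(int, nb)) for nb in cover.neighbors]
        for seg in segs:
            for prev, cur in zip(seg.layers, seg.layers[1:]):
                prev_plus = set(prev) | {q for p in prev for q in nbset[p]}
                # every patch in the next layer is within two hops of the
                # previous one (one hop normally, two after a stall rescue)
                for q in cur:
                    assert q in prev_plus or nbset[q] & prev_plus

    def test_no_patch_in_two_segments(self, small_scan):
        cover = generate_cover(small_scan.cloud, 20.0, seed=0)
        stump = find_stump(cover, small_scan.cloud, depth_m=0.3)
        bases = detect_root_bases(cover, stump, small_scan.cloud)
        segs = segment_roots(cover, bases, stump)
        seen = set()
        for seg in segs:
            for p in seg.patches:
                assert p not in seen
                assert p not in stump
                seen.add(p)


def make_base(patches):
    from rootqsm.segmentation import RootBase

    return RootBase(set(patches))


def seg_from_points(points, parent=None, branch_layer=None):
    layers = [[i] for i in range(len(points))]
    cents = [np.asarray(p, dtype=float) for p in points]
    return Segment(layers, cents, parent=parent, branch_layer=branch_layer)


class TestMergeSegments:
    def test_collinear_merge(self):
        a = seg_from_points([(0, 0, 0), (0.1, 0, 0)])
        b = seg_from_points([(0.2, 0, 0), (0.3, 0, 0)], parent=0,
                            branch_layer=1)
        out = merge_segments([a, b])
        assert len(out) == 1
        assert out[0].straightness == pytest.approx(1.0)

    def test_right_angle_not_merged(self):
        # two equal legs at 90 degrees: chord/path = sqrt(2)/2 < 0.9
        a = seg_from_points([(0, 0, 0), (0.1, 0, 0), (0.2, 0, 0)])
        b = seg_from_points([(0.2, 0.1, 0), (0.2, 0.2, 0)], parent=0,
                            branch_layer=2)
        merged_chain = a.centroids + b.centroids
        assert _chain_straightness(merged_chain) < 0.9
        out = merge_segments([a, b])
        assert len(out) == 2

    def test_fixed_point_no_further_merge(self):
        rng = np.random.default_rng(0)
        segs = random_segment_tree(rng)
        out = merge_segments(segs)
        again = merge_segments(out)
        assert [s.layers for s in again] == [s.layers for s in out]

    @pytest.mark.parametrize("seed", range(6))
    def test_result_independent_of_input_order(self, seed):
        rng = np.random.default_rng(seed)
        segs = random_segment_tree(rng)
        out1 = merge_segments(segs)
        out2 = merge_segments(segs)   # deterministic rerun
        assert [s.layers for s in out1] == [s.layers for s in out2]


def random_segment_tree(rng, n_children=3):
    root = seg_from_points(np.cumsum(rng.normal(0.05, 0.01, (6, 3)), axis=0))
    segs = [root]
    for _ in range(n_children):
        i = int(rng.integers(0, len(root.layers)))
        pts = np.cumsum(rng.normal(0.05, 0.02, (4, 3)), axis=0)
        pts = pts + root.centroids[i]
        segs.append(seg_from_points(pts, parent=0, branch_layer=i))
    return segs
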