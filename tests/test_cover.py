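"""Cover-set generation, adjacency, expansion and components."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import cKDTree

import rootqsm.cover as cover_mod
from rootqsm import PointCloud, connected_components, expand, generate_cover
from rootqsm.errors import ParameterError


def brute_force_cover(points, patch_diam_mm, seed):
    """Independent restatement of the greedy covering rule."""
    n = len(points)
    r = patch_diam_mm / 2000.0
    order = np.random.default_rng(seed).permutation(n)
    covered = np.zeros(n, dtype=bool)
    patches = []
    for i in order:
        if covered[i]:
            continue
        d = np.linalg.norm(points - points[i], axis=1)
        members = np.nonzero((d <= r) & ~covered)[0]
        covered[members] = True
        patches.append(set(members.tolist()))
    return patches


def brute_force_adjacency(points, labels, d_m):
    tree = cKDTree(points)
    pairs = tree.query_pairs(d_m, output_type="ndarray")
    edges = set()
    for i, j in pairs:
        a, b = labels[i], labels[j]
        if a != b:
            edges.add((min(a, b), max(a, b)))
    return edges


class TestGenerateCover:
    def test_single_point(self):
        cover = generate_cover(PointCloud(np.zeros((1, 3))), 20.0, seed=0)
        assert cover.n_patches == 1
        assert len(cover.neighbors[0]) == 0

    def test_two_distant_points_not_adjacent(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        cover = generate_cover(PointCloud(pts), 25.0, seed=0)
        assert cover.n_patches == 2
        assert all(len(nb) == 0 for nb in cover.neighbors)

    def test_nonpositive_diameter(self):
        with pytest.raises(ParameterError):
            generate_cover(PointCloud(np.zeros((1, 3))), 0.0, seed=0)

    def test_line_matches_brute_force_and_count_band(self):
        # 100 points in a line at 10 mm spacing, PatchDiam 25 mm
        pts = np.column_stack([np.arange(100) * 0.010, np.zeros(100),
                               np.zeros(100)])
        counts = []
        for seed in range(10):
            cover = generate_cover(PointCloud(pts), 25.0, seed=seed)
            expected = brute_force_cover(pts, 25.0, seed)
            got = [set(p.tolist()) for p in cover.patches]
            assert got == expected
            counts.append(cover.n_patches)
        # each patch holds 1-3 consecutive points -> between 34 and 50 patches
        assert all(34 <= c <= 50 for c in counts)

    @given(seed=st.integers(0, 50), diam=st.sampled_from([8.0, 20.0, 60.0]))
    @settings(max_examples=20, deadline=None)
    def test_partition_property(self, seed, diam):
        rng = np.random.default_rng(99)
        pts = rng.uniform(0, 0.15, size=(120, 3))
        cover = generate_cover(PointCloud(pts), diam, seed=seed)
        all_idx = np.sort(np.concatenate(cover.patches))
        assert np.array_equal(all_idx, np.arange(len(pts)))   # exhaustive
        sizes = sum(len(p) for p in cover.patches)
        assert sizes == len(pts)                              # disjoint
        for members in cover.patches:
            sub = pts[members]
            d = np.linalg.norm(sub[:, None] - sub[None], axis=-1)
            assert d.max() <= diam / 1000.0 + 1e-12           # bounded extent

    def test_adjacency_matches_brute_force_both_strategies(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 0.2, size=(400, 3))
        for diam in (15.0, 60.0):
            c1 = generate_cover(PointCloud(pts), diam, seed=3)
            oracle = brute_force_adjacency(pts, c1.labels, diam / 1000.0)
            mine = {(i, int(j)) for i, nb in enumerate(c1.neighbors)
                    for j in nb if j > i}
            assert mine == oracle
            # force the seed-ball hybrid strategy; result must be identical
            old = cover_mod._PAIR_CAP
            try:
                cover_mod._PAIR_CAP = -1.0
                c2 = generate_cover(PointCloud(pts), diam, seed=3)
            finally:
                cover_mod._PAIR_CAP = old
            mine2 = {(i, int(j)) for i, nb in enumerate(c2.neighbors)
                     for j in nb if j > i}
            assert mine2 == oracle

    def test_patch_count_non_increasing_in_diameter(self):
        from rootqsm import DEFAULT_GRID_MM

        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 0.3, size=(500, 3))
        cloud = PointCloud(pts)
        counts = [generate_cover(cloud, g, seed=1,
                                 build_adjacency=False).n_patches
                  for g in DEFAULT_GRID_MM]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_dense_cylinder_adjacency_connected(self):
        theta = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        z = np.linspace(0, 0.4, 80)
        tt, zz = np.meshgrid(theta, z)
        pts = np.column_stack([0.03 * np.cos(tt.ravel()),
                               0.03 * np.sin(tt.ravel()), zz.ravel()])
        cover = generate_cover(PointCloud(pts), 25.0, seed=0)
        import networkx as nx

        assert nx.is_connected(cover.graph())


class TestExpandAndComponents:
    @pytest.fixture()
    def path_cover(self):
        # four patches in a path a-b-c-d (20 mm spacing, 25 mm diameter)
        pts = np.array([[0.0, 0, 0], [0.02, 0, 0], [0.04, 0, 0],
                        [0.06, 0, 0]])
        return generate_cover(PointCloud(pts), 25.0, seed=1)

    def test_zero_layers_empty(self, path_cover):
        assert expand(path_cover, {0}, 0) == set()

    def test_path_two_layers(self, path_cover):
        a = int(path_cover.labels[0])
        b, c = int(path_cover.labels[1]), int(path_cover.labels[2])
        assert expand(path_cover, {a}, 2) == {b, c}

    def test_unknown_patch_id(self, path_cover):
        with pytest.raises(IndexError):
            expand(path_cover, {99}, 1)

    @given(seed=st.integers(0, 30))
    @settings(max_examples=15, deadline=None)
    def test_expand_monotone_and_matches_bfs(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 0.08, size=(60, 3))
        cover = generate_cover(PointCloud(pts), 25.0, seed=seed)
        region = {int(rng.integers(cover.n_patches))}
        g = cover.graph()
        import networkx as nx

        for k in range(4):
            got = expand(cover, region, k)
            lengths = nx.multi_source_dijkstra_path_length(
                g, region, cutoff=k, weight=None)
            want = set(lengths) - region
            assert got == want
            assert got <= expand(cover, region, k + 1) | region

    def test_components_empty(self, path_cover):
        assert connected_components(path_cover, set()) == []

    def test_components_disconnected(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        cover = generate_cover(PointCloud(pts), 25.0, seed=0)
        comps = connected_components(cover, {0, 1})
        assert comps == [{0}, {1}]

    @given(seed=st.integers(0, 30))
    @settings(max_examples=15, deadline=None)
    def test_components_match_networkx(self, seed):
        rng = np.random.default_rng(seed + 1000)
        pts = rng.uniform(0, 0.1, size=(50, 3))
        cover = generate_cover(PointCloud(pts), 30.0, seed=seed)
        subset = set(rng.choice(cover.n_patches,
                                size=min(cover.n_patches, 30),
                                replace=False).tolist())
        import networkx as nx

        got = connected_components(cover, subset)
        want = list(nx.connected_components(cover.graph().subgraph(subset)))
        assert sorted(map(sorted, got)) == sorted(map(sorted, want))
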