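"""Cover sets: partition a cloud into patches of bounded diameter.

A cover is a disjoint, exhaustive partition of the point cloud into
patches ("cover sets") whose spatial extent is at most *PatchDiam*,
together with a patch-adjacency graph. It is the combinatorial unit of
all downstream segmentation and cylinder fitting.

Covering rule: randomized greedy ball covering. Points are visited in a
seed-shuffled order; each still-uncovered point claims every uncovered
point within PatchDiam/2 of it as one patch. Maximum pairwise distance
within a patch is therefore bounded by PatchDiam by construction. Two
patches are adjacent iff some inter-patch point pair lies within
``adjacency_factor * PatchDiam`` (default factor 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError
from .pointcloud import PointCloud

__all__ = ["Cover", "generate_cover", "expand", "connected_components"]

# point-pair budget above which adjacency switches to the seed-ball hybrid
_PAIR_CAP = 1.5e7


def _min_dist_within(flat, offsets, pairs, d):
    """For each patch pair, is any inter-patch point distance <= d?

    ``flat`` holds the points grouped by patch, ``offsets`` delimits the
    groups. Early-exits on the first hit.
    """
    d2 = d * d
    out = np.zeros(len(pairs), dtype=np.bool_)
    for k in range(len(pairs)):
        a = pairs[k, 0]
        b = pairs[k, 1]
        found = False
        for i in range(offsets[a], offsets[a + 1]):
            xi = flat[i, 0]
            yi = flat[i, 1]
            zi = flat[i, 2]
            for j in range(offsets[b], offsets[b + 1]):
                dx = flat[j, 0] - xi
                dy = flat[j, 1] - yi
                dz = flat[j, 2] - zi
                if dx * dx + dy * dy + dz * dz <= d2:
                    found = True
                    break
            if found:
                break
        out[k] = found
    return out


def _greedy_cover(pts, order, r):
    """Sequential greedy ball covering over a voxel hash.

    Visits points in `order`; each uncovered point claims all uncovered
    points within r. Returns (labels, seed point index per patch).
    """
    n = pts.shape[0]
    mins = np.empty(3)
    for k in range(3):
        mn = pts[0, k]
        for i in range(1, n):
            if pts[i, k] < mn:
                mn = pts[i, k]
        mins[k] = mn
    inv = 1.0 / r
    cx = np.empty(n, dtype=np.int64)
    cy = np.empty(n, dtype=np.int64)
    cz = np.empty(n, dtype=np.int64)
    nx = ny = nz = 0
    for i in range(n):
        cx[i] = np.int64((pts[i, 0] - mins[0]) * inv)
        cy[i] = np.int64((pts[i, 1] - mins[1]) * inv)
        cz[i] = np.int64((pts[i, 2] - mins[2]) * inv)
        if cx[i] >= nx:
            nx = cx[i] + 1
        if cy[i] >= ny:
            ny = cy[i] + 1
        if cz[i] >= nz:
            nz = cz[i] + 1
    keys = (cx * ny + cy) * nz + cz
    ksort = np.argsort(keys, kind="mergesort")
    skeys = keys[ksort]
    labels = np.full(n, -1, dtype=np.int64)
    seeds = np.empty(n, dtype=np.int64)
    r2 = r * r
    n_patches = 0
    for oi in range(n):
        i = order[oi]
        if labels[i] >= 0:
            continue
        xi = pts[i, 0]
        yi = pts[i, 1]
        zi = pts[i, 2]
        for ax in range(max(0, cx[i] - 1), min(nx - 1, cx[i] + 1) + 1):
            for ay in range(max(0, cy[i] - 1), min(ny - 1, cy[i] + 1) + 1):
                for az in range(max(0, cz[i] - 1), min(nz - 1, cz[i] + 1) + 1):
                    key = (ax * ny + ay) * nz + az
                    lo = np.searchsorted(skeys, key)
                    hi = np.searchsorted(skeys, key + 1)
                    for q in range(lo, hi):
                        j = ksort[q]
                        if labels[j] >= 0:
                            continue
                        dx = pts[j, 0] - xi
                        dy = pts[j, 1] - yi
                        dz = pts[j, 2] - zi
                        if dx * dx + dy * dy + dz * dz <= r2:
                            labels[j] = n_patches

        seeds[n_patches] = i
        n_patches += 1
    return labels, seeds[:n_patches]


try:
    from numba import njit as _njit

    _min_dist_within = _njit(cache=True)(_min_dist_within)
    _greedy_cover = _njit(cache=True)(_greedy_cover)
except Exception:  # pragma: no cover - numba available in practice
    pass


@dataclass
class Cover:
    """A patch partition of a point cloud plus patch adjacency.

    ``patches[i]`` is a sorted array of point indices; ``labels`` maps each
    point to its patch; ``neighbors[i]`` is a sorted array of patch ids
    adjacent to patch ``i`` (symmetric, irreflexive).
    """

    patch_diam_mm: float
    patches: list[np.ndarray]
    centers: np.ndarray              # (P, 3) patch point centroids, metres
    neighbors: list[np.ndarray]
    labels: np.ndarray               # (N,) patch id per point
    seed: int
    adjacency_factor: float = 1.0

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    def graph(self):
        """Patch adjacency as a networkx Graph (for inspection/tests)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_patches))
        for i, nbrs in enumerate(self.neighbors):
            g.add_edges_from((i, int(j)) for j in nbrs if j > i)
        return g


def generate_cover(cloud: PointCloud, patch_diam_mm: float, seed: int = 0,
                   adjacency_factor: float = 1.0,
                   build_adjacency: bool = True) -> Cover:
    """Cover a cloud with patches of diameter ``patch_diam_mm``.

    Deterministic given (cloud, patch_diam_mm, seed). See the module
    docstring for the covering and adjacency rules.
    """
    if patch_diam_mm <= 0:
        raise ParameterError("patch_diam must be positive")
    pts = cloud.points
    n = len(pts)
    r = patch_diam_mm / 2000.0   # ball radius in metres
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    tree = cKDTree(pts)
    labels, seeds_arr = _greedy_cover(np.ascontiguousarray(pts), order, r)
    n_patches = int(labels.max()) + 1
    member_order = np.argsort(labels, kind="stable")   # stable: index-sorted groups
    sorted_labels = labels[member_order]
    bounds = np.searchsorted(sorted_labels, np.arange(n_patches + 1))
    patches = [member_order[bounds[i]:bounds[i + 1]]
               for i in range(n_patches)]
    seeds = seeds_arr.tolist()
    sums = np.zeros((n_patches, 3))
    np.add.at(sums, labels, pts)
    counts = np.bincount(labels, minlength=n_patches).astype(np.float64)
    centers = sums / counts[:, None]
    seed_idx = np.array(seeds, dtype=np.int64)
    if build_adjacency:
        neighbors = _build_adjacency(pts, tree, patches, seed_idx, labels,
                                     adjacency_factor * patch_diam_mm / 1000.0,
                                     patch_diam_mm / 1000.0)
    else:
        neighbors = [np.empty(0, dtype=np.int64) for _ in patches]
    return Cover(patch_diam_mm, patches, centers, neighbors, labels, seed,
                 adjacency_factor)


def _build_adjacency(pts, tree, patches, seed_idx, labels, d, ball_diam):
    """Patch pairs with some inter-patch point pair within distance d.

    Two strategies, both exact. When point pairs within d are few, they
    are enumerated directly. Otherwise the patch seed points decide most
    pairs analytically — every patch lies in a ball of radius
    ``ball_diam/2`` around its seed point, so seed pairs within d are
    certainly adjacent and seed pairs beyond d + ball_diam certainly are
    not — and only the gray shell in between gets an exact nearest-
    neighbor min-distance test.
    """
    n = len(pts)
    n_patches = len(patches)
    # estimate the point-pair count from a deterministic sample
    probe = pts[:: max(1, n // 256)]
    counts = tree.query_ball_point(probe, d, return_length=True, workers=-1)
    approx_pairs = float(np.mean(counts)) * n
    if approx_pairs <= _PAIR_CAP:
        pairs = tree.query_pairs(d, output_type="ndarray")
        if len(pairs):
            la, lb = labels[pairs[:, 0]], labels[pairs[:, 1]]
            mask = la != lb
            la, lb = la[mask], lb[mask]
            lo = np.minimum(la, lb)
            hi = np.maximum(la, lb)
            keys = np.unique(lo * n_patches + hi)
            edges = np.stack([keys // n_patches, keys % n_patches], axis=1)
        else:
            edges = np.empty((0, 2), dtype=np.int64)
    else:
        spts = pts[seed_idx]
        stree = cKDTree(spts)
        cand = stree.query_pairs(d + ball_diam, output_type="ndarray")
        accepted: list[tuple[int, int]] = []
        if len(cand):
            sep = np.linalg.norm(spts[cand[:, 0]] - spts[cand[:, 1]], axis=1)
            sure = sep <= d
            for a, b in cand[sure]:
                accepted.append((int(min(a, b)), int(max(a, b))))
            gray = cand[~sure]
            if len(gray):
                offsets = np.zeros(n_patches + 1, dtype=np.int64)
                for i, m in enumerate(patches):
                    offsets[i + 1] = offsets[i] + len(m)
                flat = pts[np.concatenate(patches)]
                hit = _min_dist_within(flat, offsets,
                                       np.ascontiguousarray(gray), d)
                for (a, b), h in zip(gray, hit):
                    if h:
                        accepted.append((int(min(a, b)), int(max(a, b))))
        if accepted:
            edges = np.array(sorted(set(accepted)), dtype=np.int64)
        else:
            edges = np.empty((0, 2), dtype=np.int64)
    nbr_sets: list[list[int]] = [[] for _ in range(n_patches)]
    for a, b in edges:
        nbr_sets[a].append(int(b))
        nbr_sets[b].append(int(a))
    return [np.array(sorted(s), dtype=np.int64) for s in nbr_sets]


def _check_ids(cover: Cover, ids) -> list[int]:
    out = []
    for pid in ids:
        pid = int(pid)
        if pid < 0 or pid >= cover.n_patches:
            raise IndexError(f"unknown patch id {pid}")
        out.append(pid)
    return out


def expand(cover: Cover, region, layers: int) -> set[int]:
    """Patches reachable from ``region`` in at most ``layers`` adjacency
    steps, excluding ``region`` itself (the "expansion layer")."""
    if layers < 0:
        raise ParameterError("layers must be >= 0")
    region = set(_check_ids(cover, region))
    if layers == 0:
        return set()
    seen = set(region)
    frontier = region
    for _ in range(layers):
        nxt = set()
        for pid in frontier:
            for nb in cover.neighbors[pid]:
                nb = int(nb)
                if nb not in seen:
                    nxt.add(nb)
        if not nxt:
            break
        seen |= nxt
        frontier = nxt
    return seen - region


def connected_components(cover: Cover, subset) -> list[set[int]]:
    """Partition ``subset`` into maximal adjacency-connected groups,
    ordered by their smallest patch id."""
    subset = set(_check_ids(cover, subset))
    comps = []
    unvisited = set(subset)
    while unvisited:
        start = min(unvisited)
        comp = {start}
        stack = [start]
        unvisited.discard(start)
        while stack:
            pid = stack.pop()
            for nb in cover.neighbors[pid]:
                nb = int(nb)
                if nb in unvisited:
                    unvisited.discard(nb)
                    comp.add(nb)
                    stack.append(nb)
        comps.append(comp)
    comps.sort(key=min)
    return comps
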