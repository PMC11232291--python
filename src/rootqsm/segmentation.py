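"""Stump detection, first-order root bases, and segment growth.

The stump (the upper taproot portion the large surface roots spring
from) is located as the patches inside a collar-centred vertical
cylinder. Root bases are found by expanding the stump by a fixed number
of adjacency layers, taking connected components of the expansion layer,
keeping those that extend further outward, and consolidating each with a
cylinder fit. Segments are then grown layer by layer from each base;
when a growth front splits into several persistent components, the one
best aligned with the running direction continues the segment and the
rest spawn child segments. Finally segments are cut and recombined so
each is as long as possible while staying nearly straight (chord/path
ratio above a threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cover import Cover, connected_components, expand
from .errors import SegmentationError
from .fitting import fit_cylinder
from .pointcloud import PointCloud

__all__ = ["RootBase", "Segment", "find_stump", "estimate_taproot_radius",
           "detect_root_bases", "segment_roots", "merge_segments",
           "unassigned_patches"]


@dataclass
class RootBase:
    """A consolidated first-order root base: its patches and base cylinder."""

    patches: set[int]
    axis_point: np.ndarray | None = None
    axis_dir: np.ndarray | None = None
    radius: float | None = None
    order: int = 1            # 0 marks the taproot continuation
    consolidated: bool = True


@dataclass
class Segment:
    """A root segment as an ordered sequence of cover-patch layers.

    Each layer is a sorted list of patch ids; every patch in layer k+1 is
    cover-adjacent to some patch in layer k. ``centroids`` is the
    point-weighted centre of each layer; path length is the arclength of
    the centroid chain and chord the base-tip distance.
    """

    layers: list[list[int]]
    centroids: list[np.ndarray]
    parent: int | None = None
    branch_layer: int | None = None
    order_hint: int | None = None    # 0 for stump / taproot continuation
    is_stump: bool = False

    @property
    def patches(self) -> list[int]:
        return [p for layer in self.layers for p in layer]

    @property
    def path_length(self) -> float:
        c = np.asarray(self.centroids)
        if len(c) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1)))

    @property
    def chord_length(self) -> float:
        if len(self.centroids) < 2:
            return 0.0
        return float(np.linalg.norm(self.centroids[-1] - self.centroids[0]))

    @property
    def straightness(self) -> float:
        path = self.path_length
        return 1.0 if path == 0 else self.chord_length / path


def _patch_sizes(cover: Cover) -> np.ndarray:
    sizes = getattr(cover, "_patch_sizes", None)
    if sizes is None:
        sizes = np.array([len(p) for p in cover.patches], dtype=np.float64)
        cover._patch_sizes = sizes
    return sizes


def _layer_centroid(cover: Cover, layer) -> np.ndarray:
    ids = list(layer)
    sizes = _patch_sizes(cover)[ids]
    return (cover.centers[ids] * sizes[:, None]).sum(axis=0) / sizes.sum()


def estimate_taproot_radius(cloud: PointCloud, band_m: float = 0.10) -> float:
    """Median horizontal point distance to the collar axis within a thin
    band just below the collar — a robust taproot radius proxy."""
    z = cloud.points[:, 2]
    for band in (band_m, 2 * band_m, 4 * band_m):
        mask = (z >= -band) & (z <= 0.05)
        if mask.sum() >= 10:
            return float(np.median(np.linalg.norm(cloud.points[mask, :2], axis=1)))
    raise SegmentationError(
        "no points near the collar; is the frame set (collar at origin, Z up)?")


def find_stump(cover: Cover, cloud: PointCloud, radius_m: float | None = None,
               radius_factor: float = 1.5, depth_m: float = 0.30) -> set[int]:
    """Patches of the stump: centroids within ``radius_m`` of the collar
    axis and within the depth band below the collar; largest connected
    component. ``radius_m`` defaults to ``radius_factor`` times an
    estimated taproot radius."""
    if radius_m is None:
        radius_m = radius_factor * estimate_taproot_radius(cloud)
    c = cover.centers
    horiz = np.linalg.norm(c[:, :2], axis=1)
    sel = np.nonzero((horiz <= radius_m) & (c[:, 2] >= -depth_m)
                     & (c[:, 2] <= 0.05))[0]
    if len(sel) == 0:
        raise SegmentationError(
            "no patches in the stump region; check that the frame is set "
            "(collar at origin, Z up) or widen the stump radius/depth")
    comps = connected_components(cover, sel)
    comps.sort(key=lambda comp: (-len(comp), min(comp)))
    return set(comps[0])


def detect_root_bases(cover: Cover, stump: set[int], cloud: PointCloud,
                      layers: int = 3, proximity: float = 0.5,
                      classify_taproot: bool = True,
                      stump_radius_m: float | None = None,
                      taproot_max_angle_deg: float = 30.0,
                      taproot_max_offset_factor: float = 1.0) -> list[RootBase]:
    """Detect first-order root bases around the stump.

    Expansion layer -> connected components -> keep components extensible
    away from the stump -> consolidate each with a cylinder fit, retaining
    patches whose centroid lies within ``proximity * radius`` of the
    cylinder surface. With ``classify_taproot``, the near-vertical,
    axis-centred base (the taproot continuing below the stump band) is
    relabelled order 0.
    """
    if not stump:
        raise SegmentationError("stump patch set is empty")
    expansion = expand(cover, stump, layers)
    blocked = set(stump) | expansion
    comps = connected_components(cover, expansion)
    if stump_radius_m is None:
        sc = cover.centers[sorted(stump)]
        stump_radius_m = float(np.max(np.linalg.norm(sc[:, :2], axis=1))) if len(sc) else 0.2
    bases: list[RootBase] = []
    assigned: set[int] = set()
    for comp in comps:
        ext = expand(cover, comp, 1) - blocked - assigned
        if not ext:
            continue    # not extensible away from the stump
        cand = sorted(comp | ext)
        pts = np.concatenate([cloud.points[cover.patches[p]] for p in cand])
        try:
            fit = fit_cylinder(pts)
            centers = cover.centers[cand]
            w = centers - fit.axis_point
            axial = w @ fit.direction
            dist = np.linalg.norm(w - np.outer(axial, fit.direction), axis=1)
            keep = [p for p, d in zip(cand, dist)
                    if abs(d - fit.radius) <= proximity * fit.radius]
            if not keep:
                keep = sorted(comp)
            base = RootBase(set(keep), fit.axis_point, fit.direction,
                            fit.radius, consolidated=True)
        except Exception:
            warnings.warn("base cylinder fit failed; keeping raw component")
            base = RootBase(set(comp), consolidated=False)
        assigned |= base.patches
        bases.append(base)
    # deduplicate: a leftover surface arc of an already-detected root can
    # form a second, stub base; merge bases whose cylinders are nearly
    # parallel, co-axial and close together (opposite collinear roots are
    # protected by the centroid-distance bound)
    near_m = max(0.1, 2.0 * cover.patch_diam_mm / 1000.0)
    merged_flags = [False] * len(bases)
    deduped: list[RootBase] = []
    for i, a in enumerate(bases):
        if merged_flags[i]:
            continue
        if a.axis_dir is not None:
            ca = cover.centers[sorted(a.patches)].mean(axis=0)
            for j in range(i + 1, len(bases)):
                b = bases[j]
                if merged_flags[j]:
                    continue
                if (b.axis_dir is not None
                        and abs(float(np.dot(a.axis_dir, b.axis_dir))) <= 0.906):
                    continue
                cb = cover.centers[sorted(b.patches)].mean(axis=0)
                if float(np.linalg.norm(cb - ca)) > near_m:
                    continue
                w = cb - a.axis_point
                off = w - np.dot(w, a.axis_dir) * a.axis_dir
                b_rad = b.radius if b.radius is not None else a.radius
                if float(np.linalg.norm(off)) <= 2.0 * max(a.radius, b_rad):
                    a.patches |= b.patches
                    merged_flags[j] = True
        deduped.append(a)
    bases = deduped
    if classify_taproot and bases:
        cos_thr = np.cos(np.deg2rad(taproot_max_angle_deg))
        candidates = []
        for i, b in enumerate(bases):
            if b.axis_dir is None:
                continue
            centroid = cover.centers[sorted(b.patches)].mean(axis=0)
            offset = float(np.linalg.norm(centroid[:2]))
            if (abs(b.axis_dir[2]) >= cos_thr
                    and offset <= taproot_max_offset_factor * stump_radius_m):
                candidates.append((len(b.patches), -i))
        if candidates:
            _, neg_i = max(candidates)
            bases[-neg_i].order = 0
    return bases


def _components_within(cover: Cover, cand: list[int]) -> list[set[int]]:
    """Connected components of the adjacency subgraph induced on cand."""
    cand_set = set(cand)
    comps = []
    unvisited = set(cand)
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


def _reach_count(cover: Cover, comp: set[int], state: np.ndarray,
                 exclude: set[int], steps: int = 2) -> int:
    """Unassigned patches reachable from comp in <= steps, excluding the
    other front components — the persistence measure for branch spawning."""
    seen = set(comp) | exclude
    frontier = set(comp)
    gained = 0
    for _ in range(steps):
        nxt = set()
        for pid in frontier:
            for nb in cover.neighbors[pid]:
                nb = int(nb)
                if nb not in seen and state[nb] == -1:
                    nxt.add(nb)
        if not nxt:
            break
        gained += len(nxt)
        seen |= nxt
        frontier = nxt
    return gained


def segment_roots(cover: Cover, bases: list[RootBase], stump: set[int],
                  min_persist: int = 3,
                  spawn_max_cos: float = 0.82) -> list[Segment]:
    """Grow a segment from each base through unassigned patches.

    Fronts advance one adjacency layer at a time. When a front splits,
    the component best aligned with the running direction (largest
    absolute cosine; ties by size then smallest id) continues the
    segment; other persistent components spawn child segments only when
    they actually diverge (|cos| below ``spawn_max_cos``, about 35
    degrees) — aligned components are kept in the front, since occlusion
    shadows routinely split the arc of one and the same root. Patches
    unreachable from any base stay unassigned (see
    :func:`unassigned_patches`).
    """
    state = np.full(cover.n_patches, -1, dtype=np.int64)
    state[sorted(stump)] = -2
    segments: list[Segment] = []
    queue: list[int] = []
    for base in bases:
        layer = sorted(base.patches)
        state[layer] = len(segments)
        seg = Segment([layer], [_layer_centroid(cover, layer)],
                      order_hint=(0 if base.order == 0 else None))
        queue.append(len(segments))
        segments.append(seg)
    qi = 0
    while qi < len(queue):
        sid = queue[qi]
        qi += 1
        seg = segments[sid]
        while True:
            front = seg.layers[-1]
            cand = sorted({int(nb) for p in front for nb in cover.neighbors[p]
                           if state[nb] == -1})
            if not cand:
                # stall rescue: when the point density is marginal for this
                # PatchDiam the adjacency graph is ragged; bridge a single
                # missing hop to unassigned patches two steps away
                one_step = {int(nb) for p in front for nb in cover.neighbors[p]}
                cand = sorted({int(q) for m in one_step
                               for q in cover.neighbors[m]
                               if state[q] == -1})
            if not cand:
                break
            comps = _components_within(cover, cand)
            if len(comps) == 1:
                nxt = cand
            else:
                cand_set = set(cand)
                persistent, absorbed = [], []
                for comp in comps:
                    reach = _reach_count(cover, comp, state, cand_set - comp)
                    if len(comp) + reach >= min_persist:
                        persistent.append(comp)
                    else:
                        absorbed.append(comp)
                if len(persistent) <= 1:
                    nxt = cand
                else:
                    c_last = seg.centroids[-1]
                    if len(seg.centroids) >= 2:
                        back = seg.centroids[max(0, len(seg.centroids) - 4)]
                        dirv = c_last - back
                        nv = np.linalg.norm(dirv)
                        dirv = dirv / nv if nv > 0 else None
                    else:
                        dirv = None
                    scored = []
                    for comp in persistent:
                        v = _layer_centroid(cover, sorted(comp)) - c_last
                        nv = np.linalg.norm(v)
                        if dirv is None or nv == 0:
                            score = 1.0
                        else:
                            score = abs(float(np.dot(v / nv, dirv)))
                        scored.append((score, len(comp), -min(comp), comp))
                    scored.sort(key=lambda t: (t[0], t[1], t[2]), reverse=True)
                    cont = set(scored[0][3])
                    spawners = []
                    for score, _, _, comp in scored[1:]:
                        if score >= spawn_max_cos:
                            cont |= comp     # same-root arc, keep in front
                        else:
                            spawners.append(comp)
                    for comp in absorbed:
                        cont |= comp
                    nxt = sorted(cont)
                    for comp in spawners:
                        layer = sorted(comp)
                        state[layer] = len(segments)
                        child = Segment([layer],
                                        [_layer_centroid(cover, layer)],
                                        parent=sid,
                                        branch_layer=len(seg.layers) - 1)
                        queue.append(len(segments))
                        segments.append(child)
            state[nxt] = sid
            seg.layers.append(nxt)
            seg.centroids.append(_layer_centroid(cover, nxt))
    return segments


def unassigned_patches(cover: Cover, segments: list[Segment],
                       stump: set[int]) -> set[int]:
    """Patches belonging to no segment and not in the stump."""
    used = set(stump)
    for seg in segments:
        used.update(seg.patches)
    return set(range(cover.n_patches)) - used


def _chain_straightness(centroids: list[np.ndarray]) -> float:
    c = np.asarray(centroids)
    if len(c) < 2:
        return 1.0
    path = float(np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1)))
    if path == 0:
        return 1.0
    return float(np.linalg.norm(c[-1] - c[0])) / path


def merge_segments(segments: list[Segment],
                   straightness: float = 0.9) -> list[Segment]:
    """Merge child segments into parents across branch points whenever the
    merged chain keeps chord/path >= ``straightness``; iterated to a fixed
    point, applying at each step the merge with the highest merged
    straightness (ties by smaller parent id, then child id). The portion
    of the parent beyond the branch point becomes a child of the merged
    segment and is marked as cut: it cannot itself re-merge into its
    parent (that re-merge would undo the cut and cycle forever), which
    bounds the iteration by the initial segment count. Topology is
    re-linked consistently."""
    segs: list[Segment | None] = [
        Segment(list(s.layers), list(s.centroids), s.parent, s.branch_layer,
                s.order_hint, s.is_stump)
        for s in segments
    ]
    frozen: set[int] = set()       # cut remainders: never re-merged

    def _path(cent: list[np.ndarray]) -> float:
        if len(cent) < 2:
            return 0.0
        c = np.asarray(cent)
        return float(np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1)))

    def cand_straightness(cid: int) -> float:
        c = segs[cid]
        if c is None or c.parent is None or cid in frozen:
            return -1.0
        p = segs[c.parent]
        # the order-0 chain (stump + taproot continuation) is never re-routed
        # through a lateral; only an order-0 child may extend it
        if (p.is_stump or p.order_hint == 0) and c.order_hint != 0:
            return -1.0
        i = c.branch_layer
        # merging re-routes the parent through the child; only do so when the
        # child is at least as long a continuation as the parent's own tail,
        # otherwise a short side strip could hijack a long parent
        if _path(p.centroids[i + 1:]) > _path(c.centroids) + 1e-12:
            return -1.0
        merged = p.centroids[:i + 1] + c.centroids
        return _chain_straightness(merged)

    svals = {cid: cand_straightness(cid) for cid in range(len(segs))}
    while True:
        best = None
        for cid, sval in svals.items():
            if sval >= straightness:
                key = (-sval, segs[cid].parent, cid)
                if best is None or key < best[0]:
                    best = (key, segs[cid].parent, cid, segs[cid].branch_layer)
        if best is None:
            break
        _, pid, cid, i = best
        p, c = segs[pid], segs[cid]
        old_children_p = [x_id for x_id, x in enumerate(segs)
                          if x is not None and x.parent == pid and x_id != cid]
        old_children_c = [x_id for x_id, x in enumerate(segs)
                          if x is not None and x.parent == cid]
        r_layers = p.layers[i + 1:]
        r_cent = p.centroids[i + 1:]
        p.layers = p.layers[:i + 1] + c.layers
        p.centroids = p.centroids[:i + 1] + c.centroids
        rid = None
        if r_layers:
            segs[cid] = Segment(r_layers, r_cent, parent=pid, branch_layer=i,
                                order_hint=p.order_hint, is_stump=p.is_stump)
            rid = cid
            frozen.add(cid)
        else:
            segs[cid] = None
            frozen.discard(cid)
        for x_id in old_children_p:
            x = segs[x_id]
            if x.branch_layer > i:
                if rid is not None:
                    x.parent = rid
                    x.branch_layer = x.branch_layer - (i + 1)
                else:     # pragma: no cover - branch beyond tip impossible
                    x.branch_layer = i
        for x_id in old_children_c:
            segs[x_id].parent = pid
            segs[x_id].branch_layer = i + 1 + segs[x_id].branch_layer
        # refresh cached straightness of every affected candidate
        touched = {cid} | set(old_children_p) | set(old_children_c)
        touched.update(x_id for x_id, x in enumerate(segs)
                       if x is not None and x.parent == pid)
        for x_id in touched:
            svals[x_id] = cand_straightness(x_id)
    # compact, remapping parent ids
    remap: dict[int, int] = {}
    out: list[Segment] = []
    for old_id, s in enumerate(segs):
        if s is not None:
            remap[old_id] = len(out)
            out.append(s)
    for s in out:
        if s.parent is not None:
            s.parent = remap[s.parent]
    return out
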