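"""Cylinder modelling of segments and QSM assembly.

Each segment is walked from base to tip. At every position a series of
candidate cylinder lengths (multiples of PatchDiam) is evaluated: each
candidate window is fitted independently and scored by surface coverage,
and the highest-coverage cylinder is emitted (ties favour the longest
candidate, giving fewer, longer cylinders). Each fit is initialized from
the previous cylinder's direction so the chain adapts to local
curvature; consecutive cylinders share endpoints. The full chain
``generate_cover -> find_stump -> detect_root_bases -> segment_roots ->
merge_segments -> model_segment`` is deterministic given (cloud,
PatchDiam, seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import QsmConfig
from .cover import Cover, generate_cover
from .errors import FitError
from .fitting import CylinderFit, fit_cylinder, surface_coverage
from .pointcloud import PointCloud
from .segmentation import (Segment, detect_root_bases, estimate_taproot_radius,
                           find_stump, merge_segments, segment_roots)

__all__ = ["Cylinder", "Qsm", "model_segment", "build_qsm",
           "qsm_to_dataframe", "write_qsm", "write_obj"]


@dataclass
class Cylinder:
    """One fitted cylinder of a QSM."""

    start: np.ndarray          # (3,) m
    axis: np.ndarray           # (3,) unit
    length: float              # m
    radius: float              # m
    cyl_id: int = -1
    parent: int | None = None
    segment: int = -1
    order: int | None = None
    coverage: float = 0.0

    @property
    def end(self) -> np.ndarray:
        return self.start + self.axis * self.length

    @property
    def midpoint(self) -> np.ndarray:
        return self.start + self.axis * (0.5 * self.length)

    @property
    def volume(self) -> float:
        return float(np.pi * self.radius ** 2 * self.length)


@dataclass
class Qsm:
    """A quantitative structure model: a rooted tree of fitted cylinders."""

    cylinders: list[Cylinder]
    segments: list[Segment]
    provenance: dict

    def total_volume(self) -> float:
        return float(sum(c.volume for c in self.cylinders))

    def total_length(self) -> float:
        return float(sum(c.length for c in self.cylinders))


def _segment_point_s(segment: Segment, cover: Cover):
    """Per-point arclength coordinates along the segment centroid chain."""
    c = np.asarray(segment.centroids)
    if len(c) > 1:
        steps = np.linalg.norm(np.diff(c, axis=0), axis=1)
        s_layer = np.concatenate([[0.0], np.cumsum(steps)])
    else:
        s_layer = np.zeros(1)
    idx_list, s_list = [], []
    for k, layer in enumerate(segment.layers):
        for p in layer:
            members = cover.patches[p]
            idx_list.append(members)
            s_list.append(np.full(len(members), s_layer[k]))
    idx = np.concatenate(idx_list)
    s = np.concatenate(s_list)
    return idx, s, float(s_layer[-1])


def _fallback_cylinder(pts: np.ndarray, direction: np.ndarray) -> CylinderFit:
    """Axis through the centroid along a given direction; radius from the
    median orthogonal distance. Used when the least-squares fit fails."""
    center = pts.mean(axis=0)
    w = pts - center
    axial = w @ direction
    perp = np.linalg.norm(w - np.outer(axial, direction), axis=1)
    radius = max(float(np.median(perp)), 1e-4)
    return CylinderFit(center, direction, radius, float(np.std(perp)))


def model_segment(segment: Segment, cloud: PointCloud, cover: Cover,
                  length_multipliers=(2.0, 3.0, 4.0, 6.0),
                  n_azimuth_cells: int = 8,
                  init_direction=None, start_point=None) -> list[Cylinder]:
    """Fit a cylinder chain along one segment (see module docstring).

    Windows with fewer than 6 points are extended to the next candidate
    length; a tip remainder shorter than the smallest candidate is
    absorbed into the final cylinder.
    """
    if not segment.layers or not segment.patches:
        return []
    if sum(len(cover.patches[p]) for layer in segment.layers
           for p in layer) < 6:
        return []
    pd_m = cover.patch_diam_mm / 1000.0
    idx, s, total = _segment_point_s(segment, cover)
    pts_all = cloud.points[idx]
    lengths = sorted(float(m) * pd_m for m in length_multipliers)
    min_len = lengths[0]
    cyls: list[Cylinder] = []
    prev_dir = None
    if init_direction is not None:
        nv = np.linalg.norm(init_direction)
        if nv > 0:
            prev_dir = np.asarray(init_direction, dtype=np.float64) / nv
    if prev_dir is None and len(segment.centroids) >= 2:
        v = (segment.centroids[min(3, len(segment.centroids) - 1)]
             - segment.centroids[0])
        nv = np.linalg.norm(v)
        if nv > 0:
            prev_dir = v / nv
    prev_end = None if start_point is None else np.asarray(start_point, float)
    s0 = 0.0
    eps = 1e-9
    history: list[tuple] = []   # (s0, prev_dir, prev_end) before each emitted cylinder

    def fit_window(lo, hi, closed, pdir, pend):
        """Fit + score one window [lo, hi) (or closed [lo, hi])."""
        mask = (s >= lo - eps) & (s <= hi + eps if closed else s < hi - eps)
        if int(mask.sum()) < 6:
            return None
        wpts = pts_all[mask]
        # fitting saturates quickly with point count; subsample large
        # windows (deterministic stride) and keep the full set for coverage
        if len(wpts) > 160:
            fpts = wpts[np.linspace(0, len(wpts) - 1, 160).astype(np.int64)]
        else:
            fpts = wpts
        try:
            fit = fit_cylinder(fpts, initial_axis=pdir)
            # a flat or one-sided window can support an absurdly large
            # radius at tiny residual; bound it by the point spread
            diag = float(np.linalg.norm(wpts.max(axis=0) - wpts.min(axis=0)))
            if fit.radius > 0.75 * diag:
                raise FitError("radius exceeds window extent")
        except FitError:
            if pdir is None:
                return None
            fit = _fallback_cylinder(fpts, pdir)
        cyl = _chain_cylinder(fit, wpts, pdir, pend)
        if cyl is None:
            return None
        n_h = max(1, round(cyl.length / pd_m))
        cyl.coverage = surface_coverage(wpts, cyl, n_azimuth_cells, n_h)
        return cyl

    while s0 < total - eps or (s0 == 0.0 and not cyls):
        remaining = total - s0
        if remaining < min_len - eps and cyls:
            # tip remainder shorter than the smallest candidate: absorb it
            # into the final cylinder by refitting its window extended to the tip
            s_prev, pdir, pend = history[-1]
            refit = fit_window(s_prev, total, True, pdir, pend)
            if refit is not None:
                cyls[-1] = refit
            break
        candidates = []
        for L in lengths:
            closed = L >= remaining - eps
            cyl = fit_window(s0, min(s0 + L, total), closed, prev_dir, prev_end)
            if cyl is not None:
                candidates.append((cyl.coverage, L, cyl))
            if closed:
                break
        if not candidates:
            s0 += min_len      # sparse stretch: skip ahead
            if s0 >= total - eps:
                break
            continue
        chosen = max(candidates, key=lambda c: (c[0], c[1]))
        assert all(chosen[0] >= c[0] for c in candidates)
        _, L_used, cyl = chosen
        history.append((s0, prev_dir, prev_end))
        cyls.append(cyl)
        prev_dir = cyl.axis
        prev_end = cyl.end
        s0 += L_used
        if s0 == 0.0:          # degenerate single-layer segment
            break
    return cyls


def _chain_cylinder(fit: CylinderFit, wpts: np.ndarray, prev_dir, prev_end):
    """Turn a window fit into a chained cylinder: orient along the walk,
    clip to the axial extent of the window points, snap the start to the
    previous cylinder's end."""
    d = fit.direction.copy()
    if prev_dir is not None and np.dot(d, prev_dir) < 0:
        d = -d
    h = (wpts - fit.axis_point) @ d
    hmin, hmax = float(h.min()), float(h.max())
    if hmax - hmin <= 1e-9:
        return None
    p0 = fit.axis_point + hmin * d
    p1 = fit.axis_point + hmax * d
    if prev_end is not None:
        start = prev_end
        v = p1 - start
        nv = np.linalg.norm(v)
        if nv <= 1e-9:
            return None
        axis = v / nv
        length = nv
    else:
        start, axis, length = p0, d, hmax - hmin
    return Cylinder(start=np.asarray(start, float), axis=axis,
                    length=float(length), radius=float(fit.radius))


def _stump_segment(cover: Cover, stump: set[int]) -> Segment:
    """Layer the stump patches by adjacency BFS from the patch nearest the
    collar, producing the order-0 segment the QSM tree is rooted at."""
    from .segmentation import _layer_centroid

    stump_sorted = sorted(stump)
    start = min(stump_sorted,
                key=lambda p: (np.linalg.norm(cover.centers[p]), p))
    layers = []
    seen = {start}
    frontier = [start]
    while frontier:
        layers.append(sorted(frontier))
        nxt = set()
        for pid in frontier:
            for nb in cover.neighbors[pid]:
                nb = int(nb)
                if nb in stump and nb not in seen:
                    seen.add(nb)
                    nxt.add(nb)
        frontier = sorted(nxt)
    for p in stump_sorted:        # isolated stump patches: keep partition exhaustive
        if p not in seen:
            layers.append([p])
    cents = [_layer_centroid(cover, layer) for layer in layers]
    return Segment(layers, cents, parent=None, order_hint=0, is_stump=True)


def build_qsm(cloud: PointCloud, patch_diam_mm: float, seed: int,
              config: QsmConfig | None = None) -> Qsm:
    """Run the full reconstruction chain and assemble the QSM."""
    cfg = config or QsmConfig()
    cover = generate_cover(cloud, patch_diam_mm, seed=seed,
                           adjacency_factor=cfg.cover_adjacency_factor)
    stump_radius = (cfg.stump_radius_m if cfg.stump_radius_m is not None
                    else cfg.stump_radius_factor * estimate_taproot_radius(cloud))
    stump = find_stump(cover, cloud, radius_m=stump_radius,
                       depth_m=cfg.stump_depth_m)
    bases = detect_root_bases(
        cover, stump, cloud, layers=cfg.segmentation_base_layers,
        proximity=cfg.segmentation_proximity, classify_taproot=True,
        stump_radius_m=stump_radius,
        taproot_max_angle_deg=cfg.taproot_max_angle_deg,
        taproot_max_offset_factor=cfg.taproot_max_offset_factor)
    stump_seg = _stump_segment(cover, stump)
    laterals = segment_roots(cover, bases, stump,
                             min_persist=cfg.segmentation_min_persist)
    segments = [stump_seg]
    for seg in laterals:
        if seg.parent is None:
            # base segment: attaches to the nearest stump layer
            d = [np.linalg.norm(c - seg.centroids[0])
                 for c in stump_seg.centroids]
            seg.parent = 0
            seg.branch_layer = int(np.argmin(d))
        else:
            seg.parent += 1
        segments.append(seg)
    segments = merge_segments(segments, straightness=cfg.segmentation_straightness)
    cylinders: list[Cylinder] = []
    seg_first_cyl: dict[int, int] = {}
    seg_cyl_ids: dict[int, list[int]] = {}
    for sid, seg in enumerate(segments):
        init_dir = None
        start_point = None
        chain = model_segment(seg, cloud, cover,
                              length_multipliers=cfg.cyl_length_multipliers,
                              n_azimuth_cells=cfg.cyl_azimuth_cells,
                              init_direction=init_dir, start_point=start_point)
        ids = []
        for k, cyl in enumerate(chain):
            cyl.cyl_id = len(cylinders)
            cyl.segment = sid
            cyl.parent = cylinders[-1].cyl_id if k > 0 else None
            if k > 0:
                cyl.parent = ids[-1]
            ids.append(cyl.cyl_id)
            cylinders.append(cyl)
        if ids:
            seg_first_cyl[sid] = ids[0]
            seg_cyl_ids[sid] = ids
    # attach each child segment's first cylinder to its parent's chain
    for sid, seg in enumerate(segments):
        if sid not in seg_first_cyl or seg.parent is None:
            continue
        first = cylinders[seg_first_cyl[sid]]
        parent_ids = _nearest_ancestor_chain(segments, seg, seg_cyl_ids)
        if not parent_ids:
            continue
        best = None
        for pcid in parent_ids:
            pc = cylinders[pcid]
            t = np.clip(np.dot(first.start - pc.start, pc.axis), 0.0, pc.length)
            foot = pc.start + t * pc.axis
            dist = float(np.linalg.norm(first.start - foot))
            if best is None or dist < best[0]:
                best = (dist, pcid, foot)
        _, pcid, foot = best
        first.parent = pcid
        end = first.end
        v = end - foot
        nv = np.linalg.norm(v)
        if nv > 1e-9:
            first.start = foot
            first.axis = v / nv
            first.length = float(nv)
    # taproot chain recovery: front growth can wander off the taproot into a
    # lateral at a junction, leaving the remaining vertical chain as a
    # "child"; any segment that is near-vertical and hugs the collar axis is
    # part of the order-0 taproot column, wherever it ended up in the tree
    cos_thr = np.cos(np.deg2rad(cfg.taproot_max_angle_deg))
    off_max = cfg.taproot_max_offset_factor * stump_radius
    for sid, ids in seg_cyl_ids.items():
        seg = segments[sid]
        if seg.order_hint == 0 or seg.is_stump:
            continue
        hits = 0
        for i in ids:
            c = cylinders[i]
            mid = c.midpoint
            if (abs(c.axis[2]) >= cos_thr
                    and float(np.hypot(mid[0], mid[1])) <= off_max):
                hits += 1
        if hits >= 0.7 * len(ids):
            seg.order_hint = 0
    # a lateral whose base sits on the taproot column emerges from the
    # taproot and is first-order by the centrifugal definition, even when
    # the growth attached its segment to a neighbouring lateral. Two
    # exclusions keep the rule honest: short junction splinters (a surface
    # root is decimetres long) and fragment strips that run parallel to
    # the segment they attach to (same-root duplicates; a real root leaves
    # its neighbour at a branching angle)
    for sid, ids in seg_cyl_ids.items():
        seg = segments[sid]
        if seg.order_hint is not None or seg.is_stump:
            continue
        first = cylinders[ids[0]]
        chain_len = sum(cylinders[i].length for i in ids)
        if (float(np.hypot(first.start[0], first.start[1])) > off_max
                or chain_len < 0.3):
            continue
        parent_cyl = (cylinders[first.parent]
                      if first.parent is not None else None)
        if parent_cyl is not None and not segments[parent_cyl.segment].is_stump \
                and segments[parent_cyl.segment].order_hint != 0:
            # compare whole-chain chord directions: junction-window axes
            # are too noisy to tell a diverging root from a parallel strip
            pids = seg_cyl_ids[parent_cyl.segment]
            v_child = cylinders[ids[-1]].end - first.start
            v_parent = (cylinders[pids[-1]].end - cylinders[pids[0]].start)
            nc, npar = np.linalg.norm(v_child), np.linalg.norm(v_parent)
            if nc > 0 and npar > 0:
                cosang = abs(float(np.dot(v_child, v_parent))) / (nc * npar)
                if cosang > 0.906:   # within ~25 deg: parallel strip
                    continue
        seg.order_hint = 1
    # taper sanity: a child cylinder cannot be much fatter than its parent
    # (mixed-root windows near junctions otherwise produce runaway radii)
    for cyl in cylinders:
        if cyl.parent is not None:
            cyl.radius = float(min(cyl.radius,
                                   1.2 * cylinders[cyl.parent].radius))
    # radius regularization: a poorly covered window (junction clutter,
    # occlusion shadow) cannot anchor a radius; rein it in toward the
    # well-covered radii of its own segment. Additionally, a root tapers,
    # so no cylinder may be fatter than twice its segment's median radius
    # — base windows of lateral segments otherwise inherit the parent
    # root's (or taproot's) surface and inflate the volume severely
    for sid, ids in seg_cyl_ids.items():
        radii = [cylinders[i].radius for i in ids]
        r_med = float(np.median(radii))
        trusted = [cylinders[i].radius for i in ids
                   if cylinders[i].coverage >= 0.5]
        r_ref = float(np.median(trusted)) if trusted else r_med
        for i in ids:
            if cylinders[i].coverage < 0.3:
                cylinders[i].radius = float(min(cylinders[i].radius,
                                                1.3 * r_ref))
        # junction guard: the first windows of a lateral segment often sit
        # on the parent root's (or taproot's) surface; a root tapers, so
        # its base cannot be much fatter than its distal body
        if (len(ids) >= 4 and not segments[sid].is_stump
                and segments[sid].order_hint != 0):
            distal = [cylinders[i].radius for i in ids[len(ids) // 2:]]
            cap = 1.5 * float(np.median(distal))
            for i in ids[:max(1, len(ids) // 4)]:
                cylinders[i].radius = float(min(cylinders[i].radius, cap))
    from .traits import assign_orders
    qsm = Qsm(cylinders, segments,
              provenance={"patch_diam_mm": float(patch_diam_mm),
                          "seed": int(seed),
                          "config_hash": cfg.config_hash(),
                          "n_points": len(cloud)})
    assign_orders(qsm, max_order=cfg.max_order)
    return qsm


def _nearest_ancestor_chain(segments, seg, seg_cyl_ids):
    """Cylinder ids of the closest ancestor segment that has cylinders."""
    pid = seg.parent
    seen = set()
    while pid is not None and pid not in seen:
        seen.add(pid)
        if pid in seg_cyl_ids:
            return seg_cyl_ids[pid]
        pid = segments[pid].parent
    return []


_QSM_COLUMNS = ["cyl_id", "parent", "segment", "order",
                "start_x", "start_y", "start_z",
                "axis_x", "axis_y", "axis_z",
                "length_m", "radius_m", "coverage"]


def qsm_to_dataframe(qsm: Qsm) -> pd.DataFrame:
    rows = []
    for c in qsm.cylinders:
        rows.append([c.cyl_id, -1 if c.parent is None else c.parent,
                     c.segment, -1 if c.order is None else c.order,
                     c.start[0], c.start[1], c.start[2],
                     c.axis[0], c.axis[1], c.axis[2],
                     c.length, c.radius, c.coverage])
    return pd.DataFrame(rows, columns=_QSM_COLUMNS)


def write_qsm(qsm: Qsm, path) -> None:
    """Tabular text export, one cylinder per row (documented header)."""
    df = qsm_to_dataframe(qsm)
    with open(path, "w") as fh:
        fh.write("# rootqsm cylinder table; units: metres; parent/order -1 = none\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def write_obj(qsm: Qsm, path, sides: int = 12) -> None:
    """OBJ mesh export (open-ended tubes) for visual inspection."""
    from .fitting import perp_basis

    with open(path, "w") as fh:
        fh.write("# rootqsm QSM mesh\n")
        base = 1
        for c in qsm.cylinders:
            u, v = perp_basis(c.axis)
            ang = np.linspace(0, 2 * np.pi, sides, endpoint=False)
            ring = c.radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
            for p in c.start + ring:
                fh.write(f"v {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            for p in c.end + ring:
                fh.write(f"v {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            for k in range(sides):
                k2 = (k + 1) % sides
                a, b = base + k, base + k2
                a2, b2 = base + sides + k, base + sides + k2
                fh.write(f"f {a} {b} {b2} {a2}\n")
            base += 2 * sides
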