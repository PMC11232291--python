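"""Procedural root systems with known ground truth, a simulated
terrestrial laser scanner, and an emulated contact digitizer.

The generator builds a taproot plus first- to third-order lateral roots
as tapered polyline chains (conical frusta between consecutive points),
with azimuthal asymmetry, branching-angle and curvature control, sized
to emulate excavated mature-conifer root systems (about 1-1.5 m deep,
extending about 1.5 m horizontally). The scanner casts rays from a few
lateral viewpoints (default three at 120 degrees), keeps the nearest
cylinder intersection (occlusion) and perturbs the range with Gaussian
noise. The digitizer samples polyline points along each root — closely
on curved roots, sparsely on straight ones — with true local diameters,
yielding a reference record in the digitized-measurement dialect.

Every output carries ground-truth labels so whole-pipeline parameter
recovery can be measured without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyCloudError, ParameterError
from .pointcloud import FRAME_ROOT, PointCloud
from .reference import REFERENCE_COLUMNS, ReferenceRecord, reference_traits
from .traits import RootTraits

__all__ = ["RootSystemSpec", "TruthRoot", "TruthSystem", "ScannerSpec",
           "ScanResult", "generate_system", "scan_system", "digitize_system"]


@dataclass
class RootSystemSpec:
    """Parameters of a procedural root system.

    Lengths/radii in metres; angles in degrees. Quadrant weights order is
    (N, E, S, W) and must sum to 1. Defaults emulate the excavated root
    systems of a mature conifer: 1.2 m taproot, ten first-order laterals
    reaching ~1.5 m horizontally, second/third-order branching, more
    roots on the downslope (N) and windward (W) sides.
    """

    taproot_depth_m: float = 1.2
    taproot_basal_radius_m: float = 0.07
    taproot_tip_radius_m: float = 0.02
    n_first_order: int = 10
    first_radius_range_m: tuple[float, float] = (0.016, 0.026)
    first_length_range_m: tuple[float, float] = (1.0, 1.6)
    second_per_first: float = 1.0      # Poisson mean
    third_per_second: float = 0.5      # Poisson mean
    second_length_range_m: tuple[float, float] = (0.4, 0.8)
    third_length_range_m: tuple[float, float] = (0.2, 0.4)
    child_radius_ratio: tuple[float, float] = (0.6, 0.75)
    child_attach_frac: tuple[float, float] = (0.15, 0.55)
    branch_angle_deg: tuple[float, float] = (40.0, 70.0)
    first_elevation_deg: tuple[float, float] = (5.0, 35.0)  # below horizontal
    attach_depth_range_m: tuple[float, float] = (0.05, 0.7)
    taper_tip_fraction: float = 0.4
    quadrant_weights: tuple[float, float, float, float] = (0.35, 0.15, 0.20, 0.30)
    curvature_deg_per_step: float = 3.0
    step_m: float = 0.05
    min_radius_m: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        w = np.asarray(self.quadrant_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ParameterError("quadrant weights must be >= 0 and sum to 1")
        if self.taproot_basal_radius_m <= 0 or self.taproot_depth_m <= 0:
            raise ParameterError("taproot dimensions must be positive")


@dataclass
class TruthRoot:
    """One generative root: a tapered polyline with per-point radii."""

    root_id: int
    parent_id: int        # -1 for the taproot
    order: int
    points: np.ndarray    # (M, 3) m
    radii: np.ndarray     # (M,) m, linear taper between points

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def arclengths(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class TruthSystem:
    """The generative root system with analytic traits and truth labels."""

    roots: list[TruthRoot]
    spec: RootSystemSpec

    def to_reference_record(self) -> ReferenceRecord:
        """Native-resolution reference record (every generative point)."""
        rows = []
        for r in self.roots:
            for k in range(len(r.points)):
                rows.append([r.root_id, r.parent_id, r.order, k,
                             *r.points[k], 2.0 * r.radii[k] * 100.0,
                             np.nan, np.nan])
        return ReferenceRecord(
            pd.DataFrame(rows, columns=REFERENCE_COLUMNS))

    def truth_traits(self, min_proximal_diam_cm: float = 1.0,
                     depth_threshold_m: float = 0.30,
                     include_taproot: bool = False) -> RootTraits:
        """Analytic traits of the generative polylines (frustum volumes)."""
        return reference_traits(self.to_reference_record(),
                                min_proximal_diam_cm=min_proximal_diam_cm,
                                depth_threshold_m=depth_threshold_m,
                                include_taproot=include_taproot)


def _quadrant_azimuth(rng, weights) -> float:
    """Sample an azimuth (deg from north toward east) by quadrant weights."""
    k = rng.choice(4, p=np.asarray(weights, dtype=float))
    center = 90.0 * k      # N, E, S, W
    return float(np.mod(center + rng.uniform(-45.0, 45.0), 360.0))


def _unit_from_azimuth(az_deg: float) -> np.ndarray:
    """Horizontal unit vector at the given azimuth (+X north, +Y west)."""
    a = np.deg2rad(az_deg)
    return np.array([np.cos(a), -np.sin(a), 0.0])


def _perturb(rng, d: np.ndarray, sigma_deg: float) -> np.ndarray:
    """Rotate d by a N(0, sigma) angle about a random perpendicular axis."""
    if sigma_deg <= 0:
        return d
    ang = np.deg2rad(rng.normal(0.0, sigma_deg))
    raw = rng.normal(size=3)
    perp = raw - np.dot(raw, d) * d
    n = np.linalg.norm(perp)
    if n < 1e-12:
        return d
    perp /= n
    out = np.cos(ang) * d + np.sin(ang) * perp
    return out / np.linalg.norm(out)


def _grow_chain(rng, start, direction, length, r_base, r_tip, step,
                curvature_deg, max_up=0.05):
    """March a polyline from start along direction with curvature noise.

    Radii taper linearly from r_base to r_tip along arclength. The chain
    is kept from curling upward (vertical direction component clamped).
    """
    n_steps = max(1, int(round(length / step)))
    pts = [np.asarray(start, dtype=float)]
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    for _ in range(n_steps):
        pts.append(pts[-1] + d * (length / n_steps))
        d = _perturb(rng, d, curvature_deg)
        if d[2] > max_up:
            d[2] = max_up
            d = d / np.linalg.norm(d)
    pts = np.asarray(pts)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    radii = r_base + (r_tip - r_base) * s / max(s[-1], 1e-12)
    return pts, radii


def _local_frame(root: TruthRoot, s_target: float):
    """Point, direction and radius of a root at arclength s_target."""
    s = root.arclengths
    k = int(np.searchsorted(s, s_target, side="right") - 1)
    k = min(max(k, 0), len(s) - 2)
    seg = root.points[k + 1] - root.points[k]
    seg_len = max(np.linalg.norm(seg), 1e-12)
    frac = np.clip((s_target - s[k]) / seg_len, 0.0, 1.0)
    point = root.points[k] + frac * seg
    radius = root.radii[k] + frac * (root.radii[k + 1] - root.radii[k])
    return point, seg / seg_len, float(radius)


def generate_system(spec: RootSystemSpec) -> TruthSystem:
    """Build a procedural root system; deterministic per spec.seed."""
    rng = np.random.default_rng(spec.seed)
    roots: list[TruthRoot] = []
    # taproot: straight vertical tapered chain, order 0
    n_steps = max(1, int(round(spec.taproot_depth_m / spec.step_m)))
    z = np.linspace(0.0, -spec.taproot_depth_m, n_steps + 1)
    tap_pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    tap_r = np.linspace(spec.taproot_basal_radius_m, spec.taproot_tip_radius_m,
                        n_steps + 1)
    roots.append(TruthRoot(0, -1, 0, tap_pts, tap_r))
    next_id = 1

    def spawn(parent: TruthRoot, order: int, start, direction, length,
              r_base) -> TruthRoot | None:
        nonlocal next_id
        r_tip = spec.taper_tip_fraction * r_base
        if r_base < spec.min_radius_m:
            return None    # branch truncated: radius below the floor
        pts, radii = _grow_chain(rng, start, direction, length, r_base, r_tip,
                                 spec.step_m, spec.curvature_deg_per_step)
        root = TruthRoot(next_id, parent.root_id, order, pts, radii)
        next_id += 1
        roots.append(root)
        return root

    firsts: list[TruthRoot] = []
    for _ in range(spec.n_first_order):
        az = _quadrant_azimuth(rng, spec.quadrant_weights)
        depth = rng.uniform(*spec.attach_depth_range_m)
        u_h = _unit_from_azimuth(az)
        _, _, tap_radius = _local_frame(roots[0], depth)
        start = u_h * tap_radius + np.array([0.0, 0.0, -depth])
        r_base = min(rng.uniform(*spec.first_radius_range_m), 0.8 * tap_radius)
        el = np.deg2rad(rng.uniform(*spec.first_elevation_deg))
        direction = np.cos(el) * u_h - np.sin(el) * np.array([0.0, 0.0, 1.0])
        length = rng.uniform(*spec.first_length_range_m)
        root = spawn(roots[0], 1, start, direction, length, r_base)
        if root is not None:
            firsts.append(root)

    def spawn_children(parent: TruthRoot, mean_count: float, order: int,
                       length_range) -> list[TruthRoot]:
        out = []
        for _ in range(rng.poisson(mean_count)):
            frac = rng.uniform(*spec.child_attach_frac)
            point, d_par, r_par = _local_frame(parent, frac * parent.length)
            ratio = rng.uniform(*spec.child_radius_ratio)
            r_base = min(ratio * r_par, 0.9 * r_par)
            ang = np.deg2rad(rng.uniform(*spec.branch_angle_deg))
            raw = rng.normal(size=3)
            perp = raw - np.dot(raw, d_par) * d_par
            n = np.linalg.norm(perp)
            if n < 1e-12:
                continue
            perp /= n
            direction = np.cos(ang) * d_par + np.sin(ang) * perp
            if direction[2] > 0.05:    # keep laterals from shooting upward
                direction[2] = 0.05
                direction /= np.linalg.norm(direction)
            length = rng.uniform(*length_range)
            child = spawn(parent, order, point, direction, length, r_base)
            if child is not None:
                out.append(child)
        return out

    seconds: list[TruthRoot] = []
    for f in firsts:
        seconds.extend(spawn_children(f, spec.second_per_first, 2,
                                      spec.second_length_range_m))
    for sroot in seconds:
        spawn_children(sroot, spec.third_per_second, 3,
                       spec.third_length_range_m)
    return TruthSystem(roots, spec)


# ---------------------------------------------------------------------------
# scanner


@dataclass
class ScannerSpec:
    """Simulated terrestrial laser scanner.

    Defaults follow the scanning setup this package emulates: three
    lateral viewpoints at 120-degree spacing within a 3-6 m range, 2 mm
    range noise (surface precision), 4 mm spot size (recorded for
    provenance; beam-footprint mixing is not simulated). The angular
    step controls the point density.
    """

    n_viewpoints: int = 3
    azimuths_deg: tuple[float, ...] | None = None   # default: even spacing
    range_m: float = 4.5
    height_m: float | None = None                   # default: scene mid-height
    noise_sigma_mm: float = 2.0
    spot_size_mm: float = 4.0
    angular_step_deg: float = 0.05
    occlusion: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_viewpoints < 1:
            raise ParameterError("at least one viewpoint required")
        if self.noise_sigma_mm < 0:
            raise ParameterError("noise sigma must be >= 0")

    def viewpoint_azimuths(self) -> np.ndarray:
        if self.azimuths_deg is not None:
            return np.asarray(self.azimuths_deg, dtype=float)
        return np.arange(self.n_viewpoints) * (360.0 / self.n_viewpoints)


@dataclass
class ScanResult:
    """A simulated scan: the merged cloud plus per-point truth labels."""

    cloud: PointCloud
    cylinder_id: np.ndarray
    root_id: np.ndarray
    order: np.ndarray
    viewpoint: np.ndarray


def _truth_cylinders(truth: TruthSystem):
    """Flatten the polylines into scan cylinders (mid-radius per step)."""
    starts, axes, lens, rads, roots_, orders = [], [], [], [], [], []
    for r in truth.roots:
        for k in range(len(r.points) - 1):
            seg = r.points[k + 1] - r.points[k]
            ell = np.linalg.norm(seg)
            if ell < 1e-9:
                continue
            starts.append(r.points[k])
            axes.append(seg / ell)
            lens.append(ell)
            rads.append(0.5 * (r.radii[k] + r.radii[k + 1]))
            roots_.append(r.root_id)
            orders.append(r.order)
    return (np.asarray(starts), np.asarray(axes), np.asarray(lens),
            np.asarray(rads), np.asarray(roots_, dtype=np.int64),
            np.asarray(orders, dtype=np.int64))


def scan_system(truth: TruthSystem, scanner: ScannerSpec) -> ScanResult:
    """Ray-cast the root system from each viewpoint.

    Rays on a regular angular grid intersect the generative cylinders
    exactly; with occlusion on, only the nearest intersection per ray is
    kept. Gaussian range noise is added along the ray. Points from all
    viewpoints are merged, each labelled with its true cylinder, root
    and order.
    """
    starts, axes, lens, rads, root_ids, orders = _truth_cylinders(truth)
    n_cyl = len(starts)
    if n_cyl == 0:
        raise EmptyCloudError("truth system has no cylinders")
    all_pts = np.concatenate([r.points for r in truth.roots])
    center = 0.5 * (all_pts.min(axis=0) + all_pts.max(axis=0))
    r_bound = float(np.max(np.linalg.norm(all_pts - center, axis=1))
                    + rads.max() + 0.05)
    rng = np.random.default_rng(scanner.seed)
    sigma_m = scanner.noise_sigma_mm / 1000.0
    step = np.deg2rad(scanner.angular_step_deg)
    height = (scanner.height_m if scanner.height_m is not None
              else float(center[2]))
    out_pts, out_cyl, out_vp = [], [], []
    for vp_idx, az in enumerate(scanner.viewpoint_azimuths()):
        v = _unit_from_azimuth(az) * scanner.range_m
        v = v + np.array([0.0, 0.0, height])
        to_c = center - v
        dist_c = np.linalg.norm(to_c)
        if dist_c <= r_bound:
            raise ParameterError("viewpoint inside the scene bounding sphere")
        u0 = to_c / dist_c
        e1 = np.cross(np.array([0.0, 0.0, 1.0]), u0)
        n1 = np.linalg.norm(e1)
        if n1 < 1e-9:        # pragma: no cover - viewpoint straight above
            e1 = np.array([1.0, 0.0, 0.0])
        else:
            e1 /= n1
        e2 = np.cross(u0, e1)
        alpha = np.arcsin(min(0.999, r_bound / dist_c))
        half = np.tan(alpha)
        m = int(np.ceil(2 * np.tan(alpha) / step)) + 1
        grid = np.linspace(-half, half, m)
        g1, g2 = np.meshgrid(grid, grid, indexing="ij")
        dirs = (u0[None, :] + g1.reshape(-1, 1) * e1[None, :]
                + g2.reshape(-1, 1) * e2[None, :])
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        n_rays = len(dirs)
        t_best = np.full(n_rays, np.inf)
        id_best = np.full(n_rays, -1, dtype=np.int64)
        extra_t, extra_id = [], []      # for occlusion-off mode
        for ci in range(n_cyl):
            mid = starts[ci] + 0.5 * lens[ci] * axes[ci]
            w = mid - v
            d_mid = np.linalg.norm(w)
            reach = 0.5 * lens[ci] + rads[ci] + 0.01
            if d_mid <= reach:
                sel = np.arange(n_rays)
            else:
                cos_r = np.sqrt(max(0.0, 1.0 - (reach / d_mid) ** 2))
                sel = np.nonzero(dirs @ (w / d_mid) >= cos_r - 1e-9)[0]
            if len(sel) == 0:
                continue
            d = dirs[sel]
            u = axes[ci]
            oc = v - starts[ci]
            du = d @ u
            ocu = float(oc @ u)
            a = 1.0 - du ** 2
            b = 2.0 * (d @ oc - du * ocu)
            cc = float(oc @ oc) - ocu ** 2 - rads[ci] ** 2
            disc = b * b - 4.0 * a * cc
            ok = (disc >= 0) & (a > 1e-12)
            if not np.any(ok):
                continue
            sq = np.sqrt(np.where(ok, disc, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = (-b - sq) / (2.0 * a)
                t2 = (-b + sq) / (2.0 * a)
            for t in (t1, t2):
                h = ocu + t * du
                valid = ok & (t > 1e-6) & (h >= 0.0) & (h <= lens[ci])
                if scanner.occlusion:
                    better = valid & (t < t_best[sel])
                    idx = sel[better]
                    t_best[idx] = t[better]
                    id_best[idx] = ci
                else:
                    idx = np.nonzero(valid)[0]
                    extra_t.append((sel[idx], t[idx], ci))
        if scanner.occlusion:
            hit = np.isfinite(t_best)
            ray_idx = np.nonzero(hit)[0]
            t_hit = t_best[hit]
            ids = id_best[hit]
        else:
            if not extra_t:
                continue
            ray_idx = np.concatenate([e[0] for e in extra_t])
            t_hit = np.concatenate([e[1] for e in extra_t])
            ids = np.concatenate([np.full(len(e[0]), e[2], dtype=np.int64)
                                  for e in extra_t])
        if len(ray_idx) == 0:
            continue
        t_noisy = t_hit + rng.normal(0.0, sigma_m, size=len(t_hit))
        pts = v[None, :] + t_noisy[:, None] * dirs[ray_idx]
        out_pts.append(pts)
        out_cyl.append(ids)
        out_vp.append(np.full(len(ids), vp_idx, dtype=np.int64))
    if not out_pts:
        raise EmptyCloudError("no ray-cylinder intersections; empty scan")
    pts = np.concatenate(out_pts)
    cyl = np.concatenate(out_cyl)
    vp = np.concatenate(out_vp)
    cloud = PointCloud(pts, frame=FRAME_ROOT)
    return ScanResult(cloud, cyl, root_ids[cyl], orders[cyl], vp)


# ---------------------------------------------------------------------------
# digitizer


def digitize_system(truth: TruthSystem, curved_step_m: float = 0.02,
                    straight_step_m: float = 0.15,
                    curved_turn_deg: float = 2.0) -> ReferenceRecord:
    """Emulated contact digitization of the truth system.

    Each root is resampled along its polyline at regular arclength steps
    (both endpoints included): a fine step on curved roots, a coarse one
    on straight roots, with the true local diameter at each point. A
    root counts as curved when its mean per-step turn angle exceeds
    ``curved_turn_deg``.
    """
    rows = []
    for r in truth.roots:
        s = r.arclengths
        total = s[-1]
        dirs = np.diff(r.points, axis=0)
        norms = np.linalg.norm(dirs, axis=1)
        dirs = dirs[norms > 1e-12] / norms[norms > 1e-12, None]
        if len(dirs) >= 2:
            cosang = np.clip(np.sum(dirs[:-1] * dirs[1:], axis=1), -1.0, 1.0)
            mean_turn = float(np.degrees(np.arccos(cosang)).mean())
        else:
            mean_turn = 0.0
        step = curved_step_m if mean_turn > curved_turn_deg else straight_step_m
        n = max(1, int(round(total / step)))
        targets = np.linspace(0.0, total, n + 1)
        px = np.interp(targets, s, r.points[:, 0])
        py = np.interp(targets, s, r.points[:, 1])
        pz = np.interp(targets, s, r.points[:, 2])
        pr = np.interp(targets, s, r.radii)
        for k in range(len(targets)):
            rows.append([r.root_id, r.parent_id, r.order, k,
                         px[k], py[k], pz[k], 2.0 * pr[k] * 100.0,
                         np.nan, np.nan])
    return ReferenceRecord(pd.DataFrame(rows, columns=REFERENCE_COLUMNS))
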