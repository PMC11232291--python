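"""Least-squares cylinder fitting and the surface-coverage statistic.

The fit minimizes the sum of squared orthogonal distance residuals
(point-to-axis distance minus radius) with a Gauss-Newton/Levenberg
scheme, initialized from a supplied axis or the largest principal
component. Surface coverage partitions the points into azimuth x height
cells as seen from the cylinder axis and reports the fraction of
non-empty cells — the cylinder-selection statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError

__all__ = ["CylinderFit", "fit_cylinder", "surface_coverage", "perp_basis"]


@dataclass
class CylinderFit:
    """Result of a cylinder fit: a point on the axis, the unit axis
    direction, the radius (m) and the RMS orthogonal residual (m)."""

    axis_point: np.ndarray
    direction: np.ndarray
    radius: float
    rms: float


def perp_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis (u, v) of the plane normal to axis.

    The reference vector is the standard basis vector least aligned with
    the axis (ties broken by index), so for an axis along +Z the basis is
    exactly (x-hat, y-hat) and azimuth = atan2(p.v, p.u).
    """
    a = np.asarray(axis, dtype=np.float64)
    k = int(np.argmin(np.abs(a)))
    ref = np.zeros(3)
    ref[k] = 1.0
    u = ref - a[k] * a
    u /= np.sqrt(u @ u)
    v = np.array([a[1] * u[2] - a[2] * u[1],
                  a[2] * u[0] - a[0] * u[2],
                  a[0] * u[1] - a[1] * u[0]])
    return u, v


def _rotation_to_z(a: np.ndarray) -> np.ndarray:
    """Rotation matrix whose application maps unit vector a onto +Z."""
    u, v = perp_basis(a)
    return np.vstack([u, v, a])


def _gn_core(p, max_iter, tol):
    """Damped Gauss-Newton for the cylinder distance residuals.

    Points ``p`` are pre-rotated so the initial axis is +Z. Parameters
    x = (a, b, x0, y0): axis direction (a, b, 1)/norm through the axis
    point (x0, y0, 0). Residuals are dist_i - mean(dist); the radius is
    profiled out analytically. The Jacobian is analytic:
    d dist/d x0 = -u_x, d dist/d y0 = -u_y, and for the direction
    parameters -(w.d) u_{x,y} / |g| with u the unit perpendicular offset.
    Returns (x, dist, status); status != 0 flags a failure.
    """
    n = p.shape[0]
    x = np.zeros(4)
    lam = 1e-10
    jac = np.empty((n, 4))
    for _ in range(max_iter):
        g = np.array([x[0], x[1], 1.0])
        m = np.sqrt(g[0] * g[0] + g[1] * g[1] + 1.0)
        d = g / m
        dist = np.empty(n)
        for i in range(n):
            w0 = p[i, 0] - x[2]
            w1 = p[i, 1] - x[3]
            w2 = p[i, 2]
            wd = w0 * d[0] + w1 * d[1] + w2 * d[2]
            p0 = w0 - wd * d[0]
            p1 = w1 - wd * d[1]
            p2 = w2 - wd * d[2]
            di = np.sqrt(p0 * p0 + p1 * p1 + p2 * p2)
            dist[i] = di
            if di < 1e-300:
                di = 1e-300
            u0 = p0 / di
            u1 = p1 / di
            jac[i, 0] = -(wd * u0) / m
            jac[i, 1] = -(wd * u1) / m
            jac[i, 2] = -u0
            jac[i, 3] = -u1
        for k in range(4):
            col_mean = jac[:, k].mean()
            for i in range(n):
                jac[i, k] -= col_mean
        res = dist - dist.mean()
        jtj = jac.T @ jac
        jtr = jac.T @ res
        tr = jtj[0, 0] + jtj[1, 1] + jtj[2, 2] + jtj[3, 3]
        for k in range(4):
            jtj[k, k] += lam * tr / 4.0
        step = np.linalg.solve(jtj, -jtr)
        x_new = x + step
        if not np.all(np.isfinite(x_new)):
            return x, dist, 1
        rel = np.sqrt(np.sum(step * step)) / (1.0 + np.sqrt(np.sum(x * x)))
        x = x_new
        if rel < tol:
            break
    g = np.array([x[0], x[1], 1.0])
    d = g / np.sqrt(g[0] * g[0] + g[1] * g[1] + 1.0)
    w = p - np.array([x[2], x[3], 0.0])
    wd = w @ d
    dist = np.sqrt(np.sum((w - np.outer(wd, d)) ** 2, axis=1))
    return x, dist, 0


try:  # numba accelerates the hot fit loop ~50x; plain numpy otherwise
    from numba import njit

    _gn_core = njit(cache=True, fastmath=False)(_gn_core)
except Exception:  # pragma: no cover - numba always present in practice
    pass


def _gauss_newton(p: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    try:
        x, dist, status = _gn_core(np.ascontiguousarray(p, dtype=np.float64),
                                   max_iter, tol)
    except Exception as exc:
        raise FitError(f"cylinder fit failed: {exc}") from exc
    if status != 0:
        raise FitError("cylinder fit diverged (non-finite parameters)")
    return x, dist


def _fit_full(pts, a0, has_init, max_iter, tol):
    """Full cylinder fit on raw points; returns
    (axis_point, direction, radius, rms, status) with status 0 = ok,
    2 = degenerate geometry, 3 = diverged."""
    n = pts.shape[0]
    center = np.zeros(3)
    for i in range(n):
        for k in range(3):
            center[k] += pts[i, k]
    center /= n
    q = pts - center
    gram = q.T @ q
    evals, evecs = np.linalg.eigh(gram)
    zero3 = np.zeros(3)
    # eigenvalue ratios square the singular-value ratios; 1e-12 here flags
    # exact collinearity/coplanarity without rejecting thin valid windows
    if evals[1] <= 1e-12 * evals[2] or evals[0] <= 1e-12 * evals[2]:
        return zero3, zero3, 0.0, 0.0, 2
    if has_init:
        na = np.sqrt(a0 @ a0)
        axis0 = a0 / na
    else:
        axis0 = evecs[:, 2].copy()     # largest principal component
    # orthonormal frame mapping axis0 -> +Z (deterministic perp basis)
    kmin = 0
    amin = abs(axis0[0])
    for k in range(1, 3):
        if abs(axis0[k]) < amin:
            amin = abs(axis0[k])
            kmin = k
    u = -axis0[kmin] * axis0
    u[kmin] += 1.0
    u /= np.sqrt(u @ u)
    v = np.array([axis0[1] * u[2] - axis0[2] * u[1],
                  axis0[2] * u[0] - axis0[0] * u[2],
                  axis0[0] * u[1] - axis0[1] * u[0]])
    rot = np.empty((3, 3))
    rot[0] = u
    rot[1] = v
    rot[2] = axis0
    p = q @ rot.T
    x, dist, gn_status = _gn_core(p, max_iter, tol)
    if gn_status != 0:
        return zero3, zero3, 0.0, 0.0, 3
    radius = dist.mean()
    rms = np.sqrt(np.mean((dist - radius) ** 2))
    d = np.array([x[0], x[1], 1.0])
    d /= np.sqrt(d @ d)
    direction = rot.T @ d
    axis_point = center + rot.T @ np.array([x[2], x[3], 0.0])
    # re-anchor axis point at the projection of the centroid
    shift = ((center[0] - axis_point[0]) * direction[0]
             + (center[1] - axis_point[1]) * direction[1]
             + (center[2] - axis_point[2]) * direction[2])
    axis_point = axis_point + shift * direction
    scale = max(np.sqrt(evals[2] / n), 1e-12)
    ok = np.isfinite(radius) and radius > 0 and radius <= 1e3 * scale
    for k in range(3):
        if not np.isfinite(direction[k]):
            ok = False
    if not ok:
        return zero3, zero3, 0.0, 0.0, 3
    return axis_point, direction, float(radius), float(rms), 0


try:
    from numba import njit as _njit2

    _fit_full = _njit2(cache=True)(_fit_full)
except Exception:  # pragma: no cover - numba available in practice
    pass


def fit_cylinder(points: np.ndarray, initial_axis=None,
                 max_iter: int = 100, tol: float = 1e-8) -> CylinderFit:
    """Least-squares cylinder through a 3-D point set.

    Raises :class:`FitError` for fewer than 6 points, collinear/coplanar
    geometry, or a diverged fit (non-finite or wildly out-of-scale radius).
    """
    pts = np.ascontiguousarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise FitError("points must be an (N, 3) array")
    n = len(pts)
    if n < 6:
        raise FitError(f"cylinder fit needs >= 6 points, got {n}")
    if initial_axis is not None:
        a0 = np.ascontiguousarray(initial_axis, dtype=np.float64)
        if np.sqrt(a0 @ a0) == 0:
            raise FitError("initial axis must be non-zero")
        has_init = True
    else:
        a0 = np.zeros(3)
        has_init = False
    try:
        axis_point, direction, radius, rms, status = _fit_full(
            pts, a0, has_init, max_iter, tol)
    except Exception as exc:
        raise FitError(f"cylinder fit failed: {exc}") from exc
    if status == 2:
        raise FitError("degenerate geometry: points are collinear or coplanar")
    if status != 0:
        raise FitError("cylinder fit diverged")
    return CylinderFit(axis_point, direction, float(radius), float(rms))


def surface_coverage(points: np.ndarray, cylinder,
                     n_azimuth_cells: int, n_height_cells: int) -> float:
    """Fraction of azimuth x height surface cells containing >= 1 point.

    Points are expressed in the cylinder frame; only those whose axial
    coordinate falls within [0, length] are binned. An empty point set
    gives coverage 0.
    """
    if n_azimuth_cells < 1 or n_height_cells < 1:
        raise FitError("cell counts must be >= 1")
    pts = np.ascontiguousarray(points, dtype=np.float64)
    if pts.size == 0:
        return 0.0
    start = np.ascontiguousarray(cylinder.start, dtype=np.float64)
    axis = np.ascontiguousarray(cylinder.axis, dtype=np.float64)
    u, v = perp_basis(axis)
    return float(_coverage_core(pts, start, axis, u, v,
                                float(cylinder.length),
                                int(n_azimuth_cells), int(n_height_cells)))


def _coverage_core(pts, start, axis, u, v, length, na, nh):
    """Occupied-cell fraction; cells indexed by azimuth (from basis u, v)
    and axial position within [0, length]."""
    occ = np.zeros(na * nh, dtype=np.bool_)
    two_pi = 2.0 * np.pi
    len_safe = length if length > 1e-300 else 1e-300
    for i in range(pts.shape[0]):
        w0 = pts[i, 0] - start[0]
        w1 = pts[i, 1] - start[1]
        w2 = pts[i, 2] - start[2]
        h = w0 * axis[0] + w1 * axis[1] + w2 * axis[2]
        if h < 0.0 or h > length:
            continue
        wu = w0 * u[0] + w1 * u[1] + w2 * u[2]
        wv = w0 * v[0] + w1 * v[1] + w2 * v[2]
        az = np.arctan2(wv, wu) % two_pi
        ia = int(az / two_pi * na)
        if ia >= na:
            ia = na - 1
        ih = int(h / len_safe * nh)
        if ih >= nh:
            ih = nh - 1
        occ[ia * nh + ih] = True
    count = 0
    for k in range(na * nh):
        if occ[k]:
            count += 1
    return count / (na * nh)


try:
    from numba import njit as _njit3

    _coverage_core = _njit3(cache=True)(_coverage_core)
except Exception:  # pragma: no cover - numba available in practice
    pass
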