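"""Point-cloud container, I/O, root coordinate frame, and density estimation.

The working frame for a root system puts the collar (root-stem interface)
at the origin with geographic north along +X and up along +Z; Y completes
a right-handed frame and therefore points west. All coordinates are metres.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from . import _las
from .errors import (CloudIOError, EmptyCloudError, EstimationError,
                     GeometryError)

FRAME_SENSOR = "sensor"
FRAME_ROOT = "root"   # collar at origin, +X north, +Z up, +Y west


@dataclass
class PointCloud:
    """N x 3 point coordinates in metres, with a frame label.

    ``frame`` records the orientation convention; pipelines downstream of
    :func:`set_frame` expect ``frame == "root"``.
    """

    points: np.ndarray
    frame: str = FRAME_SENSOR
    intensity: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise EmptyCloudError("points must be an (N, 3) array")
        if len(self.points) == 0:
            raise EmptyCloudError("point cloud has zero points")
        if not np.all(np.isfinite(self.points)):
            raise GeometryError("point cloud contains non-finite coordinates")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=np.float64)
            if self.intensity.shape != (len(self.points),):
                raise GeometryError("intensity must be length N")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DensityEstimate:
    """Per-patch point density (points/mm^2), patch hull areas (mm^2),
    and the derived median point spacing (mm)."""

    densities: np.ndarray          # points / mm^2, one per usable patch
    areas: np.ndarray              # mm^2
    median_spacing_mm: float
    n_patches_skipped: int = 0

    @property
    def spacings_mm(self) -> np.ndarray:
        return 1.0 / np.sqrt(self.densities)


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("las", "xyz"):
            raise CloudIOError(f"unknown point-cloud format {fmt!r}")
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    return "las" if ext == ".las" else "xyz"


def read_cloud(path, fmt: str | None = None) -> PointCloud:
    """Read a point cloud from LAS binary or whitespace-delimited XYZ text.

    Format is taken from ``fmt`` or inferred from the extension
    (``.las`` -> LAS, anything else -> XYZ). Coordinates are returned in
    metres, in file order.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "las":
        points, intensity = _las.read_las(path)
        return PointCloud(points, intensity=intensity)
    rows = []
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                if len(parts) < 3:
                    raise CloudIOError(
                        f"{path}: line {lineno}: expected at least 3 columns")
                try:
                    rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
                except ValueError as exc:
                    raise CloudIOError(
                        f"{path}: line {lineno}: cannot parse coordinates "
                        f"({line.strip()!r})") from exc
    except OSError as exc:
        raise CloudIOError(f"cannot read {path}: {exc}") from exc
    if not rows:
        raise EmptyCloudError(f"{path}: no points")
    return PointCloud(np.array(rows))


def write_cloud(cloud: PointCloud, path, fmt: str | None = None) -> None:
    """Write a cloud as LAS (scale 0.001 m) or XYZ text."""
    fmt = _infer_format(path, fmt)
    if len(cloud) == 0:  # pragma: no cover - PointCloud forbids this
        raise EmptyCloudError("refusing to write an empty cloud")
    if fmt == "las":
        _las.write_las(path, cloud.points, cloud.intensity)
        return
    try:
        np.savetxt(path, cloud.points, fmt="%.6f")
    except OSError as exc:
        raise CloudIOError(f"cannot write {path}: {exc}") from exc


def set_frame(cloud: PointCloud, collar, north_direction, up_direction,
              invert: bool = False) -> PointCloud:
    """Rigidly transform a cloud into the root frame.

    ``collar`` is mapped to the origin, ``north_direction`` to +X and
    ``up_direction`` (orthogonalized against north) to +Z. When ``invert``
    is set, the aligned cloud is additionally rotated 180 degrees about the
    north axis — undoing the upside-down posture of a root system scanned
    resting on its stump cut face — which flips up/down while keeping north.
    """
    collar = np.asarray(collar, dtype=np.float64)
    north = np.asarray(north_direction, dtype=np.float64)
    up = np.asarray(up_direction, dtype=np.float64)
    nu, nn = np.linalg.norm(up), np.linalg.norm(north)
    if nu == 0 or nn == 0:
        raise GeometryError("north/up directions must be non-zero")
    z = up / nu
    x = north - np.dot(north, z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-12 * nn:
        raise GeometryError("north and up directions are parallel")
    x = x / nx
    y = np.cross(z, x)
    rot = np.vstack([x, y, z])
    pts = (cloud.points - collar) @ rot.T
    if invert:
        pts = pts * np.array([1.0, -1.0, -1.0])
    return PointCloud(pts, frame=FRAME_ROOT, intensity=cloud.intensity)


def estimate_density(cloud: PointCloud, probe_patch_diam_mm: float,
                     seed: int = 0) -> DensityEstimate:
    """Estimate surface point density with a probe cover.

    The cloud is covered with patches of the probe diameter; each patch is
    projected onto the plane of its two largest principal components and
    its area taken as the convex hull of the projection. Density is points
    per hull area (points/mm^2); the median point spacing is the median
    over patches of density^(-1/2). Degenerate (near-collinear or < 3
    point) patches are skipped and counted.
    """
    from .cover import generate_cover  # local import: cover depends on this module's types

    if len(cloud) < 3:
        raise EstimationError("density estimation requires at least 3 points")
    if probe_patch_diam_mm <= 0:
        raise EstimationError("probe patch diameter must be positive")
    cover = generate_cover(cloud, probe_patch_diam_mm, seed=seed,
                           build_adjacency=False)
    densities, areas = [], []
    skipped = 0
    for idx in cover.patches:
        if len(idx) < 3:
            skipped += 1
            continue
        pts_mm = cloud.points[idx] * 1000.0
        centered = pts_mm - pts_mm.mean(axis=0)
        # two largest principal components span the local surface plane
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if s[1] <= 1e-9 * max(s[0], 1e-30):
            skipped += 1   # near-collinear patch
            continue
        proj = centered @ vt[:2].T
        try:
            hull = ConvexHull(proj)
        except QhullError:
            skipped += 1
            continue
        area = hull.volume   # 2-D hull: "volume" is the area
        if area <= 0:
            skipped += 1
            continue
        densities.append(len(idx) / area)
        areas.append(area)
    if not densities:
        raise EstimationError("all patches degenerate; cannot estimate density")
    densities = np.array(densities)
    median_spacing = float(np.median(1.0 / np.sqrt(densities)))
    return DensityEstimate(densities, np.array(areas), median_spacing, skipped)
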