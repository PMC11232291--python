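"""Digitized reference measurements (contact-digitizer dialect) and
AMAPmod-style reference traits.

The full MTG grammar is deliberately not parsed; a documented flat
tab-separated dialect carries the same information: one measurement
point per row with a topology code (root id, parent root, order,
sequence), XYZ coordinates (m) and one or two diameters (cm). Where a
perpendicular diameter is recorded the cross-section is treated as an
ellipse and the equivalent circular diameter sqrt(d1*d2) is used.

Reference volume between consecutive measurement points uses the
conical frustum: V = (pi * l / 12) * (d1^2 + d1*d2 + d2^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ReferenceFormatError
from .traits import (RootTraits, azimuth_deg, quadrant_of_azimuth)

__all__ = ["ReferenceRecord", "read_reference", "write_reference",
           "reference_traits", "frustum_volume", "REFERENCE_COLUMNS"]

REFERENCE_COLUMNS = ["root_id", "parent_id", "order", "seq",
                     "x", "y", "z", "d1", "d2", "d2_azimuth"]


@dataclass
class ReferenceRecord:
    """Validated digitized measurements, ordered by (root_id, seq).

    ``data`` has the REFERENCE_COLUMNS schema: coordinates in metres,
    diameters in cm, parent_id -1 for the taproot (order 0).
    """

    data: pd.DataFrame

    def roots(self):
        for rid, grp in self.data.groupby("root_id", sort=True):
            yield int(rid), grp


def frustum_volume(length_m: float, d1_cm: float, d2_cm: float) -> float:
    """Conical frustum volume in m^3 from diameters in cm."""
    d1 = d1_cm / 100.0
    d2 = d2_cm / 100.0
    return np.pi * length_m / 12.0 * (d1 * d1 + d1 * d2 + d2 * d2)


def _validate(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ReferenceFormatError(f"{origin}: missing columns {missing}")
    df = df.copy()
    df["d2"] = df["d2"].astype(float)
    df.loc[df["d2"].isna() | (df["d2"] <= 0), "d2"] = np.nan
    for i, row in df.iterrows():
        if not np.isfinite(row["d1"]) or row["d1"] <= 0:
            raise ReferenceFormatError(
                f"{origin}: row {i}: non-positive primary diameter")
    # topology: parent exists, no cycles
    roots = {int(r): (int(p) if p >= 0 else None)
             for r, p in df.groupby("root_id")["parent_id"].first().items()}
    for rid, pid in roots.items():
        if pid is not None and pid not in roots:
            row = df.index[df["root_id"] == rid][0]
            raise ReferenceFormatError(
                f"{origin}: row {row}: root {rid} has unknown parent {pid}")
        seen = {rid}
        cur = pid
        while cur is not None:
            if cur in seen:
                row = df.index[df["root_id"] == rid][0]
                raise ReferenceFormatError(
                    f"{origin}: row {row}: topology cycle at root {rid}")
            seen.add(cur)
            cur = roots[cur]
    counts = df.groupby("root_id").size()
    single = counts[counts < 2]
    if len(single):
        warnings.warn(f"{origin}: roots with a single measurement point "
                      f"will be skipped: {sorted(single.index)}")
    return df.sort_values(["root_id", "seq"]).reset_index(drop=True)


def read_reference(path) -> ReferenceRecord:
    """Read the tab-separated reference dialect (header + one point/row)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ReferenceFormatError(f"cannot parse {path}: {exc}") from exc
    return ReferenceRecord(_validate(df, str(path)))


def write_reference(record: ReferenceRecord, path) -> None:
    out = record.data[REFERENCE_COLUMNS]
    with open(path, "w") as fh:
        fh.write("# rootqsm reference dialect: coords m, diameters cm, "
                 "parent_id -1 = taproot\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def _equiv_diam(row) -> float:
    d2 = row["d2"]
    if np.isfinite(d2) and d2 > 0:
        return float(np.sqrt(row["d1"] * d2))
    return float(row["d1"])


def reference_traits(record: ReferenceRecord,
                     min_proximal_diam_cm: float = 1.0,
                     depth_threshold_m: float = 0.30,
                     include_taproot: bool = False) -> RootTraits:
    """AMAPmod-style traits from digitized polylines.

    Per root: length is the summed inter-point Euclidean distance and
    volume the summed conical frusta on equivalent diameters. Length and
    volume are apportioned to the quadrant/depth of each inter-point
    segment midpoint; the root count goes to the quadrant of the root's
    first inter-point direction and the depth bin of its first midpoint.
    """
    rows = []
    for rid, grp in record.roots():
        if len(grp) < 2:
            continue
        order = int(grp["order"].iloc[0])
        if order == 0 and not include_taproot:
            continue
        deq = grp.apply(_equiv_diam, axis=1).to_numpy()
        if deq[0] < min_proximal_diam_cm:
            continue
        pts = grp[["x", "y", "z"]].to_numpy(dtype=float)
        v0 = pts[1] - pts[0]
        quad_num = quadrant_of_azimuth(azimuth_deg(v0[0], v0[1]))
        mid0 = 0.5 * (pts[0] + pts[1])
        dep_num = "deep" if -mid0[2] >= depth_threshold_m else "shallow"
        rows.append(("number", order, quad_num, dep_num, 1.0, rid))
        for k in range(len(pts) - 1):
            seg = pts[k + 1] - pts[k]
            ell = float(np.linalg.norm(seg))
            mid = 0.5 * (pts[k] + pts[k + 1])
            quad = quadrant_of_azimuth(azimuth_deg(mid[0], mid[1]))
            dep = "deep" if -mid[2] >= depth_threshold_m else "shallow"
            vol = frustum_volume(ell, deq[k], deq[k + 1]) * 1000.0  # dm^3
            rows.append(("length", order, quad, dep, ell, rid))
            rows.append(("volume", order, quad, dep, vol, rid))
    df = pd.DataFrame(rows, columns=["trait", "order", "quadrant", "depth",
                                     "value", "root_id"])
    return RootTraits(df, min_proximal_diam_cm, depth_threshold_m)
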