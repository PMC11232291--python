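"""Root orders and architectural trait tables.

Orders follow the centrifugal classification: the stump/taproot chain is
order 0, roots springing from it are first-order, their children
second-order, and so on (orders above a cap are lumped into the cap
class). A *root* is the maximal chain of cylinders of one order — i.e.
one segment. Traits (length, volume, number) are reported in total and
stratified by order, cardinal quadrant and depth bin; only coarse roots
(proximal diameter >= 1 cm by default) are counted, matching the
field-measurement convention.

Quadrant convention: azimuth is measured from +X (north) toward east,
with quadrant boundaries at +/-45 degrees around the cardinal axes
(half-open intervals). Depth is the distance below the collar plane of a
cylinder's midpoint; the deep bin is closed at the threshold (a midpoint
at exactly 30 cm counts as deep).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StructureError

__all__ = ["RootTraits", "assign_orders", "compute_traits",
           "quadrant_of_azimuth", "azimuth_deg"]

QUADRANTS = ("N", "E", "S", "W")
DEPTH_BINS = ("shallow", "deep")
TRAITS = ("length", "volume", "number")


def azimuth_deg(x: float, y: float) -> float:
    """Azimuth in degrees from +X (north) toward east, in [0, 360).

    The root frame is right-handed with +Y west, so east is -Y.
    """
    return float(np.mod(np.degrees(np.arctan2(-y, x)), 360.0))


def quadrant_of_azimuth(az: float) -> str:
    az = np.mod(az + 45.0, 360.0)   # shift so N spans [0, 90)
    return QUADRANTS[int(az // 90.0) % 4]


@dataclass
class RootTraits:
    """Trait table: long-format records (trait, order, quadrant, depth, value).

    ``number`` rows carry one count per retained root (assigned to the
    quadrant/depth of the root's base); ``length``/``volume`` rows are
    apportioned cylinder-wise (or frustum-wise for digitized references).
    Lengths in m, volumes in dm^3.
    """

    records: pd.DataFrame
    min_proximal_diam_cm: float = 1.0
    depth_threshold_m: float = 0.30

    def _sel(self, trait: str) -> pd.DataFrame:
        return self.records[self.records["trait"] == trait]

    def total(self, trait: str) -> float:
        return float(self._sel(trait)["value"].sum())

    @property
    def total_length(self) -> float:
        return self.total("length")

    @property
    def total_volume(self) -> float:
        return self.total("volume")

    @property
    def total_number(self) -> float:
        return self.total("number")

    def by_order(self, trait: str) -> dict[int, float]:
        g = self._sel(trait).groupby("order")["value"].sum()
        return {int(k): float(v) for k, v in g.items()}

    def by_quadrant(self, trait: str) -> dict[str, float]:
        g = self._sel(trait).groupby("quadrant")["value"].sum()
        out = {q: 0.0 for q in QUADRANTS}
        out.update({str(k): float(v) for k, v in g.items()})
        return out

    def by_depth(self, trait: str) -> dict[str, float]:
        g = self._sel(trait).groupby("depth")["value"].sum()
        out = {d: 0.0 for d in DEPTH_BINS}
        out.update({str(k): float(v) for k, v in g.items()})
        return out

    def value(self, trait: str, order: int | None = None,
              quadrant: str | None = None, depth: str | None = None) -> float:
        df = self._sel(trait)
        if order is not None:
            df = df[df["order"] == order]
        if quadrant is not None:
            df = df[df["quadrant"] == quadrant]
        if depth is not None:
            df = df[df["depth"] == depth]
        return float(df["value"].sum())

    def to_csv(self, path) -> None:
        out = self.records.copy()
        out["units"] = out["trait"].map(
            {"length": "m", "volume": "dm3", "number": "count"})
        out.to_csv(path, index=False)


def _segment_orders(qsm, max_order: int) -> dict[int, int]:
    """Order per segment from the segment parent tree."""
    segments = qsm.segments
    orders: dict[int, int] = {}
    # roots of the segment forest
    pending = [sid for sid, s in enumerate(segments) if s.parent is None]
    for sid in pending:
        orders[sid] = 0 if (segments[sid].is_stump
                            or segments[sid].order_hint == 0) else 1
    # iterate until all assigned, detecting cycles
    remaining = [sid for sid in range(len(segments)) if sid not in orders]
    guard = 0
    while remaining:
        progressed = False
        nxt = []
        for sid in remaining:
            p = segments[sid].parent
            if p in orders:
                hint = segments[sid].order_hint
                if hint is not None:
                    orders[sid] = min(hint, max_order)
                else:
                    orders[sid] = min(orders[p] + 1, max_order)
                progressed = True
            else:
                nxt.append(sid)
        remaining = nxt
        guard += 1
        if not progressed and remaining:
            raise StructureError("cycle or broken parent link in segment tree")
        if guard > len(segments) + 1:   # pragma: no cover
            raise StructureError("segment order assignment did not terminate")
    return orders


def assign_orders(qsm, max_order: int = 3):
    """Assign centrifugal orders to all cylinders in place; returns qsm."""
    orders = _segment_orders(qsm, max_order)
    for cyl in qsm.cylinders:
        cyl.order = orders.get(cyl.segment)
    return qsm


def _depth_bin(z_mid: float, threshold: float) -> str:
    return "deep" if -z_mid >= threshold else "shallow"


def compute_traits(qsm, min_proximal_diam_cm: float = 1.0,
                   depth_threshold_m: float = 0.30,
                   include_taproot: bool = False) -> RootTraits:
    """Trait table of a QSM (see module docstring for conventions).

    One root = one segment; its proximal diameter is twice the radius of
    its first cylinder. Roots below the diameter threshold are excluded
    from number, length and volume alike.
    """
    if any(c.order is None for c in qsm.cylinders):
        raise StructureError("orders not assigned; call assign_orders first")
    by_seg: dict[int, list] = {}
    for c in qsm.cylinders:
        by_seg.setdefault(c.segment, []).append(c)
    rows = []
    for sid in sorted(by_seg):
        chain = by_seg[sid]
        order = chain[0].order
        if order == 0 and not include_taproot:
            continue
        prox_cm = 2.0 * chain[0].radius * 100.0
        if prox_cm < min_proximal_diam_cm:
            continue
        base_mid = chain[0].midpoint
        quad0 = quadrant_of_azimuth(azimuth_deg(base_mid[0], base_mid[1]))
        dep0 = _depth_bin(base_mid[2], depth_threshold_m)
        rows.append(("number", order, quad0, dep0, 1.0, sid))
        for c in chain:
            mid = c.midpoint
            quad = quadrant_of_azimuth(azimuth_deg(mid[0], mid[1]))
            dep = _depth_bin(mid[2], depth_threshold_m)
            rows.append(("length", order, quad, dep, c.length, sid))
            rows.append(("volume", order, quad, dep, c.volume * 1000.0, sid))
    df = pd.DataFrame(rows, columns=["trait", "order", "quadrant", "depth",
                                     "value", "root_id"])
    return RootTraits(df, min_proximal_diam_cm, depth_threshold_m)
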