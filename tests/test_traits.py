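"""Root orders and trait tables."""

import numpy as np
import pytest

from rootqsm import Cylinder, Qsm, assign_orders, compute_traits
from rootqsm.errors import StructureError
from rootqsm.segmentation import Segment
from rootqsm.traits import azimuth_deg, quadrant_of_azimuth


def _seg(parent=None, order_hint=None, is_stump=False):
    return Segment([[0]], [np.zeros(3)], parent=parent,
                   order_hint=order_hint, is_stump=is_stump)


def chain_qsm(radii_lengths, orders_chain=True):
    """QSM of nested segments: taproot -> lateral A -> B -> C ..."""
    segments = [_seg(is_stump=True, order_hint=0)]
    cylinders = [Cylinder(start=np.zeros(3), axis=np.array([0, 0, -1.0]),
                          length=0.5, radius=0.06, cyl_id=0, segment=0)]
    for k, (r, ell) in enumerate(radii_lengths):
        segments.append(_seg(parent=k))
        start = np.array([0.1 * (k + 1), 0.0, -0.1])
        cyl = Cylinder(start=start, axis=np.array([1.0, 0, 0]), length=ell,
                       radius=r, cyl_id=k + 1, parent=k, segment=k + 1)
        cylinders.append(cyl)
    return Qsm(cylinders, segments, provenance={})


class TestAssignOrders:
    def test_taproot_only(self):
        qsm = chain_qsm([])
        assign_orders(qsm)
        assert [c.order for c in qsm.cylinders] == [0]

    def test_chain_orders(self):
        qsm = chain_qsm([(0.02, 1.0), (0.01, 0.5), (0.007, 0.3)])
        assign_orders(qsm)
        assert [c.order for c in qsm.cylinders] == [0, 1, 2, 3]

    def test_orders_above_cap_lumped(self):
        qsm = chain_qsm([(0.02, 1.0)] * 5)
        assign_orders(qsm, max_order=3)
        assert [c.order for c in qsm.cylinders] == [0, 1, 2, 3, 3, 3]

    def test_cycle_detected(self):
        qsm = chain_qsm([(0.02, 1.0)])
        qsm.segments[0].parent = 1
        qsm.segments[0].is_stump = False
        qsm.segments[0].order_hint = None
        with pytest.raises(StructureError):
            assign_orders(qsm)


class TestComputeTraits:
    def test_orders_required(self):
        qsm = chain_qsm([(0.02, 1.0)])
        with pytest.raises(StructureError):
            compute_traits(qsm)

    def test_single_root_analytic(self):
        # one first-order root: r = 20 mm, l = 2 m, along +X at depth 0.1 m
        segments = [_seg(is_stump=True, order_hint=0), _seg(parent=0)]
        cyls = [
            Cylinder(start=np.zeros(3), axis=np.array([0, 0, -1.0]),
                     length=0.3, radius=0.06, cyl_id=0, segment=0),
            Cylinder(start=np.array([0.0, 0.0, -0.1]),
                     axis=np.array([1.0, 0, 0]), length=2.0, radius=0.02,
                     cyl_id=1, parent=0, segment=1),
        ]
        qsm = assign_orders(Qsm(cyls, segments, {}))
        tr = compute_traits(qsm)
        assert tr.total_length == pytest.approx(2.0)
        assert tr.total_volume == pytest.approx(np.pi * 0.02**2 * 2.0 * 1000)
        assert tr.total_number == 1
        assert tr.by_quadrant("length")["N"] == pytest.approx(2.0)
        assert tr.by_depth("volume")["shallow"] == pytest.approx(tr.total_volume)

    def test_two_root_hand_summation(self):
        segments = [_seg(is_stump=True, order_hint=0), _seg(parent=0),
                    _seg(parent=1)]
        cyls = [
            Cylinder(start=np.zeros(3), axis=np.array([0, 0, -1.0]),
                     length=0.3, radius=0.06, cyl_id=0, segment=0),
            Cylinder(start=np.array([0.0, 0.0, -0.1]),
                     axis=np.array([1.0, 0, 0]), length=2.0, radius=0.02,
                     cyl_id=1, parent=0, segment=1),
            Cylinder(start=np.array([1.0, 0.0, -0.1]),
                     axis=np.array([0.0, -1.0, 0]), length=1.0, radius=0.01,
                     cyl_id=2, parent=1, segment=2),
        ]
        qsm = assign_orders(Qsm(cyls, segments, {}))
        tr = compute_traits(qsm)
        assert tr.total_length == pytest.approx(3.0)
        assert tr.total_volume == pytest.approx(2.513 + 0.314, abs=2e-3)
        assert tr.by_order("length") == pytest.approx({1: 2.0, 2: 1.0})
        assert tr.by_order("volume")[1] == pytest.approx(2.513, abs=1e-3)
        assert tr.by_order("volume")[2] == pytest.approx(0.314, abs=1e-3)
        assert tr.by_order("number") == {1: 1, 2: 1}

    def test_thin_root_filtered(self):
        segments = [_seg(is_stump=True, order_hint=0), _seg(parent=0)]
        cyls = [
            Cylinder(start=np.zeros(3), axis=np.array([0, 0, -1.0]),
                     length=0.3, radius=0.06, cyl_id=0, segment=0),
            Cylinder(start=np.array([0, 0, -0.1]), axis=np.array([1.0, 0, 0]),
                     length=1.0, radius=0.004, cyl_id=1, parent=0, segment=1),
        ]
        qsm = assign_orders(Qsm(cyls, segments, {}))
        tr = compute_traits(qsm)   # proximal diameter 0.8 cm < 1 cm
        assert tr.total_number == 0
        assert tr.total_length == 0.0
        assert tr.total_volume == 0.0

    def test_marginals_sum_to_totals(self, small_scan):
        import rootqsm as rq

        qsm = rq.build_qsm(small_scan.cloud, 20.0, seed=0)
        tr = compute_traits(qsm)
        for trait in ("length", "volume", "number"):
            tot = tr.total(trait)
            assert sum(tr.by_order(trait).values()) == pytest.approx(tot, rel=1e-9)
            assert sum(tr.by_quadrant(trait).values()) == pytest.approx(tot, rel=1e-9)
            assert sum(tr.by_depth(trait).values()) == pytest.approx(tot, rel=1e-9)

    def test_rotation_permutes_quadrants(self):
        qsm = chain_qsm([(0.02, 1.0)])
        assign_orders(qsm)
        base = compute_traits(qsm)
        # rotate +90 degrees about Z: (x, y) -> (-y, x); N -> W -> S -> E
        rot = np.array([[0.0, -1.0, 0], [1.0, 0.0, 0], [0, 0, 1.0]])
        for c in qsm.cylinders:
            c.start = rot @ c.start
            c.axis = rot @ c.axis
        rotated = compute_traits(qsm)
        for trait in ("length", "volume", "number"):
            b, r = base.by_quadrant(trait), rotated.by_quadrant(trait)
            assert r["W"] == pytest.approx(b["N"])
            assert r["S"] == pytest.approx(b["W"])
            assert r["E"] == pytest.approx(b["S"])
            assert r["N"] == pytest.approx(b["E"])
            assert rotated.total(trait) == pytest.approx(base.total(trait))


class TestQuadrantConvention:
    @pytest.mark.parametrize("x,y,quad", [
        (1.0, 0.0, "N"),        # +X = north
        (0.0, -1.0, "E"),       # east = -Y (Y points west)
        (-1.0, 0.0, "S"),
        (0.0, 1.0, "W"),
        (1.0, -1.0, "E"),       # azimuth 45 -> half-open boundary goes east
        (1.0, 1.0, "N"),        # azimuth -45 -> north
    ])
    def test_boundaries(self, x, y, quad):
        assert quadrant_of_azimuth(azimuth_deg(x, y)) == quad
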