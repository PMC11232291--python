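"""Generator, scanner and digitizer ground-truth properties."""

import numpy as np
import pytest
from scipy import stats

from rootqsm import (Cylinder, RootSystemSpec, ScannerSpec, digitize_system,
                     generate_system, reference_traits, scan_system,
                     surface_coverage)
from rootqsm.errors import EmptyCloudError, ParameterError
from rootqsm.synthetic import _truth_cylinders


class TestGenerateSystem:
    def test_zero_laterals_taproot_only(self):
        spec = RootSystemSpec(seed=0, n_first_order=0)
        truth = generate_system(spec)
        assert len(truth.roots) == 1
        tr = truth.truth_traits()
        assert tr.total_length == 0.0
        assert tr.total_number == 0.0

    def test_analytic_five_root_case(self):
        # 5 first-order roots, r = 20 mm, l = 1.5 m, no taper, no curvature
        spec = RootSystemSpec(seed=0, n_first_order=5, second_per_first=0.0,
                              third_per_second=0.0,
                              first_radius_range_m=(0.02, 0.02),
                              first_length_range_m=(1.5, 1.5),
                              taper_tip_fraction=1.0,
                              curvature_deg_per_step=0.0)
        truth = generate_system(spec)
        tr = truth.truth_traits()
        assert tr.total_length == pytest.approx(7.5, rel=1e-9)
        assert tr.total_volume == pytest.approx(5 * np.pi * 0.02**2 * 1.5 * 1000,
                                                rel=1e-9)
        assert tr.total_number == 5

    def test_truth_matches_brute_force_summation(self, small_truth):
        tr = small_truth.truth_traits(include_taproot=True)
        length = volume = 0.0
        for r in small_truth.roots:
            for k in range(len(r.points) - 1):
                ell = np.linalg.norm(r.points[k + 1] - r.points[k])
                d1, d2 = 2 * r.radii[k], 2 * r.radii[k + 1]
                length += ell
                volume += np.pi * ell / 12 * (d1**2 + d1 * d2 + d2**2) * 1000
        assert tr.total_length == pytest.approx(length, rel=1e-9)
        assert tr.total_volume == pytest.approx(volume, rel=1e-9)

    def test_determinism(self):
        a = generate_system(RootSystemSpec(seed=5))
        b = generate_system(RootSystemSpec(seed=5))
        assert len(a.roots) == len(b.roots)
        for ra, rb in zip(a.roots, b.roots):
            assert np.array_equal(ra.points, rb.points)

    def test_asymmetry_weights_binomial(self):
        spec = RootSystemSpec(seed=12, n_first_order=200,
                              second_per_first=0.0, third_per_second=0.0,
                              quadrant_weights=(0.7, 0.1, 0.1, 0.1))
        truth = generate_system(spec)
        tr = truth.truth_traits()
        n_north = tr.by_quadrant("number")["N"]
        lo, hi = stats.binom.interval(0.99, 200, 0.7)
        assert lo <= n_north <= hi

    def test_bad_weights_rejected(self):
        with pytest.raises(ParameterError):
            RootSystemSpec(quadrant_weights=(0.5, 0.5, 0.5, 0.5))


class TestScanSystem:
    def test_single_cylinder_one_viewpoint_half_coverage(self):
        # one viewpoint sees one side of an isolated cylinder: coverage ~ 0.5
        spec = RootSystemSpec(seed=0, n_first_order=0, taproot_depth_m=1.0,
                              taproot_basal_radius_m=0.05,
                              taproot_tip_radius_m=0.05)
        truth = generate_system(spec)
        scan = scan_system(truth, ScannerSpec(n_viewpoints=1, seed=0,
                                              noise_sigma_mm=0.0,
                                              angular_step_deg=0.05))
        cyl = Cylinder(start=np.array([0.0, 0, -1.0]),
                       axis=np.array([0.0, 0, 1.0]), length=1.0, radius=0.05)
        cov = surface_coverage(scan.cloud.points, cyl, 16, 8)
        assert cov == pytest.approx(0.5, abs=0.1)

    def test_noiseless_points_on_surface(self, small_truth):
        scan = scan_system(small_truth, ScannerSpec(seed=0, noise_sigma_mm=0.0,
                                                    angular_step_deg=0.1))
        starts, axes, lens, rads, _, _ = _truth_cylinders(small_truth)
        w = scan.cloud.points - starts[scan.cylinder_id]
        ax = axes[scan.cylinder_id]
        h = np.sum(w * ax, axis=1)
        perp = np.linalg.norm(w - h[:, None] * ax, axis=1)
        assert np.abs(perp - rads[scan.cylinder_id]).max() < 1e-9

    def test_noise_quantile(self, small_truth):
        scan = scan_system(small_truth, ScannerSpec(seed=1, noise_sigma_mm=2.0,
                                                    angular_step_deg=0.1))
        starts, axes, lens, rads, _, _ = _truth_cylinders(small_truth)
        w = scan.cloud.points - starts[scan.cylinder_id]
        ax = axes[scan.cylinder_id]
        h = np.sum(w * ax, axis=1)
        perp = np.linalg.norm(w - h[:, None] * ax, axis=1)
        dev = np.abs(perp - rads[scan.cylinder_id])
        # range noise is along the ray; its radial component is <= the noise,
        # so the 2-sigma bound of the 2 mm noise holds for >= 95% of points
        assert np.mean(dev <= 0.004) >= 0.95

    def test_three_viewpoints_by_default(self, small_truth):
        scan = scan_system(small_truth, ScannerSpec(seed=0,
                                                    angular_step_deg=0.15))
        assert set(np.unique(scan.viewpoint)) == {0, 1, 2}

    def test_empty_scan_raises(self):
        spec = RootSystemSpec(seed=0, n_first_order=0)
        truth = generate_system(spec)
        # degenerate truth: polylines collapse to points, no cylinders
        for r in truth.roots:
            r.points = r.points[:1]
            r.radii = r.radii[:1]
        with pytest.raises(EmptyCloudError):
            scan_system(truth, ScannerSpec(seed=0, angular_step_deg=0.5))

    def test_occlusion_off_superset(self, small_truth):
        on = scan_system(small_truth, ScannerSpec(seed=0, noise_sigma_mm=0.0,
                                                  angular_step_deg=0.2))
        off = scan_system(small_truth,
                          ScannerSpec(seed=0, noise_sigma_mm=0.0,
                                      angular_step_deg=0.2, occlusion=False))
        assert len(off.cloud) >= len(on.cloud)


class TestDigitizeSystem:
    def test_straight_root_point_count(self):
        spec = RootSystemSpec(seed=0, n_first_order=1, second_per_first=0.0,
                              third_per_second=0.0,
                              first_length_range_m=(1.5, 1.5),
                              curvature_deg_per_step=0.0)
        truth = generate_system(spec)
        rec = digitize_system(truth)
        lateral = rec.data[rec.data.root_id == 1]
        # 1.5 m straight root at 0.15 m steps -> 11 points incl. both ends
        assert len(lateral) == 11

    def test_curved_root_fine_step(self):
        spec = RootSystemSpec(seed=2, n_first_order=1, second_per_first=0.0,
                              third_per_second=0.0,
                              first_length_range_m=(0.2, 0.2), step_m=0.02,
                              curvature_deg_per_step=8.0)
        truth = generate_system(spec)
        rec = digitize_system(truth)
        lateral = rec.data[rec.data.root_id == 1]
        arc = truth.roots[1].length
        assert len(lateral) == round(arc / 0.02) + 1

    def test_reference_closure_within_tolerance(self):
        truth = generate_system(RootSystemSpec(seed=4))
        rec = digitize_system(truth)
        got = reference_traits(rec)
        want = truth.truth_traits()
        assert got.total_length == pytest.approx(want.total_length, rel=0.01)
        assert got.total_volume == pytest.approx(want.total_volume, rel=0.02)
        assert got.total_number == want.total_number
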