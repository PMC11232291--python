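import numpy as np
import pytest

from rootqsm import (PointCloud, RootSystemSpec, ScannerSpec, generate_system,
                     scan_system)


@pytest.fixture(scope="session")
def cylinder_points():
    """5000 exact surface points of a vertical cylinder, r = 25 mm."""
    rng = np.random.default_rng(42)
    theta = rng.uniform(0.0, 2.0 * np.pi, 5000)
    z = rng.uniform(0.0, 0.5, 5000)
    return np.column_stack([0.025 * np.cos(theta), 0.025 * np.sin(theta), z])


@pytest.fixture(scope="session")
def small_truth():
    """A modest deterministic root system for structural tests."""
    spec = RootSystemSpec(seed=7, n_first_order=5, second_per_first=0.5,
                          third_per_second=0.0)
    return generate_system(spec)


@pytest.fixture(scope="session")
def small_scan(small_truth):
    """Coarse scan of the small system (kept cheap for unit tests)."""
    return scan_system(small_truth, ScannerSpec(seed=7, angular_step_deg=0.08))


def grid_cloud(n_side: int = 11, spacing_m: float = 0.001) -> PointCloud:
    """Planar square grid in the XY plane (z = 0)."""
    ax = np.arange(n_side) * spacing_m
    xx, yy = np.meshgrid(ax, ax)
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n_side * n_side)])
    return PointCloud(pts)
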