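"""PatchDiam optimization: sweep, interpolation, intersection, ensembles.

The resolution hyperparameter PatchDiam dominates QSM output, and its
optimum differs per trait. The calibration procedure: reconstruct QSMs
across a grid of 18 patch diameters, fit a straight interpolation line
of each trait against PatchDiam, intersect the line with the trait's
reference value (from digitized measurements) to obtain a per-trait
optimum, refine it by brute force (a few replicate models per candidate
around the optimum), and build a 20-model ensemble at the selected value
to quantify the spread from the randomized cover (median, 5th and 95th
percentiles, linear-interpolation definition). Agreement between the
reference method and the scan-based predictions is summarized by an OLS
regression of observed on predicted with its R^2 and slope p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import QsmConfig
from .cylinders import build_qsm
from .errors import InputError, ParameterError
from .pointcloud import PointCloud
from .traits import compute_traits

__all__ = ["SweepResult", "EnsembleSummary", "sweep", "fit_interpolation",
           "intersect_reference", "refine_and_ensemble",
           "agreement_regression", "TRAIT_COLUMNS", "qsm_trait_row"]

#: trait columns tracked through sweeps/ensembles
TRAIT_COLUMNS = ("length", "volume", "number",
                 "length_o1", "volume_o1", "number_o1",
                 "length_o2", "volume_o2", "number_o2",
                 "length_o3", "volume_o3", "number_o3")


def qsm_trait_row(qsm, config: QsmConfig) -> dict[str, float]:
    """Total and per-order trait values of one QSM as a flat dict."""
    tr = compute_traits(qsm, min_proximal_diam_cm=config.min_proximal_diam_cm,
                        depth_threshold_m=config.depth_threshold_m,
                        include_taproot=config.include_taproot)
    row = {"length": tr.total_length, "volume": tr.total_volume,
           "number": tr.total_number}
    for trait in ("length", "volume", "number"):
        by = tr.by_order(trait)
        for o in (1, 2, 3):
            row[f"{trait}_o{o}"] = float(by.get(o, 0.0))
    return row


@dataclass
class SweepResult:
    """Per-(grid value, seed) trait table from a PatchDiam sweep.

    ``table`` has one row per model with columns patch_diam_mm, seed and
    the TRAIT_COLUMNS; ``means`` aggregates over seeds per grid value.
    ``failed`` lists grid values where the QSM build errored (flagged and
    excluded from fitting).
    """

    grid_mm: tuple[float, ...]
    table: pd.DataFrame
    failed: tuple[float, ...] = ()

    @property
    def means(self) -> pd.DataFrame:
        return (self.table.drop(columns=["seed"])
                .groupby("patch_diam_mm", sort=True).mean().reset_index())

    def trait_curve(self, trait: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.means
        return m["patch_diam_mm"].to_numpy(), m[trait].to_numpy()


@dataclass
class EnsembleSummary:
    """Ensemble summaries at a selected PatchDiam: per trait the median
    (50th) and the 5th/95th percentiles, plus the raw model table."""

    patch_diam_mm: float
    table: pd.DataFrame
    median: dict[str, float]
    p5: dict[str, float]
    p95: dict[str, float]


class _QsmCache:
    """Memoize QSM trait rows by (patch_diam, seed) within one analysis."""

    def __init__(self, cloud: PointCloud, config: QsmConfig):
        self.cloud = cloud
        self.config = config
        self._rows: dict[tuple[float, int], dict[str, float]] = {}

    def row(self, patch_diam_mm: float, seed: int) -> dict[str, float]:
        key = (round(float(patch_diam_mm), 6), int(seed))
        if key not in self._rows:
            qsm = build_qsm(self.cloud, patch_diam_mm, seed, self.config)
            self._rows[key] = qsm_trait_row(qsm, self.config)
        return self._rows[key]


def sweep(cloud: PointCloud, grid_mm: Sequence[float] | None = None,
          seeds: Sequence[int] = (0, 1, 2),
          config: QsmConfig | None = None,
          cache: "_QsmCache | None" = None,
          progress: Callable[[str], None] | None = None) -> SweepResult:
    """Build one QSM per (grid value, seed) and tabulate the traits.

    The default grid is the 18-value PatchDiam grid. A failing grid value
    is flagged and excluded rather than aborting the sweep.
    """
    cfg = config or QsmConfig()
    grid = tuple(float(g) for g in (grid_mm if grid_mm is not None
                                    else cfg.grid_mm))
    if not grid or any(g <= 0 for g in grid):
        raise ParameterError("grid must be non-empty and positive")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ParameterError("grid must be strictly increasing")
    cache = cache or _QsmCache(cloud, cfg)
    rows = []
    failed = []
    for g in grid:
        ok = False
        for seed in seeds:
            try:
                row = dict(cache.row(g, seed))
            except Exception as exc:
                import warnings
                warnings.warn(f"QSM failed at PatchDiam {g} mm seed {seed}: {exc}")
                continue
            row["patch_diam_mm"] = g
            row["seed"] = seed
            rows.append(row)
            ok = True
        if not ok:
            failed.append(g)
        if progress is not None:
            progress(f"PatchDiam {g} mm done")
    table = pd.DataFrame(rows, columns=["patch_diam_mm", "seed", *TRAIT_COLUMNS])
    return SweepResult(grid, table, tuple(failed))


def fit_interpolation(sweep_result: SweepResult,
                      trait: str) -> tuple[float, float, float]:
    """OLS straight line of the trait's per-grid mean on PatchDiam.

    Returns (intercept, slope, R^2).
    """
    x, y = sweep_result.trait_curve(trait)
    if len(x) < 2:
        raise InputError("interpolation needs at least 2 valid grid points")
    if np.allclose(y, y[0]):
        raise InputError("degenerate fit: trait has zero variance on the grid")
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = float(model.params[0]), float(model.params[1])
    return intercept, slope, float(model.rsquared)


def intersect_reference(line: tuple[float, float],
                        reference_value: float,
                        grid_mm: Sequence[float] | None = None) -> float:
    """Solve intercept + slope * x = reference for the optimum PatchDiam.

    An optimum outside the grid hull is returned with a warning.
    """
    intercept, slope = float(line[0]), float(line[1])
    if slope == 0.0:
        raise InputError("zero slope: the line never meets the reference value")
    x = (float(reference_value) - intercept) / slope
    if grid_mm is not None and len(grid_mm) and not (min(grid_mm) <= x <= max(grid_mm)):
        import warnings
        warnings.warn(f"optimum PatchDiam {x:.1f} mm lies outside the swept grid")
    return x


def _percentiles(values: np.ndarray) -> tuple[float, float, float]:
    """(median, p5, p95) with linear interpolation between order statistics."""
    med = float(np.percentile(values, 50.0, method="linear"))
    p5 = float(np.percentile(values, 5.0, method="linear"))
    p95 = float(np.percentile(values, 95.0, method="linear"))
    return med, p5, p95


def refine_and_ensemble(cloud: PointCloud, optimum_mm: float, trait: str,
                        reference_value: float,
                        n_refine: int = 5, n_models: int = 20,
                        seeds: Sequence[int] | None = None,
                        candidates: Sequence[float] | None = None,
                        clamp_mm: tuple[float, float] | None = None,
                        config: QsmConfig | None = None,
                        cache: "_QsmCache | None" = None) -> EnsembleSummary:
    """Brute-force refinement around the interpolated optimum, then a
    final multi-model ensemble at the selected PatchDiam.

    Each candidate (multiples of the optimum, optionally clamped into
    ``clamp_mm`` and deduplicated) is evaluated with ``n_refine``
    replicate models; the candidate whose mean trait is closest to the
    reference value wins. ``n_models`` models are then built there with
    distinct seeds and summarized by the median and the 5th/95th
    percentiles of every trait.
    """
    if optimum_mm <= 0:
        raise ParameterError("optimum PatchDiam must be positive")
    cfg = config or QsmConfig()
    cache = cache or _QsmCache(cloud, cfg)
    if candidates is None:
        candidates = cfg.refine_candidates
    if seeds is None:
        seeds = range(1000, 1000 + max(n_refine, n_models))
    seeds = list(seeds)
    cand_vals = []
    for mult in candidates:
        g = optimum_mm * float(mult)
        if clamp_mm is not None:
            g = float(np.clip(g, clamp_mm[0], clamp_mm[1]))
        g = round(g, 6)
        if g not in cand_vals:
            cand_vals.append(g)
    best = None
    for g in cand_vals:
        vals = []
        for seed in seeds[:n_refine]:
            try:
                vals.append(cache.row(g, seed)[trait])
            except Exception:
                continue
        if not vals:
            continue
        err = abs(float(np.mean(vals)) - float(reference_value))
        if best is None or err < best[0]:
            best = (err, g)
    if best is None:
        raise InputError("all refinement candidates failed")
    selected = best[1]
    rows = []
    for seed in seeds[:n_models]:
        row = dict(cache.row(selected, seed))
        row["seed"] = seed
        rows.append(row)
    table = pd.DataFrame(rows)
    median, p5, p95 = {}, {}, {}
    for col in TRAIT_COLUMNS:
        med, lo, hi = _percentiles(table[col].to_numpy(dtype=float))
        median[col], p5[col], p95[col] = med, lo, hi
    return EnsembleSummary(selected, table, median, p5, p95)


def agreement_regression(reference_values: Sequence[float],
                         predicted_means: Sequence[float]
                         ) -> tuple[float, float, float, float]:
    """OLS of observed reference values on predicted means.

    Returns (slope, intercept, R^2, two-sided p for slope != 0).
    """
    y = np.asarray(reference_values, dtype=float)
    x = np.asarray(predicted_means, dtype=float)
    if len(x) != len(y):
        raise InputError("reference and predicted vectors differ in length")
    if len(x) < 3:
        raise InputError("agreement regression needs at least 3 systems")
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    intercept = float(model.params[0])
    p = float(model.pvalues[1])
    return slope, intercept, float(model.rsquared), p
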