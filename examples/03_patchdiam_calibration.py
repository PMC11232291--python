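"""The PatchDiam calibration: sweep, interpolate, intersect, ensemble.

Runs a reduced sweep (a subset of the grid, one cover replicate) on a
coarse scan so the example completes in about a minute, then calibrates
total length against the digitized reference and summarizes the final
model ensemble. The full workflow uses the 18-value grid, 3 replicates
and 20-model ensembles (see scripts/acceptance.py).
"""

import numpy as np

import rootqsm as rq
from rootqsm.optimize import (fit_interpolation, intersect_reference,
                              refine_and_ensemble, sweep)

truth = rq.generate_system(rq.RootSystemSpec(seed=1))
scan = rq.scan_system(truth, rq.ScannerSpec(seed=1, angular_step_deg=0.06))
record = rq.digitize_system(truth)
ref = rq.reference_traits(record)

grid = [10.0, 15.0, 20.0, 25.0, 35.0, 50.0]
res = sweep(scan.cloud, grid, seeds=[0])
x, y = res.trait_curve("length")
print("PatchDiam (mm) vs modeled total length (m):")
for xi, yi in zip(x, y):
    print(f"  {xi:5.1f}  {yi:6.2f}")

intercept, slope, r2 = fit_interpolation(res, "length")
opt = intersect_reference((intercept, slope), ref.total_length, grid)
opt = float(np.clip(opt, min(grid), max(grid)))
print(f"interpolation line: y = {intercept:.2f} + {slope:.4f} x (R2 = {r2:.2f})")
print(f"reference length {ref.total_length:.2f} m -> optimum PatchDiam {opt:.1f} mm")

ens = refine_and_ensemble(scan.cloud, opt, "length", ref.total_length,
                          n_refine=2, n_models=5, seeds=range(50, 60))
print(f"ensemble at {ens.patch_diam_mm:.1f} mm: median length "
      f"{ens.median['length']:.2f} m  [p5 {ens.p5['length']:.2f}, "
      f"p95 {ens.p95['length']:.2f}]")
print(f"generator truth: {truth.truth_traits().total_length:.2f} m")
print("The ensemble median should bracket the truth; the p5-p95 band is the")
print("cover-randomness uncertainty at the selected PatchDiam.")
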