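"""Emulated contact digitization and AMAPmod-style reference traits.

Digitizes a synthetic root system into the flat reference dialect
(polyline points with diameters), recomputes traits with conical-frustum
volumes, and shows the closure against generator truth.
"""

import rootqsm as rq

truth = rq.generate_system(rq.RootSystemSpec(seed=4))
record = rq.digitize_system(truth)
n_points = len(record.data)
print(f"digitized {len(truth.roots)} roots into {n_points} measurement points")

ref = rq.reference_traits(record)
tt = truth.truth_traits()
for name, a, b in [("length (m)", ref.total_length, tt.total_length),
                   ("volume (dm3)", ref.total_volume, tt.total_volume),
                   ("number", ref.total_number, tt.total_number)]:
    print(f"  {name:12s} reference {a:8.3f}   truth {b:8.3f}")
print("Frustum volumes on 2 cm / 15 cm sampling reproduce the truth to ~1-2%;")
print("the residual is the chord-vs-arc difference on curved roots.")

print("\nby quadrant (number of roots):", ref.by_quadrant("number"))
print("Quadrant counts at this sample size fluctuate around the generator's")
print("downslope/windward weighting; 04_quadrant_and_depth_traits.py uses a")
print("stronger asymmetry to make the signal unmistakable.")
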