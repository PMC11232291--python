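# Methods

`rootqsm` reconstructs quantitative structure models (QSMs) of excavated
coarse-root systems from terrestrial-laser-scan (TLS) point clouds,
extracts architectural traits, and calibrates the reconstruction against
contact-digitized reference measurements. This note records the models,
the numerical choices, and what the synthetic testbed does and does not
establish.

## Coordinate frame and units

All computation happens in a root frame: origin at the root collar,
+X geographic north, +Z up; +Y completes a right-handed frame and
therefore points west (only the north convention is externally imposed;
Z-up/Y-west are this package's choice for right-handedness). Azimuth is
measured from north toward east. Coordinates are metres; PatchDiam and
point spacing are quoted in millimetres; root diameters in centimetres
(the field convention); volumes in dm^3.

Clouds scanned upside down (a root system resting on its stump cut
face) are restored with a 180-degree rotation about the north axis
(`set_frame(..., invert=True)`), which flips up/down while preserving
north and all pairwise distances.

## Cover sets

The cloud is partitioned into *cover sets* ("patches") of bounded
diameter by randomized greedy ball covering: points are visited in a
seed-shuffled order, and each still-uncovered point claims every
uncovered point within PatchDiam/2. The patch diameter bound (max
pairwise distance <= PatchDiam) holds by construction. Two patches are
adjacent iff some inter-patch point pair lies within
`adjacency_factor x PatchDiam` (factor 1 by default). Both adjacency
strategies (direct pair enumeration, and a seed-ball accept/reject
hybrid with exact min-distance tests in the gray shell) compute exactly
the same relation; the choice is made on a sampled pair-count estimate
purely for speed. The covering seed is an explicit parameter because the
randomness of the cover propagates into segmentation and the trait
ensembles; everything downstream is bit-reproducible given (cloud,
PatchDiam, seed, config).

## Stump, root bases, segments

The stump — the upper taproot portion that the large surface roots
spring from — is operationalized as the patches whose centroids lie in a
collar-centred vertical cylinder (radius 1.5x an estimated taproot
radius by default; the estimate is the median horizontal distance of
points in a thin band below the collar) and within a 0-0.30 m depth
band; the largest connected component is taken.

First-order root bases: the stump is expanded by three adjacency
layers; connected components of the expansion layer that can be
extended further away from the stump are kept; each is consolidated by
fitting a cylinder to its points and retaining patches whose centroid is
within `0.5 x radius` of the cylinder surface (the proximity factor is a
package choice; no external value exists). Bases whose cylinders are
nearly parallel, co-axial and close together are merged — a leftover
surface arc of an already-detected root otherwise forms a stub base
that later counts as a phantom root (opposite collinear roots are
protected by a centroid-distance bound). The near-vertical,
axis-centred base — the taproot continuing below the stump band — is
relabelled order 0 so that deep laterals attached to it come out as
first-order.

Segments grow from each base one adjacency layer at a time. When a
front splits into several components, a component spawns a child
segment only if it (a) persists (reaches at least
`segmentation_min_persist` = 3 patches within two further steps) and
(b) actually diverges from the running direction (absolute cosine below
0.82, about 35 degrees). Aligned components stay in the front: with a
few viewpoints, occlusion shadows routinely split the arc of one and
the same root, and spawning those arcs as children would shred the
segmentation. If a front has no unassigned neighbours at all, growth
bridges a single missing adjacency hop (two-step lookahead) before
giving up — point densities marginal for the smallest PatchDiam values
otherwise stall fronts in grazing-incidence regions. Patches unreachable
from any base stay unassigned and are reported, not silently absorbed.

Segments are then cut and recombined to be as long as possible while
staying nearly straight: a child merges into its parent across its
branch point when the merged centroid chain keeps chord/path >= 0.9
(configurable), applying at each step the merge with the highest merged
straightness. Two guards make this well-defined: the parent's remainder
beyond the branch point becomes a child marked as *cut* and can never
re-merge (otherwise cut/merge cycles recur forever), and a merge is
only allowed when the child is at least as long a continuation as the
parent's own tail, so a short side strip cannot re-root a long segment.
The order-0 chain is never re-routed through a lateral.

## Cylinder modelling

Cylinders are fitted by damped Gauss-Newton on orthogonal distance
residuals (point-to-axis distance minus radius; the radius is profiled
out as the mean distance), initialized from the previous cylinder's
direction or the largest principal component, with an analytic Jacobian,
convergence at relative step < 1e-8, at most 100 iterations. Windows
with fewer than 6 points, collinear/coplanar geometry, or diverged fits
raise errors.

Along each segment, candidate windows of {2, 3, 4, 6} x PatchDiam are
fitted independently and scored by *surface coverage*: the fraction of
non-empty azimuth x height cells (8 azimuth cells; one height cell per
PatchDiam of length) as seen from the fitted axis. The
highest-coverage cylinder is emitted (ties prefer the longest
candidate), the walk advances by the window length, and consecutive
cylinders share endpoints. A tip remainder shorter than the smallest
candidate is absorbed into the final cylinder by refitting its window
extended to the tip. Windows larger than 160 points are subsampled by a
deterministic stride for the fit only (least-squares cylinder
parameters saturate well below that); coverage always uses all points.

Four radius safeguards handle windows that geometry cannot constrain:
a fit whose radius exceeds 0.75x the window's spatial extent (a flat or
one-sided arc supports an arbitrarily large radius at tiny residual)
falls back to a robust axis (previous direction through the centroid,
median orthogonal distance as radius); a child cylinder's radius is
capped at 1.2x its parent's; a cylinder with surface coverage < 0.3
cannot exceed 1.3x the median radius of the well-covered (>= 0.5)
cylinders of its own segment; and the first quarter of a lateral chain
is capped at 1.5x the median radius of its distal half — the base
windows of a lateral routinely sit on the parent root's (or taproot's)
surface near the junction and otherwise inherit its girth. These mirror
the taper-sanity corrections customary in cylinder-based tree models.

Child chains attach to the nearest point on the parent's axis segment.
Orders follow the centrifugal classification (stump/taproot chain 0,
their children 1, and so on; orders above 3 are lumped into 3), with
two geometric repairs applied before assignment. First, any segment
that is near-vertical (within 30 degrees) and hugs the collar axis is
part of the order-0 taproot column wherever the growth attached it —
fronts can wander off the taproot into a lateral at a junction, leaving
the rest of the vertical chain stranded as a "child". Second, a
segment of substantial length (>= 0.3 m) whose base sits on the taproot
column and which diverges from the segment it attached to (by more than
about 25 degrees) emerges from the taproot and is first-order by
definition, even when front growth hung it off a neighbouring lateral;
the divergence test keeps parallel occlusion-fragment strips of one and
the same root from being double-counted.

## Traits

A *root* is one segment: the maximal chain of cylinders of one order.
Only coarse roots pass the filter — proximal diameter (2x the first
cylinder's radius) >= 1 cm. Length is the cylinder-length sum, volume
the sum of pi r^2 l in dm^3, number the count of retained roots.
Quadrant stratification uses azimuth classes at +/-45 degrees around
the cardinal axes (half-open); a cylinder contributes length/volume to
the quadrant and depth bin of its midpoint, while the root's count goes
to its base cylinder's quadrant/depth. Depth bins split at 0.30 m below
the collar; exactly 0.30 m counts as deep. Totals exclude the order-0
taproot chain by default (`include_taproot` switches this).

## Digitized reference

Contact-digitized measurements are read from a flat tab-separated
dialect (root id, parent, order, sequence, XYZ, one or two diameters);
the full MTG grammar is deliberately not parsed — the container is
incidental, the computation is not. Reference length is the polyline
length; volume sums conical frusta, V = (pi l / 12)(d1^2 + d1 d2 +
d2^2), using the equivalent circular diameter sqrt(d1 d2) where an
oblong cross-section was recorded with its perpendicular diameter. The
frustum is exact for linear taper, reduces to the cylinder for constant
diameter, and is the standard choice where the upstream software's
formula is not published.

## PatchDiam calibration

QSM output is highly sensitive to PatchDiam, and the optimum differs by
trait. The calibration: (1) sweep the 18-value grid [5, 7.5, 10, 12.5,
15, 17.5, 20, 25, 30, 35, 40, 45, 50, 60, 70, 80, 90, 100] mm with 3
replicate covers per value (replicate count configurable); (2) fit an
ordinary-least-squares straight line of each trait's per-grid mean on
PatchDiam; (3) intersect the line with the trait's reference value to
get the per-trait optimum; (4) refine by brute force — candidates at
{0.6, 0.8, 0.9, 1.0, 1.1, 1.25, 1.6, 2.0, 2.5} x the optimum (clamped
into the swept grid and deduplicated), 5 replicate models each, the
candidate whose mean trait lands closest to the reference wins; (5) build 20
models at the selected value and summarize each trait by the median and
the 5th/95th percentiles (linear interpolation between order
statistics). Method agreement across systems is an OLS regression of
observed reference values on predicted means, with R^2 and the
two-sided slope t-test p-value. Per-trait optima are kept separate;
there is no single compromise PatchDiam.

The refinement bracket is deliberately wide and is this package's
reading of a brute-force step whose candidate set is not externally
specified (configurable). The width matters: a trait can respond
non-linearly to PatchDiam (the first-order count is nearly a step at
desk-scale density), and the straight interpolation line then meets the
reference value far from where the trait response itself crosses it;
the brute-force stage is what recovers the usable neighbourhood.

## Synthetic testbed

The generator builds a taproot (1.2 m, basal radius 7 cm) plus ten
first-order laterals (basal radii 16-26 mm, lengths 1.0-1.6 m, mostly
shallowly descending), Poisson-distributed second- and third-order
children, linear taper to 40% at the tip, mild curvature (3 degrees per
5 cm step), and azimuthal asymmetry weighted toward the downslope (N)
and windward (W) quadrants — sized to emulate excavated mature-conifer
root systems about 1-1.5 m deep and 1.5 m in horizontal extent. Truth
traits are computed analytically from the generative polylines (frusta
over linear taper), and every scan point carries its true cylinder,
root and order label.

The scanner casts exact ray/cylinder intersections from three lateral
viewpoints at 120 degrees (range 4.5 m, within the 3-6 m operating
band), keeps the nearest hit per ray (occlusion), and adds 2 mm
Gaussian range noise along the ray; the 4 mm spot size is recorded but
beam-footprint mixing is not simulated. The angular step sets point
density; the default 0.05 degrees gives millimetre-scale spacing at
range. Scans are upright by default (the posture recommended for such
measurements); an inverted posture is available via the frame tools.

The digitizer resamples each root polyline at 2 cm steps when curved
(mean per-step turn above 2 degrees) and 15 cm when straight, with true
local diameters, and writes the reference dialect.

What the testbed does not emulate: registration error between scans,
background clutter and its manual removal, gravitational sagging of
thin roots, bark roughness and non-circular cross-sections in the
scanned surface, and beam-footprint effects. Passing the closed-loop
tests therefore demonstrates the correctness and calibration behaviour
of the algorithms under the stated scanning geometry and noise — not
field performance on real scans.

## Problem sizes and runtime choices

The closed-loop validation (tests and `scripts/acceptance.py`) runs the
full calibration on one ten-root system scanned at an angular step of
0.033 degrees (about 2.5 mm spacing at range, roughly 2x10^5 points).
This is the package's chosen desk-scale operating point: it keeps the
smallest grid value (5 mm) about twice the point spacing, the same
regime-ordering as a survey-grade scan, while the whole calibration
(54 sweep models + refinement + three 20-model ensembles) completes in
minutes on one CPU. At PatchDiam values below ~2x the spacing the
segmentation degrades gracefully (shorter recovered length, inflated
counts); that behaviour is visible at the low end of the sweep and is
one reason the calibration intersects trait curves rather than trusting
any single PatchDiam.

## Known limitations

- The segmentation forces a tree; root grafts and fused roots (cycles)
  are split arbitrarily at the contested patches.
- Radius estimates on windows seen from a narrow azimuth arc are biased
  and are reined in by the safeguards above rather than estimated
  honestly with uncertainty.
- Number-of-roots is the most PatchDiam-sensitive trait: small values
  fragment (overcount), large values merge neighbouring roots
  (undercount). The per-trait calibration is essential for it.
- The stump boundary (and hence what counts as taproot volume) is a
  convention; totals exclude order 0 by default, and the switch matters
  when comparing against references that include the stump.
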