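# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind each stage of the package, and what the synthetic benchmark
does and does not establish about real data.

## Synthetic data

The generator emulates the four inputs the pipeline consumes.

**Cell images.**  A cell is a filled ellipse of moderate intensity
(default 100) on a dark background with straight, capsule-shaped
filaments drawn at 1.5× the body intensity, 3 px thick, each making a
prescribed angle α ∈ [0°, 90°] with the ellipse major axis.  Filaments
span 75 % of the available chord by default (stress fibers traverse most
of a spread cell) and are placed at seeded random offsets, rejected if
they would leave the ellipse.  The image is blurred with a Gaussian
point-spread proxy (σ = 1 px) and Gaussian read-noise is added.  The
convention used throughout the package: row-major arrays, origin top-left,
a point is (x = column, y = row), angles in degrees from the +x axis
toward +y; filament angles and the long axis are undirected, folded into
[0°, 90°] and [0°, 180°).

Every image carries its `GroundTruth` (ellipse, per-filament angles and
endpoints, seed), so downstream estimates can be scored exactly.  All
generators are pure functions of (parameters, seed).

What the images do **not** emulate: photon shot noise, depth structure of
confocal stacks, filament curvature and crossing networks, multi-cell
crowding, uneven illumination.  Passing the recovery tests therefore
shows the algorithm chain is correct and well-conditioned, not that its
accuracy transfers to arbitrary microscopy data.

**Signals and curves.**  Voltage traces are exact sinusoids
V(t) = A·sin(2πf(t + t₀)) + C; stress–strain curves are linear with
optional Gaussian noise; viability counts are binomial draws
ND ~ Binomial(T, p) rather than deterministic rounding, so the statistics
stage sees realistic sampling noise.

## Orientation quantification

Pipeline: Otsu threshold on a smoothed image → largest connected
component (hole-filled) → outer contour → least-squares ellipse (the
major axis is the cell long axis; near-circular fits, axis ratio > 0.98,
are flagged degenerate since their axis direction is arbitrary) →
filament detection inside the eroded mask → per-filament α → mean
orientation value 1 − α̅/45.

Filament detection combines a Canny edge map with a brightness gate (98th
percentile of the in-mask intensity; filaments are the brightest
structures) and a probabilistic Hough line transform (minimum length
0.2 × the semi-major axis, gap 3 px).  Two post-passes make the detected
directions sub-degree accurate:

1. **Collinear merging** — segments within 3° and 5 px perpendicular
   offset are duplicates of one filament (the transform reports both
   edges of a thick line and fragments long ones); the longest is kept.
2. **PCA refinement** — each kept segment is replaced by the principal
   axis of the bright pixels within a 2.5 px band around it, iterated
   twice so the band re-selects with the refined direction and pixels of
   crossing filaments drop out.  A second merge pass then collapses
   double-edge duplicates whose raw Hough directions differed by more
   than the 3° tolerance.

The statistic is computed from the **mean angle**; because
1 − α/45 is linear in α this equals averaging per-filament values, a fact
asserted by a property test.  Filaments are unweighted by default (a
length-weighted option exists).  Cells touching the image border are not
treated specially; the synthetic scenes keep the cell interior.

Measured performance on the synthetic grid α ∈ {0, 15, …, 90}° (10 images
per angle, 4 filaments each): mean recovered α within ~1° at zero noise
and within ~4–5° at signal-to-noise 5 (noise SD = filament intensity / 5).
The acceptance tolerances are 3° and 6° respectively.

## Device stage

The gel modulus is the OLS slope over the initial half of the strain
range (configurable `linear_fraction`), on engineering stress/strain.
The actuator is a linear gain — 10 µm displacement at 30 V, no
hysteresis — and transduction assumes ideal uniaxial small-strain
compression of the gel layer: σ(t) = E·g·V(t)/h, warning when the implied
strain reaches 20 %.

Sinusoid fitting uses `scipy.optimize.curve_fit` seeded with the dominant
discrete-spectrum frequency, half the trace range, and the trace mean; a
linear solve at the seed frequency initialises the phase.  Amplitude is
reported non-negative with the phase normalised accordingly ((−A, φ) and
(A, φ+π) describe the same curve) and compared modulo 2π; the printed
device-curve phase constant (281.516) has an unstated unit convention, so
only amplitude, angular frequency and offset are recovery contracts.
Flat traces return zero amplitude with an undefined-phase flag.

## Finite-element cell model

**Geometry.**  Half-ellipsoid cell, semi-axes 20 × 10 × 8 µm (long axis
= +x, adhesion plane z = 0), with an ellipsoidal nucleus of semi-axes
6 × 4 × 2 µm centred 3.5 µm above the base.  These dimensions are
configurable defaults for a spread myoblast, not measured values.

**Meshing.**  Points are laid out in a unit half-ball reference space — a
jittered interior lattice, Fibonacci points on the hemisphere, a ring on
the base circle — triangulated with Delaunay and scaled anisotropically
to the physical semi-axes.  Linear 4-node tetrahedra with a target count
(default 5000) are used instead of quadratic elements; correctness is
established by patch tests and a mesh-refinement property rather than by
matching any particular element count.  Tets are labelled nucleus or
cytoplasm by the in-nucleus fraction of ten fixed interior sample points;
at the default resolution both region volumes land within ~1 % of the
analytic values.  The membrane is the single layer of elements owning a
face on the curved apical surface (cytoplasm material; no separate
membrane constitutive law).  The base nodes are fixed in all degrees of
freedom.

**Materials.**  One-term Prony (standard linear solid) relaxation of the
shear modulus only, G(t) = G∞ + (G0 − G∞)e^(−t/τ), with the bulk modulus
elastic, K = 2G0(1+ν)/(3(1−2ν)).  Defaults (kPa, –, s): nucleus
G0 = 3.8, G∞ = 2.0, ν = 0.3, τ = 0.3; cytoplasm G0 = 1.8, G∞ = 0.9,
ν = 0.37, τ = 0.3.  Relaxing shear only is the simplest reading
consistent with a single relaxation constant and Poisson ratio per
region.  Note the long-term uniaxial modulus is then 9KG∞/(3K+G∞), not
2G∞(1+ν).

**Stress fibers.**  Straight parallel truss chains at angle α to the long
axis, embedded 0.6 µm above the adhesion plane (just above the fixed
base, where basal stress fibers run).  Chain endpoints are located inside
host tetrahedra and tied to the host nodes by barycentric interpolation,
so fiber directions are exact regardless of the mesh.  Defaults: 8
chains spread across 80 % of the footprint, reaching 97 % of the way to
the rim, axial rigidity EA = E_actin · n_bundle · πr² with
E_actin = 2 GPa, r = 3.5 nm and a bundle of 50 filaments — representative
stress-fiber values from the cytoskeletal-mechanics literature, all
configurable.  Chains that leave the footprint are clipped with a
warning.

**Loading.**  Two modes.  (i) Dead pressure normal to the apical faces —
used for verification.  (ii) The default `platen` contact: the agarose
overlay (~50 kPa) is an order of magnitude stiffer than the cell
(~2–5 kPa), so the contact is kinematic — the apical cap (nodes above
80 % of the cell height) is driven to a prescribed vertical displacement
with in-plane motion suppressed (adhesion/friction), while the flanks are
free.  The displacement is calibrated by force balance in the long-term
limit: δ(σ) is the displacement at which the platen reaction equals
σ·πab, the applied stress times the footprint area.  The calibration uses
the continuum cell **without** trusses, because the platen position is
imposed by the far-field gel and must not depend on the cell's internal
architecture; a test pins this invariance.  This is the conservative end
of the contact-stiffness spectrum; a fully conforming-gel model would
impose larger displacements and proportionally larger strains.

**Time integration.**  Quasi-static (loading ≤ 10 Hz is far below
inertial scales for a cell); small-strain kinematics (calibrated loads
give strains of order 10⁻²).  The deviatoric internal variables follow
the exact exponential recurrence for strain linear within a step, so the
effective stiffness is constant for a fixed dt and is factorised once;
each step is one sparse back-substitution.  Cyclic runs use dt =
period/40 (dt ≤ period/20 enforced) over 3 cycles; static runs 4 s
(≈ 13τ) at dt = 0.05 s.

**Reported metrics.**  At the cycle-maximum load of the final cycle
(static: the final step), the membrane's maximum principal strain is
summarised as the apical-face-area-weighted average and the elementwise
peak.  Elements touching a constrained node (fixed base ring, platen
edge) are excluded: their strain is dominated by the boundary-condition
singularity, which sharpens under refinement and does not represent the
solution field.  Verification: a uniaxial box patch test reproduces the
closed-form homogeneous strain within 1 % at both elastic limits; a
confined-compression relaxation run reproduces the analytic deviatoric
decay to G∞/G0 = 0.5 within 1 %; cyclic strain amplitude on a single
element moves monotonically between the long-term and instantaneous
elastic responses as frequency grows.

**Angle–strain mechanism.**  Under platen (displacement-controlled)
contact, fibers along the long axis let the imposed flattening escape
through the compliant short-axis flanks, while perpendicular fibers block
that route and redirect strain into the membrane, adding concentrations
where they anchor.  Average and peak membrane strain therefore grow with
α, with angle–strain Pearson correlations ≈ 0.98 at the default
resolution.  The average is monotone across the α grid in every mesh
realisation examined; the peak — a single-element extremum — can wiggle
at the few-tenths-of-a-percent level between neighbouring angles, so the
monotonicity assertion carries a 1 % discretisation-noise allowance and
is paired with the correlation requirement.  Under dead-pressure loading
the effect size is much smaller and can invert: any passive reinforcement
reduces mean deformation under force control, which is why the contact
mode matters and is documented here as a modelling conclusion of this
package.

## Damage and viability statistics

Damaged elements are counted with a **strict** inequality (strain >
threshold); a value exactly at the threshold is undamaged.  The
physiological membrane threshold default is 20 %.  The scaled-down model
operates at a smaller strain scale (averages ~2 %, peaks ~7–10 % under
the calibrated platen loads), so the end-to-end trend study uses a
threshold of 3 % — the value standing to this model's strain scale as
20 % stands to a real membrane — while every formula keeps 20 % as its
default.

The simulated viability model makes death probability linear in the
average membrane strain (baseline 2 %, slope 10 per unit strain, clipped
to [0, 1]) with binomial counts over T = 10 000 cells, mirroring a
live/dead assay at normal seeding density.  In the end-to-end study both
the damaged-element percentage difference and the death-rate reduction
derive from the same strain field, so they move in the same direction
across frequencies — the sign agreement asserted by the acceptance test.
At the cycle-peak evaluation instant the cyclic conditions carry 1.5× the
static load, which outweighs the reorientation benefit in this model, so
both statistics come out negative relative to static; their agreement,
not their sign, is the tested property.

Pearson correlation is preceded by a Kolmogorov–Smirnov normality check
on each standardised variable; the result is recorded as a flag, never a
gate.  Two groups are compared with Student's t-test, more with one-way
ANOVA, with significance tiers at 0.05/0.01/0.001 and no
multiple-testing correction — both choices mirror the reporting
conventions of the experimental field this package serves.  Identical
constant groups report p = 1 (no evidence of difference) rather than the
NaN a degenerate t-statistic would give.

## Numerical choices and degenerate inputs

* Ellipse fits need ≥ 5 contour points; collinear contours raise a fit
  error; circles are flagged degenerate rather than rejected.
* Empty images and all-background scenes raise an empty-scene error; an
  image with no detectable filaments returns an empty list and a NaN
  orientation value (no filaments is a valid observation).
* Flat stress traces return amplitude 0 with the phase flagged
  undefined; non-convergent sinusoid fits raise with the last residual.
* Zero-variance inputs to the correlation raise an undefined-correlation
  error; DE_static = 0 makes the percentage difference undefined and
  raises.
* Meshes with inverted or degenerate tets are rejected; a sliver filter
  removes near-zero-volume Delaunay artefacts before assembly.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical parameters and seed give
  byte-identical outputs everywhere.

## Problem sizes

Default study sizes: 256×256 px images with 4 filaments; 5000-element
meshes (~1200 nodes) for the angle sweep; 2000-element meshes and 3–4
images per condition for the five-condition end-to-end study.  These
sizes put every verification target (patch tests at 1 %, orientation
recovery at 3°/6°, monotone angle–strain trend) comfortably within reach
of the discretisations used.

## Known limitations

* Small-strain linear kinematics: the real contact problem is finite-
  deformation with evolving contact area; the platen calibration is a
  linearised stand-in.
* The membrane has no constitutive identity of its own — it is the
  apical element layer of cytoplasm material — so absolute membrane
  strain values are indicative, not predictive; only relative trends
  across α, frequency and load are interpreted.
* Microtubules and intermediate filaments are absent; nuclear strain is
  not a validated output.
* The viability model is phenomenological; it propagates strain into
  counts for statistical testing, it does not model death mechanisms.
* The synthetic images are far cleaner than real confocal projections;
  the recovery tolerances certify the algorithm, not microscope-grade
  accuracy.
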