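# Methods

## Model overview

`callusim` simulates secondary fracture healing in a nailed femoral shaft
fracture as a coupled mechano-biological process and classifies the
predicted outcome the way a radiologist would: per-cortex bridging and a
modified Radiographic Union Score for Tibia (mRUST) applied to the femur.

The simulated day loop is:

1. **Homogenize.** Each voxel's isotropic Young's modulus is the
   concentration-weighted (Voigt) mixture of its tissue moduli; a Reuss
   (harmonic) rule is available in the material configuration.  Cortex and
   nail voxels use fixed materials.
2. **Solve.** A small-strain linear-elastic finite-element problem on the
   voxel grid (trilinear hexahedra, 2x2x2 Gauss) gives the displacement
   field under body-weight-scaled loading.  Element-center strains yield
   the two stimulus invariants: distortional strain (octahedral shear of
   the deviator) and dilatational strain (trace).
3. **Classify.** Crisp strain windows map the local stimulus to a signal:
   destruction above the distortional cutoff; intramembranous ossification
   in the low-strain window when vascularity is adequate; chondrogenesis at
   moderate distortional strain; otherwise no differentiation.
4. **Advance.** Vascularity spreads from vascularized neighbors as a front
   and is reset in voxels under destructive strain.  Tissue fractions move
   along the allowed transitions -- connective -> woven (intramembranous),
   connective -> cartilage (chondrogenic), cartilage -> woven
   (endochondral, gated by vascularity), woven -> lamellar (remodeling at
   low strain and near-full vascularity), formed tissue -> connective
   (destruction) -- with per-day fractional rates, computed simultaneously
   from start-of-day pools and renormalized to unit sum.

There are no stochastic terms in the loop; all randomness lives in the
scenario generator.  Outcomes: a cortical quadrant is *bridged* on the
first day a face-connected (6-neighbor) column of voxels with lamellar
concentration >= 0.70 spans the healing region axially inside the
quadrant's 90-degree sector (the intact cortex participates, so the column
must cross the fracture slab through newly formed bone).  A case is a
*union* when at least 3 of 4 quadrants bridge within 280 days; the
consolidation day is the third quadrant's bridging day.  mRUST scores each
of the four cortices 1-4 (no callus / non-bridging callus / bridging
callus with visible fracture line / bridging callus without fracture
line), summed to 4-16 with >= 9 defined as consolidated.

## Geometry and discretization

The diaphyseal segment is an idealized straight hollow cylinder scaled
linearly with patient height (outer diameter 28 mm and cortical thickness
6 mm at the reference height of 173.4 cm; segment length 72 mm).  The
fracture is a planar slab of configurable thickness and obliquity, with
optional translational offset of the distal fragment; the periosteal
callus envelope is a 4 mm annulus extending 10 mm beyond the gap.  The
nail is a straight cylinder; locking screws are stiff chords through the
canal at +/-25 mm.  Canal marrow is excluded from the mesh: its stiffness
is negligible and the physiological load path runs through the locking
screws.

The gap slab's effective half-thickness is floored at half a voxel so a
thin gap always severs the cortex on a coarse grid; consequently gap sizes
are quantized by the grid pitch at desk resolutions (several nominal gap
sizes can map to the same discrete slab), which flattens, but never
inverts, the gap-size/healing-time relationship.

Default resolutions (the package's own desk-scale choices): 2.5 mm voxels
for headline single-case runs (grid about 18x18x30), 3.0 mm for parameter
sweeps (about 12x12x24, the coarsest grid that still resolves the cortex
with two voxels).  A refinement check in the test suite verifies region
volume fractions change by < 2% between 1.0 and 0.5 mm grids.

## Mechanics

Boundary conditions: the distal cross-section is fully fixed; the proximal
cross-section carries consistent surface tractions representing a
compressive axial resultant plus linear bending stress for the two moment
components (a deliberate reduction of per-muscle attachment loading).  The
load resultants scale with body weight: axial force 2.5 x BW, and bending
moments given by calibrated lever arms (65 mm about the anterior axis,
160 mm about the mediolateral axis).  The lever arms are calibration
constants of the desk-scale model, chosen once so that the favorable
default scenario (2 mm gap, 13 mm nail) consolidates inside the 120-280
day envelope while the compromised default (8 mm gap, 9 mm undersized
nail) exhibits persistent destructive strain and fails to bridge; they are
not measured quantities.

Default materials (MPa): connective tissue 3, fibrocartilage 10, woven
bone 1000, lamellar/cortical bone 10,000, titanium nail 110,000; Poisson's
ratio 0.3 throughout.  These are literature-typical values exposed in the
configuration, not asserted as measurements.

The linear solver is deterministic: conjugate gradients preconditioned by
a cached sparse LU factorization (symmetric-mode minimum-degree ordering)
of a recent stiffness matrix, warm-started from the previous day's
displacements, with relative tolerance 1e-8.  Because tissue moduli evolve
by a few percent per day, a stale factor remains an excellent
preconditioner; it is rebuilt automatically once CG needs more than 40
iterations.  A patch test (closed-form bar strain within 1%), a dense-solve
oracle comparison, linearity, and stiffening-monotonicity checks verify
the implementation.  Solvability is checked structurally: any mesh
component without a fixed degree of freedom raises a floating-fragment
diagnostic.

`simulate_healing` accepts a `mechanics_interval` (default 1 day) that
re-solves the elastic problem only every N days, reusing the last strain
field in between -- a quasi-static coarsening used for the sweep studies.

## Differentiation rule set

The fuzzy-rule formulations this model family descends from are not
available in full anywhere accessible, so the rule set here is a documented
crisp strain-window scheme with every threshold and rate exposed in
`RuleSet`:

| parameter | default | meaning |
|---|---|---|
| `im_distortional_max` | 0.05 | upper distortional bound for intramembranous ossification |
| `im_dilatational_max` | 0.05 | absolute dilatational bound for the same window |
| `chondro_distortional_min` | 0.05 | lower distortional bound for chondrogenesis |
| `destruction_cutoff` | 0.17 | distortional strain destroying formed tissue (configurable up to 1.0) |
| `v_min_ossification` | 0.5 | vascularity gate for bone formation |
| `v_min_remodeling` | 0.9 | vascularity gate for remodeling |
| `remodel_distortional_max` | 0.05 | strain gate for remodeling |
| `rate_intramembranous` | 0.2/day | connective -> woven |
| `rate_chondrogenesis` | 0.1/day | connective -> cartilage |
| `rate_endochondral` | 0.15/day | cartilage -> woven |
| `rate_remodeling` | 0.008/day | woven -> lamellar |
| `rate_destruction` | 0.5/day | formed tissue -> connective |
| `vascular_rate` | 0.1 mm/day | vascular front speed |

Bone-formation rates (intramembranous and endochondral) are multiplied by
the largest mineral fraction in the voxel's 6-neighborhood
(osteoconduction, the intact cortex counting as bone), so ossification
advances as an appositional front from existing bone surfaces rather than
appearing simultaneously throughout the gap; together with the vascular
front this makes healing time grow with gap size.  The slow remodeling
rate dominates the consolidation clock (lamellar reaches the 70% bridging
threshold after roughly `ln(0.3)/ln(1 - rate)` ~ 150 days of remodeling),
which places the favorable default's consolidation near the middle of the
120-280 day envelope.  All rates and windows are calibration knobs of this
package; no parameter recovery against the unavailable source rule tables
is possible, and none is claimed.

## Synthetic cohort

The generator emulates the target population's summary statistics: age
30.4 +/- 14.5 years truncated to the clinical inclusion window [16, 65],
height 173.4 +/- 12.8 cm, weight 80.4 +/- 18.3 kg (both truncated at
+/-4 SD, a negligible correction), sex 20 M : 7 F, side 17 L : 10 R.  BMI
is derived, never sampled.  A note on the age window: no truncated normal
on a 49-year window can have a standard deviation of 14.5 (the supremum is
about 14.1), so the parent moments are used as configured and the realized
truncated mean (~34.3 y) exceeds the parent mean; the moment-recovery test
therefore compares the age mean against the analytic truncated-normal
expectation rather than the parent value.  Height and weight means are
recovered within 3 standard errors at n = 10,000.

Scenarios are a two-class mixture at a configurable compromised fraction
(default 6/27, the clinical non-union prevalence): favorable cases draw
gaps of 1-3 mm and nails of 12.5-14 mm; compromised cases draw gaps of
6-10 mm and undersized nails of 8.5-9.5 mm.  The class boundary is an
artifact construct that guarantees both outcome classes at desk scale; the
per-case gap sizes and nail diameters of the original cohort are unknown.

What the generator does *not* emulate: patient-specific femoral geometry
beyond linear height scaling, comorbidities, variable weight-bearing
compliance, fracture comminution, and the correlation structure between
anthropometrics and fracture severity.  Passing cohort-level tests
therefore demonstrates that the machinery is correct and calibrated on its
own terms, not that it reproduces any clinical accuracy figure.

## Numerical choices and degenerate inputs

- Concentrations are renormalized to unit sum after each update; the mass
  defect per day is at round-off level and is tracked over whole runs
  (max deviation < 1e-9 over 280 days in the acceptance suite).
- Quadrant boundaries lie on the diagonals, half-open and rotationally
  symmetric, so sector voxel counts are balanced; ties cannot occur
  because the shaft axis passes through a voxel-corner line.
- The bridging window is inclusive (day <= 280 counts); the lamellar
  threshold is inclusive (>= 0.70).
- Path connectivity is 6-neighbor by default (a diagonal-only chain is not
  a physical column); 26-connectivity is available.
- A zero gap produces a continuous cortex (bridged at day 0); `max_days=0`
  returns a trajectory holding only the initial state; an empty cohort is
  a valid file but cannot be evaluated into a confusion matrix (accuracy
  undefined, rejected with an error).
- Scenario infeasibility (nail not fitting the canal, offset leaving no
  room for the nail, screws outside the segment) raises dedicated errors
  at domain-build time.

## Confusion-matrix convention

Union (consolidation) is the positive class.  `true_positive` = predicted
union and truly union; `false_negative` = predicted union but truly
non-union; `true_negative` / `false_positive` analogously.  The source
literature on this pipeline is internally inconsistent about which
misclassification is the "false negative"; this package fixes the
convention above and documents it at every surface.

## Known limitations

- Desk-scale voxel grids (thousands to tens of thousands of elements)
  cannot resolve screw threads, nail curvature, or cortical thickness
  variation; gap sizes are quantized by the grid pitch.
- The crisp rule set has hard window edges; trajectories can be sensitive
  near thresholds where a fuzzy formulation would interpolate.
- Loading is a single static resultant per day; gait cycles, muscle
  co-contraction and load progression during rehabilitation are not
  modeled.
- The two-class scenario mixture makes cohort-level accuracy a property of
  the generator's class separation, not a clinical claim.
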