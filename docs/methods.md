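# Methods

This note records the models, conventions and numerical choices behind
`contourqa`, and what the synthetic validation does and does not show.

## Geometry and surfaces

Volumes live on axis-aligned voxel grids indexed `(x, y, z)` with the
voxel center of index `(i, j, k)` at `origin + spacing·(i, j, k)` in mm.
Anisotropic spacing is first-class: the motivating scan protocol combines
~1–1.6 mm in-plane resolution with 7.5 mm slice spacing, so treating
distances in voxel units would distort the longitudinal axis by a factor
of ~6. All distances everywhere in the package are Euclidean in physical
millimetres.

A structure's **surface** is the set of centers of its boundary voxels
under 6-connectivity (an occupied voxel with at least one face-adjacent
unoccupied or out-of-grid neighbor). No sub-voxel vertices or meshes are
introduced; voxel centers are the coarsest surface representation
consistent with a binary volume, and they make the distance distribution a
finite multiset with one element per surface voxel — which is what the
order-statistic percentile and the cardinality ratio Eff(δ) are defined
on.

**Rasterization** of planar contours uses the even-odd rule on voxel
centers: a center is inside if a horizontal ray crosses the polygon edges
an odd number of times, with a half-open edge convention (strict
inequality against the intersection abscissa, upward/downward edge
asymmetry) so boundary-grazing centers resolve deterministically. Nested
polygons on one plane XOR together, so holes need no special casing.
Contour planes must land within half a slice spacing of a grid slice;
anything else is rejected as a coordinate mismatch. The inverse operation
(`mask_to_contours`) traces exact voxel-edge loops, so
mask → polygons → mask round-trips are bit-exact; this is how RT-STRUCT
fixtures are built.

Only axis-aligned geometry is supported. Oblique DICOM orientations and
non-diagonal NIfTI affines are rejected at read time rather than silently
resampled.

## Metrics

* **Dice** is computed on occupied-voxel counts. The Dice of two empty
  masks is an error, not 0; a single empty mask yields a degenerate report
  (Dice 0, NaN distances) with a flag, since "distance to an empty
  surface" has no value.
* **Distance distributions** are exact nearest-neighbor queries between
  the two surface point sets (k-d tree). Directions: `a_to_b`, `b_to_a`,
  or `symmetric` (the multiset union, cardinality |A|+|B|).
* **HD percentiles** are order statistics without interpolation: the
  smallest distance t with at least p% of distances ≤ t. `p = 100` is the
  Hausdorff distance proper.
* **Eff(δ)** counts distances *strictly* below δ, per its defining ratio;
  exact-zero distances (coincident surface voxels) therefore count, and
  identical contours score Eff = 1 for any δ > 0. The default δ = 1 mm
  approximates one in-plane voxel. Eff is computed on the *directed*
  AI→clinical distribution by default — it estimates the fraction of the
  AI surface a clinician left alone, which is an asymmetric question — with
  the symmetric variant available by flag. HD95, by contrast, is reported
  on the symmetric distribution, matching the symmetric definition of the
  Hausdorff distance.

One consequence of the directed default worth knowing: for a structure
confined to a single slice, an in-plane enlargement of the clinical
contour leaves the AI top/bottom faces on the clinical surface, so
directed Eff can stay high even though the clinical contour grew. This is
a property of the definition, not a bug; the symmetric variant penalizes
it.

## DVH engine

Cumulative DVHs are binned at 1 cGy: `V(d)` is the fraction of structure
volume receiving ≥ d cGy, so `V(0) = 1` and the curve is monotone
non-increasing. Before dose sampling the mask is refined longitudinally by
slice replication (default factor 3, turning 7.5 mm slices into 2.5 mm
sampling); replication conserves volume exactly and adds no new in-plane
information, matching the policy of evaluating dose on a finer
longitudinal grid than the contours were drawn on. Dose is read by
trilinear interpolation at the refined voxel centers; the dose grid may
differ from the mask grid, and a structure whose occupied centers leave
the dose grid's physical extent (voxel boundaries, i.e. half a voxel
beyond the outermost sample centers) raises a coverage error reporting the
out-of-grid fraction.

DVH statistics follow the clinical reading "dose to p% volume":
`D(p)` is the **largest** dose level with `V(d) ≥ p/100` (so a uniform
1000 cGy bath has D50 = 1000 cGy, and a half-0/half-1000 structure also
has D50 = 1000 cGy at the boundary), `Dmean` is the integral of the
cumulative curve (bin sum × width, equal to the mean voxel dose within one
bin), and `Dmax` the largest dose with positive volume.

**Flagging.** Two curves are compared with a windowed discrepancy: at each
dose level d, each curve may be matched against the other anywhere within
±20 cGy, and the discrepancy is the larger of the two directed residuals.
Because a cumulative DVH is monotone, the windowed minimum is the distance
from one curve's value to the [min, max] band of the other over the
window, computed with running min/max filters. A pair fails when the
discrepancy exceeds 0.05 relative volume at any dose level ≥ 20 cGy. This
bidirectional-window reading is the one under which the 20 cGy tolerance
actually changes outcomes: it forgives pure horizontal (dose-axis) shifts
up to 20 cGy in steep-gradient regions while catching vertical (volume)
discrepancies of any shape. Setting the window to 0 recovers the plain
pointwise rule. The flagging window may extend below 20 cGy, but flags are
only raised at d ≥ 20 cGy. Structures receiving no dose produce valid
degenerate curves and pass vacuously (any two contours agree under zero
dose); cohort rows carry a `zero_dose` flag for this.

## Cohort statistics

Per-structure summaries report mean ± sample SD (n−1 denominator; the
convention is a package choice); single-row groups report SD 0 and are
identifiable by n = 1. Left/right pairs group via laterality-normalized
name keys (`Lens_L`, `L Lens`, `Lens (L)` → `lens_l`; the token table is
overridable). The pass/fail comparison runs a two-sample KS test per
metric, with the asymptotic p-value (group sizes here are tens to
hundreds; an exact enumeration would buy nothing) and the statistic
computed exactly. Zero-dose structures are excluded from the pass/fail
comparison by default because their vacuous passes dilute the contrast;
they remain in metric summaries.

## Phantoms

The generator emulates the study conditions the toolkit targets: a grid of
1.17 mm in-plane pitch and 7.5 mm slices (64×64×24 voxels ≈ 75×75×173 mm
per synthetic patient — a deliberately compact torso surrogate that keeps
a full cohort evaluation in seconds while preserving the anisotropy that
drives the interesting behavior), an inventory of 27 OARs + 4 PTVs with
organ-scale parametric shapes (spheres, ellipsoids, z-aligned tubes,
boxes), and a conformal dose field (prescription 1200 cGy inside the bone
PTV, exponential falloff with a 12 mm length scale) so that different
structures sit in genuinely different dose gradients.

Editing perturbations mirror clinically observed patterns, each with an
analytic signature used in validation:

* `truncate_superior(k)` (kidney/esophagus-style superior-border edits):
  directed AI→clinical distance peaks at k × slice spacing at the cut, and
  Eff(1 mm) ≈ 1 − f where f is the fraction of the AI surface on the
  removed slices;
* `dilate(r)` (systematically larger clinical contours): surface distances
  concentrate at r;
* `shift(v)`: rigid translation snapped to whole voxels, HD ≈ |v| for slab
  geometries;
* `boundary_noise(σ)`: surface-adjacent voxels toggle with probability
  `σ/(σ + s)` (s the minimum in-plane pitch) — a saturating map chosen so
  σ has mm units and σ → 0 is the identity.

Default assignments leave eyes and lenses unedited (Eff = 100%), apply
truncation to kidneys and esophagus, dilation to optic structures and two
PTVs, and noise elsewhere, with magnitudes drawn per patient from fixed
ranges; PTVs receive larger edits than OARs. These defaults are
qualitative, not calibrated to any clinical cohort's numbers. All
randomness derives from one seed via CRC-hashed per-(patient, structure)
substreams, so cohorts are pure functions of (spec, seed).

**What passing phantoms does not show.** Phantom shapes are convex-ish
parametric solids without the thin, branching, low-contrast anatomy where
real auto-segmentation fails; the dose model is a caricature of a plan,
not a calculation; and the perturbations are independent per structure,
unlike correlated human editing styles. The phantom suite validates the
*measurement machinery* — that the metrics recover known deviations and
the flagging rule behaves as specified — not any claim about real
segmentation quality.

## Numerical choices and limitations

* Voxelization tolerances in tests scale with the voxel diagonal; sphere
  closed forms (Dice = 2ρ³/(1+ρ³), cap-volume DVH fractions) are recovered
  within tolerances that shrink as spacing/radius → 0.
* The k-d tree nearest-neighbor path is checked against all-pairs
  brute-force distances on instances ≤ 10⁴ surface points; rasterization
  against an independent point-in-polygon oracle; the KS statistic against
  the pooled-point supremum; Pearson against the direct formula.
* Problem sizes in the test and acceptance runs (203³ voxels for the
  two-sphere bound, ≤ 90³ for DVH oracles, 21 synthetic patients × 31
  structures for the cohort) were chosen as the smallest scales at which
  the analytic expectations are sharp.
* RT-STRUCT/RT-DOSE writing exists for fixtures and phantom export only;
  dose is stored as 32-bit integers with a Gy scaling chosen so round-trip
  error is below one scaling quantum.
* Not implemented by design: mesh/sub-voxel surfaces, deformable
  registration, oblique geometry, absolute-volume DVHs, dose calculation,
  and biological (TCP/NTCP) models.
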