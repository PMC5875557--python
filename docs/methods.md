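# Methods

## Model and assumptions

`dose4d` computes the respiration-accumulated ("4D") dose by *pointwise
deformable dose tracing*. The inputs are K phase-binned 3D dose grids
`D_x` (Gy), K deformation vector fields `φ_x` mapping reference-CT
coordinates to phase-x coordinates, and per-phase time weights `w_x`
(fractions of the breathing cycle, Σ w_x = 1). For each reference voxel
center `p`, the dose received during phase x is obtained by *pulling* the
phase dose at the displaced position:

    TDx[p] = D_x(φ_x(p)),        D4D(p) = Σ_x w_x · TDx[p]

Assumptions and limitations:

* **Pointwise tracing, no mass/energy correction.** No Jacobian weighting
  is applied when a DVF compresses or expands tissue, so locally the traced
  dose is the dose *at* the displaced point, not an energy-conserving
  remap. This is adequate for the near-rigid motion this tool targets and
  is the standard simplification of voxel-tracking accumulation; strongly
  compressive fields will bias hot/cold spots.
* **Per-phase dose grids are inputs.** The toolbox does not recompute dose;
  it assumes each `D_x` was produced by a treatment planning system on the
  corresponding phase CT.
* **DVFs are inputs.** Any registration algorithm may produce them; the
  toolbox only validates (displacement statistics, fraction of voxels
  displaced off the dose grid) and interpolates them.
* **Interpolation.** Phase doses and dense DVFs are sampled trilinearly at
  exact displaced coordinates (exact for affine functions, error
  ≤ max|∂²f| · h²/8 per axis otherwise). The craniocaudal refinement step
  (default 3 mm → 1 mm) is retained as an explicit pipeline stage; because
  linear interpolation of linearly interpolated samples reproduces the same
  piecewise-linear function, it does not change traced values, but it
  materializes the 1 mm intermediate dose artifact for QA. A
  nearest-neighbour sampling mode exists as a compatibility option.

## Coordinate and data conventions

All coordinates are DICOM patient LPS millimetres; voxel indices are
0-based and refer to voxel centers; arrays are `(nx, ny, nz)` with x along
image rows. Point-correspondence ("M-matrix") files are 6 numeric columns
(source xyz, target xyz), whitespace- or comma-delimited, one optional
header line; they may be expressed in mm or in **1-based** voxel indices of
the reference CT — the unit is an explicit import flag, never guessed, since
exported registration files rarely document it. Row order is preserved:
when the correspondence points coincide with the traced voxel set, traced
arrays follow M-matrix row order, otherwise raster order.

Out-of-hull DVF queries clamp to the nearest in-hull displacement.
Reference voxels displaced off a phase dose grid follow a configurable
policy: `zero` (default — a voxel that leaves the planned beam genuinely
receives ≈0 Gy; silent nearest-fill would inflate coverage), `nearest`, or
`error`. Affected voxels are flagged, counted in the run report, and the
accumulated voxel carries the union of per-phase flags. Under the zero
policy the missing phases contribute 0 Gy; the remaining weights are *not*
renormalized, since the dose is physically absent, not unmeasured.

RTDOSE export stores 32-bit unsigned integers with
`DoseGridScaling = max/(2³²−1)`, so write→read round-trips are exact to one
scaling quantum (~5 nGy for a 23 Gy grid). DICOM decimal-string attributes
are capped at 16 characters, which bounds geometry/contour round-trip
precision at ≈1e-6 mm.

Contours are rasterized slice-wise by voxel-center point-in-polygon tests
(shapely), boundary points counting as inside; multiple contours on a slice
combine by XOR (even-odd rule), so nested contours form holes.

## Plan metrics

* DVH: exact cumulative counts at uniform bin edges (default 0.05 Gy),
  `V(d)` linearly interpolated between edges; thresholds use ≥.
* Dmin/Dmax: true voxel extrema (no percentile smoothing); Dmin is
  therefore sensitive to single cold voxels, by design.
* TCI = % of target voxels ≥ D_p.
* CI: the isodose level D_RI is the largest dose covering the requested
  target fraction (default 99.5%, i.e. the ⌈0.995·N⌉-th largest target
  dose); CI = (body voxels ≥ D_RI)/(target voxels), whole grid as body if no
  body mask. The definition is isolated so a Paddick-style alternative can
  be swapped in.
* HI = point maximum target dose / D_p.
* Matching Index = |A∩B| / |A∪B| by voxel count (Jaccard).

## The synthetic 4D phantom

The phantom emulates free-breathing delivery of a static conformal plan in
the simplest geometry with exact ground truth: a sphere (radius r, +1000 HU
over a −800 HU background, optional seeded HU noise) translates rigidly
along `t_k = A·sin²(πk/K)` (end-inhale at k = 0 with zero displacement,
end-exhale at k = K/2 with the full peak-to-peak amplitude A, longer dwell
near end-exhale), while the planned dose stays fixed in patient
coordinates: a plateau of `D_p/f` inside r falling as a half-Gaussian of
width σ outside, encoding "D_p prescribed at the f isodose" (defaults
20 Gy at 85%, σ = 3 mm — a clinical beam-penumbra scale). Each phase bin is
written as a DICOM CT series, an RTDOSE grid, and a rigid M-matrix DVF
(exact under trilinear interpolation even on its coarse 5³ lattice), plus a
reference-phase RTSTRUCT GTV and a JSON manifest with uniform 1/K weights.

Because motion is rigid and the beam fixed, the exact accumulated dose is
available in closed form,

    D4D(p) = Σ_k (1/K) · profile(|p + t_k − c₀|),

i.e. the static profile blurred by the discrete motion probability mass
function. This yields sharp oracles: zero amplitude reproduces the static
dose bit-for-bit through the whole file pipeline; translations that are
integer multiples of the voxel spacing make tracing exact (≤1e-9 Gy);
voxels whose displaced positions stay a full cell diagonal inside the
plateau at every phase accumulate exactly `D_p/f`; and the general case is
bounded by twice the measured trilinear error estimate
`Σ_axis max|Δ²| / 8` of the static dose array.

Deliberately *not* modelled: lung texture, non-rigid deformation (rigid
motion is what admits exact ground truth; deformable fields are verified
against independent numerical interpolation oracles instead), interplay
with dynamic delivery, and density-driven dose differences between phases.
Passing phantom tests therefore demonstrates correctness of the
registration/accumulation/metric machinery, not of any registration
algorithm or dose engine applied to real anatomy.

Default study conditions: 48×48×26 grid at 1.25×1.25×3 mm, r = 10 mm,
A = (0,0,9) mm craniocaudal (the upper end of reported lung-tumor
excursions), K = 10 phase bins. The test suite uses a 24×24×16 twin at
2×2×3 mm with 6 mm motion to keep the full-file round trips fast; problem
sizes are stated in each test.

## Numerical choices

* Weights must sum to 1 within 1e-9 at construction; `normalized()` is the
  explicit rescaling path. Sub-range (duty-cycle) accumulation renormalizes
  the selected weights, making it the conditional time average.
* In-grid tests use a 1e-7 continuous-index tolerance so boundary voxel
  centers are inside; rasterization boundary ties count as inside.
* CT series are sorted by projected slice position along the slice normal
  (not InstanceNumber); slice gaps must be uniform within 1%; mixed series
  UIDs are an error naming both UIDs.
* Degenerate inputs fail loudly: empty masks, non-GY dose units, missing
  DoseGridScaling, negative/NaN dose at export, malformed M-matrix rows
  (with line numbers), frame-of-reference mismatches.

## Open design points resolved

* General RTDOSE grids need not coincide with the CT lattice, so an
  explicit trilinear alignment stage precedes tracing; coincident lattices
  pass through unchanged.
* Correspondence DVFs whose source points do not form a regular grid fall
  back to nearest-neighbour displacement (still exact at source points);
  regular grids — the intended format — interpolate trilinearly.
* `V_D` and TCI use ≥ at the threshold; HI uses the point maximum — both
  per the plain reading of the index definitions.
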