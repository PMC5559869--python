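# Methods

## Problem

Axial vertebral rotation is a defining feature of adolescent idiopathic
scoliosis, and holding the surgically achieved de-rotation is one goal of
instrumented fusion. On post-operative CT, each vertebral endplate can be
re-oriented into its own plane (a *true axial* slice), traced, and its
axial orientation measured; differences between adjacent endplates give
inter-vertebral (intra-discal) and intra-vertebral rotations, and their
differences between two post-operative timepoints give the longitudinal
change at every level of the instrumented segment and the adjacent
un-instrumented levels. `vertrot` implements that measurement chain and
the statistics around it, and ships a synthetic phantom generator so the
entire chain is testable against known ground truth without patient data.

## Orientation measurement: the maximum-symmetry axis

A traced endplate outline is filled into a binary raster `S` (pixel
centre-inside rule on a half-pixel-offset grid, which keeps the raster
area an unbiased estimate of the polygon area). For a candidate axis
through the foreground centroid at clockwise angle φ from the in-slice
anteroposterior (AP) reference, the symmetry ratio is

    r(φ) = area(S ∩ mirror(S, φ)) / area(S) ∈ [0, 1],

computed in continuous coordinates: every foreground pixel centre is
reflected about the axis (`p' = c + (2uuᵀ − I)(p − c)`) and the mask is
sampled bilinearly at `p'`. Bilinear continuous-coordinate reflection
(rather than pixel-index flipping) removes most of the grid-axis bias
that would otherwise attract the peak toward 0°/90°. `r` is exactly
180°-periodic and equals 1 (up to raster tolerance) iff the mask is its
own mirror image about the tested axis.

The profile `r(φ)` is sampled over [0, 180) on a uniform grid
(`angle_step`, default 0.1°, matching the 0.1° reporting precision of
the measurement), lightly smoothed circularly (Gaussian, σ = 0.3°), and
its local maxima are refined by parabolic interpolation of the three
samples around each peak. The selected orientation is the
global-maximum peak.

### Ambiguity

Near-elliptical endplates have two perpendicular reflection axes, so
their profiles carry two rival peaks ~90° apart; a disc is symmetric
about every diameter and its profile is flat. The profile is flagged
*ambiguous* when ≥2 peaks lie within `peak_tolerance` (2%) of the global
maximum and are separated by more than `min_peak_separation` (10°,
circular), or when the profile's total range is below `flat_tolerance`
(2%, set above the ~1.5% residual raster anisotropy a disc shows at
0.4–0.5 mm pixels). Ambiguous measurements are resolved against a
caller-supplied prior angle — typically the same endplate at the other
timepoint or an adjacent endplate, standing in for manual review of the
ratio-vs-angle graph — by choosing the rival peak circularly nearest the
prior; exactly equidistant rivals break ties toward the smaller angle.
Without a prior the endplate is *unmeasurable* and the patient is
excluded from cohort summaries, mirroring clinical practice for ovoid,
misshapen vertebral bodies.

### Numerical behaviour

On noise-free pedicled phantoms at the default operating point
(0.4 mm pixels, 0.1° step) the recovered angle is within ~0.2° of truth
(RMSE ≈ 0.08°, worst case ≈ 0.3° over randomized shapes and angles), and
the equivariance defect — the difference between measuring a rotated
shape and rotating a measurement — stays below the same bound. The
0.4 mm default matches typical CT in-plane resolution and keeps raster
jitter an order of magnitude below the 0.6° tolerance the measurement
chain budgets (one angular grid step + 0.5°).

## True-axial reformatting

The endplate plane is fitted to ≥3 observer-placed landmarks by
total-least-squares (SVD); the normal is oriented cranially so every
slice is viewed from above, and the scanner-bed AP axis is projected
into the plane to define the in-slice angular reference. The slice is
resampled by trilinear interpolation on a square pixel grid in the
plane; mask phantoms are re-binarized at 0.5. The reference is returned
in slice coordinates, making measured angles invariant to the slice
pixel-grid orientation (checked by re-extracting with the grid rotated
90°). By default the slice passes exactly through the fitted plane; an
`offset_mm` parameter can shift it along the normal, and the end-to-end
phantom pipeline slices a few mm inside the endplate, because sampling
exactly at the top face of a voxelized solid is a knife-edge case of
trilinear interpolation (values ≈ 0.5 on the face itself).

## Rotation calculus and sign convention

Endplate orientations are undirected axes, so all angles live on the
180°-circle in [0, 180), clockwise-positive viewed from above relative
to the AP reference. Differences use the minimal signed circular
difference mapped to (−90, +90] — lossless for anatomically plausible
angles (near 90°) while keeping the 0/180 seam well-defined:

* intra-vertebral rotation: superior − inferior endplate of one vertebra;
* inter-vertebral (intra-discal) rotation: inferior endplate of the
  cephalad vertebra − superior endplate of the caudal vertebra;
* change between timepoints: value(t2) − value(t1).

Relative to the curve apex (a vertebra or a disc), negative changes
above the apex and positive changes below it increase the deformity and
are flagged *loss of correction*; at the apex itself the flag is left
unset. A change is *significant* when its magnitude strictly exceeds
the intra-observer 95% limit of agreement. Unmeasurable endplates
propagate as missing records, never as zeros.

## Intra-observer reliability

With paired repeat measurements (αₙ, αₘ) of the same change values, the
intra-observer difference is Δα = |αₙ − αₘ| and the significance gate is
1.96 × SD(Δα) with the sample (n−1) SD — small repeatability sets make
the bias correction material. Note the SD is taken over the *absolute*
differences, which is how the gate reported for this measurement chain
(SD 4.2° → limit 8.232°, reported 8.2°) is defined; the classical
signed-difference Bland–Altman variant is available via
`method="signed"`. For per-read Gaussian noise of SD σ, Δα is folded
normal and SD(Δα) → √(2σ²(1 − 2/π)), the closed form the simulation
recovery tests check against.

## Synthetic data: what it emulates and what it does not

The endplate cross-section is a polar superellipse (lateral × AP
semi-axes, exponent 2.5; 2.0 gives a true ellipse) with a smoothly
modulated posterior flattening (scaled by `asymmetry_strength`) and two
posterior pedicle lobes raised as Gaussian radial bumps whose width and
posterior extent map from `pedicle_width`/`pedicle_length`. The polar
construction makes the polygon star-shaped and simple by construction,
exactly mirror-symmetric about the AP axis on the sampled vertex grid,
and — because the canonical shape is built first and then rotated —
rotation-equivariant to machine precision. With flattening and pedicles
off, the shape has two perpendicular symmetry axes (the degenerate case
for ambiguity tests). Tracing noise is an independent radial Gaussian
perturbation of the vertices (SD in mm), drawn in the canonical frame so
a fixed seed preserves equivariance.

Spine studies place per-endplate truth angles near 90° (an
anterior-facing supine spine) and inject per-entity changes between the
two timepoints by cumulative summation from the most caudal endplate, so
each entity changes by exactly its injected value and every other entity
by exactly zero. A rigid en-bloc rotation of the construct by δ is the
special case of −δ at the superior junction disc and +δ at the inferior
one. The default cohort generator emulates an instrumented thoracic
series: proximal levels drawn from {T4:2, T5:14, T6:14, T7:2}/32,
distal from {T11:5, T12:21, L1:6}/32, 6–9 instrumented levels, apex
mid-construct, one supra-gate injected change (9–13°) in a configurable
number of patients (default 11 of 32) and only sub-gate changes (≤4°)
elsewhere.

Tilted-volume phantoms extrude the cross-section along the endplate
normal and voxelize it as *fractional occupancy* (3×3×3 subvoxel
sampling), emulating the CT partial-volume effect; a purely binary
voxelization leaves a staircase whose mirror-consistency about the world
grid axes biases the symmetry peak toward 0°/90° by up to ~0.7°.

Deliberately not emulated: Hounsfield textures, scanner noise, metal
artefact from instrumentation (measurement operates on traced outlines,
which is also why no automatic segmentation is attempted), level-to-level
correlation of endplate shape, and vertebral wedging in 3D. Passing
tests therefore demonstrate correctness of the measurement and analysis
chain given faithful outlines — not robustness to segmentation error on
real post-operative images.

## Design choices on genuinely open points

* The exact symmetry-ratio formula of the original measurement plugin is
  not published; the mirror-overlap ratio above is a documented stand-in
  chosen for boundedness, oracle-checkability and equivariance, not for
  numerical agreement with that plugin. Published single-image angle
  values are used only as interface-shape examples.
* Ambiguity thresholds replace a human's reading of the profile graph;
  both are exposed in `SymmetrySettings`.
* The en-bloc criterion — both junction-disc mean changes beyond the
  gate with opposite, construct-consistent signs — operationalizes what
  is otherwise a narrative judgement; it is config-exposed through the
  summary's inputs.
* Levels are treated as i.i.d. shapes; nothing is known about systematic
  shape variation across thoracic levels at endplate-tracing fidelity.
* The 8.2° gate is treated as a limit of agreement applied to individual
  changes (how it is used), not as a confidence interval on a mean.

## Problem sizes used by the validation suites

Rotation recovery uses 200 randomized pedicled phantoms; equivariance
20 shapes × 17 offsets; degeneracy handling 100 ellipse trials; the
change pipeline a 32-patient cohort; reliability 10⁵ simulated pairs;
reformat fidelity 8 tilt configurations up to 30°; the exhaustive
pixel-reflection oracle 50 shapes on ≤64×64 masks. These sizes give
stable estimates of worst-case errors while keeping the suites quick to
run on one CPU.
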