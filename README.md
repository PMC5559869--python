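# vertrot

Vertebral endplate axial-rotation measurement on true-axial CT slices,
with longitudinal change analysis for instrumented scoliosis.

After corrective fusion surgery for adolescent idiopathic scoliosis, a
key question is whether the achieved de-rotation of the spine holds:
does anything rotate inside the fused segment between post-operative CT
scans, and does the construct move *en bloc* against the adjacent
un-instrumented levels? `vertrot` is a Python library for researchers
analysing such CT series. It implements:

* **Maximum-symmetry-axis measurement** — an endplate's axial
  orientation φ ∈ [0°, 180°) is the axis through the centroid of its
  binarized cross-section `S` that maximizes the symmetry ratio
  `r(φ) = area(S ∩ mirror(S, φ)) / area(S)`, measured clockwise (viewed
  from above) from the anteroposterior scanner-bed reference. Profiles
  with rival peaks (near-elliptical endplates) are flagged ambiguous and
  resolved against a prior angle or reported unmeasurable.
* **True-axial reformatting** — least-squares endplate-plane fit to
  landmarks, oblique slice extraction with trilinear interpolation, and
  propagation of the AP reference into the slice so angles are
  comparable across endplates and pixel grids.
* **Rotation calculus** — inter-vertebral (intra-discal) rotation
  `φ_u − φ_l` between adjacent endplates, intra-vertebral rotation
  within one vertebra, signed changes between timepoints on the
  180°-circle, and loss-of-correction classification relative to the
  curve apex (negative changes above / positive below the apex increase
  the deformity).
* **Reliability gating** — intra-observer differences Δα = |αₙ − αₘ| of
  repeated change measurements; a change is significant when it exceeds
  the 95% limit of agreement 1.96 × SD(Δα).
* **Cohort aggregation** — level × patient change matrices, junction
  (en-bloc) summaries, counts of patients with measurable change, and
  exclusion reporting.
* **Synthetic phantoms** — endplate outlines, tilted 3D volumes, spine
  studies with injected changes and observer repeat pairs, all with
  exact ground truth, so every stage is testable without patient data.

## Worked example

```python
import vertrot as vr

params = vr.ShapeParams()          # pedicled thoracic endplate, 40 x 26 mm
outline = vr.generate_endplate_outline(params, true_angle=93.4)
rotation = vr.measure_endplate_rotation(outline, pixel_spacing=0.4, angle_step=0.1)
print(rotation.phi, rotation.quality)
```

prints

```
ground-truth rotation : 93.4 deg
measured rotation     : 93.5 deg  (quality: ok)
absolute error        : 0.08 deg
```

i.e. the symmetry-axis search recovers the phantom's injected
orientation to about a tenth of a degree. At cohort level
(`examples/04_cohort_change_analysis.py`), a synthetic 32-patient series
with 11 patients carrying one injected change above the 8.2° gate gives

```
patients analysed              : 32
patients with measurable change: 11
junction mean changes (deg):
  adjacent_superior_vertebra    -0.00
  adjacent_inferior_vertebra    +0.00
  adjacent_superior_disc        +0.00
  adjacent_inferior_disc        +0.00
  apex                          -0.02
en-bloc movement detected      : False
```

— localized changes are counted exactly, junction means stay at zero and
no en-bloc construct movement is declared. The `examples/` directory
holds one short script per capability (measurement, ambiguity handling,
reformatting, cohort analysis, reliability).

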