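"""Measure the axial rotation of a single endplate phantom.

Builds a pedicled endplate outline with a known ground-truth rotation,
rasterizes it, computes the symmetry-ratio profile over all candidate
axis angles and reports the selected maximum-symmetry axis.
"""

import vertrot as vr

params = vr.ShapeParams()  # pedicled thoracic endplate, 40 x 26 mm body
true_angle = 93.4  # degrees clockwise from the scanner-bed AP reference

outline = vr.generate_endplate_outline(params, true_angle)
rotation = vr.measure_endplate_rotation(outline, pixel_spacing=0.4, angle_step=0.1)

print(f"ground-truth rotation : {true_angle:.1f} deg")
print(f"measured rotation     : {rotation.phi:.1f} deg  (quality: {rotation.quality})")
print(f"absolute error        : {vr.axial_distance(rotation.phi, true_angle):.2f} deg")
# The measured angle is the axis of maximum reflection symmetry of the
# binarized outline, relative to the anteroposterior reference; on a
# noise-free pedicled phantom it recovers the truth to ~0.1 deg.
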