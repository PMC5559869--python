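"""Ambiguity handling: near-elliptical endplates have two rival symmetry axes.

An ellipse is mirror-symmetric about both principal axes, so its
symmetry-ratio profile has two peaks ~90 degrees apart and the true
orientation cannot be decided from the shape alone.  A prior angle
(e.g. the same endplate at the other timepoint) resolves the ambiguity;
without one the endplate is unmeasurable and the patient is excluded.
"""

import vertrot as vr

ellipse = vr.ShapeParams(pedicle_present=False, asymmetry_strength=0.0, body_exponent=2.0)
true_angle = 100.0

outline = vr.generate_endplate_outline(ellipse, true_angle)
image = vr.rasterize_outline(outline, pixel_spacing=0.5)
profile = vr.compute_symmetry_profile(image, angle_step=0.2)

print(f"profile ambiguous : {profile.ambiguous}")
print("rival peaks       :", [f"{a:.1f} deg (ratio {v:.3f})" for a, v in profile.peaks])

angle, quality = vr.select_rotation_angle(profile)
print(f"no prior          -> angle={angle}, quality={quality}")

angle, quality = vr.select_rotation_angle(profile, prior_angle=95.0)
print(f"prior 95.0 deg    -> angle={angle:.1f}, quality={quality}")
# The prior picks the rival axis circularly nearest to it, recovering the
# injected 100-degree orientation; the 90-degree rival is rejected.
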