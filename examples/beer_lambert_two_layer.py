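"""Beer-Lambert marker inversion on a two-layer geometry.

A homogeneous "unknown" layer (e.g. plaque) sits above a fluence marker
with known absorption (e.g. India-ink-like, 0.44 mm^-1). The forward model
gives the two absorbed-energy readings; the marker inversion solves
x * exp(x*r) = (H_u/H_m) * mu_a_marker for the unknown absorption, while the
equal-fluence shortcut ignores the attenuation over the separation r and
overestimates.
"""

import qpamark as q

MU_UNKNOWN = 0.51   # mm^-1, ground truth of the unknown layer
MU_MARKER = 0.44    # mm^-1, known marker absorption

print(f"ground truth mu_a of the unknown layer: {MU_UNKNOWN} mm^-1\n")
print(f"{'r (mm)':>7} {'marker inversion':>17} {'equal fluence':>14}")
for r in (0.0, 0.5, 1.0, 2.0, 4.0):
    h_u, h_m = q.make_two_layer_phantom(MU_UNKNOWN, MU_MARKER, r)
    bl = q.invert_beer_lambert_marker(h_u, h_m, MU_MARKER, r)
    ef = q.invert_equal_fluence(h_u, h_m, MU_MARKER)
    print(f"{r:7.1f} {bl:17.6f} {ef:14.6f}")

print("\nThe marker inversion recovers 0.51 mm^-1 at every separation;")
print("the equal-fluence estimate grows with r because it attributes the")
print("marker's extra attenuation to the unknown chromophore.")
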