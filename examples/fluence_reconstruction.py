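"""Reconstruct the relative light-dose distribution inside tissue from a
single measured μeff.

Builds normalized fluence maps for a low- and a high-attenuation tissue
(two-distance 855 nm estimates from two different forearms) and compares
the on-axis depth profiles. Everything is relative to the fluence at the
shallow reference point (r=0, z=1 mm), so no source power calibration is
needed.
"""

import numpy as np

from lightdose import axis_profile, fluence_map, relative_fluence, FieldPoint

MU_LOW, MU_HIGH = 0.136, 0.252  # mm^-1

for label, mu in (("low attenuation ", MU_LOW), ("high attenuation", MU_HIGH)):
    field = fluence_map(mu, r_range=(-10, 10), z_range=(0, 10), step=0.1)
    z, profile = axis_profile(field, "depth")
    for depth in (2.0, 5.0, 10.0):
        frac = profile[np.argmin(np.abs(z - depth))]
        print(f"{label} (mu_eff={mu}): normalized intensity at z={depth:>4} mm = {frac:.4f}")

ratio = relative_fluence(MU_LOW, FieldPoint(0, 5), FieldPoint(0, 1)) / relative_fluence(
    MU_HIGH, FieldPoint(0, 5), FieldPoint(0, 1)
)
print(f"\nat 5 mm depth the low-attenuation tissue receives {ratio:.2f}x the")
print("relative dose of the high-attenuation tissue - the dose map must be")
print("personalized from each user's own mu_eff, not from population defaults.")
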