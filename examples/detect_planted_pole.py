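"""Winding-number pole detection on coil maps with a planted phase vortex.

Multiplies the image by a unit-magnitude phase vortex and every coil by its
conjugate — the measured data is unchanged, but every coil map now carries a
phase singularity.  The detector computes per-pixel winding numbers on small
circles in each coil, averages them weighted by |c_i|^2, and thresholds the
consensus.  Printed: the detected pole position/sign versus the planted one,
and the (empty) detection on the original singularity-free coils.
"""

import numpy as np

import nlinvpp as nv
from nlinvpp import polefix

grid = nv.Grid2D(64, 64)
phantom = nv.make_phantom(grid, nv.default_phantom_spec())
coils = nv.make_coils(grid, nv.CoilLayout(nc=8))

r0, sign = (0.12, -0.07), +1
_, coils_planted = nv.plant_artificial_pole(phantom, coils, r0, sign)

cfg = polefix.DetectConfig()  # d = 0.05 FoV, t = 1/2, closing disk = d
pm = polefix.coil_winding_maps(coils_planted, cfg)
poles = polefix.detect_poles(pm, cfg)

print(f"planted pole  : position {r0}, image-side sign {sign:+d}")
for loc, s in zip(poles.locations, poles.signs):
    err = np.hypot(loc[0] - r0[0], loc[1] - r0[1])
    print(f"detected pole : position ({loc[0]:+.4f}, {loc[1]:+.4f}), "
          f"coil-side sign {s:+d}, error {err:.4f} FoV")
print("(coil maps carry the conjugate of the image pole, so the detected")
print(" sign is opposite; localization error is a fraction of a pixel)")

clean = polefix.detect_poles(polefix.coil_winding_maps(coils, cfg), cfg)
print(f"poles on the original singularity-free coils: {clean.count}")
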