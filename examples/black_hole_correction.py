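"""Removing a reconstruction 'black hole' by in-loop pole correction.

A phase pole in the image compensated by conjugate poles in the coils fits
the data exactly, but the coil smoothness penalty forces the coil magnitude
to zero at the pole — a signal void in the regularized reconstruction.  This
script starts the solver inside such a pole gauge and reconstructs twice:
without correction (the void persists) and with detection + vortex correction
after eight Gauss-Newton steps (the remaining steps heal the magnitude).
Printed: residual pole count and the coil-RSS minimum/median ratio over the
phantom support — a ratio near 1 means a homogeneous, hole-free estimate.
"""

import numpy as np

import nlinvpp as nv
from nlinvpp import polefix, validate
from nlinvpp.forward import SobolevWeights, apply_weighting_pinv

grid = nv.Grid2D(64, 64)
phantom = nv.make_phantom(grid, nv.default_phantom_spec())
coils = nv.make_coils(grid, nv.CoilLayout(nc=8))
pattern = nv.make_pattern(grid, 2, 2, ac_size=7)

rho_p, coils_p = nv.plant_artificial_pole(phantom, coils, (0.08, -0.06), +1)
kspace = nv.sample_kspace(rho_p, coils_p, pattern)

weights = SobolevWeights(grid)
scale = 100.0 / np.linalg.norm(kspace.values)
init = (nv.ComplexImage(grid, rho_p.values * scale),
        apply_weighting_pinv(coils_p, weights))
support = validate.support_mask(phantom)
dcfg = polefix.DetectConfig()

for correct in (False, True):
    cfg = nv.ReconConfig(pole_correction=correct)
    _, c_out, log = nv.nlinv(kspace, cfg, init=init, rss_normalize=False)
    poles = polefix.detect_poles(polefix.coil_winding_maps(c_out, dcfg), dcfg)
    rss = np.sqrt(np.sum(np.abs(c_out.values) ** 2, axis=0))
    ratio = rss[support].min() / np.median(rss[support])
    events = [e for e in log if e["event"] == "pole_correction"]
    print(f"correction {'on ' if correct else 'off'}: "
          f"corrections applied = {len(events)}, residual poles = {poles.count}, "
          f"coil RSS min/median = {ratio:.3f}")
print("(without correction the pole survives and RSS collapses at its")
print(" location; with correction the final coils are pole-free)")
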