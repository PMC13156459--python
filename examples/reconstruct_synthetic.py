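"""Joint image/coil reconstruction of a synthetic undersampled acquisition.

Builds a phantom with a smooth polynomial phase, eight ring-arranged coil
sensitivities, a 2x2-undersampled Cartesian pattern with a 7x7 calibration
block, and runs the nonlinear-inversion solver.  Prints the relative error of
the recovered coil images (the observable product c_i * rho) against ground
truth: a few percent at 4-fold undersampling; on fully sampled data the same
solver reaches the ~1e-2 regularization-bias floor.
"""

import numpy as np

import nlinvpp as nv

grid = nv.Grid2D(64, 64)
phantom = nv.make_phantom(grid, nv.default_phantom_spec())
coils = nv.make_coils(grid, nv.CoilLayout(nc=8))
pattern = nv.make_pattern(grid, rx=2, ry=2, ac_size=7)
kspace = nv.sample_kspace(phantom, coils, pattern, noise_sigma=0.0, seed=0)

rho, coils_hat, log = nv.nlinv(kspace)

truth = coils.values * phantom.values[None]
estimate = coils_hat.values * rho.values[None]
rel_err = np.linalg.norm(estimate - truth) / np.linalg.norm(truth)

print(f"sampled k-space fraction : {pattern.mask.mean():.2f}")
for e in log:
    if e["event"] == "gn_step":
        print(f"  step {e['k']:2d}  alpha={e['alpha']:.4g}  residual={e['residual']:.3g}")
print(f"relative coil-image error: {rel_err:.3e}")
print("(the data-consistency residual shrinks as alpha decays; the final")
print(" error combines the alpha_min bias with the undersampling)")
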