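"""Simulate a cortical slab phantom, synthesize DWI, and refit the tensors.

The phantom is a flat grey-matter slab whose principal diffusion axes point
along the slab normal with Watson-type angular scatter.  The single-shell
scheme (54 directions at b = 4500 s/mm^2 plus six b = 0 volumes) is forward
simulated and refit by log-linear least squares; on noiseless data the fit
recovers the ground-truth tensors to numerical precision.
"""

import math

import numpy as np

import cortrad as ct

spec = ct.PhantomSpec(
    grid_shape=(24, 24, 24),
    cortex_thickness=10.0,     # mm; slab normal along z
    eigenvalues=(0.8e-3, 0.2e-3, 0.2e-3),  # mm^2/s, prolate
    dispersion_kappa=8.0,      # Watson concentration about the radial axis
    seed=0,
)
truth, tensors = ct.make_phantom(spec)
scheme = ct.default_scheme()
dwi = ct.synthesize_dwi(tensors, scheme, s0=1000.0, snr=math.inf)
fit = ct.fit_tensor_loglinear(dwi, scheme, tensors.mask)

rel_err = np.abs(fit.components - tensors.components).max() / 0.8e-3
eigen = ct.eigendecompose(fit)
fa = ct.fa_map(eigen).data[tensors.mask]
md = ct.md_map(eigen).data[tensors.mask]

print(f"cortical voxels:            {int(tensors.mask.sum())}")
print(f"noiseless refit rel. error: {rel_err:.2e}   (exact model class)")
print(f"FA  mean:                   {fa.mean():.4f}  (prolate tensor -> 0.7071)")
print(f"MD  mean:                   {md.mean() * 1e3:.4f} x10-3 mm^2/s  (trace/3 = 0.40)")

# with Rician noise the fit degrades gracefully
noisy = ct.synthesize_dwi(tensors, scheme, s0=1000.0, snr=15.0, seed=1)
fit_n = ct.fit_tensor_loglinear(noisy, scheme, tensors.mask)
md_n = ct.md_map(ct.eigendecompose(fit_n)).data[tensors.mask]
print(f"MD  mean at SNR 15:         {md_n.mean() * 1e3:.4f} x10-3 mm^2/s")
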