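"""Compute AngleR / ParlPD / PerpPD on phantoms with known orientation scatter.

AngleR is the angle between the principal diffusion direction and the local
radial axis; ParlPD and PerpPD are the projections of the principal
diffusion component onto the radial axis and the tangential plane.  ROI mean
AngleR grows monotonically with the phantom's orientation dispersion, from 0
(perfectly radial minicolumns) toward 1 rad (uniformly random axes); a
tangential mid-depth layer — emulating the heavily myelinated band of
primary visual cortex — pushes it higher still.
"""

import numpy as np

import cortrad as ct

print("kappa      ROI AngleR   expected   ParlPD   PerpPD   (x10-3 mm^2/s)")
for kappa in (np.inf, 16.0, 4.0, 1.0, 0.0):
    spec = ct.PhantomSpec(grid_shape=(24, 24, 24), cortex_thickness=10.0,
                          dispersion_kappa=kappa, seed=7)
    _, result = ct.process_phantom(spec, through_dwi=False)
    m = result.roi_metrics[0]
    label = "inf" if np.isinf(kappa) else f"{kappa:g}"
    print(f"{label:>5}      {m.angleR:8.4f}   {ct.expected_angle(kappa):8.4f}"
          f"   {m.parlPD:6.4f}   {m.perpPD:6.4f}")

# a tangential layer at mid-depth (stria of Gennari analogue)
spec = ct.PhantomSpec(grid_shape=(24, 24, 24), cortex_thickness=10.0,
                      dispersion_kappa=np.inf, tangential_layer=(0.45, 0.55),
                      seed=7)
_, result = ct.process_phantom(spec, through_dwi=False)
m = result.roi_metrics[0]
print(f"\nwith tangential mid-depth layer: ROI AngleR = {m.angleR:.4f} rad")
print("(one tenth of each profile crosses a pi/2 band, lifting the mean)")
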