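"""Diffusion-weighted EPI and ADC mapping on the synthetic phantom.

Simulates the 2D spin-echo EPI DWI protocol (b = 0 and 500 s/mm^2 along
three orthogonal directions) noise-free, combines the directional b1 images
with the geometric mean, computes the ADC map, and compares the per-tissue
median ADC with the phantom's ground truth.
"""

import numpy as np

from ulfmri.acquisition import dwi_epi, simulate_epi_dwi
from ulfmri.phantom import make_phantom
from ulfmri.recon import recon_dwi_scan

phantom = make_phantom((64, 64, 1))
scan = simulate_epi_dwi(phantom, dwi_epi(matrix=(64, 64, 1), nex=1), None, seed=0)
images = recon_dwi_scan(scan, ghost_correct=False)

names = [t.name for t in phantom.tissues]
print(f"{'tissue':8s}{'true ADC':>12s}{'recovered':>12s}{'error':>8s}")
for tissue in ("WM", "GM", "CSF"):
    idx = names.index(tissue)
    mask = phantom.labels[:, :, 0] == idx
    got = float(np.median(images["adc"][mask]))
    true = phantom.tissues[idx].adc
    print(f"{tissue:8s}{true:12.2e}{got:12.2e}{100*(got/true-1):7.2f}%")

print("\nADC in mm^2/s; the b1/b0 log-ratio recovers each tissue's")
print("diffusivity, and CSF (ADC 3.0e-3) attenuates most at b = 500.")
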