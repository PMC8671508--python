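"""EPI Nyquist-ghost and geometric-distortion correction.

Injects a known odd/even readout phase error (the Nyquist-ghost mechanism)
and a uniform off-resonance field (the distortion mechanism) into a
single-shot EPI simulation of a compact object, then corrects both: the
ghost via the constant + linear phase estimated from the 3-line reference
scan, the distortion via the known field map.  Prints the ghost-to-main
intensity ratio before/after and the residual object displacement.
"""

import numpy as np

from ulfmri.acquisition import dwi_epi, simulate_epi_dwi
from ulfmri.phantom import Phantom, default_tissues
from ulfmri.recon import (distortion_correct, epi_ghost_correct,
                          estimate_ghost_phase)

labels = np.zeros((64, 64, 1), np.int16)
labels[20:44, 24:40, 0] = 2                      # compact GM block
field = np.full((64, 64, 1), 40.0)               # 40 Hz off-resonance
phantom = Phantom(labels, default_tissues(), (4.0, 4.0, 10.0), field_map=field)
protocol = dwi_epi(matrix=(64, 64, 1), nex=1, b=0.0,
                   ghost_phi0=0.5, ghost_phi1=0.1)
scan = simulate_epi_dwi(phantom, protocol, None, seed=0)


def image(k):
    return np.abs(np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k))))


def ghost_ratio(img):
    n = img.shape[1]
    main = img[:, n // 4: 3 * n // 4]
    ghost = np.roll(img, n // 2, axis=1)[:, n // 4: 3 * n // 4]
    obj = main > 0.2 * main.max()
    return float(np.mean(ghost[obj]) / np.mean(main[obj]))


k = scan.kspace["b0"][0]
phi0, phi1 = estimate_ghost_phase(scan.reference["b0"])
print(f"injected odd/even phase: phi0=0.500, phi1=0.100")
print(f"estimated from 3-line reference: phi0={phi0:.3f}, phi1={phi1:.3f}")

kc = epi_ghost_correct(k, scan.reference["b0"])
print(f"ghost-to-main ratio: {100*ghost_ratio(image(k)):.1f}% before, "
      f"{100*ghost_ratio(image(kc)):.1f}% after correction")

img = image(kc)
fixed = distortion_correct(img, field[:, :, 0], protocol.pe_bandwidth_per_pixel)
shift = 40.0 / protocol.pe_bandwidth_per_pixel


def com(im):
    w = np.where(im[32] > 0.2 * im[32].max(), im[32], 0.0)
    return float(np.sum(np.arange(len(w)) * w) / np.sum(w))


print(f"off-resonance displacement: {shift:.2f} px along phase encode; "
      f"residual after correction: {abs(com(fixed) - 31.5):.2f} px (object "
      f"centred by construction)")
print("\nBoth corrections are the standard minimal approaches: a 2-parameter")
print("odd/even phase model and field-map-driven voxel shifting.")
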