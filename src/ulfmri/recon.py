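"""Cartesian Fourier reconstruction, EPI corrections, NEX averaging, ADC maps.

All reconstruction is deterministic: complex NEX averaging of the cleaned FE
lines into k-space, centered zero-padding for display interpolation (e.g.
pad factors (2, 2, 2) turn 2 x 2 x 10 mm acquisition voxels into 1 x 1 x 5 mm
display voxels), inverse orthonormal FFT, magnitude.  EPI Nyquist ghosts are
corrected with a constant + linear odd/even phase model estimated from a
3-line non-phase-encoded reference scan; geometric distortion is corrected by
shifting voxels along the phase-encode axis by -(off-resonance)/(bandwidth
per pixel) with linear interpolation, using the simulator's own field map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from .acquisition import AcquisitionRecord, DWIScan
from .contrast import adc_from_pair, isotropic_combine

__all__ = [
    "KSpaceVolume",
    "ImageVolume",
    "average_nex",
    "recon_cartesian",
    "epi_ghost_correct",
    "estimate_ghost_phase",
    "distortion_correct",
    "adc_pipeline",
    "recon_dwi_scan",
]


@dataclass
class KSpaceVolume:
    """Averaged complex k-space (fe x pe1 x pe2) with its sampling mask."""

    data: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    averages: int = 1

    def __post_init__(self) -> None:
        unsampled = self.data[:, ~self.mask]
        if unsampled.size and np.any(unsampled != 0):
            raise ValueError("unsampled k-space entries must be exactly zero")


@dataclass
class ImageVolume:
    """Magnitude image with display voxel size and provenance tags."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def save_nifti(self, path: str) -> None:
        import nibabel as nib

        affine = np.diag(list(self.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), path)


def average_nex(record: AcquisitionRecord) -> KSpaceVolume:
    """Complex mean across NEX repeats, placed at each line's k-space
    coordinate.  Every sampled coordinate must have all NEX repeats."""
    n_x, n_pe1, n_pe2 = record.protocol.matrix
    nex = record.protocol.nex
    acc = np.zeros((n_x, n_pe1, n_pe2), dtype=complex)
    count = np.zeros((n_pe1, n_pe2), dtype=int)
    for line, (i1, i2, _) in zip(record.acq_rx, record.acq_coords):
        acc[:, i1, i2] += line
        count[i1, i2] += 1
    expected = record.mask * nex
    if np.any(count != expected):
        missing = np.argwhere(count != expected)
        raise ValueError(f"missing NEX repeats at phase encodes {missing[:5].tolist()}"
                         + ("..." if len(missing) > 5 else ""))
    acc[:, record.mask] /= nex
    return KSpaceVolume(acc, record.mask.copy(),
                        record.protocol.voxel_size, averages=nex)


def _embed_centered(ksp: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Center k-space (DC at N//2) inside a larger zero grid."""
    out = np.zeros(shape, dtype=ksp.dtype)
    sl = tuple(slice(S // 2 - n // 2, S // 2 - n // 2 + n)
               for n, S in zip(ksp.shape, shape))
    out[sl] = ksp
    return out


def recon_cartesian(kspace: KSpaceVolume | np.ndarray,
                    pad_factors: tuple[int, int, int] = (1, 1, 1),
                    voxel_size: Optional[tuple] = None,
                    provenance: Optional[dict] = None) -> ImageVolume:
    """Zero-pad in k-space, inverse orthonormal FFT, magnitude.

    Display voxel size is the acquisition voxel size divided by the pad
    factor per axis; zero-padding only refines display sampling.
    """
    if isinstance(kspace, KSpaceVolume):
        data, vox = kspace.data, kspace.voxel_size
    else:
        data = np.asarray(kspace)
        vox = voxel_size if voxel_size is not None else (1.0,) * data.ndim
    if any(int(p) < 1 or p != int(p) for p in pad_factors):
        raise ValueError("pad factors must be integers >= 1")
    shape = tuple(int(n * p) for n, p in zip(data.shape, pad_factors))
    padded = _embed_centered(data, shape)
    img = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(padded), norm="ortho"))
    # keep total energy independent of padding (pure interpolation)
    img *= np.sqrt(np.prod(shape) / data.size)
    disp_vox = tuple(v / p for v, p in zip(vox, pad_factors))
    return ImageVolume(np.abs(img), disp_vox, dict(provenance or {}))


# --- EPI corrections ------------------------------------------------------

def _hybrid(line: np.ndarray) -> np.ndarray:
    """k-space FE line -> hybrid (readout-space) domain, x origin at N//2."""
    return np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(line), norm="ortho"))


def _unhybrid(hyb: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft(np.fft.ifftshift(hyb), norm="ortho"))


def estimate_ghost_phase(reference: np.ndarray) -> tuple[float, float]:
    """Constant + linear odd/even phase from a non-phase-encoded reference.

    ``reference``: (n_lines >= 2, n_x) k-space lines alternating
    even/odd readout polarity.  Returns (phi0, phi1) such that odd lines in
    hybrid space carry the extra phase exp(i(phi0 + phi1 * (x - n_x//2))).
    """
    ref = np.asarray(reference)
    if ref.ndim != 2 or ref.shape[0] < 2:
        raise ValueError("reference scan needs at least 2 lines")
    even = _hybrid(np.mean(ref[0::2], axis=0))
    odd = _hybrid(np.mean(ref[1::2], axis=0))
    p = odd * np.conj(even)            # |S|^2 exp(i(phi0 + phi1 x))
    w = np.abs(p)
    # slope from the phase increment between neighbouring samples
    phi1 = float(np.angle(np.sum(p[1:] * np.conj(p[:-1]))))
    n = ref.shape[1]
    x = np.arange(n) - n // 2
    phi0 = float(np.angle(np.sum(p * np.exp(-1j * phi1 * x) * w)))
    return phi0, phi1


def epi_ghost_correct(kspace2d: np.ndarray,
                      reference: np.ndarray) -> np.ndarray:
    """Remove the odd/even phase mismatch from reversed (odd) EPI lines.

    ``kspace2d``: (n_fe, n_pe) single-shot EPI k-space with line-reversal
    bookkeeping already applied.  The constant + linear phase estimated from
    the reference scan is removed from odd phase-encode lines in hybrid
    space.  Idempotent once corrected (re-estimated slope ~ 0).
    """
    if reference is None:
        raise ValueError("ghost correction requires the reference scan")
    phi0, phi1 = estimate_ghost_phase(reference)
    n_fe, n_pe = kspace2d.shape
    x = np.arange(n_fe) - n_fe // 2
    corr = np.exp(-1j * (phi0 + phi1 * x))
    out = kspace2d.copy()
    for r in range(1, n_pe, 2):
        out[:, r] = _unhybrid(_hybrid(out[:, r]) * corr)
    return out


def distortion_correct(image: np.ndarray,
                       field_map: np.ndarray,
                       bw_per_pixel: float,
                       pe_axis: int = 1) -> np.ndarray:
    """Undo off-resonance displacement along the phase-encode axis.

    Off-resonance f displaces a voxel by -f/bw pixels along ``pe_axis``
    during the EPI train; the correction shifts each voxel back by +f/bw
    pixels (linear interpolation), so a uniform offset is exactly undone as
    a rigid shift.
    """
    img = np.asarray(image, dtype=float)
    if field_map.shape != img.shape:
        raise ValueError("field map must be on the image grid")
    coords = np.indices(img.shape).astype(float)
    coords[pe_axis] -= field_map / bw_per_pixel
    return map_coordinates(img, coords, order=1, mode="constant")


# --- diffusion ------------------------------------------------------------

def adc_pipeline(b0_img: np.ndarray,
                 b1_imgs: tuple[np.ndarray, np.ndarray, np.ndarray],
                 b: float,
                 mask: Optional[np.ndarray] = None,
                 floor_frac: float = 1e-6):
    """Isotropic b1 combination (geometric mean) and ADC map.

    Voxels outside ``mask`` (default: b0 above a small threshold) get ADC 0.
    Magnitudes are floored at ``floor_frac`` times the b0 peak so
    noise-dominated voxels cannot produce infinities.
    """
    b0 = np.asarray(b0_img, dtype=float)
    floor = floor_frac * float(b0.max())
    b1s = [np.maximum(np.asarray(v, dtype=float), floor) for v in b1_imgs]
    iso = isotropic_combine(*b1s)
    if mask is None:
        mask = b0 > 0.1 * float(b0.max())
    adc = np.zeros_like(b0)
    adc[mask] = adc_from_pair(np.maximum(b0[mask], floor), iso[mask], b)
    iso = np.where(mask, iso, 0.0)
    return iso, adc


def recon_dwi_scan(scan: DWIScan,
                   pad_factors: tuple[int, int] = (1, 1),
                   ghost_correct: bool = True,
                   dist_correct: bool = False,
                   field_map: Optional[np.ndarray] = None,
                   shielded: bool = False) -> dict:
    """Full EPI DWI reconstruction: NEX average, ghost correction,
    magnitude recon, optional distortion correction, isotropic b1 + ADC.

    Returns a dict with per-volume magnitude images plus ``iso_b1`` and
    ``adc``.
    """
    src = scan.kspace_shielded if shielded else scan.kspace
    vox = scan.protocol.voxel_size
    images = {}
    for name, k in src.items():
        ksp = k.mean(axis=0)  # complex NEX average
        if ghost_correct:
            ksp = epi_ghost_correct(ksp, scan.reference[name])
        img = recon_cartesian(ksp[:, :, None], (*pad_factors, 1),
                              voxel_size=vox).data[:, :, 0]
        if dist_correct:
            fmap = field_map
            if fmap is None:
                raise ValueError("distortion correction requires a field map")
            if fmap.shape != img.shape:  # display grid may be zero-padded
                reps = tuple(s // f for s, f in zip(img.shape, fmap.shape))
                fmap = np.kron(fmap, np.ones(reps))
            img = distortion_correct(img, fmap,
                                     scan.protocol.pe_bandwidth_per_pixel,
                                     pe_axis=1)
        images[name] = img
    if scan.meta["b"] > 0:
        iso, adc = adc_pipeline(images["b0"],
                                (images["b1x"], images["b1y"], images["b1z"]),
                                b=scan.meta["b"])
        images["iso_b1"] = iso
        images["adc"] = adc
    return images
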