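"""Synthetic brain-like phantom with 0.055 T tissue parameters.

The phantom is a labelled 3D grid of nested ellipsoids (skull/CSF rim, grey
matter shell, white matter core, optional spherical lesion) together with the
per-tissue NMR and diffusion parameters every downstream stage consumes.
Relaxation times default to apparent 0.055 T estimates: GM T1/T2 = 330/110 ms,
WM = 260/100 ms, and long CSF values (T1 > 1500 ms, T2 > 1000 ms).

Geometry is analytic (point-in-ellipsoid per voxel), so per-tissue voxel
counts can be verified by brute-force enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TissueParams",
    "Phantom",
    "LesionSpec",
    "default_tissues",
    "make_phantom",
    "parameter_maps",
    "save_labels_nifti",
]


@dataclass(frozen=True)
class TissueParams:
    """NMR and diffusion parameters of one tissue class.

    Parameters
    ----------
    name : tissue label.
    pd : relative proton density in (0, 1] (0 allowed only for background).
    t1, t2 : longitudinal / transverse relaxation times in ms, with t2 <= t1.
    adc : apparent diffusion coefficient in mm^2/s.
    """

    name: str
    pd: float
    t1: float
    t2: float
    adc: float = 0.0

    def __post_init__(self) -> None:
        if self.name != "background":
            if not (0.0 < self.pd <= 1.0):
                raise ValueError(f"pd must be in (0, 1], got {self.pd}")
            if self.t1 <= 0 or self.t2 <= 0:
                raise ValueError("relaxation times must be positive")
            if self.t2 > self.t1:
                raise ValueError(f"t2 ({self.t2}) must not exceed t1 ({self.t1})")
        if self.adc < 0:
            raise ValueError("adc must be non-negative")


def default_tissues() -> list[TissueParams]:
    """Default tissue table at 0.055 T.

    GM and WM use the apparent ultra-low-field estimates (T1/T2 of 330/110 ms
    and 260/100 ms); CSF uses long values (4000/2000 ms) consistent with
    T1 > 1500 ms and T2 > 1000 ms, long enough for visible short-TR
    (FLAIR-like) suppression.  Proton densities and ADCs follow standard
    brain-phantom convention.  Index order is the label convention: 0 is
    always background with pd = 0.
    """
    return [
        TissueParams("background", 0.0, 1.0, 1.0, 0.0),
        TissueParams("CSF", 1.0, 4000.0, 2000.0, 3.0e-3),
        TissueParams("GM", 0.9, 330.0, 110.0, 0.8e-3),
        TissueParams("WM", 0.8, 260.0, 100.0, 0.7e-3),
        TissueParams("lesion", 0.95, 500.0, 200.0, 1.1e-3),
    ]


def tissue_by_name(tissues: Sequence[TissueParams], name: str) -> TissueParams:
    for t in tissues:
        if t.name == name:
            return t
    raise KeyError(name)


@dataclass(frozen=True)
class LesionSpec:
    """Spherical lesion: center in voxel coordinates, radius in voxels."""

    center: tuple[float, float, float]
    radius: float
    tissue: Optional[TissueParams] = None


@dataclass
class Phantom:
    """Labelled tissue grid plus per-tissue parameters.

    ``labels`` is a 3D integer grid indexing into ``tissues``; label 0 is
    background (pd = 0).  ``field_map``, if present, holds off-resonance in Hz
    on the same grid and drives geometric-distortion simulation/correction.
    """

    labels: np.ndarray
    tissues: list[TissueParams]
    voxel_size: tuple[float, float, float]
    field_map: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        if self.labels.max(initial=0) >= len(self.tissues):
            raise ValueError("label grid refers to a missing TissueParams entry")
        if self.tissues[0].pd != 0.0:
            raise ValueError("label 0 must be background with pd = 0")
        if self.field_map is not None:
            self.field_map = np.asarray(self.field_map, dtype=float)
            if self.field_map.shape != self.labels.shape:
                raise ValueError("field_map shape must match the label grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def voxel_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=len(self.tissues))
        return {t.name: int(c) for t, c in zip(self.tissues, counts)}

    def with_field_map(self, field_map: np.ndarray) -> "Phantom":
        return Phantom(self.labels, self.tissues, self.voxel_size, field_map)


def _ellipsoid_mask(shape: tuple[int, int, int],
                    center: Sequence[float],
                    semi_axes: Sequence[float]) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    r2 = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        a = max(a, 1e-9)
        r2 += ((g - c) / a) ** 2
    return r2 <= 1.0


def make_phantom(grid_shape: tuple[int, int, int] = (64, 64, 1),
                 voxel_size: tuple[float, float, float] = (4.0, 4.0, 10.0),
                 lesion: Optional[LesionSpec] = None,
                 seed: int = 0,
                 tissues: Optional[list[TissueParams]] = None,
                 uniform: Optional[str] = None) -> Phantom:
    """Build the nested-ellipsoid brain layout.

    Outermost ellipsoid rim is CSF, inside it a GM shell, inside that a WM
    core, plus an optional spherical lesion.  Deterministic for a fixed
    (spec, seed) pair; ``seed`` is recorded for provenance but the geometry
    itself is analytic.  ``uniform`` fills the whole grid with one named
    tissue (degenerate phantoms for tests).
    """
    tissues = list(tissues) if tissues is not None else default_tissues()
    shape = tuple(int(n) for n in grid_shape)
    if any(n <= 0 for n in shape):
        raise ValueError("grid_shape entries must be positive")
    labels = np.zeros(shape, dtype=np.int16)

    name_to_idx = {t.name: i for i, t in enumerate(tissues)}
    if uniform is not None:
        labels[...] = name_to_idx[uniform]
        return Phantom(labels, tissues, voxel_size)

    center = [(n - 1) / 2.0 for n in shape]
    # in-plane semi-axes as fractions of the grid; slab axis spans all slices
    def axes(frac: float) -> list[float]:
        return [frac * (n - 1) / 2.0 if n > 1 else 0.6 for n in shape]

    labels[_ellipsoid_mask(shape, center, axes(0.92))] = name_to_idx["CSF"]
    labels[_ellipsoid_mask(shape, center, axes(0.80))] = name_to_idx["GM"]
    labels[_ellipsoid_mask(shape, center, axes(0.55))] = name_to_idx["WM"]

    if lesion is not None:
        c = lesion.center
        if any(not (0 <= c[i] <= shape[i] - 1) for i in range(3)):
            raise ValueError(f"lesion center {c} lies outside grid {shape}")
        if lesion.tissue is not None and lesion.tissue.name not in name_to_idx:
            tissues.append(lesion.tissue)
            name_to_idx[lesion.tissue.name] = len(tissues) - 1
        idx = name_to_idx[(lesion.tissue.name if lesion.tissue else "lesion")]
        mask = _ellipsoid_mask(shape, c, [lesion.radius] * 3)
        labels[mask] = idx

    return Phantom(labels, tissues, voxel_size)


def parameter_maps(phantom: Phantom) -> dict[str, np.ndarray]:
    """Per-voxel pd/t1/t2/adc volumes from the label grid."""
    out = {}
    for attr in ("pd", "t1", "t2", "adc"):
        table = np.array([getattr(t, attr) for t in phantom.tissues])
        out[attr] = table[phantom.labels]
    return out


def save_labels_nifti(phantom: Phantom, path: str) -> None:
    """Export the label grid as NIfTI with voxel size in the affine."""
    import nibabel as nib

    affine = np.diag(list(phantom.voxel_size) + [1.0])
    img = nib.Nifti1Image(phantom.labels.astype(np.int16), affine)
    nib.save(img, path)
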