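"""Closed-form steady-state signal models and diffusion math.

Maps tissue parameters (pd, T1, T2, ADC) and protocol parameters (TR, TE,
flip angle, b-value) to per-voxel signal amplitude for the four clinical
contrasts at 0.055 T:

* spoiled gradient echo (Ernst steady state) for T1 weighting,
* saturation-recovery fast spin echo for T2 weighting,
* the same FSE expression at short TR for FLAIR-like CSF suppression, and
* mono-exponential diffusion attenuation for spin-echo EPI DWI.

T2* is taken equal to T2: at 0.055 T with field homogeneity < 250 ppm,
intravoxel dephasing is negligible at these voxel sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "SequenceKind",
    "DiffusionEncoding",
    "GAMMA_PROTON",
    "gre_signal",
    "fse_signal",
    "stejskal_tanner_b",
    "gradient_for_b",
    "dwi_signal",
    "adc_from_pair",
    "isotropic_combine",
]

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_PROTON = 2.675e8


class SequenceKind(str, Enum):
    GRE3D = "GRE3D"
    FSE3D = "FSE3D"
    FLAIR_LIKE_FSE3D = "FLAIR_LIKE_FSE3D"
    EPI_DWI_2D = "EPI_DWI_2D"


_ORTHO = (np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))


@dataclass(frozen=True)
class DiffusionEncoding:
    """Stejskal–Tanner diffusion encoding.

    b in s/mm^2; gradient separation ``big_delta`` and duration
    ``small_delta`` in ms; directions default to the three orthogonal axes.
    """

    b: float
    big_delta: float = 49.0
    small_delta: float = 30.0
    gamma: float = GAMMA_PROTON
    directions: tuple = _ORTHO

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError("b must be non-negative")
        if self.big_delta <= self.small_delta / 3.0:
            raise ValueError("require big_delta > small_delta/3")

    @property
    def gradient_amplitude(self) -> float:
        """Required gradient amplitude in T/m for this b."""
        return gradient_for_b(self.b, self.small_delta * 1e-3,
                              self.big_delta * 1e-3, self.gamma)


def _check_relaxation(t1, t2, tr, te) -> None:
    if np.any(np.asarray(t1) <= 0) or np.any(np.asarray(t2) <= 0):
        raise ValueError("relaxation times must be positive")
    if np.any(np.asarray(tr) <= 0) or np.any(np.asarray(te) < 0):
        raise ValueError("tr must be positive and te non-negative")


def gre_signal(pd, t1, t2, tr, te, fa):
    """Spoiled GRE steady-state (Ernst) signal.

    S = pd * sin(fa) * (1 - E1) / (1 - E1 cos(fa)) * exp(-TE/T2),
    E1 = exp(-TR/T1).  ``fa`` in degrees; times in ms (any consistent unit).
    """
    _check_relaxation(t1, t2, tr, te)
    fa_rad = np.deg2rad(fa)
    e1 = np.exp(-np.asarray(tr, dtype=float) / np.asarray(t1, dtype=float))
    s = np.sin(fa_rad) * (1.0 - e1) / (1.0 - e1 * np.cos(fa_rad))
    return pd * s * np.exp(-np.asarray(te, dtype=float) / np.asarray(t2, dtype=float))


def ernst_angle(tr, t1):
    """Flip angle (degrees) maximizing the spoiled-GRE steady state."""
    return np.rad2deg(np.arccos(np.exp(-np.asarray(tr, float) / np.asarray(t1, float))))


def fse_signal(pd, t1, t2, tr, te):
    """Saturation-recovery FSE signal: pd * (1 - exp(-TR/T1)) * exp(-TE/T2).

    At TR = 1500 / TE = 202 ms this yields T2 weighting with bright CSF; at
    TR = 500 / TE = 129 ms the short-TR saturation suppresses long-T1 CSF,
    giving FLAIR-like contrast without inversion recovery.
    """
    _check_relaxation(t1, t2, tr, te)
    e1 = np.exp(-np.asarray(tr, dtype=float) / np.asarray(t1, dtype=float))
    return pd * (1.0 - e1) * np.exp(-np.asarray(te, dtype=float) / np.asarray(t2, dtype=float))


def stejskal_tanner_b(g_amp, small_delta, big_delta, gamma: float = GAMMA_PROTON):
    """b-value (s/mm^2) of a pulsed gradient pair.

    b = gamma^2 G^2 delta^2 (Delta - delta/3), with ``g_amp`` in T/m and
    ``small_delta``/``big_delta`` in seconds.  The SI result (s/m^2) is
    converted to s/mm^2.
    """
    g_amp = np.asarray(g_amp, dtype=float)
    if np.any(g_amp < 0):
        raise ValueError("gradient amplitude must be non-negative")
    if big_delta <= small_delta / 3.0:
        raise ValueError("require big_delta > small_delta/3")
    b_si = gamma**2 * g_amp**2 * small_delta**2 * (big_delta - small_delta / 3.0)
    return b_si * 1e-6


def gradient_for_b(b, small_delta, big_delta, gamma: float = GAMMA_PROTON):
    """Gradient amplitude (T/m) required for b (s/mm^2); inverse of
    :func:`stejskal_tanner_b`."""
    if big_delta <= small_delta / 3.0:
        raise ValueError("require big_delta > small_delta/3")
    b_si = np.asarray(b, dtype=float) * 1e6
    return np.sqrt(b_si / (gamma**2 * small_delta**2 * (big_delta - small_delta / 3.0)))


def dwi_signal(s0, adc, b):
    """Mono-exponential diffusion attenuation s0 * exp(-b * adc)."""
    if np.any(np.asarray(s0) < 0):
        raise ValueError("s0 must be non-negative")
    return s0 * np.exp(-np.asarray(b, dtype=float) * np.asarray(adc, dtype=float))


def adc_from_pair(s_b0, s_b1, b1, b0: float = 0.0):
    """ADC (mm^2/s) from a b0/b1 magnitude pair: ln(s_b0/s_b1)/(b1-b0).

    Caller must floor noise-dominated voxels: non-positive magnitudes raise.
    """
    s_b0 = np.asarray(s_b0, dtype=float)
    s_b1 = np.asarray(s_b1, dtype=float)
    if b1 <= b0:
        raise ValueError("require b1 > b0")
    if np.any(s_b0 <= 0) or np.any(s_b1 <= 0):
        raise ValueError("magnitudes must be positive (mask or floor first)")
    return np.log(s_b0 / s_b1) / (b1 - b0)


def isotropic_combine(s_x, s_y, s_z):
    """Geometric mean of three directional DWI magnitudes.

    Chosen so the ADC of the combined image equals the arithmetic mean of the
    per-direction ADCs (trace/3).
    """
    arrs = [np.asarray(s, dtype=float) for s in (s_x, s_y, s_z)]
    if any(np.any(a <= 0) for a in arrs):
        raise ValueError("combine inputs must be positive")
    return np.exp((np.log(arrs[0]) + np.log(arrs[1]) + np.log(arrs[2])) / 3.0)
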