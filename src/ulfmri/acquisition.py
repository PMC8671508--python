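"""Dual-window, multichannel ULF acquisition simulator.

Each TR contains (i) the conventional MRI signal acquisition window(s) — one
per echo — and (ii) one or more EMI characterization windows scheduled in the
TR dead time after the echo train, where the dephased transverse signal
contributes nothing, so they contain EMI and receiver noise but no MRI
signal.  The MRI receive coil and the ten EMI
sensing coils are sampled simultaneously in both window types; sensing coils
never see MRI signal.

The MRI content of an FE line is a row of the orthonormal DFT of the
contrast-weighted phantom volume (k-space DC at index N//2, FE along axis 0).
Every record can carry a "shielded twin": the identical MRI signal and
receiver-noise realization with EMI forced off — the ground-truth comparator
for cancellation quality.

The characterization acquisition is genuine time overhead: configurations
whose windows do not fit inside the TR are rejected.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .contrast import DiffusionEncoding, SequenceKind, dwi_signal, fse_signal, gre_signal
from .emi import EMIWorld, N_SENSING
from .phantom import Phantom, parameter_maps

__all__ = [
    "ProtocolConfig",
    "AcquisitionRecord",
    "DWIScan",
    "elliptic_mask",
    "simulate_scan",
    "simulate_epi_dwi",
    "t1w_gre",
    "t2w_fse",
    "flair_fse",
    "dwi_epi",
    "t2w_smoke",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Sequence type plus all timing and encoding parameters.

    Times in ms (tr, te), dwell in seconds.  ``matrix`` is
    (n_fe, n_pe1, n_pe2) and n_x = n_fe readout samples per FE line.
    ``char_count`` characterization windows of ``n_char`` samples are placed
    in each TR's dead time (see :meth:`char_window_starts`).
    ``echo_start_ms`` is the offset of the first acquisition window within
    the TR.
    """

    kind: SequenceKind
    tr: float
    te: float
    matrix: tuple[int, int, int]
    fov: tuple[float, float, float] = (250.0, 250.0, 320.0)
    fa: float = 90.0
    etl: int = 1
    nex: int = 1
    dwell: float = 2.0e-5
    char_count: int = 1
    n_char: Optional[int] = None
    elliptic: bool = True
    diffusion: Optional[DiffusionEncoding] = None
    receiver_noise_sigma: float = 0.0
    echo_start_ms: float = 5.0
    char_placement: str = "spread"   # spread | end (within the TR dead time)
    # EPI artifact mechanisms (odd/even hybrid-space phase, Hz/pixel bandwidth)
    ghost_phi0: float = 0.0
    ghost_phi1: float = 0.0
    epi_echo_spacing: float = 1.5e-3

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.matrix):
            raise ValueError("matrix entries must be positive")
        if self.char_placement not in ("spread", "end"):
            raise ValueError("char_placement must be 'spread' or 'end'")
        if self.etl < 1 or self.nex < 1 or self.char_count < 0:
            raise ValueError("etl, nex >= 1 and char_count >= 0 required")
        if self.tr <= self.window_budget_ms:
            raise ValueError(
                f"TR = {self.tr} ms does not cover the acquisition plus EMI "
                f"characterization time overhead ({self.window_budget_ms:.2f} ms); "
                "the characterization windows lengthen the shortest possible TR")

    @property
    def n_x(self) -> int:
        return self.matrix[0]

    @property
    def n_char_len(self) -> int:
        return self.n_char if self.n_char is not None else self.n_x

    @property
    def line_duration(self) -> float:
        """One FE readout window, seconds."""
        return self.n_x * self.dwell

    @property
    def lines_per_tr(self) -> int:
        if self.kind is SequenceKind.EPI_DWI_2D:
            return self.matrix[1]
        return self.etl

    @property
    def window_budget_ms(self) -> float:
        acq = self.lines_per_tr * self.line_duration
        char = self.char_count * self.n_char_len * self.dwell
        return self.echo_start_ms + (acq + char) * 1e3

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return tuple(f / n for f, n in zip(self.fov, self.matrix))  # type: ignore

    def char_window_starts(self) -> np.ndarray:
        """Characterization-window start offsets within one TR, seconds.

        After the echo train the transverse magnetization is no longer
        refocused and dephases within milliseconds, so any window in the
        remaining dead time is MRI-signal-free.  "spread" distributes the
        windows evenly across that dead time so the characterization data
        sample the interference at times representative of the whole TR
        (important when EMI spectra drift during the scan); "end" packs
        them back-to-back at the end of the TR.
        """
        tr_s = self.tr * 1e-3
        char_dur = self.n_char_len * self.dwell
        acq_end = self.echo_start_ms * 1e-3 + self.lines_per_tr * self.line_duration
        n = self.char_count
        if n == 0:
            return np.array([])
        if self.char_placement == "end":
            return tr_s - (n - np.arange(n)) * char_dur
        start = acq_end + 0.005
        gap = (tr_s - start) / n
        if gap < char_dur:
            raise ValueError("TR dead time too short to spread the "
                             "characterization windows")
        return start + gap * np.arange(n)

    @property
    def pe_bandwidth_per_pixel(self) -> float:
        """EPI phase-encode bandwidth per pixel, Hz."""
        return 1.0 / (self.matrix[1] * self.epi_echo_spacing)


# --- paper protocol presets (0.055 T) ------------------------------------

def t1w_gre(**kw) -> ProtocolConfig:
    """3D GRE T1W: TR/TE 52/13 ms, FA 40°, 128x128x32, NEX 2."""
    kw.setdefault("char_count", 1)
    return ProtocolConfig(SequenceKind.GRE3D, tr=52.0, te=13.0, fa=40.0,
                          matrix=kw.pop("matrix", (128, 128, 32)), nex=kw.pop("nex", 2),
                          echo_start_ms=kw.pop("echo_start_ms", 10.0), **kw)


def t2w_fse(**kw) -> ProtocolConfig:
    """3D FSE T2W: TR/TE 1500/202 ms, ETL 21, 128x126x32, NEX 2."""
    return ProtocolConfig(SequenceKind.FSE3D, tr=1500.0, te=202.0,
                          matrix=kw.pop("matrix", (128, 126, 32)),
                          etl=kw.pop("etl", 21), nex=kw.pop("nex", 2), **kw)


def flair_fse(**kw) -> ProtocolConfig:
    """FLAIR-like short-TR FSE: TR/TE 500/129 ms, ETL 13, 128x117x32, NEX 4."""
    return ProtocolConfig(SequenceKind.FLAIR_LIKE_FSE3D, tr=500.0, te=129.0,
                          matrix=kw.pop("matrix", (128, 117, 32)),
                          etl=kw.pop("etl", 13), nex=kw.pop("nex", 4), **kw)


def dwi_epi(b: float = 500.0, **kw) -> ProtocolConfig:
    """2D spin-echo EPI DWI: TR/TE 2800/102 ms, 64x64, b 0/500 s/mm^2, NEX 52."""
    return ProtocolConfig(SequenceKind.EPI_DWI_2D, tr=2800.0, te=102.0,
                          matrix=kw.pop("matrix", (64, 64, 1)),
                          nex=kw.pop("nex", 52), elliptic=False,
                          diffusion=kw.pop("diffusion", DiffusionEncoding(b=b)),
                          echo_start_ms=kw.pop("echo_start_ms", 30.0), **kw)


def t2w_smoke(**kw) -> ProtocolConfig:
    """Desk-scale single-slice T2W FSE: 64x64, ETL 8, NEX 2, 16 char windows/TR."""
    return t2w_fse(matrix=kw.pop("matrix", (64, 64, 1)), etl=kw.pop("etl", 8),
                   nex=kw.pop("nex", 2), char_count=kw.pop("char_count", 16),
                   elliptic=kw.pop("elliptic", False), **kw)


# --- phase encoding -------------------------------------------------------

def elliptic_mask(n_pe1: int, n_pe2: int) -> np.ndarray:
    """Boolean phase-encode inclusion mask for elliptic 2D encoding.

    Includes centered integer offsets (k1, k2) with
    (k1/a)^2 + (k2/b)^2 <= 1, semi-axes a = n_pe1//2, b = n_pe2//2 (an axis
    of length 1 contributes only its DC offset).  DC is always included.
    Covers ~pi/4 of a full grid, the scan-time saving of elliptic encoding.
    """
    if n_pe1 < 1 or n_pe2 < 1:
        raise ValueError("phase-encode dimensions must be >= 1")
    k1 = np.arange(n_pe1) - n_pe1 // 2
    k2 = np.arange(n_pe2) - n_pe2 // 2
    a = max(n_pe1 // 2, 1) if n_pe1 > 1 else 1
    b = max(n_pe2 // 2, 1) if n_pe2 > 1 else 1
    r2 = (k1[:, None] / a) ** 2 + (k2[None, :] / b) ** 2
    mask = r2 <= 1.0 + 1e-12
    mask[n_pe1 // 2, n_pe2 // 2] = True
    return mask


def _pe_order(mask: np.ndarray) -> np.ndarray:
    """Center-out ordering of the masked phase encodes (so the nominal TE
    applies at k-space center).  Returns (n, 2) index array."""
    n1, n2 = mask.shape
    idx = np.argwhere(mask)
    k1 = idx[:, 0] - n1 // 2
    k2 = idx[:, 1] - n2 // 2
    a = max(n1 / 2.0, 0.5)
    b = max(n2 / 2.0, 0.5)
    r = (k1 / a) ** 2 + (k2 / b) ** 2
    order = np.lexsort((idx[:, 1], idx[:, 0], r))
    return idx[order]


# --- k-space --------------------------------------------------------------

def kspace_of_volume(vol: np.ndarray) -> np.ndarray:
    """Orthonormal centered DFT; DC at index N//2 on every axis."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vol), norm="ortho"))


def signal_volume(phantom: Phantom, protocol: ProtocolConfig) -> np.ndarray:
    """Contrast-weighted phantom volume for the protocol's sequence."""
    maps = parameter_maps(phantom)
    pd, t1, t2 = maps["pd"], maps["t1"], maps["t2"]
    body = phantom.labels > 0
    out = np.zeros(phantom.shape, dtype=float)
    if protocol.kind is SequenceKind.GRE3D:
        out[body] = gre_signal(pd[body], t1[body], t2[body],
                               protocol.tr, protocol.te, protocol.fa)
    elif protocol.kind in (SequenceKind.FSE3D, SequenceKind.FLAIR_LIKE_FSE3D):
        out[body] = fse_signal(pd[body], t1[body], t2[body], protocol.tr, protocol.te)
    elif protocol.kind is SequenceKind.EPI_DWI_2D:
        s = fse_signal(pd[body], t1[body], t2[body], protocol.tr, protocol.te)
        if protocol.diffusion is not None and protocol.diffusion.b > 0:
            s = dwi_signal(s, maps["adc"][body], protocol.diffusion.b)
        out[body] = s
    else:  # pragma: no cover
        raise ValueError(protocol.kind)
    return out


# --- records --------------------------------------------------------------

@dataclass
class AcquisitionRecord:
    """Raw dual-window record of one scan.

    Acquisition lines are stored flat: ``acq_rx[i]`` is FE line i (complex,
    n_x samples) with phase-encode indices and NEX repeat in
    ``acq_coords[i] = (i_pe1, i_pe2, i_nex)`` and wall-clock window start in
    ``acq_times[i]``.  ``acq_rx_shielded`` shares the identical MRI signal and
    receiver-noise realization with EMI off.  Characterization windows carry
    EMI plus receiver noise only.
    """

    protocol: ProtocolConfig
    acq_rx: np.ndarray
    acq_rx_shielded: np.ndarray
    acq_sens: np.ndarray
    acq_coords: np.ndarray
    acq_times: np.ndarray
    char_rx: np.ndarray
    char_rx_shielded: np.ndarray
    char_sens: np.ndarray
    char_times: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)
    phantom_labels: Optional[np.ndarray] = None
    emi_world: Optional[EMIWorld] = None

    @property
    def n_lines(self) -> int:
        return self.acq_rx.shape[0]

    @property
    def n_char_windows(self) -> int:
        return self.char_rx.shape[0]

    def shielded_twin(self) -> "AcquisitionRecord":
        """The same scan with EMI forced off (identical MRI + receiver noise)."""
        twin = copy.copy(self)
        twin.acq_rx = self.acq_rx_shielded
        twin.char_rx = self.char_rx_shielded
        twin.emi_world = None
        twin.meta = dict(self.meta, shielded=True)
        return twin

    def with_acq_rx(self, acq_rx: np.ndarray) -> "AcquisitionRecord":
        out = copy.copy(self)
        out.acq_rx = np.asarray(acq_rx)
        return out

    def emi_replay(self) -> np.ndarray:
        """Noise-free coupled EMI in the receive coil for every acquisition
        window, (n_lines, n_x); requires the EMI world."""
        if self.emi_world is None:
            raise ValueError("record has no EMI world to replay")
        out = np.empty_like(self.acq_rx)
        for i, t0 in enumerate(self.acq_times):
            out[i] = self.emi_world.coupled(t0, self.acq_rx.shape[1],
                                            self.protocol.dwell)[0]
        return out


def _draw_cnoise(rng: np.random.Generator, sigma: float, shape) -> np.ndarray:
    if sigma <= 0:
        return np.zeros(shape, dtype=complex)
    return sigma / np.sqrt(2) * (rng.standard_normal(shape)
                                 + 1j * rng.standard_normal(shape))


def simulate_scan(phantom: Phantom,
                  protocol: ProtocolConfig,
                  emi_world: Optional[EMIWorld] = None,
                  seed: int = 0) -> AcquisitionRecord:
    """Simulate a 3D GRE/FSE scan with dual-window sampling.

    Returns the contaminated record; its EMI-free shielded twin (same MRI
    signal, same receiver noise) is embedded and available via
    ``record.shielded_twin()``.  Deterministic for fixed inputs and seed.
    """
    if protocol.kind is SequenceKind.EPI_DWI_2D:
        raise ValueError("use simulate_epi_dwi for EPI protocols")
    if phantom.shape != tuple(protocol.matrix):
        raise ValueError(f"phantom grid {phantom.shape} does not match "
                         f"protocol matrix {protocol.matrix}")
    n_x, n_pe1, n_pe2 = protocol.matrix
    ksp = kspace_of_volume(signal_volume(phantom, protocol))
    mask = elliptic_mask(n_pe1, n_pe2) if protocol.elliptic else np.ones((n_pe1, n_pe2), bool)
    order = _pe_order(mask)
    shots = [order[i:i + protocol.etl] for i in range(0, len(order), protocol.etl)]

    ss = np.random.SeedSequence(seed)
    rng_rcv, rng_sens = (np.random.default_rng(s) for s in ss.spawn(2))

    tr_s = protocol.tr * 1e-3
    line_dur = protocol.line_duration
    char_len = protocol.n_char_len
    echo0 = protocol.echo_start_ms * 1e-3

    acq_rx, acq_sh, acq_sens, coords, times = [], [], [], [], []
    char_rx, char_sh, char_sens, char_times = [], [], [], []
    dwell = protocol.dwell
    sigma = protocol.receiver_noise_sigma

    tr_index = 0
    for i_nex in range(protocol.nex):
        for shot in shots:
            t_tr = tr_index * tr_s
            for e, (i1, i2) in enumerate(shot):
                t0 = t_tr + echo0 + e * line_dur
                mri = ksp[:, i1, i2]
                noise = _draw_cnoise(rng_rcv, sigma, n_x)
                clean = mri + noise
                if emi_world is not None:
                    emi = emi_world.coupled(t0, n_x, dwell, rng_sens)
                    acq_rx.append(clean + emi[0])
                    acq_sens.append(emi[1:])
                else:
                    acq_rx.append(clean)
                    acq_sens.append(np.zeros((N_SENSING, n_x), complex))
                acq_sh.append(clean)
                coords.append((i1, i2, i_nex))
                times.append(t0)
            # characterization windows in the TR dead time: no MRI signal
            for off in protocol.char_window_starts():
                t0 = t_tr + off
                noise = _draw_cnoise(rng_rcv, sigma, char_len)
                if emi_world is not None:
                    emi = emi_world.coupled(t0, char_len, dwell, rng_sens)
                    char_rx.append(noise + emi[0])
                    char_sens.append(emi[1:])
                else:
                    char_rx.append(noise)
                    char_sens.append(np.zeros((N_SENSING, char_len), complex))
                char_sh.append(noise)
                char_times.append(t0)
            tr_index += 1

    scan_time_s = tr_index * tr_s
    meta = {
        "seed": seed,
        "shots": len(shots),
        "scan_time_s": scan_time_s,
        "char_overhead_s": tr_index * protocol.char_count * char_len * dwell,
        "n_masked_pe": int(mask.sum()),
    }
    return AcquisitionRecord(
        protocol=protocol,
        acq_rx=np.array(acq_rx), acq_rx_shielded=np.array(acq_sh),
        acq_sens=np.array(acq_sens),
        acq_coords=np.array(coords, dtype=int), acq_times=np.array(times),
        char_rx=np.array(char_rx).reshape(-1, char_len),
        char_rx_shielded=np.array(char_sh).reshape(-1, char_len),
        char_sens=np.array(char_sens).reshape(-1, N_SENSING, char_len),
        char_times=np.array(char_times, dtype=float),
        mask=mask, meta=meta, phantom_labels=phantom.labels.copy(),
        emi_world=emi_world,
    )


# --- EPI DWI --------------------------------------------------------------

@dataclass
class DWIScan:
    """Single-shot EPI DWI acquisition: b0 plus three orthogonal b1 volumes.

    ``kspace[name]`` has shape (nex, n_fe, n_pe) — line-reversal bookkeeping
    already applied, ghost phase and distortion phase included.
    ``reference[name]`` holds the 3-line non-phase-encoded reference scan for
    ghost calibration.  When an EMI world is attached, per-line receive/
    sensing windows and characterization windows are stored like in
    :class:`AcquisitionRecord`.
    """

    protocol: ProtocolConfig
    kspace: dict
    kspace_shielded: dict
    reference: dict
    char_rx: np.ndarray
    char_sens: np.ndarray
    meta: dict = field(default_factory=dict)
    phantom_labels: Optional[np.ndarray] = None


def _epi_volume_kspace(vol2d: np.ndarray, field_map: Optional[np.ndarray],
                       protocol: ProtocolConfig) -> np.ndarray:
    """Ideal single-shot EPI k-space of a 2D slice (n_fe, n_pe), with
    off-resonance phase accrual along the echo train and odd/even ghost phase."""
    n_fe, n_pe = vol2d.shape
    ksp = np.empty((n_fe, n_pe), dtype=complex)
    esp = protocol.epi_echo_spacing
    c = n_pe // 2
    if field_map is None or not np.any(field_map):
        base = kspace_of_volume(vol2d[:, :, None])[:, :, 0]
        ksp[:] = base
    else:
        for r in range(n_pe):
            t_r = (r - c) * esp  # spin echo refocuses at the center line
            phase = np.exp(2j * np.pi * field_map * t_r)
            ksp[:, r] = kspace_of_volume((vol2d * phase)[:, :, None])[:, r, 0]
    if protocol.ghost_phi0 != 0.0 or protocol.ghost_phi1 != 0.0:
        x = np.arange(n_fe) - n_fe // 2
        ramp = np.exp(1j * (protocol.ghost_phi0 + protocol.ghost_phi1 * x))
        for r in range(1, n_pe, 2):  # reversed-readout lines
            hyb = np.fft.ifft(np.fft.ifftshift(ksp[:, r]), norm="ortho")
            hyb *= np.fft.ifftshift(ramp)
            ksp[:, r] = np.fft.fftshift(np.fft.fft(hyb, norm="ortho"))
    return ksp


def simulate_epi_dwi(phantom: Phantom,
                     protocol: ProtocolConfig,
                     emi_world: Optional[EMIWorld] = None,
                     seed: int = 0,
                     adc_override: Optional[dict] = None) -> DWIScan:
    """Simulate 2D spin-echo EPI DWI: one b0 and three orthogonal b1 volumes.

    ``adc_override`` maps tissue name -> length-3 per-direction ADCs
    (mm^2/s) for anisotropic tests; default uses the phantom's scalar ADC in
    every direction.  Each volume also gets a 3-line non-phase-encoded
    reference scan carrying the same odd/even ghost phase.
    """
    if protocol.kind is not SequenceKind.EPI_DWI_2D:
        raise ValueError("protocol must be EPI_DWI_2D")
    if protocol.diffusion is None:
        raise ValueError("EPI DWI requires a diffusion encoding")
    n_fe, n_pe, n_sl = protocol.matrix
    if phantom.shape != (n_fe, n_pe, n_sl) or n_sl != 1:
        raise ValueError("phantom must match the single-slice EPI matrix")
    fmap = phantom.field_map[:, :, 0] if phantom.field_map is not None else None

    maps = parameter_maps(phantom)
    body = phantom.labels[:, :, 0] > 0
    pd, t1, t2 = (maps[k][:, :, 0] for k in ("pd", "t1", "t2"))
    s0 = np.zeros((n_fe, n_pe))
    s0[body] = fse_signal(pd[body], t1[body], t2[body], protocol.tr, protocol.te)

    b = protocol.diffusion.b
    adc = maps["adc"][:, :, 0]
    names = ["b0", "b1x", "b1y", "b1z"]
    vols = {"b0": s0}
    for d, name in enumerate(names[1:]):
        adc_d = adc.copy()
        if adc_override:
            for tname, vals in adc_override.items():
                lbl = [t.name for t in phantom.tissues].index(tname)
                adc_d[phantom.labels[:, :, 0] == lbl] = vals[d]
        vols[name] = dwi_signal(s0, adc_d, b)

    ss = np.random.SeedSequence(seed)
    rng_rcv, rng_sens = (np.random.default_rng(s) for s in ss.spawn(2))
    sigma = protocol.receiver_noise_sigma
    dwell = protocol.dwell
    tr_s = protocol.tr * 1e-3
    echo0 = protocol.echo_start_ms * 1e-3
    line_dur = protocol.line_duration
    char_len = protocol.n_char_len

    kspace, kshield, reference = {}, {}, {}
    char_rx, char_sens = [], []
    tr_index = 0
    for name in names:
        ideal = _epi_volume_kspace(vols[name], fmap, protocol)
        # reference scan: 3 non-phase-encoded lines with the same ghost phase
        ref_ideal = _epi_volume_kspace(vols[name], None, protocol)
        dc = ref_ideal[:, n_pe // 2]
        x = np.arange(n_fe) - n_fe // 2
        ramp = np.exp(1j * (protocol.ghost_phi0 + protocol.ghost_phi1 * x))
        hyb = np.fft.ifft(np.fft.ifftshift(dc), norm="ortho")
        dc_odd = np.fft.fftshift(np.fft.fft(hyb * np.fft.ifftshift(ramp), norm="ortho"))
        reference[name] = np.stack([dc, dc_odd, dc]) \
            + _draw_cnoise(rng_rcv, sigma, (3, n_fe))

        acc = np.zeros((protocol.nex, n_fe, n_pe), complex)
        acc_sh = np.zeros_like(acc)
        for i_nex in range(protocol.nex):
            t_tr = tr_index * tr_s
            noise = _draw_cnoise(rng_rcv, sigma, (n_fe, n_pe))
            clean = ideal + noise
            acc_sh[i_nex] = clean
            if emi_world is not None:
                emi_rx = np.empty((n_fe, n_pe), complex)
                for r in range(n_pe):
                    t0 = t_tr + echo0 + r * line_dur
                    emi_rx[:, r] = emi_world.coupled(t0, n_fe, dwell, rng_sens)[0]
                acc[i_nex] = clean + emi_rx
            else:
                acc[i_nex] = clean
            for off in protocol.char_window_starts():
                t0 = t_tr + off
                cnoise = _draw_cnoise(rng_rcv, sigma, char_len)
                if emi_world is not None:
                    emi = emi_world.coupled(t0, char_len, dwell, rng_sens)
                    char_rx.append(cnoise + emi[0])
                    char_sens.append(emi[1:])
                else:
                    char_rx.append(cnoise)
                    char_sens.append(np.zeros((N_SENSING, char_len), complex))
            tr_index += 1
        kspace[name] = acc
        kshield[name] = acc_sh

    meta = {"seed": seed, "scan_time_s": tr_index * tr_s, "b": b,
            "pe_bandwidth_per_pixel": protocol.pe_bandwidth_per_pixel}
    return DWIScan(protocol=protocol, kspace=kspace, kspace_shielded=kshield,
                   reference=reference,
                   char_rx=np.array(char_rx).reshape(-1, char_len),
                   char_sens=np.array(char_sens).reshape(-1, N_SENSING, char_len),
                   meta=meta, phantom_labels=phantom.labels.copy())
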