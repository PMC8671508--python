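"""EMI source waveforms and their linear coupling into the coil array.

Everything lives at complex baseband around the 2.32 MHz proton carrier:
frequencies are offsets within the receive bandwidth (default sampling rate
50 kHz, so offsets within ±25 kHz).  Four source kinds are provided:

* ``tone`` — single offset frequency, analytic phase;
* ``swept`` — linear chirp traversing a band over a sweep period (the
  dynamic-EMI case: its spectral ridge moves during the scan);
* ``powerline_harmonics`` — comb at multiples of a mains fundamental
  (default 50 Hz) with 1/m amplitude roll-off and seeded phases;
* ``broadband`` — a dense seeded comb of random tones inside a band, which
  is stationary, band-limited, and (unlike filtered noise) exactly
  reproducible at any absolute time, so waveforms are continuous across
  arbitrarily scheduled acquisition windows.

Coupling is linear: each (source, channel) pair has a complex FIR filter;
channel 0 is the MRI receive coil and channels 1..10 are the EMI sensing
coils.  Sensing channels carry independent complex-Gaussian sensor noise
(receive-chain thermal noise is added by the acquisition module instead).
An optional slow multiplicative gain drift per channel phenomenologically
models body-antenna and posture effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EMISource",
    "CouplingModel",
    "EMIWorld",
    "gen_source_segment",
    "couple",
    "make_random_coupling",
    "source_comb",
    "fir_power_response",
]

N_SENSING = 10
N_CHANNELS = N_SENSING + 1  # receive + sensing


@dataclass(frozen=True)
class EMISource:
    """One interference source at complex baseband.

    ``band`` is (f_lo, f_hi) in Hz offsets for broadband/swept kinds;
    ``freq`` the tone offset; ``fundamental`` the mains frequency for the
    harmonic comb.  ``sweep_period`` is the time (s) a swept source takes to
    traverse its band.  ``drift`` is an optional (depth, period_s) amplitude
    modulation 1 + depth*sin(2*pi*t/period).
    """

    kind: str
    amplitude: float = 1.0
    band: tuple[float, float] = (-10e3, 10e3)
    freq: float = 0.0
    fundamental: float = 50.0
    sweep_period: float = 10.0
    n_tones: int = 256
    seed: int = 0
    drift: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("broadband", "swept", "tone", "powerline_harmonics"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


def _check_band(f_lo: float, f_hi: float, dwell: float) -> None:
    nyq = 0.5 / dwell
    if f_lo < -nyq or f_hi > nyq or f_lo > f_hi:
        raise ValueError(f"band ({f_lo}, {f_hi}) Hz outside Nyquist ±{nyq:.0f} Hz")


def _broadband_comb(source: EMISource):
    """Seeded random tone comb (freqs, phases, weights) for a broadband source."""
    rng = np.random.default_rng(source.seed)
    f = rng.uniform(source.band[0], source.band[1], source.n_tones)
    ph = rng.uniform(0.0, 2 * np.pi, source.n_tones)
    w = rng.rayleigh(1.0, source.n_tones)
    w = w / np.sqrt(np.sum(w**2))  # unit total power
    return f, ph, w


def gen_source_segment(source: EMISource, t_start: float, n_samples: int,
                       dwell: float) -> np.ndarray:
    """Complex baseband samples of a source at absolute times t_start + k*dwell.

    All kinds are analytic functions of absolute time (broadband through its
    seeded tone comb), so segments generated for adjacent or overlapping
    windows agree sample-for-sample and are phase-continuous.
    """
    if dwell <= 0:
        raise ValueError("dwell must be positive")
    t = t_start + dwell * np.arange(n_samples)
    kind = source.kind
    if kind == "tone":
        _check_band(source.freq, source.freq, dwell)
        x = np.exp(2j * np.pi * source.freq * t)
    elif kind == "swept":
        f1, f2 = source.band
        _check_band(f1, f2, dwell)
        # periodic linear chirp; instantaneous frequency f1 -> f2 each period
        tau = np.mod(t, source.sweep_period)
        rate = (f2 - f1) / source.sweep_period
        phase = 2 * np.pi * (f1 * tau + 0.5 * rate * tau**2)
        x = np.exp(1j * phase)
    elif kind == "powerline_harmonics":
        f_max = min(source.band[1], 0.5 / dwell * 0.99)
        _check_band(source.fundamental, f_max, dwell)
        m = np.arange(1, int(f_max / source.fundamental) + 1)
        if m.size == 0:
            raise ValueError("no harmonics of the fundamental fall inside the band")
        rng = np.random.default_rng(source.seed)
        ph = rng.uniform(0.0, 2 * np.pi, m.size)
        w = 1.0 / m
        w = w / np.sqrt(np.sum(w**2))
        x = np.exp(1j * (2 * np.pi * np.outer(t, m * source.fundamental) + ph)) @ w.astype(complex)
    elif kind == "broadband":
        _check_band(source.band[0], source.band[1], dwell)
        f, ph, w = _broadband_comb(source)
        x = np.exp(1j * (2 * np.pi * np.outer(t, f) + ph)) @ w.astype(complex)
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(kind)
    if source.drift is not None:
        depth, period = source.drift
        x = x * (1.0 + depth * np.sin(2 * np.pi * t / period))
    return source.amplitude * x


def source_comb(source: EMISource, dwell: float):
    """Spectral content of a source: (frequencies Hz, power weights).

    Power weights sum to the source's total power (amplitude^2).  The swept
    chirp dwells uniformly across its band, so it is represented by a fine
    uniform grid.  Used to evaluate exactly how much power a FIR coupling
    delivers (the filter's response at the comb frequencies matters, not
    just its tap energy).
    """
    a2 = source.amplitude**2
    if source.kind == "tone":
        return np.array([source.freq]), np.array([a2])
    if source.kind == "broadband":
        f, _, w = _broadband_comb(source)
        return f, a2 * w**2
    if source.kind == "powerline_harmonics":
        f_max = min(source.band[1], 0.5 / dwell * 0.99)
        m = np.arange(1, int(f_max / source.fundamental) + 1)
        w = 1.0 / m
        w = w / np.sqrt(np.sum(w**2))
        return m * source.fundamental, a2 * w**2
    if source.kind == "swept":
        f = np.linspace(source.band[0], source.band[1], 256)
        return f, np.full(256, a2 / 256)
    raise ValueError(source.kind)  # pragma: no cover


def fir_power_response(taps: np.ndarray, freqs: np.ndarray, dwell: float) -> np.ndarray:
    """|H(f)|^2 of a causal complex FIR at baseband frequencies ``freqs``."""
    lags = np.arange(len(taps))
    H = np.exp(-2j * np.pi * np.outer(freqs, lags) * dwell) @ np.asarray(taps)
    return np.abs(H) ** 2


@dataclass
class CouplingModel:
    """Linear FIR coupling of each source into each of the 11 channels.

    ``taps[s, c]`` is the complex FIR (length L, tap 0 = current sample) from
    source s into channel c.  Channel 0 is the receive coil.
    ``sensor_noise_sigma`` is the per-sensing-channel complex-Gaussian std.
    ``drift`` optionally holds per-channel (depth, period_s) slow gain
    modulation applied multiplicatively to the coupled EMI.
    """

    taps: np.ndarray
    sensor_noise_sigma: float = 0.0
    drift: Optional[Sequence[Optional[tuple[float, float]]]] = None

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=complex)
        if self.taps.ndim != 3:
            raise ValueError("taps must have shape (n_sources, n_channels, n_taps)")
        if self.taps.shape[1] != N_CHANNELS:
            raise ValueError(f"channel count must be {N_CHANNELS} (1 receive + {N_SENSING} sensing)")
        if self.taps.shape[2] < 1:
            raise ValueError("filter length must be >= 1")

    @property
    def n_sources(self) -> int:
        return self.taps.shape[0]

    @property
    def n_taps(self) -> int:
        return self.taps.shape[2]


def make_random_coupling(n_sources: int,
                         seed: int = 0,
                         receive_taps: int = 3,
                         sensing_taps: int = 1,
                         sensor_noise_sigma: float = 0.0,
                         receive_gain: float = 1.0,
                         sensing_gain: float = 1.0,
                         drift: Optional[Sequence] = None) -> CouplingModel:
    """Random complex coupling with O(1) gains.

    Sensing couplings default to a single tap (each sensing coil picks the
    sources up with its own complex gain), which keeps the sensing-to-receive
    map expressible as a short FIR — the realistic regime the cancellers face.
    """
    rng = np.random.default_rng(seed)
    L = max(receive_taps, sensing_taps)
    taps = np.zeros((n_sources, N_CHANNELS, L), dtype=complex)

    def cplx(shape, scale):
        return scale * (rng.normal(size=shape) + 1j * rng.normal(size=shape)) / np.sqrt(2)

    taps[:, 0, :receive_taps] = cplx((n_sources, receive_taps), receive_gain / np.sqrt(receive_taps))
    taps[:, 1:, :sensing_taps] = cplx((n_sources, N_SENSING, sensing_taps),
                                      sensing_gain / np.sqrt(sensing_taps))
    return CouplingModel(taps, sensor_noise_sigma=sensor_noise_sigma, drift=drift)


def couple(sources: Sequence[EMISource],
           coupling: CouplingModel,
           t_start: float,
           n_samples: int,
           dwell: float,
           rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Coupled EMI for one window: complex array (11, n_samples).

    Channel c receives sum_s FIR_{s,c} * source_s evaluated exactly (each
    source is generated with n_taps-1 pre-roll samples so the causal FIR has
    no boundary transient).  Sensing channels additionally receive sensor
    noise drawn from ``rng``; the receive channel gets none (its thermal
    noise belongs to the acquisition chain).
    """
    if len(sources) != coupling.n_sources:
        raise ValueError("number of sources does not match coupling model")
    L = coupling.n_taps
    out = np.zeros((N_CHANNELS, n_samples), dtype=complex)
    for s_idx, src in enumerate(sources):
        seg = gen_source_segment(src, t_start - (L - 1) * dwell, n_samples + L - 1, dwell)
        for lag in range(L):
            chunk = seg[L - 1 - lag: L - 1 - lag + n_samples]
            out += np.multiply.outer(coupling.taps[s_idx, :, lag], chunk)
    if coupling.drift is not None:
        t = t_start + dwell * np.arange(n_samples)
        for c, d in enumerate(coupling.drift):
            if d is not None:
                depth, period = d
                out[c] *= 1.0 + depth * np.sin(2 * np.pi * t / period)
    if rng is not None and coupling.sensor_noise_sigma > 0:
        noise = coupling.sensor_noise_sigma / np.sqrt(2) * (
            rng.standard_normal((N_SENSING, n_samples))
            + 1j * rng.standard_normal((N_SENSING, n_samples)))
        out[1:] += noise
    return out


@dataclass
class EMIWorld:
    """A set of EMI sources plus their coupling into the coil array."""

    sources: list[EMISource]
    coupling: CouplingModel

    def coupled(self, t_start: float, n_samples: int, dwell: float,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        return couple(self.sources, self.coupling, t_start, n_samples, dwell, rng)

    def emi_band(self, dwell: float) -> tuple[float, float]:
        """Union of the source bands (Hz offsets), for suppression metrics."""
        lo, hi = np.inf, -np.inf
        for s in self.sources:
            if s.kind == "tone":
                lo, hi = min(lo, s.freq), max(hi, s.freq)
            elif s.kind == "powerline_harmonics":
                lo = min(lo, s.fundamental)
                hi = max(hi, min(s.band[1], 0.5 / dwell * 0.99))
            else:
                lo, hi = min(lo, s.band[0]), max(hi, s.band[1])
        return lo, hi
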