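"""End-to-end workflow: simulate -> train -> cancel -> reconstruct -> evaluate.

Also defines the standard simulated EMI environments (broadband plus mains
harmonics; a swept-frequency source for the dynamic-EMI case) and the seed
fan-out scheme: a single run seed is multiplied by 10 and offset by a fixed
per-stage counter (0 EMI world, 1 acquisition, 2 training), so any stage can
be re-run in isolation and no two (seed, stage) pairs collide.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import io as uio
from .acquisition import AcquisitionRecord, simulate_scan, t2w_smoke
from .canceller import (TrainConfig, apply_linear, assemble_training, cancel,
                        fit_linear, train_cnn)
from .emi import (EMISource, EMIWorld, fir_power_response, make_random_coupling,
                  source_comb)
from .metrics import MetricsReport, suppression_report
from .phantom import Phantom, make_phantom
from .recon import average_nex, recon_cartesian

log = logging.getLogger("ulfmri")

__all__ = ["RunConfig", "PipelineResult", "stage_seed", "standard_world",
           "swept_world", "source_power", "run_pipeline"]

_STAGES = {"emi": 0, "acquisition": 1, "training": 2}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: seed * 10 + stage counter (< 2**31)."""
    return (seed * 10 + _STAGES[stage]) % (2**31)


def source_power(src: EMISource) -> float:
    """Expected baseband power of a source (all kinds are unit-power combs
    or unit-modulus waveforms scaled by amplitude)."""
    return src.amplitude**2


def _pin_receive_power(world: EMIWorld, target_power: float,
                       dwell: float = 2e-5) -> EMIWorld:
    """Rescale receive-coil coupling taps so the EMI power delivered into
    the receive channel equals ``target_power`` (sensing couplings
    untouched).  Evaluated exactly over each source's spectral comb and the
    filter's frequency response, so the realized EMI-to-noise ratio stays at
    its pinned value instead of fluctuating with how the random taps happen
    to shape the band."""
    taps = world.coupling.taps
    cur = 0.0
    for i, src in enumerate(world.sources):
        f, pw = source_comb(src, dwell)
        cur += float(np.sum(pw * fir_power_response(taps[i, 0], f, dwell)))
    if cur > 0:
        taps[:, 0, :] *= np.sqrt(target_power / cur)
    return world


def standard_world(seed: int, noise_sigma: float,
                   emi_to_noise: float = 20.0,
                   sensor_noise_sigma: float = 0.01,
                   receive_taps: int = 3) -> EMIWorld:
    """Broadband (2-20 kHz) plus 50 Hz mains-harmonic EMI.

    Receive-coil coupling is scaled so the EMI-to-receiver-noise power ratio
    equals ``emi_to_noise`` in expectation; sensing coils pick the sources up
    at O(1) gain with weak sensor noise (~40 dB sensing SNR).
    """
    srcs = [EMISource("broadband", amplitude=1.0, band=(2e3, 20e3), seed=seed * 100 + 1),
            EMISource("powerline_harmonics", amplitude=0.7, band=(0.0, 24e3),
                      seed=seed * 100 + 2)]
    coup = make_random_coupling(len(srcs), seed=seed * 100 + 3,
                                receive_taps=receive_taps, sensing_taps=1,
                                sensor_noise_sigma=sensor_noise_sigma)
    return _pin_receive_power(EMIWorld(srcs, coup),
                              emi_to_noise * noise_sigma**2)


def swept_world(seed: int, noise_sigma: float,
                emi_to_noise: float = 20.0,
                sweep_period: float = 24.0,
                band: tuple[float, float] = (-18e3, 18e3),
                sensor_noise_sigma: float = 0.01) -> EMIWorld:
    """A swept-frequency source traversing the band during the scan — the
    dynamic-EMI environment whose spectral ridge moves while scanning.

    The default period matches the standard evaluation scan (24 s), so the
    ridge walks monotonically across the whole band once per scan with no
    sawtooth retrace discontinuity inside it.
    """
    srcs = [EMISource("swept", amplitude=1.0, band=band,
                      sweep_period=sweep_period, seed=seed * 100 + 7)]
    # single receive tap: a frequency-flat coupling keeps the realized
    # EMI-to-noise ratio at its pinned value as the chirp crosses the band
    coup = make_random_coupling(1, seed=seed * 100 + 8, receive_taps=1,
                                sensing_taps=1,
                                sensor_noise_sigma=sensor_noise_sigma)
    return _pin_receive_power(EMIWorld(srcs, coup),
                              emi_to_noise * noise_sigma**2)


@dataclass
class RunConfig:
    """Configuration of one simulate-to-report run."""

    seed: int = 0
    matrix: tuple[int, int, int] = (64, 64, 1)
    etl: int = 8
    nex: int = 2
    char_count: int = 16
    receiver_noise_sigma: float = 0.007
    emi: str = "standard"            # standard | swept | none
    emi_to_noise: float = 20.0
    canceller: str = "cnn"           # cnn | linear | none
    linear_taps: int = 3
    linear_reg: float = 1e-10
    epochs: int = 20
    batch: int = 16
    lr: float = 5e-4
    pad_factors: tuple[int, int, int] = (2, 2, 1)
    outdir: Optional[str] = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}")
        d = dict(d)
        for k in ("matrix", "pad_factors"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return uio.config_hash(self.to_dict())


@dataclass
class PipelineResult:
    config: RunConfig
    record: AcquisitionRecord
    cleaned: AcquisitionRecord
    report: MetricsReport
    image: "np.ndarray"
    model: Optional[object] = None
    timings: dict = field(default_factory=dict)


def build_world(config: RunConfig) -> Optional[EMIWorld]:
    seed = stage_seed(config.seed, "emi")
    if config.emi == "standard":
        return standard_world(seed, config.receiver_noise_sigma, config.emi_to_noise)
    if config.emi == "swept":
        return swept_world(seed, config.receiver_noise_sigma, config.emi_to_noise)
    if config.emi == "none":
        return None
    raise ValueError(f"unknown EMI environment {config.emi!r}")


def run_pipeline(config: RunConfig,
                 phantom: Optional[Phantom] = None) -> PipelineResult:
    """One full experiment: the whole workflow from phantom to MetricsReport.

    Simulates the dual-window scan in the configured EMI environment, trains
    the configured canceller on the characterization windows, subtracts the
    predicted EMI per FE line, averages, reconstructs, and evaluates against
    the shielded twin.
    """
    timings: dict[str, float] = {}
    if phantom is None:
        phantom = make_phantom(config.matrix)
    protocol = t2w_smoke(matrix=config.matrix, etl=config.etl, nex=config.nex,
                         char_count=config.char_count,
                         receiver_noise_sigma=config.receiver_noise_sigma)
    world = build_world(config)

    t0 = time.perf_counter()
    record = simulate_scan(phantom, protocol, world,
                           seed=stage_seed(config.seed, "acquisition"))
    timings["simulate"] = time.perf_counter() - t0
    log.info("simulated %d FE lines, %d characterization windows "
             "(scan %.0f s, characterization overhead %.2f s)",
             record.n_lines, record.n_char_windows,
             record.meta["scan_time_s"], record.meta["char_overhead_s"])

    model = None
    t0 = time.perf_counter()
    if world is None or config.canceller == "none":
        cleaned = record
    elif config.canceller == "cnn":
        tcfg = TrainConfig(epochs=config.epochs, batch=config.batch, lr=config.lr,
                           seed=stage_seed(config.seed, "training"))
        train_set = assemble_training(record, tcfg)
        model = train_cnn(train_set, tcfg)
        timings["train"] = time.perf_counter() - t0
        log.info("CNN validation loss %.3e -> %.3e over %d epochs",
                 model.history["val_loss"][0], model.history["val_loss"][-1],
                 config.epochs)
        t0 = time.perf_counter()
        cleaned = cancel(record, model)
    elif config.canceller == "linear":
        model = fit_linear(record, taps=config.linear_taps, reg=config.linear_reg)
        cleaned = apply_linear(model, record)
    else:
        raise ValueError(f"unknown canceller {config.canceller!r}")
    timings["cancel"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    shielded = record.shielded_twin()
    report = suppression_report(cleaned, record, shielded,
                                pad_factors=config.pad_factors)
    image = recon_cartesian(average_nex(cleaned), config.pad_factors,
                            provenance={"config": config.hash,
                                        "seed": config.seed})
    timings["recon+metrics"] = time.perf_counter() - t0
    if world is None:
        log.info("EMI absent: shielded deviation %.4f (trivially ~0)",
                 report.shielded_deviation)
    else:
        log.info("shielded deviation %.2f%% (pass_5pct=%s), suppression %.1f dB",
                 100 * report.shielded_deviation, report.pass_5pct,
                 report.suppression_db)

    result = PipelineResult(config=config, record=record, cleaned=cleaned,
                            report=report, image=image.data, model=model,
                            timings=timings)
    if config.outdir:
        _write_outputs(result, image)
    return result


def _write_outputs(result: PipelineResult, image) -> None:
    os.makedirs(result.config.outdir, exist_ok=True)
    out = result.config.outdir
    uio.save_record(result.record, os.path.join(out, "record.h5"))
    from .canceller import CancellerModel

    if isinstance(result.model, CancellerModel):
        uio.save_model(result.model, os.path.join(out, "model.h5"))
    image.provenance.update(config=result.config.hash, seed=result.config.seed)
    image.save_nifti(os.path.join(out, "image.nii.gz"))
    uio.save_report_json({**result.report.to_dict(),
                          "config": result.config.to_dict(),
                          "config_hash": result.config.hash,
                          "timings": result.timings},
                         os.path.join(out, "report.json"))
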