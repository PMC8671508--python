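"""HDF5 / YAML / JSON persistence for records, models and reports.

Raw acquisition records use the group layout
``/receive/acq``, ``/receive/char``, ``/sensing/acq``, ``/sensing/char``,
``/kspace_coords`` and ``/meta`` (shielded-twin arrays live next to their
contaminated counterparts).  Canceller models store per-layer weights,
normalization statistics and constants, the training configuration and the
per-epoch loss history.  Every file carries the configuration hash and seed
of the run that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import h5py
import numpy as np
import yaml

from .acquisition import AcquisitionRecord, ProtocolConfig
from .canceller import CancellerModel, TrainConfig, build_cnn
from .contrast import DiffusionEncoding, SequenceKind

__all__ = [
    "config_hash",
    "load_yaml",
    "save_record",
    "load_record",
    "save_model",
    "load_model",
    "save_report_json",
]


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_yaml(path: str) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"{path} does not contain a mapping")
    return out


def _protocol_to_dict(p: ProtocolConfig) -> dict:
    d = dataclasses.asdict(p)
    d["kind"] = p.kind.value
    if p.diffusion is not None:
        d["diffusion"] = {"b": p.diffusion.b, "big_delta": p.diffusion.big_delta,
                          "small_delta": p.diffusion.small_delta}
    return d


def protocol_from_dict(d: dict) -> ProtocolConfig:
    d = dict(d)
    d["kind"] = SequenceKind(d["kind"])
    if d.get("diffusion") is not None:
        diff = d["diffusion"]
        if isinstance(diff, dict):
            d["diffusion"] = DiffusionEncoding(**{k: diff[k] for k in
                                                  ("b", "big_delta", "small_delta")
                                                  if k in diff})
    d.pop("directions", None)
    for k in ("matrix", "fov"):
        if k in d:
            d[k] = tuple(d[k])
    return ProtocolConfig(**d)


def save_record(record: AcquisitionRecord, path: str) -> None:
    with h5py.File(path, "w") as f:
        rx = f.create_group("receive")
        rx.create_dataset("acq", data=record.acq_rx)
        rx.create_dataset("acq_shielded", data=record.acq_rx_shielded)
        rx.create_dataset("char", data=record.char_rx)
        rx.create_dataset("char_shielded", data=record.char_rx_shielded)
        sens = f.create_group("sensing")
        sens.create_dataset("acq", data=record.acq_sens)
        sens.create_dataset("char", data=record.char_sens)
        f.create_dataset("kspace_coords", data=record.acq_coords)
        f.create_dataset("acq_times", data=record.acq_times)
        f.create_dataset("char_times", data=record.char_times)
        f.create_dataset("mask", data=record.mask.astype(np.uint8))
        if record.phantom_labels is not None:
            f.create_dataset("phantom_labels", data=record.phantom_labels)
        meta = f.create_group("meta")
        meta.attrs["protocol"] = json.dumps(_protocol_to_dict(record.protocol))
        meta.attrs["meta"] = json.dumps(record.meta, default=str)


def load_record(path: str) -> AcquisitionRecord:
    with h5py.File(path, "r") as f:
        protocol = protocol_from_dict(json.loads(f["meta"].attrs["protocol"]))
        labels = f["phantom_labels"][()] if "phantom_labels" in f else None
        return AcquisitionRecord(
            protocol=protocol,
            acq_rx=f["receive/acq"][()],
            acq_rx_shielded=f["receive/acq_shielded"][()],
            acq_sens=f["sensing/acq"][()],
            acq_coords=f["kspace_coords"][()],
            acq_times=f["acq_times"][()],
            char_rx=f["receive/char"][()],
            char_rx_shielded=f["receive/char_shielded"][()],
            char_sens=f["sensing/char"][()],
            char_times=f["char_times"][()],
            mask=f["mask"][()].astype(bool),
            meta=json.loads(f["meta"].attrs["meta"]),
            phantom_labels=labels,
        )


def save_model(model: CancellerModel, path: str) -> None:
    with h5py.File(path, "w") as f:
        w = f.create_group("weights")
        for name, arr in model.net.state_arrays().items():
            w.create_dataset(name.replace("/", "__"), data=arr)
        f.attrs["x_scale"] = model.x_scale
        f.attrs["y_scale"] = model.y_scale
        f.attrs["n_x"] = model.n_x
        f.attrs["coil_reduction"] = model.coil_reduction
        f.attrs["fingerprint"] = model.fingerprint or ""
        f.attrs["config"] = json.dumps(dataclasses.asdict(model.config))
        f.attrs["history"] = json.dumps(model.history)


def load_model(path: str) -> CancellerModel:
    with h5py.File(path, "r") as f:
        cfg = TrainConfig(**{**json.loads(f.attrs["config"]),
                             "split": tuple(json.loads(f.attrs["config"])["split"])})
        net = build_cnn(seed=cfg.seed)
        net.load_state({k.replace("__", "/"): v[()]
                        for k, v in f["weights"].items()})
        return CancellerModel(net=net, x_scale=float(f.attrs["x_scale"]),
                              y_scale=float(f.attrs["y_scale"]),
                              n_x=int(f.attrs["n_x"]), config=cfg,
                              history=json.loads(f.attrs["history"]),
                              fingerprint=f.attrs["fingerprint"] or None,
                              coil_reduction=str(f.attrs["coil_reduction"]))


def save_report_json(report_dict: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report_dict, fh, indent=2, default=float)
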