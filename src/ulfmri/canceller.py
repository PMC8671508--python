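"""Per-scan EMI cancellation: five-layer CNN and linear least-squares baseline.

The CNN maps the ten sensing-coil signals of one FE line (input
n_x x 10 x 2, real/imag as channels) to the receive-coil EMI of that line
(output n_x x 2).  It is trained per scan, purely on the EMI
characterization windows (which contain no MRI signal), with an 85/15
train/validation split, MSE loss, and Adam (lr 5e-4, beta1 0.9, beta2 0.999)
for 20 epochs at batch size 16.  The five convolutional layers have kernels
11x11, 9x9, 5x5, 1x1, 7x7 and 128, 64, 32, 32, 2 channels; the first four
are conv + batch norm + ReLU, the last is convolution only.  All
convolutions use same-padding, and the two-channel output is averaged across
the 10-wide coil axis to produce the n_x x 2 prediction (the coil-axis
reduction rule).  Inputs and targets are each normalized to unit standard
deviation computed on the training portion only (the two constants are
stored in the model), so the network always trains at its natural
initialization scale regardless of how weakly the EMI couples into the
receive coil.

The linear canceller solves a regularized least-squares regression from
lagged sensing samples to receive samples over the same windows.  In a
noiseless linear time-invariant world it is exact, which makes it the
analytic oracle the CNN is checked against.

Per-scan discipline: a model remembers a fingerprint of the
characterization data it was trained on and refuses to cancel a different
record.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .acquisition import AcquisitionRecord
from .nnet import Adam, BatchNorm2d, Conv2d, ReLU, Sequential, mse_grad, mse_loss

__all__ = [
    "TrainConfig",
    "TrainingSet",
    "CancellerModel",
    "LinearCanceller",
    "assemble_training",
    "build_cnn",
    "train_cnn",
    "predict_emi",
    "cancel",
    "fit_linear",
    "apply_linear",
    "predict_linear",
]

#: (kernel, channels) of the five convolutional layers
CNN_ARCH = [((11, 11), 128), ((9, 9), 64), ((5, 5), 32), ((1, 1), 32), ((7, 7), 2)]
N_COILS = 10


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters (defaults as used on the scanner)."""

    split: tuple[float, float] = (0.85, 0.15)
    batch: int = 16
    epochs: int = 20
    lr: float = 5e-4
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch < 1 or self.epochs < 1 or self.lr <= 0:
            raise ValueError("batch, epochs >= 1 and lr > 0 required")
        if not np.isclose(sum(self.split), 1.0) or min(self.split) <= 0:
            raise ValueError("split fractions must be positive and sum to 1")


def _fingerprint(char_rx: np.ndarray, char_sens: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(char_rx).tobytes())
    h.update(np.ascontiguousarray(char_sens).tobytes())
    return h.hexdigest()[:16]


@dataclass
class TrainingSet:
    """Scaled example pairs drawn from characterization windows only."""

    x: np.ndarray            # (N, n_x, 10, 2) float32, scaled by x_scale
    y: np.ndarray            # (N, n_x, 2) float32, scaled by y_scale
    train_idx: np.ndarray
    val_idx: np.ndarray
    x_scale: float
    y_scale: float
    fingerprint: str

    @property
    def n_x(self) -> int:
        return self.x.shape[1]


def _windows_to_examples(char_rx: np.ndarray, char_sens: np.ndarray):
    x = np.stack([char_sens.real, char_sens.imag], axis=-1)  # (N, 10, n_x, 2)
    x = np.ascontiguousarray(x.transpose(0, 2, 1, 3))        # (N, n_x, 10, 2)
    y = np.stack([char_rx.real, char_rx.imag], axis=-1)      # (N, n_x, 2)
    return x, y


def assemble_training(record: AcquisitionRecord,
                      config: TrainConfig = TrainConfig()) -> TrainingSet:
    """Build the train/validation sets from a record's characterization windows.

    The split is a seeded random partition at the configured fractions
    (85/15 by default); the input and target scaling constants are standard
    deviations computed on the training portion only.
    """
    n = record.n_char_windows
    min_needed = 20
    if n < min_needed:
        raise ValueError(
            f"only {n} characterization windows available (need >= {min_needed}); "
            "increase NEX or the number of characterization windows per TR")
    x, y = _windows_to_examples(record.char_rx, record.char_sens)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * config.split[0]))
    train_idx, val_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    x_scale = float(np.std(x[train_idx])) or 1.0
    y_scale = float(np.std(y[train_idx])) or 1.0
    return TrainingSet(x=(x / x_scale).astype(np.float32),
                       y=(y / y_scale).astype(np.float32),
                       train_idx=train_idx, val_idx=val_idx,
                       x_scale=x_scale, y_scale=y_scale,
                       fingerprint=_fingerprint(record.char_rx, record.char_sens))


def build_cnn(seed: int = 0) -> Sequential:
    """The five-layer network (He-initialized, seeded)."""
    rng = np.random.default_rng(seed)
    layers: list = []
    c_in = 2
    for i, (kernel, c_out) in enumerate(CNN_ARCH):
        layers.append(Conv2d(c_in, c_out, kernel, rng))
        if i < len(CNN_ARCH) - 1:  # last layer: convolution only
            layers.append(BatchNorm2d(c_out))
            layers.append(ReLU())
        c_in = c_out
    return Sequential(layers)


@dataclass
class CancellerModel:
    """Trained five-layer CNN plus its normalization constants and history."""

    net: Sequential
    x_scale: float
    y_scale: float
    n_x: int
    config: TrainConfig
    history: dict = field(default_factory=dict)
    fingerprint: Optional[str] = None
    coil_reduction: str = "mean"

    def reduce_coils(self, out: np.ndarray) -> np.ndarray:
        if self.coil_reduction == "mean":
            return out.mean(axis=2)
        if self.coil_reduction == "center":
            return out[:, :, out.shape[2] // 2]
        raise ValueError(f"unknown coil reduction {self.coil_reduction!r}")


def _forward_reduce(model: CancellerModel, x: np.ndarray,
                    train: bool = False) -> np.ndarray:
    """Network forward pass plus coil-axis reduction: (B,n_x,10,2)->(B,n_x,2)."""
    return model.reduce_coils(model.net.forward(x, train=train))


def _eval_loss(model: CancellerModel, x: np.ndarray, y: np.ndarray,
               chunk: int = 32) -> float:
    tot, n = 0.0, 0
    for i in range(0, len(x), chunk):
        pred = _forward_reduce(model, x[i:i + chunk], train=False)
        d = pred.astype(np.float64) - y[i:i + chunk]
        tot += float(np.sum(d * d))
        n += d.size
    return tot / max(n, 1)


def train_cnn(train_set: TrainingSet,
              config: TrainConfig = TrainConfig()) -> CancellerModel:
    """Train the five-layer CNN on a scan's characterization windows.

    Runs exactly ``config.epochs`` passes at the configured batch size with
    Adam; records the validation loss before training ("epoch 0") and the
    train/validation losses after every epoch; returns the final-epoch
    model.  Deterministic given the seed.
    """
    net = build_cnn(seed=config.seed)
    model = CancellerModel(net=net, x_scale=train_set.x_scale,
                           y_scale=train_set.y_scale, n_x=train_set.n_x,
                           config=config, fingerprint=train_set.fingerprint)
    opt = Adam(net, lr=config.lr, beta1=config.beta1, beta2=config.beta2)
    rng = np.random.default_rng(config.seed + 1)

    x_tr, y_tr = train_set.x[train_set.train_idx], train_set.y[train_set.train_idx]
    x_val, y_val = train_set.x[train_set.val_idx], train_set.y[train_set.val_idx]

    history = {"train_loss": [], "val_loss": [_eval_loss(model, x_val, y_val)]}
    n_tr = len(x_tr)
    for epoch in range(config.epochs):
        order = rng.permutation(n_tr)
        losses = []
        for i in range(0, n_tr, config.batch):
            sel = order[i:i + config.batch]
            pred_full = net.forward(x_tr[sel], train=True)
            pred = model.reduce_coils(pred_full)
            loss = mse_loss(pred, y_tr[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch + 1} (lr={config.lr}); "
                    "loss is non-finite")
            losses.append(loss)
            # gradient of the coil-axis mean broadcasts evenly across coils
            dy = mse_grad(pred, y_tr[sel]).astype(np.float32)
            d_full = np.repeat(dy[:, :, None, :] / pred_full.shape[2],
                               pred_full.shape[2], axis=2)
            net.backward(d_full)
            opt.step()
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(_eval_loss(model, x_val, y_val))
    model.history = history
    return model


def predict_emi(model: CancellerModel, sensing: np.ndarray,
                chunk: int = 32) -> np.ndarray:
    """Predict receive-coil EMI from a sensing stack.

    ``sensing``: complex (10, n_x) for one FE line or (B, 10, n_x) for a
    batch; returns complex (n_x,) or (B, n_x).
    """
    sens = np.asarray(sensing)
    single = sens.ndim == 2
    if single:
        sens = sens[None]
    if sens.shape[1] != N_COILS or sens.shape[2] != model.n_x:
        raise ValueError(f"expected sensing shape (B, {N_COILS}, {model.n_x}), "
                         f"got {sens.shape}")
    x = np.stack([sens.real, sens.imag], axis=-1).transpose(0, 2, 1, 3)
    x = np.ascontiguousarray(x / model.x_scale, dtype=np.float32)
    outs = []
    for i in range(0, len(x), chunk):
        outs.append(_forward_reduce(model, x[i:i + chunk], train=False))
    out = np.concatenate(outs, axis=0).astype(np.float64) * model.y_scale
    pred = out[..., 0] + 1j * out[..., 1]
    return pred[0] if single else pred


def cancel(record: AcquisitionRecord, model: CancellerModel,
           allow_foreign: bool = False) -> AcquisitionRecord:
    """Subtract the model's predicted EMI from every FE acquisition line.

    Cancellation happens per individual FE line, before any NEX averaging;
    sensing data and the shielded twin are untouched.  Refuses to run on a
    record the model was not trained on unless ``allow_foreign``.
    """
    if model is None:
        raise ValueError("no canceller model provided")
    fp = _fingerprint(record.char_rx, record.char_sens)
    if not allow_foreign and model.fingerprint is not None and fp != model.fingerprint:
        raise ValueError("model was trained on a different record's "
                         "characterization data (per-scan training contract)")
    pred = predict_emi(model, record.acq_sens)
    return record.with_acq_rx(record.acq_rx - pred)


# --- linear least-squares baseline ---------------------------------------

@dataclass
class LinearCanceller:
    """Complex FIR coefficients (10 coils x L taps) mapping lagged sensing
    samples to the receive-coil EMI."""

    coeffs: np.ndarray
    reg: float = 0.0
    residual_mse: float = 0.0  # per complex sample, on the fit data
    fingerprint: Optional[str] = None

    @property
    def n_taps(self) -> int:
        return self.coeffs.shape[1]


def _lagged_design(sens: np.ndarray, taps: int) -> np.ndarray:
    """(N, 10, n) windows -> (N, n, 10*taps) causal lag design (zero-padded
    at each window start)."""
    N, C, n = sens.shape
    cols = np.zeros((N, n, C, taps), dtype=complex)
    for lag in range(taps):
        cols[:, lag:, :, lag] = sens[:, :, :n - lag].transpose(0, 2, 1)
    return cols.reshape(N, n, C * taps)


def fit_linear(record: AcquisitionRecord, taps: int = 1,
               reg: float = 0.0, drop_edge: bool = True) -> LinearCanceller:
    """Regularized least squares from lagged sensing to receive samples over
    the characterization windows.

    With ``drop_edge`` the first ``taps - 1`` samples of each window are
    excluded from the fit (their lags would reach before the window).
    Rank-deficient designs with ``reg = 0`` raise.
    """
    if record.n_char_windows < 1:
        raise ValueError("no characterization windows available")
    A = _lagged_design(record.char_sens, taps)
    y = record.char_rx.astype(complex)
    lead = taps - 1 if drop_edge else 0
    A = A[:, lead:, :].reshape(-1, A.shape[-1])
    y = y[:, lead:].reshape(-1)
    p = A.shape[1]
    if reg == 0.0:
        w, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < p:
            raise np.linalg.LinAlgError(
                f"design matrix is rank-deficient (rank {rank} < {p}); "
                "set reg > 0")
    else:
        gram = A.conj().T @ A + reg * np.eye(p)
        w = np.linalg.solve(gram, A.conj().T @ y)
    resid = y - A @ w
    return LinearCanceller(coeffs=w.reshape(N_COILS, taps), reg=reg,
                           residual_mse=float(np.mean(np.abs(resid) ** 2)),
                           fingerprint=_fingerprint(record.char_rx, record.char_sens))


def predict_linear(lc: LinearCanceller, sens: np.ndarray) -> np.ndarray:
    """FIR prediction of receive-coil EMI: complex (..., 10, n) -> (..., n)."""
    sens = np.asarray(sens, dtype=complex)
    single = sens.ndim == 2
    if single:
        sens = sens[None]
    N, C, n = sens.shape
    L = lc.n_taps
    pred = np.zeros((N, n), dtype=complex)
    for lag in range(L):
        pred[:, lag:] += np.einsum("c,Ncn->Nn", lc.coeffs[:, lag],
                                   sens[:, :, :n - lag])
    return pred[0] if single else pred


def apply_linear(lc: LinearCanceller, record: AcquisitionRecord,
                 allow_foreign: bool = False) -> AcquisitionRecord:
    """Mirror of :func:`cancel` for the linear baseline."""
    fp = _fingerprint(record.char_rx, record.char_sens)
    if not allow_foreign and lc.fingerprint is not None and fp != lc.fingerprint:
        raise ValueError("linear canceller was fit on a different record")
    pred = predict_linear(lc, record.acq_sens)
    return record.with_acq_rx(record.acq_rx - pred)
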