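"""Training of the convolutional yield surrogate.

Distills the process-based simulator into a small CNN: mean-squared-error
loss, adaptive-moment (Adam) optimization, early stopping on validation
loss with a fixed patience, and restoration of the weights from the epoch
with the lowest validation loss.

Targets are standardized internally with training-split statistics so the
optimizer sees unit-scale residuals; predictions and all recorded losses
are reported back in raw g m⁻² units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import Adam, CNNRegressor, DivergenceError, calibrate_init


@dataclass(frozen=True)
class SurrogateSpec:
    """Geometry of the surrogate network.

    Two 3×3 stride-1 convolutions with padding 2 (1 → ``conv1_maps`` →
    ``conv2_maps`` feature maps, ReLU), flatten, one ReLU dense layer of
    ``hidden`` units, scalar linear output.
    """

    conv1_maps: int = 32
    conv2_maps: int = 64
    kernel: int = 3
    padding: int = 2
    hidden: int = 64
    input_shape: tuple[int, int] = (184, 5)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (loss is always MSE, optimizer always Adam)."""

    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 60
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch losses in raw target units and the best-validation epoch."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.val_loss)


def build_surrogate(spec: SurrogateSpec = SurrogateSpec(), seed: int = 0,
                    dtype: type = np.float32) -> CNNRegressor:
    """Instantiate the surrogate with seeded initial weights."""
    return CNNRegressor(
        input_shape=spec.input_shape,
        conv1_maps=spec.conv1_maps,
        conv2_maps=spec.conv2_maps,
        kernel=spec.kernel,
        padding=spec.padding,
        hidden=spec.hidden,
        seed=seed,
        dtype=dtype,
    )


def _batched_forward(model: CNNRegressor, x: np.ndarray,
                     batch: int = 256) -> np.ndarray:
    outs = [model.forward(x[i:i + batch]) for i in range(0, len(x), batch)]
    return np.concatenate(outs) if outs else np.empty(0)


def predict(model: CNNRegressor, x: np.ndarray, batch: int = 256) -> np.ndarray:
    """Raw-unit yield predictions, one scalar per input matrix."""
    x = np.asarray(x)
    if x.ndim == 2:
        x = x[None]
    if len(x) == 0:
        return np.empty(0)
    return _batched_forward(model, x, batch) * model.y_scale + model.y_center


def train(
    model: CNNRegressor,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainConfig = TrainConfig(),
) -> tuple[CNNRegressor, TrainHistory]:
    """Fit the surrogate by minibatch MSE descent with early stopping.

    Stops when validation loss has not strictly improved for
    ``config.patience`` consecutive epochs (ties count as
    non-improvements) or at ``config.max_epochs``; the returned model
    carries the weights of the epoch with minimum validation loss.
    """
    x_tr, y_tr = train_set
    x_val, y_val = val_set
    if len(x_tr) == 0 or len(x_val) == 0:
        raise ValueError("training and validation sets must be nonempty")

    y_center = float(np.mean(y_tr))
    y_scale = float(np.std(y_tr))
    if y_scale < 1e-12:
        y_scale = 1.0
    model.y_center, model.y_scale = y_center, y_scale
    yt = ((np.asarray(y_tr, float) - y_center) / y_scale)
    yv = ((np.asarray(y_val, float) - y_center) / y_scale)
    raw_units = y_scale ** 2  # scaled-space MSE -> raw-unit MSE

    # unit-variance rescaling of the initial weights on a sample batch
    # keeps early optimization well conditioned whatever the input scales
    calibrate_init(model, x_tr[: min(256, len(x_tr))])

    opt = Adam(model.params, lr=config.lr)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    best_val = np.inf
    best_params = model.copy_params()
    since_best = 0

    for epoch in range(config.max_epochs):
        perm = rng.permutation(len(x_tr))
        epoch_losses = []
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb = x_tr[idx]
            pred = model.forward(xb, cache=True)
            resid = pred - yt[idx]
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}")
            grads = model.backward((2.0 / len(idx)) * resid)
            opt.step(model.params, grads)
            epoch_losses.append(loss)
        model._cache = None

        val_pred = _batched_forward(model, x_val)
        val_loss = float(np.mean((val_pred - yv) ** 2))
        if not np.isfinite(val_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(float(np.mean(epoch_losses)) * raw_units)
        history.val_loss.append(val_loss * raw_units)

        if val_loss < best_val:
            best_val = val_loss
            history.best_epoch = epoch
            best_params = model.copy_params()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    model.set_params(best_params)
    return model, history


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination of predictions against actual yields."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


# --- persistence ----------------------------------------------------------

def save_model(model: CNNRegressor, path: str | Path,
               history: TrainHistory | None = None,
               extra: dict | None = None) -> None:
    """Weights as .npz with a JSON sidecar (geometry, scaling, history)."""
    path = Path(path)
    np.savez_compressed(path, **model.params)
    sidecar = {
        "input_shape": list(model.input_shape),
        "conv1_maps": model.conv1_maps,
        "conv2_maps": model.conv2_maps,
        "kernel": model.kernel,
        "padding": model.padding,
        "hidden": model.hidden,
        "seed": model.seed,
        "y_center": model.y_center,
        "y_scale": model.y_scale,
    }
    if history is not None:
        sidecar["history"] = {
            "train_loss": history.train_loss,
            "val_loss": history.val_loss,
            "best_epoch": history.best_epoch,
        }
    if extra:
        sidecar["extra"] = extra
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1),
                                         encoding="utf-8")


def load_model(path: str | Path) -> tuple[CNNRegressor, TrainHistory | None]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    model = CNNRegressor(
        input_shape=tuple(sidecar["input_shape"]),
        conv1_maps=sidecar["conv1_maps"],
        conv2_maps=sidecar["conv2_maps"],
        kernel=sidecar["kernel"],
        padding=sidecar["padding"],
        hidden=sidecar["hidden"],
        seed=sidecar["seed"],
    )
    with np.load(path) as z:
        model.set_params({k: z[k] for k in z.files})
    model.y_center = float(sidecar["y_center"])
    model.y_scale = float(sidecar["y_scale"])
    history = None
    if "history" in sidecar:
        h = sidecar["history"]
        history = TrainHistory(train_loss=h["train_loss"],
                               val_loss=h["val_loss"],
                               best_epoch=h["best_epoch"])
    return model, history
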