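"""Stacked-LSTM sequence reconstructor mapping raw reflectance to clean VI.

The network is a three-layer LSTM (eight hidden units per layer) followed by
a GELU nonlinearity and a per-timestep linear head. It is trained with Adam
under mean-squared error, with the learning rate decaying from ``lr_max`` to
``lr_min`` along a half-cosine. The implementation is self-contained numpy:
forward, backpropagation-through-time and the optimizer are written out
explicitly, which keeps training deterministic and dependency-light for a
model this small. Gradients are validated against finite differences in the
test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import ndtr

from .series import (
    SENTINEL,
    STEPS_PER_YEAR,
    VI_MAX,
    VI_MIN,
    ReflectanceSeries,
    SeriesError,
    VISeries,
)


class TrainingError(RuntimeError):
    pass


@dataclass
class ModelConfig:
    """Architecture of the reconstructor."""

    n_layers: int = 3
    hidden_size: int = 8
    input_features: int = 3  # red, nir, blue
    output_features: int = 1
    sequence_length: int = 2 * STEPS_PER_YEAR
    fill_value: float = 0.0  # fed at invalid reflectance steps
    use_validity_flag: bool = False  # optional 4th binary input channel
    # The two-year window is seasonally periodic, so the recurrent state is
    # warmed by feeding the sequence this many times before outputs are
    # read; without it the first weeks of the window suffer a cold-start
    # artefact (the state starts at zero with no history to draw on).
    warmup_passes: int = 1

    def __post_init__(self):
        if min(self.n_layers, self.hidden_size, self.input_features,
               self.output_features, self.sequence_length) <= 0:
            raise SeriesError("all ModelConfig sizes must be positive")
        if self.warmup_passes < 0:
            raise SeriesError("warmup_passes must be >= 0")
        if self.sequence_length % STEPS_PER_YEAR != 0:
            raise SeriesError("sequence_length must be a multiple of 46")

    @property
    def n_inputs(self) -> int:
        return self.input_features + (1 if self.use_validity_flag else 0)


@dataclass
class TrainConfig:
    """Optimisation settings."""

    lr_max: float = 1e-4
    lr_min: float = 1e-8
    max_epochs: int = 300
    batch_size: int = 1
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if not self.lr_min < self.lr_max:
            raise SeriesError("require lr_min < lr_max")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise SeriesError("split fractions must sum to 1")


def cosine_lr(t: int, total: int, lr_max: float, lr_min: float) -> float:
    """Half-cosine decay from lr_max (t=0) to lr_min (t=total)."""
    return lr_min + (lr_max - lr_min) * (1.0 + np.cos(np.pi * t / total)) / 2.0


def _gelu(x: np.ndarray) -> np.ndarray:
    return x * ndtr(x)


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    return ndtr(x) + x * pdf


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def init_params(mcfg: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Uniform(-1/sqrt(H), 1/sqrt(H)) weights; forget-gate bias +1; head bias
    at the midpoint of the valid VI range so optimisation starts centred."""
    H = mcfg.hidden_size
    bound = 1.0 / np.sqrt(H)
    p: dict[str, np.ndarray] = {}
    f_in = mcfg.n_inputs
    for layer in range(mcfg.n_layers):
        p[f"W{layer}"] = rng.uniform(-bound, bound, size=(f_in, 4 * H))
        p[f"U{layer}"] = rng.uniform(-bound, bound, size=(H, 4 * H))
        b = rng.uniform(-bound, bound, size=4 * H)
        b[H : 2 * H] += 1.0  # forget gate bias
        p[f"b{layer}"] = b
        f_in = H
    p["Wo"] = rng.uniform(-bound, bound, size=(H, mcfg.output_features))
    p["bo"] = np.full(mcfg.output_features, (VI_MIN + VI_MAX) / 2.0)
    return p


# The sequential recurrence dominates run time for a model this small, so
# the two per-layer loops are written in nopython-compatible numpy and JIT
# compiled when numba is available; the same code runs un-jitted otherwise.
try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _jit(f):
        return _njit(cache=True, fastmath=False)(f)
except ImportError:  # pragma: no cover
    def _jit(f):
        return f


# gate layout along the 4H axis: input, forget, cell, output
@_jit
def _layer_forward_core(x, W, U, b):
    """One LSTM layer over a full sequence. x: (B,T,Fin) -> (h, gates, c)."""
    B, T, Fin = x.shape
    H = U.shape[0]
    xw = (x.copy().reshape(B * T, Fin) @ W).reshape(B, T, 4 * H)
    h = np.zeros((B, T, H))
    c = np.zeros((B, T, H))
    gates = np.zeros((B, T, 4 * H))
    h_prev = np.zeros((B, H))
    c_prev = np.zeros((B, H))
    for t in range(T):
        a = xw[:, t] + h_prev @ U + b
        i = 1.0 / (1.0 + np.exp(-a[:, :H]))
        f = 1.0 / (1.0 + np.exp(-a[:, H : 2 * H]))
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = 1.0 / (1.0 + np.exp(-a[:, 3 * H :]))
        c_t = f * c_prev + i * g
        h_t = o * np.tanh(c_t)
        gates[:, t, :H] = i
        gates[:, t, H : 2 * H] = f
        gates[:, t, 2 * H : 3 * H] = g
        gates[:, t, 3 * H :] = o
        c[:, t] = c_t
        h[:, t] = h_t
        h_prev, c_prev = h_t, c_t
    return h, gates, c


@_jit
def _layer_backward_core(dh_out, x, gates, c, W, U):
    """BPTT for one layer. dh_out: (B,T,H) gradient w.r.t. layer output."""
    B, T, H = dh_out.shape
    Fin = x.shape[2]
    da = np.zeros((B, T, 4 * H))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    Ut = U.T.copy()
    for t in range(T - 1, -1, -1):
        i = gates[:, t, :H]
        f = gates[:, t, H : 2 * H]
        g = gates[:, t, 2 * H : 3 * H]
        o = gates[:, t, 3 * H :]
        c_t = c[:, t]
        c_prev = c[:, t - 1] if t > 0 else np.zeros((B, H))
        tc = np.tanh(c_t)
        dh = dh_out[:, t] + dh_next
        dc = dc_next + dh * o * (1.0 - tc * tc)
        da[:, t, :H] = dc * g * i * (1.0 - i)
        da[:, t, H : 2 * H] = dc * c_prev * f * (1.0 - f)
        da[:, t, 2 * H : 3 * H] = dc * i * (1.0 - g * g)
        da[:, t, 3 * H :] = dh * tc * o * (1.0 - o)
        dh_next = da[:, t].copy() @ Ut
        dc_next = dc * f
    flat_da = da.reshape(B * T, 4 * H)
    dW = x.copy().reshape(B * T, Fin).T @ flat_da
    h_prev = np.zeros((B, T, H))
    h_prev[:, 1:] = gates[:, : T - 1, 3 * H :] * np.tanh(c[:, : T - 1])
    dU = h_prev.reshape(B * T, H).T @ flat_da
    db = flat_da.sum(axis=0)
    dx = (flat_da @ W.T).reshape(B, T, Fin)
    return dx, dW, dU, db


def _layer_forward(x, W, U, b):
    h, gates, c = _layer_forward_core(
        np.ascontiguousarray(x), W, U, b)
    return h, (x, gates, c)


def _layer_backward(dh_out, cache, W, U):
    x, gates, c = cache
    return _layer_backward_core(
        np.ascontiguousarray(dh_out), np.ascontiguousarray(x), gates, c, W, U)


def forward(params: dict, x: np.ndarray, mcfg: ModelConfig,
            with_cache: bool = False):
    """Full network forward. x: (B,T,F) -> y: (B,T)."""
    h = x
    caches = []
    for layer in range(mcfg.n_layers):
        h, cache = _layer_forward(h, params[f"W{layer}"], params[f"U{layer}"],
                                  params[f"b{layer}"])
        caches.append(cache)
    z = _gelu(h)
    y = z @ params["Wo"] + params["bo"]
    y = y[..., 0]
    if with_cache:
        return y, (caches, h, z)
    return y


def backward(params: dict, x: np.ndarray, dy: np.ndarray, cache,
             mcfg: ModelConfig) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss with upstream dL/dy (B,T)."""
    caches, h, z = cache
    B, T = dy.shape
    H = mcfg.hidden_size
    dz = dy[..., None] * params["Wo"][None, None, :, 0]
    grads = {
        "Wo": z.reshape(B * T, H).T @ dy.reshape(B * T, 1),
        "bo": np.array([dy.sum()]),
    }
    dh = dz * _gelu_grad(h)
    for layer in range(mcfg.n_layers - 1, -1, -1):
        dh, dW, dU, db = _layer_backward(
            dh, caches[layer], params[f"W{layer}"], params[f"U{layer}"]
        )
        grads[f"W{layer}"] = dW
        grads[f"U{layer}"] = dU
        grads[f"b{layer}"] = db
    return grads


class _Adam:
    def __init__(self, params: dict, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedModel:
    """Weights plus the configuration and loss history that produced them."""

    params: dict[str, np.ndarray]
    model_config: ModelConfig
    train_config: TrainConfig
    history: list[dict] = field(default_factory=list)
    index_kind: str = "NDVI"
    best_epoch: int = -1


def features_from_reflectance(r: ReflectanceSeries, mcfg: ModelConfig) -> np.ndarray:
    """(T, n_inputs) feature matrix; invalid steps carry ``fill_value``."""
    blue = r.blue if r.blue is not None else np.zeros(len(r))
    x = np.stack([r.red, r.nir, blue], axis=1).astype(np.float64)
    ok = r.valid & np.all(np.isfinite(x), axis=1)
    x[~ok] = mcfg.fill_value
    if mcfg.use_validity_flag:
        x = np.concatenate([x, ok[:, None].astype(np.float64)], axis=1)
    return x


def split_samples(records: list, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Random pixel-level partition into (train, val, test), seeded."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise SeriesError("split fractions must sum to 1")
    n = len(records)
    if n < 10:
        raise SeriesError("need at least 10 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_val = min(n_val, n - n_train)
    train = [records[i] for i in order[:n_train]]
    val = [records[i] for i in order[n_train : n_train + n_val]]
    test = [records[i] for i in order[n_train + n_val :]]
    return train, val, test


def _stack_dataset(records: list, mcfg: ModelConfig):
    xs, ys = [], []
    for rec in records:
        x = features_from_reflectance(rec.reflectance, mcfg)
        if x.shape[0] != mcfg.sequence_length:
            raise SeriesError(
                f"sequence length {x.shape[0]} != configured {mcfg.sequence_length}"
            )
        y = rec.target_vi.values
        if np.any(y == SENTINEL):
            raise SeriesError("training targets must be gap-free")
        xs.append(x)
        ys.append(y)
    return np.stack(xs), np.stack(ys)


def _tile_warmup(x: np.ndarray, passes: int) -> np.ndarray:
    return np.concatenate([x] * (passes + 1), axis=1) if passes else x


def _predict_array(params: dict, x: np.ndarray, mcfg: ModelConfig) -> np.ndarray:
    off = mcfg.warmup_passes * x.shape[1]
    return forward(params, _tile_warmup(x, mcfg.warmup_passes), mcfg)[:, off:]


def fit(train_records: list, val_records: list, mcfg: ModelConfig | None = None,
        tcfg: TrainConfig | None = None, index_kind: str = "NDVI") -> TrainedModel:
    """Train the reconstructor by MSE; returns the checkpoint with the lowest
    validation loss (last epoch, with a warning, when no validation set)."""
    mcfg = mcfg or ModelConfig()
    tcfg = tcfg or TrainConfig()
    x_train, y_train = _stack_dataset(train_records, mcfg)
    have_val = len(val_records) > 0
    if have_val:
        x_val, y_val = _stack_dataset(val_records, mcfg)
    else:
        warnings.warn("empty validation set: returning the final epoch")
    rng = np.random.default_rng(tcfg.seed)
    params = init_params(mcfg, rng)
    opt = _Adam(params)
    n = x_train.shape[0]
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_epoch = -1
    history: list[dict] = []
    for epoch in range(tcfg.max_epochs):
        lr = cosine_lr(epoch, tcfg.max_epochs, tcfg.lr_max, tcfg.lr_min)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            x_in = _tile_warmup(xb, mcfg.warmup_passes)
            off = mcfg.warmup_passes * xb.shape[1]
            pred_full, cache = forward(params, x_in, mcfg, with_cache=True)
            err = pred_full[:, off:] - yb
            loss = float(np.mean(err * err))
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            dy = np.zeros_like(pred_full)
            dy[:, off:] = 2.0 * err / err.size
            grads = backward(params, x_in, dy, cache, mcfg)
            opt.step(params, grads, lr)
            epoch_loss += loss * len(idx)
        epoch_loss /= n
        if have_val:
            val_pred = _predict_array(params, x_val, mcfg)
            val_loss = float(np.mean((val_pred - y_val) ** 2))
        else:
            val_loss = float("nan")
        history.append({"epoch": epoch, "lr": lr,
                        "train_loss": epoch_loss, "val_loss": val_loss})
        if have_val and val_loss < best_val:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            best_epoch = epoch
    if not have_val:
        best_params, best_epoch = params, tcfg.max_epochs - 1
    return TrainedModel(params=best_params, model_config=mcfg, train_config=tcfg,
                        history=history, index_kind=index_kind,
                        best_epoch=best_epoch)


def predict(model: TrainedModel, r: ReflectanceSeries) -> VISeries:
    """Gap-free VI series for one reflectance series; deterministic."""
    mcfg = model.model_config
    x = features_from_reflectance(r, mcfg)
    if x.shape[1] != model.params["W0"].shape[0]:
        raise SeriesError("feature count mismatch with the trained model")
    y = _predict_array(model.params, x[None], mcfg)[0]
    # keep strictly above the sentinel so output is never read as missing
    y = np.clip(y, VI_MIN + 1e-9, VI_MAX)
    return VISeries(values=y, index_kind=model.index_kind)


def predict_batch(model: TrainedModel, series: list[ReflectanceSeries]) -> np.ndarray:
    mcfg = model.model_config
    x = np.stack([features_from_reflectance(r, mcfg) for r in series])
    y = _predict_array(model.params, x, mcfg)
    return np.clip(y, VI_MIN + 1e-9, VI_MAX)


def save_model(model: TrainedModel, path) -> None:
    """Single-file checkpoint: weights + config snapshot + loss history."""
    meta = json.dumps({
        "model_config": asdict(model.model_config),
        "train_config": asdict(model.train_config),
        "history": model.history,
        "index_kind": model.index_kind,
        "best_epoch": model.best_epoch,
    })
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.params)


def load_model(path) -> TrainedModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["_meta"]).decode())
        params = {k: z[k] for k in z.files if k != "_meta"}
    mc = meta["model_config"]
    mc["sequence_length"] = int(mc["sequence_length"])
    tc = meta["train_config"]
    tc["split_fractions"] = tuple(tc["split_fractions"])
    return TrainedModel(params=params, model_config=ModelConfig(**mc),
                        train_config=TrainConfig(**tc), history=meta["history"],
                        index_kind=meta["index_kind"],
                        best_epoch=meta["best_epoch"])
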