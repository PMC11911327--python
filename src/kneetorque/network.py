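"""CNN-GRU-Attention torque regressor, implemented directly in NumPy.

The model maps a sliding window of multichannel features (7 EMG envelopes +
knee angle, optionally + 7 normalized muscle forces for the hybrid variant)
to the knee torque at the window's final sample (Nm/kg):

* convolution blocks: 2D convolutions with fixed 3x3 kernels and ReLU,
  each followed by 2x2 max pooling (window = time x channels, treated as a
  single-channel image at the input);
* the pooled feature maps are read out as a time-major sequence and fed to
  a GRU: ``r = sigma(Wr [h, x])``, ``z = sigma(Wz [h, x])``,
  ``h~ = tanh(Wh [r*h, x])``, ``h' = (1 - z)*h + z*h~`` (elementwise ``*``);
* additive attention pools the hidden-state sequence:
  ``e_t = v . tanh(W h_t + b)``, ``alpha = softmax(e)``,
  ``context = sum_t alpha_t h_t``;
* dense layers map the context vector to a scalar torque.

Forward and backward passes are written out by hand (no autodiff framework)
and the backward pass is verified against finite differences in the test
suite.  Training uses mini-batch Adam on the MSE loss with early stopping on
a validation set; everything is driven by explicit seeds, so runs are fully
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

DTYPE = np.float64


class TrainingError(RuntimeError):
    """Raised when training diverges (non-finite loss)."""


class ShapeError(ValueError):
    """Raised on input/weight shape mismatches."""


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    The kernel (3x3) and pooling window (2x2) are fixed; everything else is
    tunable.  ``input_channels`` is 8 for the standard variant (7 envelopes +
    angle) and 15 for the hybrid variant (+ 7 normalized muscle forces).
    """

    input_channels: int
    window_len: int = 15
    conv_filters: tuple[int, ...] = (16, 32)
    gru_units: int = 64
    attention_dim: int = 64
    dense_units: tuple[int, ...] = (64,)
    seed: int = 0

    def __post_init__(self) -> None:
        self.conv_filters = tuple(int(f) for f in self.conv_filters)
        self.dense_units = tuple(int(u) for u in self.dense_units)
        n_pools = len(self.conv_filters)
        if self.window_len < 2**n_pools or self.input_channels < 2**n_pools:
            raise ShapeError(
                f"window_len ({self.window_len}) and input_channels "
                f"({self.input_channels}) must each be >= {2 ** n_pools} for "
                f"{n_pools} 2x2 pooling stages"
            )

    def feature_shape(self) -> tuple[int, int, int]:
        """(time, width, channels) after the conv blocks."""
        h, w = self.window_len, self.input_channels
        c = 1
        for f in self.conv_filters:
            h, w, c = h // 2, w // 2, f
        return h, w, c


@dataclass
class TrainConfig:
    batch_size: int = 512
    lr: float = 1e-3
    max_epochs: int = 1000
    patience: int = 20
    min_delta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


class WeightSet:
    """Named parameter tensors of the network plus config and metadata."""

    def __init__(self, tensors: dict[str, np.ndarray], config: NetworkConfig, meta: dict | None = None):
        self.tensors = {k: np.asarray(v, dtype=DTYPE) for k, v in tensors.items()}
        self.config = config
        self.meta = dict(meta or {})

    def copy(self) -> "WeightSet":
        return WeightSet({k: v.copy() for k, v in self.tensors.items()}, self.config, dict(self.meta))

    def __getitem__(self, key: str) -> np.ndarray:
        return self.tensors[key]

    def keys(self):
        return self.tensors.keys()

    #: tensor names of the final (output) dense layer
    FINAL_DENSE_KEYS = ("out_W", "out_b")

    def save(self, path) -> None:
        payload = dict(self.tensors)
        payload["__config__"] = np.frombuffer(
            json.dumps({"config": asdict(self.config), "meta": self.meta}).encode(), dtype=np.uint8
        )
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "WeightSet":
        with np.load(path) as npz:
            blob = json.loads(bytes(npz["__config__"].tobytes()).decode())
            tensors = {k: npz[k] for k in npz.files if k != "__config__"}
        cfg = blob["config"]
        cfg["conv_filters"] = tuple(cfg["conv_filters"])
        cfg["dense_units"] = tuple(cfg["dense_units"])
        return cls(tensors, NetworkConfig(**cfg), blob.get("meta", {}))


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def init_weights(config: NetworkConfig, seed: int | None = None, meta: dict | None = None) -> WeightSet:
    """Variance-scaled uniform initialization; biases start at zero."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t: dict[str, np.ndarray] = {}
    c_in = 1
    for i, c_out in enumerate(config.conv_filters):
        t[f"conv{i}_W"] = _uniform_init(rng, (3, 3, c_in, c_out), 9 * c_in, 9 * c_out)
        t[f"conv{i}_b"] = np.zeros(c_out, dtype=DTYPE)
        c_in = c_out
    _, w, c = config.feature_shape()
    feat = w * c
    u = config.gru_units
    for gate in ("r", "z", "h"):
        t[f"gru_W{gate}"] = _uniform_init(rng, (u + feat, u), u + feat, u)
        t[f"gru_b{gate}"] = np.zeros(u, dtype=DTYPE)
    a = config.attention_dim
    t["att_W"] = _uniform_init(rng, (u, a), u, a)
    t["att_b"] = np.zeros(a, dtype=DTYPE)
    t["att_v"] = _uniform_init(rng, (a,), a, 1)
    d_in = u
    for i, d_out in enumerate(config.dense_units):
        t[f"dense{i}_W"] = _uniform_init(rng, (d_in, d_out), d_in, d_out)
        t[f"dense{i}_b"] = np.zeros(d_out, dtype=DTYPE)
        d_in = d_out
    t["out_W"] = _uniform_init(rng, (d_in, 1), d_in, 1)
    t["out_b"] = np.zeros(1, dtype=DTYPE)
    return WeightSet(t, config, meta)


# ---------------------------------------------------------------------------
# Elementary layers (public, oracle-checkable)
# ---------------------------------------------------------------------------

def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(np.asarray(x, dtype=DTYPE), 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def conv2d_forward(
    X: np.ndarray, kernel: np.ndarray, bias: float = 0.0, padding: str = "valid"
) -> np.ndarray:
    """Single-channel 3x3 convolution + ReLU on a 2D array.

    ``f[i, j] = ReLU(sum_{m,n} kernel[m, n] * Xp[i + m, j + n] + bias)``
    where Xp is X zero-padded by one on each side for ``padding='same'``.
    """
    X = np.asarray(X, dtype=DTYPE)
    kernel = np.asarray(kernel, dtype=DTYPE)
    if kernel.shape != (3, 3):
        raise ShapeError(f"kernel must be 3x3, got {kernel.shape}")
    if padding == "same":
        Xp = np.pad(X, 1)
    elif padding == "valid":
        Xp = X
    else:
        raise ValueError(f"unknown padding {padding!r}")
    H, W = Xp.shape[0] - 2, Xp.shape[1] - 2
    if H < 1 or W < 1:
        raise ShapeError(f"input {X.shape} too small for 3x3 convolution")
    out = np.full((H, W), float(bias), dtype=DTYPE)
    for m in range(3):
        for n in range(3):
            out += kernel[m, n] * Xp[m : m + H, n : n + W]
    return np.maximum(out, 0.0)


def maxpool2d(X: np.ndarray) -> np.ndarray:
    """Non-overlapping 2x2 max pooling; a trailing odd row/column is dropped."""
    X = np.asarray(X, dtype=DTYPE)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ShapeError(f"both dims must be >= 2 for 2x2 pooling, got {X.shape}")
    H2, W2 = X.shape[0] // 2, X.shape[1] // 2
    return X[: 2 * H2, : 2 * W2].reshape(H2, 2, W2, 2).max(axis=(1, 3))


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, weights: dict[str, np.ndarray]) -> np.ndarray:
    """One GRU forward step (batched or single vector).

    ``weights`` holds ``gru_Wr/Wz/Wh`` of shape (units + features, units)
    and biases ``gru_br/bz/bh``; the gate input is the concatenation
    ``[h_prev, x_t]``.
    """
    single = np.asarray(x_t).ndim == 1
    x_t = np.atleast_2d(np.asarray(x_t, dtype=DTYPE))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=DTYPE))
    u = h_prev.shape[1]
    if weights["gru_Wr"].shape[0] != u + x_t.shape[1]:
        raise ShapeError(
            f"gate matrix expects {weights['gru_Wr'].shape[0]} inputs, got "
            f"{u + x_t.shape[1]}"
        )
    hx = np.concatenate([h_prev, x_t], axis=1)
    r = _sigmoid(hx @ weights["gru_Wr"] + weights["gru_br"])
    z = _sigmoid(hx @ weights["gru_Wz"] + weights["gru_bz"])
    rhx = np.concatenate([r * h_prev, x_t], axis=1)
    h_cand = np.tanh(rhx @ weights["gru_Wh"] + weights["gru_bh"])
    h_new = (1.0 - z) * h_prev + z * h_cand
    return h_new.squeeze(0) if single else h_new


def gru_forward(
    sequence: np.ndarray, weights: dict[str, np.ndarray], h0: np.ndarray | None = None
) -> np.ndarray:
    """Iterate :func:`gru_step` over a (time x features) sequence.

    Returns all hidden states (time x units); attention needs the full
    sequence.  A (batch x time x features) input returns
    (batch x time x units).
    """
    seq = np.asarray(sequence, dtype=DTYPE)
    single = seq.ndim == 2
    if single:
        seq = seq[None]
    if seq.shape[1] < 1:
        raise ShapeError("sequence must have at least one timestep")
    b, t_len, _ = seq.shape
    u = weights["gru_Wr"].shape[1]
    h = np.zeros((b, u), dtype=DTYPE) if h0 is None else np.broadcast_to(
        np.asarray(h0, dtype=DTYPE), (b, u)
    ).copy()
    states = np.empty((b, t_len, u), dtype=DTYPE)
    for t in range(t_len):
        h = np.atleast_2d(gru_step(seq[:, t, :], h, weights))
        states[:, t, :] = h
    return states[0] if single else states


def attention_pool(
    H: np.ndarray, weights: dict[str, np.ndarray], return_alpha: bool = False
):
    """Additive attention over a hidden-state sequence.

    ``e_t = v . tanh(W h_t + b)``, ``alpha = softmax(e)``,
    ``context = sum_t alpha_t h_t``.  Accepts (time x units) or
    (batch x time x units).
    """
    H = np.asarray(H, dtype=DTYPE)
    single = H.ndim == 2
    if single:
        H = H[None]
    s = np.tanh(H @ weights["att_W"] + weights["att_b"])
    e = s @ weights["att_v"]
    e = e - e.max(axis=1, keepdims=True)
    alpha = np.exp(e)
    alpha /= alpha.sum(axis=1, keepdims=True)
    context = np.einsum("bt,btu->bu", alpha, H)
    if single:
        context, alpha = context[0], alpha[0]
    return (context, alpha) if return_alpha else context


# ---------------------------------------------------------------------------
# Batched internal layers with caches for backprop
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, H: int, W: int) -> np.ndarray:
    # xp: (B, H+2, W+2, C) zero-padded input -> (B, H, W, 9*C)
    B, _, _, C = xp.shape
    cols = np.empty((B, H, W, 9, C), dtype=DTYPE)
    k = 0
    for m in range(3):
        for n in range(3):
            cols[:, :, :, k, :] = xp[:, m : m + H, n : n + W, :]
            k += 1
    return cols.reshape(B, H, W, 9 * C)


def _conv_block_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    # x: (B, H, W, Cin); W: (3, 3, Cin, Cout). Same padding, ReLU, 2x2 pool.
    B, H, Wd, Cin = x.shape
    Cout = W.shape[3]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = _im2col(xp, H, Wd)  # (B,H,W,9*Cin)
    Wmat = W.reshape(9 * Cin, Cout)
    pre = cols @ Wmat + b
    act = np.maximum(pre, 0.0)
    # pooling (drop trailing odd row/col)
    H2, W2 = H // 2, Wd // 2
    win = act[:, : 2 * H2, : 2 * W2, :].reshape(B, H2, 2, W2, 2, Cout)
    win = win.transpose(0, 1, 3, 2, 4, 5).reshape(B, H2, W2, 4, Cout)
    idx = win.argmax(axis=3)
    pooled = np.take_along_axis(win, idx[:, :, :, None, :], axis=3).squeeze(3)
    cache = (cols, pre > 0, idx, (B, H, Wd, Cin, Cout), Wmat)
    return pooled, cache


def _conv_block_backward(dpooled: np.ndarray, cache):
    cols, relu_mask, idx, (B, H, Wd, Cin, Cout), Wmat = cache
    H2, W2 = H // 2, Wd // 2
    dwin = np.zeros((B, H2, W2, 4, Cout), dtype=DTYPE)
    np.put_along_axis(dwin, idx[:, :, :, None, :], dpooled[:, :, :, None, :], axis=3)
    dact = np.zeros((B, H, Wd, Cout), dtype=DTYPE)
    dact_view = dwin.reshape(B, H2, W2, 2, 2, Cout).transpose(0, 1, 3, 2, 4, 5)
    dact[:, : 2 * H2, : 2 * W2, :] = dact_view.reshape(B, 2 * H2, 2 * W2, Cout)
    dpre = dact * relu_mask
    dpre_flat = dpre.reshape(-1, Cout)
    cols_flat = cols.reshape(-1, 9 * Cin)
    dW = (cols_flat.T @ dpre_flat).reshape(3, 3, Cin, Cout)
    db = dpre_flat.sum(axis=0)
    dcols = (dpre_flat @ Wmat.T).reshape(B, H, Wd, 9, Cin)
    dxp = np.zeros((B, H + 2, Wd + 2, Cin), dtype=DTYPE)
    k = 0
    for m in range(3):
        for n in range(3):
            dxp[:, m : m + H, n : n + Wd, :] += dcols[:, :, :, k, :]
            k += 1
    dx = dxp[:, 1 : 1 + H, 1 : 1 + Wd, :]
    return dx, dW, db


def model_forward(
    X: np.ndarray, weights: WeightSet, config: NetworkConfig | None = None, with_cache: bool = False
):
    """Full forward pass: conv blocks -> GRU -> attention -> dense -> scalar.

    ``X`` is (batch x window_len x channels); returns (batch,) predictions.
    """
    config = config or weights.config
    X = np.asarray(X, dtype=DTYPE)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1] != config.window_len or X.shape[2] != config.input_channels:
        raise ShapeError(
            f"input windows {X.shape[1:]} do not match config "
            f"({config.window_len}, {config.input_channels})"
        )
    B = X.shape[0]
    t = weights.tensors
    x = X[..., None]
    conv_caches = []
    for i in range(len(config.conv_filters)):
        x, cache = _conv_block_forward(x, t[f"conv{i}_W"], t[f"conv{i}_b"])
        conv_caches.append(cache)
    Bh, Ht, Wt, Ct = x.shape
    seq = x.reshape(Bh, Ht, Wt * Ct)

    # GRU with caches
    u = config.gru_units
    h = np.zeros((B, u), dtype=DTYPE)
    gru_caches = []
    states = np.empty((B, Ht, u), dtype=DTYPE)
    for step in range(Ht):
        x_t = seq[:, step, :]
        hx = np.concatenate([h, x_t], axis=1)
        r = _sigmoid(hx @ t["gru_Wr"] + t["gru_br"])
        z = _sigmoid(hx @ t["gru_Wz"] + t["gru_bz"])
        rhx = np.concatenate([r * h, x_t], axis=1)
        h_cand = np.tanh(rhx @ t["gru_Wh"] + t["gru_bh"])
        h_new = (1.0 - z) * h + z * h_cand
        gru_caches.append((hx, r, z, rhx, h_cand, h))
        h = h_new
        states[:, step, :] = h

    # attention
    s = np.tanh(states @ t["att_W"] + t["att_b"])
    e = s @ t["att_v"]
    e_shift = e - e.max(axis=1, keepdims=True)
    alpha = np.exp(e_shift)
    alpha /= alpha.sum(axis=1, keepdims=True)
    context = np.einsum("bt,btu->bu", alpha, states)

    # dense head
    dense_caches = []
    hvec = context
    for i in range(len(config.dense_units)):
        pre = hvec @ t[f"dense{i}_W"] + t[f"dense{i}_b"]
        act = np.maximum(pre, 0.0)
        dense_caches.append((hvec, pre > 0))
        hvec = act
    pred = (hvec @ t["out_W"] + t["out_b"])[:, 0]

    if not with_cache:
        return pred
    cache = {
        "conv": conv_caches,
        "feature_shape": (Bh, Ht, Wt, Ct),
        "seq": seq,
        "gru": gru_caches,
        "states": states,
        "att": (s, alpha),
        "dense": dense_caches,
        "head_in": hvec,
        "pred": pred,
    }
    return pred, cache


def model_backward(
    dpred: np.ndarray, weights: WeightSet, cache: dict, config: NetworkConfig | None = None
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. every tensor, given d(loss)/d(pred)."""
    config = config or weights.config
    t = weights.tensors
    grads: dict[str, np.ndarray] = {}
    B = dpred.shape[0]

    # dense head
    dpred = dpred[:, None]
    head_in = cache["head_in"]
    grads["out_W"] = head_in.T @ dpred
    grads["out_b"] = dpred.sum(axis=0)
    dh = dpred @ t["out_W"].T
    for i in reversed(range(len(config.dense_units))):
        hin, mask = cache["dense"][i]
        dpre = dh * mask
        grads[f"dense{i}_W"] = hin.T @ dpre
        grads[f"dense{i}_b"] = dpre.sum(axis=0)
        dh = dpre @ t[f"dense{i}_W"].T
    dcontext = dh

    # attention
    states = cache["states"]
    s, alpha = cache["att"]
    dalpha = np.einsum("bu,btu->bt", dcontext, states)
    dstates = alpha[:, :, None] * dcontext[:, None, :]
    de = alpha * (dalpha - np.sum(alpha * dalpha, axis=1, keepdims=True))
    ds = de[:, :, None] * t["att_v"]
    dpre_att = ds * (1.0 - s**2)
    grads["att_v"] = np.einsum("bta,bt->a", s, de)
    grads["att_W"] = np.einsum("btu,bta->ua", states, dpre_att)
    grads["att_b"] = dpre_att.sum(axis=(0, 1))
    dstates = dstates + dpre_att @ t["att_W"].T

    # GRU BPTT
    u = config.gru_units
    Bh, Ht, Wt, Ct = cache["feature_shape"]
    feat = Wt * Ct
    for name in ("gru_Wr", "gru_Wz", "gru_Wh"):
        grads[name] = np.zeros_like(t[name])
    for name in ("gru_br", "gru_bz", "gru_bh"):
        grads[name] = np.zeros_like(t[name])
    dseq = np.empty((B, Ht, feat), dtype=DTYPE)
    dh_next = np.zeros((B, u), dtype=DTYPE)
    for step in reversed(range(Ht)):
        dh_total = dstates[:, step, :] + dh_next
        hx, r, z, rhx, h_cand, h_prev = cache["gru"][step]
        dz = dh_total * (h_cand - h_prev)
        dh_cand = dh_total * z
        dh_prev = dh_total * (1.0 - z)
        dpre_h = dh_cand * (1.0 - h_cand**2)
        grads["gru_Wh"] += rhx.T @ dpre_h
        grads["gru_bh"] += dpre_h.sum(axis=0)
        drhx = dpre_h @ t["gru_Wh"].T
        dr = drhx[:, :u] * h_prev
        dh_prev = dh_prev + drhx[:, :u] * r
        dx = drhx[:, u:]
        dpre_r = dr * r * (1.0 - r)
        dpre_z = dz * z * (1.0 - z)
        grads["gru_Wr"] += hx.T @ dpre_r
        grads["gru_br"] += dpre_r.sum(axis=0)
        grads["gru_Wz"] += hx.T @ dpre_z
        grads["gru_bz"] += dpre_z.sum(axis=0)
        dhx = dpre_r @ t["gru_Wr"].T + dpre_z @ t["gru_Wz"].T
        dh_prev = dh_prev + dhx[:, :u]
        dx = dx + dhx[:, u:]
        dseq[:, step, :] = dx
        dh_next = dh_prev

    # conv blocks
    dx4 = dseq.reshape(Bh, Ht, Wt, Ct)
    for i in reversed(range(len(config.conv_filters))):
        dx4, dW, db = _conv_block_backward(dx4, cache["conv"][i])
        grads[f"conv{i}_W"] = dW
        grads[f"conv{i}_b"] = db
    return grads


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, keys, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0

    def step(self, tensors: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            tensors[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _mse_and_grad(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - y
    return float(np.mean(diff**2)), (2.0 / y.shape[0]) * diff


def evaluate_mse(X: np.ndarray, y: np.ndarray, weights: WeightSet, batch: int = 2048) -> float:
    total, n = 0.0, 0
    for i in range(0, X.shape[0], batch):
        pred = model_forward(X[i : i + batch], weights)
        total += float(np.sum((pred - y[i : i + batch]) ** 2))
        n += min(batch, X.shape[0] - i)
    return total / n


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    config: NetworkConfig,
    train_config: TrainConfig,
    X_val: np.ndarray,
    y_val: np.ndarray,
    initial_weights: WeightSet | None = None,
    meta: dict | None = None,
) -> tuple[WeightSet, dict[str, list[float]]]:
    """Mini-batch Adam on the MSE loss with validation early stopping.

    Returns the best-validation weights and a history dict with per-epoch
    ``train_mse`` and ``val_mse``.  The batch size is reduced to the dataset
    size when the dataset is smaller than the configured batch.  Fully
    deterministic given the seeds in the configs.
    """
    X = np.asarray(X, dtype=DTYPE)
    y = np.asarray(y, dtype=DTYPE)
    if X.shape[0] == 0:
        raise ValueError("training set is empty")
    weights = (initial_weights.copy() if initial_weights is not None
               else init_weights(config, meta=meta))
    if meta:
        weights.meta.update(meta)
    rng = np.random.default_rng(train_config.seed)
    batch = min(train_config.batch_size, X.shape[0])
    opt = _Adam(weights.tensors.keys(), train_config.lr)
    history: dict[str, list[float]] = {"train_mse": [], "val_mse": []}
    best_val = np.inf
    best = weights.copy()
    stale = 0
    for epoch in range(train_config.max_epochs):
        order = rng.permutation(X.shape[0])
        epoch_loss, seen = 0.0, 0
        for i in range(0, X.shape[0], batch):
            idx = order[i : i + batch]
            pred, cache = model_forward(X[idx], weights, with_cache=True)
            loss, dpred = _mse_and_grad(pred, y[idx])
            if not np.isfinite(loss):
                raise TrainingError(
                    "training loss is non-finite; reduce the learning rate"
                )
            grads = model_backward(dpred, weights, cache)
            opt.step(weights.tensors, grads)
            epoch_loss += loss * idx.shape[0]
            seen += idx.shape[0]
        history["train_mse"].append(epoch_loss / seen)
        val = evaluate_mse(X_val, y_val, weights)
        history["val_mse"].append(val)
        if val < best_val - train_config.min_delta:
            best_val = val
            best = weights.copy()
            stale = 0
        else:
            stale += 1
            if stale > train_config.patience:
                break
    best.meta.setdefault("epochs_run", len(history["train_mse"]))
    best.meta["best_val_mse"] = best_val
    return best, history


def predict_windows(X: np.ndarray, weights: WeightSet, batch: int = 2048) -> np.ndarray:
    """Batched deterministic forward pass over precomputed windows."""
    out = np.empty(X.shape[0], dtype=DTYPE)
    for i in range(0, X.shape[0], batch):
        out[i : i + batch] = model_forward(X[i : i + batch], weights)
    return out


def predict(features: np.ndarray, weights: WeightSet, stride: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Slide over a (time x channels) trial and predict torque per window.

    Returns ``(end_indices, predictions)`` — each window's output maps to
    the timestamp of its final sample (causal windows).  The number of
    stride-1 windows is ``T - window_len + 1``.
    """
    cfg = weights.config
    features = np.asarray(features, dtype=DTYPE)
    T = features.shape[0]
    if features.shape[1] != cfg.input_channels:
        raise ShapeError(
            f"trial has {features.shape[1]} channels, weights expect "
            f"{cfg.input_channels} (hybrid weights on standard input?)"
        )
    if T < cfg.window_len:
        raise ShapeError("trial shorter than the model window")
    ends = np.arange(cfg.window_len - 1, T, stride)
    X = np.stack([features[e - cfg.window_len + 1 : e + 1] for e in ends])
    return ends, predict_windows(X, weights)
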