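"""NumPy implementation of the Bi-LSTM regression network.

The network reads an L x F feature sequence (default 10 cardiac cycles x 7
features), runs one forward and one backward LSTM pass (hidden size 128,
tanh cell activation), concatenates the per-timestep outputs (width 2H),
flattens them (L * 2H, 2560 for the default), optionally appends demographic
inputs, and maps through a ReLU layer (64 units) to a 2-unit linear head for
(SBP, DBP).  Training uses Adam on the mean-squared error with variational
dropout on the LSTM input and recurrent connections.

Everything is plain NumPy: parameters live in a flat ``dict[str, ndarray]``
partitioned by key prefix into a recurrent block (``lstm_*``) and a fully
connected block (``fc*``), which is what the fine-tuning freeze operates on.
Gradients are exact (validated against finite differences in the test
suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetSpec",
    "init_params",
    "forward",
    "backward",
    "mse_loss",
    "Adam",
    "recurrent_keys",
    "fc_keys",
    "param_count",
    "make_dropout_masks",
]


@dataclass(frozen=True)
class NetSpec:
    """Architecture hyperparameters."""

    seq_len: int = 10
    n_features: int = 7
    lstm_hidden: int = 128
    fc1_units: int = 64
    out_units: int = 2
    dropout: float = 0.10
    use_demographics: bool = False
    n_demographics: int = 5

    def __post_init__(self) -> None:
        if min(self.seq_len, self.n_features, self.lstm_hidden, self.fc1_units) < 1:
            raise ValueError("all layer sizes must be >= 1")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")

    @property
    def per_timestep_width(self) -> int:
        return 2 * self.lstm_hidden

    @property
    def flattened_width(self) -> int:
        return self.seq_len * 2 * self.lstm_hidden

    @property
    def fc1_in(self) -> int:
        return self.flattened_width + (self.n_demographics if self.use_demographics else 0)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def init_params(
    spec: NetSpec, rng: np.random.Generator | int = 0,
    scheme: str = "glorot", dtype=np.float32,
) -> dict[str, np.ndarray]:
    """Initialize the parameter store.

    ``scheme='glorot'`` uses Glorot-uniform weights with the forget-gate bias
    at 1; ``scheme='zeros'`` zeroes everything (useful to verify that the
    network output is identically zero).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    F, H = spec.n_features, spec.lstm_hidden
    params: dict[str, np.ndarray] = {}
    for d in ("fw", "bw"):
        if scheme == "zeros":
            params[f"lstm_{d}.W"] = np.zeros((F, 4 * H), dtype=dtype)
            params[f"lstm_{d}.U"] = np.zeros((H, 4 * H), dtype=dtype)
            params[f"lstm_{d}.b"] = np.zeros(4 * H, dtype=dtype)
        else:
            params[f"lstm_{d}.W"] = _glorot(rng, (F, 4 * H), dtype)
            params[f"lstm_{d}.U"] = _glorot(rng, (H, 4 * H), dtype)
            b = np.zeros(4 * H, dtype=dtype)
            b[H: 2 * H] = 1.0   # forget-gate bias
            params[f"lstm_{d}.b"] = b
    if scheme == "zeros":
        params["fc1.W"] = np.zeros((spec.fc1_in, spec.fc1_units), dtype=dtype)
        params["fc2.W"] = np.zeros((spec.fc1_units, spec.out_units), dtype=dtype)
    else:
        params["fc1.W"] = _glorot(rng, (spec.fc1_in, spec.fc1_units), dtype)
        params["fc2.W"] = _glorot(rng, (spec.fc1_units, spec.out_units), dtype)
    params["fc1.b"] = np.zeros(spec.fc1_units, dtype=dtype)
    params["fc2.b"] = np.zeros(spec.out_units, dtype=dtype)
    return params


def recurrent_keys(params: dict[str, np.ndarray]) -> list[str]:
    return [k for k in params if k.startswith("lstm_")]


def fc_keys(params: dict[str, np.ndarray]) -> list[str]:
    return [k for k in params if k.startswith("fc")]


def param_count(params: dict[str, np.ndarray], block: str | None = None) -> int:
    keys = params.keys()
    if block == "recurrent":
        keys = recurrent_keys(params)
    elif block == "fc":
        keys = fc_keys(params)
    return int(sum(params[k].size for k in keys))


def make_dropout_masks(
    spec: NetSpec, batch: int, rng: np.random.Generator,
) -> dict[str, np.ndarray] | None:
    """Variational dropout masks, fixed across timesteps within a batch:
    one input mask and one recurrent-state mask per direction."""
    p = spec.dropout
    if p == 0:
        return None
    keep = 1.0 - p
    masks = {}
    for d in ("fw", "bw"):
        masks[f"x_{d}"] = (rng.random((batch, spec.n_features)) < keep) / keep
        masks[f"h_{d}"] = (rng.random((batch, spec.lstm_hidden)) < keep) / keep
    return masks


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _lstm_forward_dir(W, U, b, X, mask_x, mask_h):
    """One-direction LSTM over X (B, T, F); returns (H_seq, cache)."""
    B, T, F = X.shape
    Hn = U.shape[0]
    Xm = X * mask_x[:, None, :] if mask_x is not None else X
    xp = Xm.reshape(B * T, F) @ W
    xp = xp.reshape(B, T, 4 * Hn)
    h = np.zeros((B, Hn), dtype=W.dtype)
    c = np.zeros((B, Hn), dtype=W.dtype)
    H_seq = np.empty((B, T, Hn), dtype=W.dtype)
    gates_i = np.empty((B, T, Hn), dtype=W.dtype)
    gates_f = np.empty_like(gates_i)
    gates_g = np.empty_like(gates_i)
    gates_o = np.empty_like(gates_i)
    c_prev_seq = np.empty_like(gates_i)
    tanh_c_seq = np.empty_like(gates_i)
    h_prev_m_seq = np.empty_like(gates_i)
    for t in range(T):
        hm = h * mask_h if mask_h is not None else h
        z = xp[:, t] + hm @ U + b
        i = _sigmoid(z[:, :Hn])
        f = _sigmoid(z[:, Hn: 2 * Hn])
        g = np.tanh(z[:, 2 * Hn: 3 * Hn])
        o = _sigmoid(z[:, 3 * Hn:])
        c_prev_seq[:, t] = c
        h_prev_m_seq[:, t] = hm
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        H_seq[:, t] = h
        gates_i[:, t], gates_f[:, t], gates_g[:, t], gates_o[:, t] = i, f, g, o
        tanh_c_seq[:, t] = tc
    cache = {
        "Xm": Xm, "i": gates_i, "f": gates_f, "g": gates_g, "o": gates_o,
        "c_prev": c_prev_seq, "tanh_c": tanh_c_seq, "h_prev_m": h_prev_m_seq,
        "mask_h": mask_h,
    }
    return H_seq, cache


def _lstm_backward_dir(W, U, b, cache, dH_seq):
    """BPTT for one direction; returns (dW, dU, db)."""
    Xm = cache["Xm"]
    B, T, F = Xm.shape
    Hn = U.shape[0]
    i, f, g, o = cache["i"], cache["f"], cache["g"], cache["o"]
    c_prev, tanh_c = cache["c_prev"], cache["tanh_c"]
    mask_h = cache["mask_h"]
    dZ = np.empty((B, T, 4 * Hn), dtype=W.dtype)
    dh_next = np.zeros((B, Hn), dtype=W.dtype)
    dc_next = np.zeros((B, Hn), dtype=W.dtype)
    Ut = U.T
    for t in range(T - 1, -1, -1):
        dh = dH_seq[:, t] + dh_next
        it, ft, gt, ot = i[:, t], f[:, t], g[:, t], o[:, t]
        tct = tanh_c[:, t]
        do = dh * tct
        dc = dh * ot * (1.0 - tct * tct) + dc_next
        di = dc * gt
        df = dc * c_prev[:, t]
        dg = dc * it
        dc_next = dc * ft
        dz = dZ[:, t]
        dz[:, :Hn] = di * it * (1.0 - it)
        dz[:, Hn: 2 * Hn] = df * ft * (1.0 - ft)
        dz[:, 2 * Hn: 3 * Hn] = dg * (1.0 - gt * gt)
        dz[:, 3 * Hn:] = do * ot * (1.0 - ot)
        dh_next = dz @ Ut
        if mask_h is not None:
            dh_next = dh_next * mask_h
    dW = Xm.reshape(B * T, F).T @ dZ.reshape(B * T, 4 * Hn)
    dU = cache["h_prev_m"].reshape(B * T, Hn).T @ dZ.reshape(B * T, 4 * Hn)
    db = dZ.sum(axis=(0, 1))
    return dW, dU, db


def forward(
    params: dict[str, np.ndarray],
    spec: NetSpec,
    X: np.ndarray,
    demographics: np.ndarray | None = None,
    dropout_masks: dict[str, np.ndarray] | None = None,
    return_cache: bool = False,
):
    """Forward pass: X (B, T, F) [+ demographics (B, D)] -> predictions (B, 2).

    Pass ``dropout_masks`` (from :func:`make_dropout_masks`) during training
    only; inference runs the deterministic network.
    """
    dtype = params["fc1.W"].dtype
    X = np.ascontiguousarray(X, dtype=dtype)
    B, T, F = X.shape
    if (T, F) != (spec.seq_len, spec.n_features):
        raise ValueError(f"input shape {(T, F)} does not match spec "
                         f"{(spec.seq_len, spec.n_features)}")
    if spec.use_demographics:
        if demographics is None:
            raise ValueError("spec.use_demographics=True but none provided")
        demographics = np.ascontiguousarray(demographics, dtype=dtype)

    m = dropout_masks or {}
    H_fw, cache_fw = _lstm_forward_dir(
        params["lstm_fw.W"], params["lstm_fw.U"], params["lstm_fw.b"],
        X, m.get("x_fw"), m.get("h_fw"))
    Xr = X[:, ::-1]
    H_bw_rev, cache_bw = _lstm_forward_dir(
        params["lstm_bw.W"], params["lstm_bw.U"], params["lstm_bw.b"],
        Xr, m.get("x_bw"), m.get("h_bw"))
    H_bw = H_bw_rev[:, ::-1]

    concat = np.concatenate([H_fw, H_bw], axis=2)       # (B, T, 2H)
    flat = concat.reshape(B, spec.flattened_width)
    fc_in = np.concatenate([flat, demographics], axis=1) if spec.use_demographics else flat
    a1 = fc_in @ params["fc1.W"] + params["fc1.b"]
    r1 = np.maximum(a1, 0.0)
    y = r1 @ params["fc2.W"] + params["fc2.b"]
    if not return_cache:
        return y
    cache = {"cache_fw": cache_fw, "cache_bw": cache_bw, "fc_in": fc_in,
             "a1": a1, "r1": r1, "B": B}
    return y, cache


def backward(
    params: dict[str, np.ndarray], spec: NetSpec, cache: dict, dY: np.ndarray,
) -> dict[str, np.ndarray]:
    """Exact gradients of the scalar loss wrt every parameter, given dL/dY."""
    B = cache["B"]
    T, Hn = spec.seq_len, spec.lstm_hidden
    dY = dY.astype(params["fc2.W"].dtype, copy=False)
    grads: dict[str, np.ndarray] = {}
    grads["fc2.W"] = cache["r1"].T @ dY
    grads["fc2.b"] = dY.sum(axis=0)
    dr1 = dY @ params["fc2.W"].T
    da1 = dr1 * (cache["a1"] > 0)
    grads["fc1.W"] = cache["fc_in"].T @ da1
    grads["fc1.b"] = da1.sum(axis=0)
    dfc_in = da1 @ params["fc1.W"].T
    dflat = dfc_in[:, : spec.flattened_width]
    dconcat = dflat.reshape(B, T, 2 * Hn)
    dH_fw = dconcat[:, :, :Hn]
    dH_bw = dconcat[:, :, Hn:]
    dW, dU, db = _lstm_backward_dir(
        params["lstm_fw.W"], params["lstm_fw.U"], params["lstm_fw.b"],
        cache["cache_fw"], dH_fw)
    grads["lstm_fw.W"], grads["lstm_fw.U"], grads["lstm_fw.b"] = dW, dU, db
    dW, dU, db = _lstm_backward_dir(
        params["lstm_bw.W"], params["lstm_bw.U"], params["lstm_bw.b"],
        cache["cache_bw"], np.ascontiguousarray(dH_bw[:, ::-1]))
    grads["lstm_bw.W"], grads["lstm_bw.U"], grads["lstm_bw.b"] = dW, dU, db
    return grads


def mse_loss(y_pred: np.ndarray, y_true: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all outputs; returns (loss, dL/dY)."""
    y_true = y_true.astype(y_pred.dtype, copy=False)
    diff = y_pred - y_true
    loss = float(np.mean(diff**2))
    dY = 2.0 * diff / diff.size
    return loss, dY


@dataclass
class Adam:
    """Adam optimizer over a parameter dict; updates only ``trainable`` keys."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             trainable: list[str] | None = None) -> None:
        keys = trainable if trainable is not None else list(params)
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k in keys:
            g = grads[k].astype(np.float64)
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] = (params[k].astype(np.float64)
                         - self.lr * mhat / (np.sqrt(vhat) + self.eps)
                         ).astype(params[k].dtype)
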