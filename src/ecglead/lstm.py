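"""Stacked-LSTM sequence-to-sequence regressor, written on numpy.

The network maps a 3-channel input sequence (leads II, V2, V6) to a
12-channel output sequence at every time step.  Cells are the original
LSTM formulation (input, forget, cell-candidate and output gates; no
peepholes), stacked, with a per-time-step affine projection from the
last layer's hidden state to the 12 output channels.

Initialization:

* input weights — uniform, zero mean, variance ``2 / (input_size +
  4 * hidden_units)`` where input_size for layers above the first is
  the previous layer's hidden width;
* recurrent weights — orthogonal, the Q factor of a QR decomposition
  of a unit-normal random matrix, applied blockwise per gate;
* forget-gate biases 1, all other biases 0.

The training loss for one sequence of length S with R output channels
is ``(1/(2S)) * Σ_t Σ_j (ŷ_tj − y_tj)²`` — summed, not averaged, over
channels — and a minibatch contributes the mean of its per-sequence
losses.  Gradients are exact backpropagation through time; the update
rule is Adam with bias correction, optionally on a piecewise schedule
that multiplies the learning rate by 0.1 every 10 epochs.

Gate blocks are ordered (input, forget, cell-candidate, output) in all
concatenated weight matrices.  Training runs in float32; float64 is
supported throughout for oracle-grade checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description of the stacked LSTM."""

    hidden_units: tuple[int, ...]
    input_size: int = 3
    output_size: int = 12

    def __post_init__(self):
        object.__setattr__(self, "hidden_units", tuple(int(h) for h in self.hidden_units))
        if len(self.hidden_units) < 1:
            raise ValueError("need at least one layer")
        if any(h < 1 for h in self.hidden_units):
            raise ValueError("hidden unit counts must be positive")

    @property
    def num_layers(self) -> int:
        return len(self.hidden_units)

    def layer_input_sizes(self) -> list[int]:
        return [self.input_size, *self.hidden_units[:-1]]


@dataclass
class TrainingConfig:
    """Optimizer settings for one training run."""

    minibatch: int = 27
    learning_rate: float = 0.028805
    schedule: str = "none"              # "none" | "piecewise"
    beta1: float = 0.90034
    beta2: float = 0.9175
    epochs: int = 100
    seed: int = 0
    epsilon: float = 1e-8

    def __post_init__(self):
        if self.schedule not in ("none", "piecewise"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.minibatch < 1 or self.learning_rate <= 0:
            raise ValueError("invalid minibatch or learning rate")

    def lr_at_epoch(self, epoch: int) -> float:
        """Effective learning rate during 0-based ``epoch``."""
        if self.schedule == "piecewise":
            return self.learning_rate * 0.1 ** (epoch // 10)
        return self.learning_rate


@dataclass
class Weights:
    """Trainable parameters; gate order (i, f, g, o) in all 4H blocks."""

    spec: NetworkSpec
    Wx: list[np.ndarray]      # per layer (in_l, 4*H_l)
    U: list[np.ndarray]       # per layer (H_l, 4*H_l)
    b: list[np.ndarray]       # per layer (4*H_l,)
    Wout: np.ndarray          # (H_last, R)
    bout: np.ndarray          # (R,)

    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for l in range(self.spec.num_layers):
            out += [self.Wx[l], self.U[l], self.b[l]]
        out += [self.Wout, self.bout]
        return out

    def copy(self) -> "Weights":
        return Weights(spec=self.spec,
                       Wx=[w.copy() for w in self.Wx],
                       U=[u.copy() for u in self.U],
                       b=[v.copy() for v in self.b],
                       Wout=self.Wout.copy(), bout=self.bout.copy())

    def astype(self, dtype) -> "Weights":
        return Weights(spec=self.spec,
                       Wx=[w.astype(dtype) for w in self.Wx],
                       U=[u.astype(dtype) for u in self.U],
                       b=[v.astype(dtype) for v in self.b],
                       Wout=self.Wout.astype(dtype),
                       bout=self.bout.astype(dtype))


def _orthogonal(n: int, rng: np.random.Generator, dtype) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    # fix signs so the factorization (hence the init) is unique
    q = q * np.sign(np.diag(r))
    return q.astype(dtype)


def init_weights(spec: NetworkSpec, seed: int = 0,
                 dtype=np.float32) -> Weights:
    """Draw initial weights; deterministic given ``seed``.

    Input weights are uniform with variance ``2/(in + 4H)`` (so
    half-width ``sqrt(3 * var)``); recurrent weights are blockwise
    orthogonal; forget biases 1, other biases 0.  The output projection
    uses the same uniform scheme with fan ``2/(H + R)``.
    """
    rng = np.random.default_rng(seed)
    Wx, U, b = [], [], []
    for in_l, h in zip(spec.layer_input_sizes(), spec.hidden_units):
        var = 2.0 / (in_l + 4 * h)
        a = np.sqrt(3.0 * var)
        Wx.append(rng.uniform(-a, a, size=(in_l, 4 * h)).astype(dtype))
        blocks = [_orthogonal(h, rng, dtype) for _ in range(4)]
        U.append(np.concatenate(blocks, axis=1))
        bias = np.zeros(4 * h, dtype=dtype)
        bias[h:2 * h] = 1.0          # forget gate
        b.append(bias)
    h_last, r_out = spec.hidden_units[-1], spec.output_size
    a_out = np.sqrt(3.0 * 2.0 / (h_last + r_out))
    Wout = rng.uniform(-a_out, a_out, size=(h_last, r_out)).astype(dtype)
    bout = np.zeros(r_out, dtype=dtype)
    return Weights(spec=spec, Wx=Wx, U=U, b=b, Wout=Wout, bout=bout)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def forward(w: Weights, x: np.ndarray, return_cache: bool = False):
    """Run the network over ``x`` of shape (S, input_size) or (S, B, input_size).

    Hidden and cell states start at zero for every sequence; the output
    is emitted at every time step.
    """
    squeeze = x.ndim == 2
    if squeeze:
        x = x[:, None, :]
    if x.shape[2] != w.spec.input_size:
        raise ValueError(f"expected input width {w.spec.input_size}, "
                         f"got {x.shape[2]}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    S, B, _ = x.shape
    dtype = w.Wout.dtype
    h_below = x.astype(dtype, copy=False)
    cache: list[dict] = []
    for l, H in enumerate(w.spec.hidden_units):
        xp = h_below.reshape(S * B, -1) @ w.Wx[l]
        xp = xp.reshape(S, B, 4 * H) + w.b[l]
        i_g = np.empty((S, B, H), dtype)
        f_g = np.empty((S, B, H), dtype)
        g_g = np.empty((S, B, H), dtype)
        o_g = np.empty((S, B, H), dtype)
        c_s = np.empty((S, B, H), dtype)
        tc = np.empty((S, B, H), dtype)
        h_s = np.empty((S, B, H), dtype)
        h = np.zeros((B, H), dtype)
        c = np.zeros((B, H), dtype)
        U = w.U[l]
        for t in range(S):
            z = xp[t] + h @ U
            i_t = _sigmoid(z[:, :H])
            f_t = _sigmoid(z[:, H:2 * H])
            g_t = np.tanh(z[:, 2 * H:3 * H])
            o_t = _sigmoid(z[:, 3 * H:])
            c = f_t * c + i_t * g_t
            tc_t = np.tanh(c)
            h = o_t * tc_t
            i_g[t], f_g[t], g_g[t], o_g[t] = i_t, f_t, g_t, o_t
            c_s[t], tc[t], h_s[t] = c, tc_t, h
        cache.append({"x": h_below, "i": i_g, "f": f_g, "g": g_g,
                      "o": o_g, "c": c_s, "tc": tc, "h": h_s})
        h_below = h_s
    y = h_below.reshape(S * B, -1) @ w.Wout + w.bout
    y = y.reshape(S, B, w.spec.output_size)
    if squeeze:
        y = y[:, 0, :]
    if return_cache:
        return y, cache
    return y


def predict(w: Weights, x: np.ndarray) -> np.ndarray:
    """Forward pass without caches (alias with an estimator-friendly name)."""
    return forward(w, x)


def loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Half summed-square error per time step, averaged over sequences.

    For one (S, R) sequence: ``(1/(2S)) Σ_t Σ_j (ŷ − y)²`` — the channel
    sum is *not* normalized by R.  Batched (S, B, R) input returns the
    mean of the B per-sequence losses.
    """
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    resid = pred.astype(np.float64) - target.astype(np.float64)
    S = resid.shape[0]
    if resid.ndim == 2:
        return float(np.sum(resid ** 2) / (2 * S))
    B = resid.shape[1]
    return float(np.sum(resid ** 2) / (2 * S * B))


@dataclass
class Gradients:
    dWx: list[np.ndarray]
    dU: list[np.ndarray]
    db: list[np.ndarray]
    dWout: np.ndarray
    dbout: np.ndarray

    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for wx, u, b in zip(self.dWx, self.dU, self.db):
            out += [wx, u, b]
        out += [self.dWout, self.dbout]
        return out


def gradients(w: Weights, x: np.ndarray, target: np.ndarray
              ) -> tuple[float, Gradients]:
    """Loss and its exact gradient for a (batch of) sequence(s) via BPTT."""
    squeeze = x.ndim == 2
    if squeeze:
        x = x[:, None, :]
        target = target[:, None, :]
    y, cache = forward(w, x, return_cache=True)
    S, B, _ = y.shape
    val = loss(y, target)
    dtype = w.Wout.dtype
    dY = ((y - target) / (S * B)).astype(dtype)

    h_top = cache[-1]["h"]
    dWout = h_top.reshape(S * B, -1).T @ dY.reshape(S * B, -1)
    dbout = dY.sum(axis=(0, 1))
    dh_seq = (dY.reshape(S * B, -1) @ w.Wout.T).reshape(S, B, -1)

    dWx, dU, db = [], [], []
    for l in range(w.spec.num_layers - 1, -1, -1):
        cc = cache[l]
        H = w.spec.hidden_units[l]
        U = w.U[l]
        gWx = np.zeros_like(w.Wx[l], dtype=np.float64)
        gU = np.zeros_like(U, dtype=np.float64)
        gb = np.zeros(4 * H, dtype=np.float64)
        dx_seq = np.empty_like(cc["x"])
        dh_next = np.zeros((B, H), dtype)
        dc_next = np.zeros((B, H), dtype)
        for t in range(S - 1, -1, -1):
            dh = dh_seq[t] + dh_next
            o_t, tc_t = cc["o"][t], cc["tc"][t]
            i_t, f_t, g_t = cc["i"][t], cc["f"][t], cc["g"][t]
            dc = dh * o_t * (1.0 - tc_t ** 2) + dc_next
            c_prev = cc["c"][t - 1] if t > 0 else 0.0
            dz = np.concatenate([
                dc * g_t * i_t * (1.0 - i_t),
                dc * c_prev * f_t * (1.0 - f_t),
                dc * i_t * (1.0 - g_t ** 2),
                dh * tc_t * o_t * (1.0 - o_t),
            ], axis=1)
            h_prev = cc["h"][t - 1] if t > 0 else np.zeros((B, H), dtype)
            gWx += cc["x"][t].T @ dz
            gU += h_prev.T @ dz
            gb += dz.sum(axis=0)
            dx_seq[t] = dz @ w.Wx[l].T
            dh_next = dz @ U.T
            dc_next = dc * f_t
        dWx.append(gWx.astype(dtype))
        dU.append(gU.astype(dtype))
        db.append(gb.astype(dtype))
        dh_seq = dx_seq
    dWx.reverse(); dU.reverse(); db.reverse()
    return val, Gradients(dWx=dWx, dU=dU, db=db,
                          dWout=dWout.astype(dtype), dbout=dbout.astype(dtype))


class Adam:
    """Adam with bias correction, operating on a Weights structure."""

    def __init__(self, w: Weights, cfg: TrainingConfig):
        self.cfg = cfg
        self.t = 0
        self.m = [np.zeros_like(p, dtype=np.float64) for p in w.params()]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in w.params()]

    def step(self, w: Weights, g: Gradients, lr: float | None = None) -> None:
        """One in-place update; ``lr`` overrides the configured rate
        (used by the piecewise schedule)."""
        cfg = self.cfg
        lr = cfg.learning_rate if lr is None else lr
        self.t += 1
        b1t = 1.0 - cfg.beta1 ** self.t
        b2t = 1.0 - cfg.beta2 ** self.t
        for p, gp, m, v in zip(w.params(), g.params(), self.m, self.v):
            m *= cfg.beta1
            m += (1.0 - cfg.beta1) * gp
            v *= cfg.beta2
            v += (1.0 - cfg.beta2) * gp.astype(np.float64) ** 2
            p -= (lr * (m / b1t) / (np.sqrt(v / b2t) + cfg.epsilon)).astype(p.dtype)


def pooled_rmse(w: Weights, x: np.ndarray, y: np.ndarray) -> float:
    """RMSE in mV pooled over every sample, lead and sequence."""
    pred = forward(w, x)
    resid = pred.astype(np.float64) - y.astype(np.float64)
    return float(np.sqrt(np.mean(resid ** 2)))


def train(spec: NetworkSpec, cfg: TrainingConfig,
          train_xy: tuple[np.ndarray, np.ndarray],
          val_xy: tuple[np.ndarray, np.ndarray] | None = None,
          init: Weights | None = None,
          dtype=np.float32) -> tuple[Weights, dict]:
    """Train for ``cfg.epochs`` epochs of reshuffled minibatches.

    Parameters
    ----------
    train_xy, val_xy : (x, y) with x (S, B, 3) and y (S, B, 12)
        Stacked equal-length windows (see WindowedDataset.stacked).
    init : Weights, optional
        Warm start (transfer learning); fresh initialization from
        ``cfg.seed`` when omitted.

    Returns
    -------
    weights, history
        history["train_loss"] and history["val_rmse"] hold one entry
        per epoch; history["objective"] is the final validation RMSE
        (the Bayesian-optimization objective).
    """
    x_tr, y_tr = train_xy
    x_tr = np.ascontiguousarray(x_tr, dtype=dtype)
    y_tr = np.ascontiguousarray(y_tr, dtype=dtype)
    if x_tr.ndim != 3 or x_tr.shape[1] != y_tr.shape[1]:
        raise ValueError("train_xy must be stacked (S, B, C) arrays")
    n = x_tr.shape[1]
    if n == 0:
        raise ValueError("empty training set")

    w = init_weights(spec, seed=cfg.seed, dtype=dtype) if init is None \
        else init.copy().astype(dtype)
    opt = Adam(w, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    history: dict = {"train_loss": [], "val_rmse": []}

    for epoch in range(cfg.epochs):
        lr = cfg.lr_at_epoch(epoch)
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.minibatch):
            idx = perm[start:start + cfg.minibatch]
            val, g = gradients(w, x_tr[:, idx], y_tr[:, idx])
            if not np.isfinite(val):
                raise TrainingDivergedError(
                    f"loss became non-finite at epoch {epoch}")
            opt.step(w, g, lr=lr)
            losses.append(val)
        history["train_loss"].append(float(np.mean(losses)))
        if val_xy is not None:
            history["val_rmse"].append(pooled_rmse(w, *val_xy))

    if val_xy is not None:
        history["objective"] = history["val_rmse"][-1] if cfg.epochs > 0 \
            else pooled_rmse(w, *val_xy)
    return w, history


# ---------------------------------------------------------------------------
# Checkpointing

def save_checkpoint(path, w: Weights, cfg: TrainingConfig | None = None,
                    meta: dict | None = None) -> None:
    """Persist spec + weights (+ config, metadata) to HDF5, bit-exact."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["spec"] = json.dumps({
            "hidden_units": list(w.spec.hidden_units),
            "input_size": w.spec.input_size,
            "output_size": w.spec.output_size,
        })
        if cfg is not None:
            f.attrs["config"] = json.dumps(vars(cfg))
        if meta:
            f.attrs["meta"] = json.dumps(meta)
        for l in range(w.spec.num_layers):
            f.create_dataset(f"layer{l}/Wx", data=w.Wx[l])
            f.create_dataset(f"layer{l}/U", data=w.U[l])
            f.create_dataset(f"layer{l}/b", data=w.b[l])
        f.create_dataset("Wout", data=w.Wout)
        f.create_dataset("bout", data=w.bout)


def load_checkpoint(path) -> tuple[Weights, TrainingConfig | None, dict]:
    import h5py

    with h5py.File(path, "r") as f:
        sp = json.loads(f.attrs["spec"])
        spec = NetworkSpec(hidden_units=tuple(sp["hidden_units"]),
                           input_size=sp["input_size"],
                           output_size=sp["output_size"])
        w = Weights(
            spec=spec,
            Wx=[f[f"layer{l}/Wx"][()] for l in range(spec.num_layers)],
            U=[f[f"layer{l}/U"][()] for l in range(spec.num_layers)],
            b=[f[f"layer{l}/b"][()] for l in range(spec.num_layers)],
            Wout=f["Wout"][()], bout=f["bout"][()],
        )
        cfg = None
        if "config" in f.attrs:
            cfg = TrainingConfig(**json.loads(f.attrs["config"]))
        meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else {}
    return w, cfg, meta
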