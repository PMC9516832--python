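"""Minimal NumPy sequence-model core: embedding -> GRU stack -> linear.

Forward, backward (backprop through time) and the Adam optimizer are written
directly against NumPy arrays.  Gradients are analytic and are verified
against finite differences in the test suite.  The network is small by
design: desk-scale experiments use one 64-unit layer, and the full-size
configuration (3 x 512) is the same code path.

GRU cell (Cho et al. formulation; r gates the previous hidden state before
the candidate projection):

    z_t = sigmoid(x W_z + h_{t-1} U_z + b_z)
    r_t = sigmoid(x W_r + h_{t-1} U_r + b_r)
    n_t = tanh(x W_n + (r_t * h_{t-1}) U_n + b_n)
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}
"""
from __future__ import annotations

import copy
import json

import numpy as np

__all__ = ["GRUNetwork", "Adam", "weighted_nll", "log_softmax"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # split by sign for numerical stability
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def log_softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise log-softmax over the last axis, max-shifted for stability."""
    m = logits.max(axis=-1, keepdims=True)
    shifted = logits - m
    lse = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    return shifted - lse


class GRUNetwork:
    """Embedding -> ``num_layers`` GRU layers -> linear readout to vocab_size.

    Parameters are plain float64 arrays in ``self.params`` so that training
    runs are bit-reproducible for a fixed seed.
    """

    def __init__(
        self,
        vocab_size: int,
        embedding_dim: int,
        hidden_units: int,
        num_layers: int,
        rng: np.random.Generator,
    ):
        if min(vocab_size, embedding_dim, hidden_units, num_layers) < 1:
            raise ValueError("all network dimensions must be >= 1")
        self.vocab_size = vocab_size
        self.embedding_dim = embedding_dim
        self.hidden_units = hidden_units
        self.num_layers = num_layers
        k = 1.0 / np.sqrt(hidden_units)
        p: dict[str, np.ndarray] = {}
        p["E"] = rng.uniform(-k, k, size=(vocab_size, embedding_dim))
        for layer in range(num_layers):
            d_in = embedding_dim if layer == 0 else hidden_units
            for gate in ("z", "r", "n"):
                p[f"W{gate}{layer}"] = rng.uniform(-k, k, size=(d_in, hidden_units))
                p[f"U{gate}{layer}"] = rng.uniform(-k, k, size=(hidden_units, hidden_units))
                p[f"b{gate}{layer}"] = np.zeros(hidden_units)
        p["Wout"] = rng.uniform(-k, k, size=(hidden_units, vocab_size))
        p["bout"] = np.zeros(vocab_size)
        self.params = p

    # ------------------------------------------------------------------ #
    def copy(self) -> "GRUNetwork":
        new = object.__new__(GRUNetwork)
        new.vocab_size = self.vocab_size
        new.embedding_dim = self.embedding_dim
        new.hidden_units = self.hidden_units
        new.num_layers = self.num_layers
        new.params = {k: v.copy() for k, v in self.params.items()}
        return new

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def parameter_vector(self) -> np.ndarray:
        return np.concatenate([self.params[k].ravel() for k in sorted(self.params)])

    # ------------------------------------------------------------------ #
    def init_state(self, batch: int) -> list[np.ndarray]:
        return [np.zeros((batch, self.hidden_units)) for _ in range(self.num_layers)]

    def step(self, x_ids: np.ndarray, state: list[np.ndarray]) -> np.ndarray:
        """One autoregressive step.  Mutates ``state`` in place, returns logits [B,k]."""
        p = self.params
        x = p["E"][x_ids]
        for layer in range(self.num_layers):
            h_prev = state[layer]
            z = _sigmoid(x @ p[f"Wz{layer}"] + h_prev @ p[f"Uz{layer}"] + p[f"bz{layer}"])
            r = _sigmoid(x @ p[f"Wr{layer}"] + h_prev @ p[f"Ur{layer}"] + p[f"br{layer}"])
            n = np.tanh(x @ p[f"Wn{layer}"] + (r * h_prev) @ p[f"Un{layer}"] + p[f"bn{layer}"])
            h = (1.0 - z) * n + z * h_prev
            state[layer] = h
            x = h
        return x @ p["Wout"] + p["bout"]

    def forward(self, X: np.ndarray):
        """Teacher-forced forward pass.

        X : int array [B, T] of token ids.
        Returns (logits [B, T, k], cache for backward()).
        """
        p = self.params
        B, T = X.shape
        inp = p["E"][X]  # [B, T, d]
        layer_caches = []
        for layer in range(num_layers := self.num_layers):
            Wz, Uz, bz = p[f"Wz{layer}"], p[f"Uz{layer}"], p[f"bz{layer}"]
            Wr, Ur, br = p[f"Wr{layer}"], p[f"Ur{layer}"], p[f"br{layer}"]
            Wn, Un, bn = p[f"Wn{layer}"], p[f"Un{layer}"], p[f"bn{layer}"]
            h_prev = np.zeros((B, self.hidden_units))
            H = np.empty((B, T, self.hidden_units))
            steps = []
            for t in range(T):
                x = inp[:, t]
                z = _sigmoid(x @ Wz + h_prev @ Uz + bz)
                r = _sigmoid(x @ Wr + h_prev @ Ur + br)
                rh = r * h_prev
                n = np.tanh(x @ Wn + rh @ Un + bn)
                h = (1.0 - z) * n + z * h_prev
                steps.append((x, h_prev, z, r, rh, n))
                H[:, t] = h
                h_prev = h
            layer_caches.append(steps)
            inp = H
        logits = inp @ p["Wout"] + p["bout"]
        return logits, (X, layer_caches, inp)

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss given d(loss)/d(logits)."""
        p = self.params
        X, layer_caches, H_last = cache
        B, T = X.shape
        g = {k: np.zeros_like(v) for k, v in p.items()}
        flatH = H_last.reshape(B * T, -1)
        flatD = dlogits.reshape(B * T, -1)
        g["Wout"] = flatH.T @ flatD
        g["bout"] = flatD.sum(axis=0)
        dH = dlogits @ p["Wout"].T  # [B, T, h] grad wrt top-layer outputs
        for layer in range(self.num_layers - 1, -1, -1):
            Wz, Uz = p[f"Wz{layer}"], p[f"Uz{layer}"]
            Wr, Ur = p[f"Wr{layer}"], p[f"Ur{layer}"]
            Wn, Un = p[f"Wn{layer}"], p[f"Un{layer}"]
            steps = layer_caches[layer]
            d_in = Wz.shape[0]
            dX = np.empty((B, T, d_in))
            dh_next = np.zeros((B, self.hidden_units))
            for t in range(T - 1, -1, -1):
                x, h_prev, z, r, rh, n = steps[t]
                dh = dH[:, t] + dh_next
                dn = dh * (1.0 - z)
                dz = dh * (h_prev - n)
                dh_prev = dh * z
                dan = dn * (1.0 - n * n)
                g[f"Wn{layer}"] += x.T @ dan
                g[f"Un{layer}"] += rh.T @ dan
                g[f"bn{layer}"] += dan.sum(axis=0)
                drh = dan @ Un.T
                dr = drh * h_prev
                dh_prev += drh * r
                dar = dr * r * (1.0 - r)
                g[f"Wr{layer}"] += x.T @ dar
                g[f"Ur{layer}"] += h_prev.T @ dar
                g[f"br{layer}"] += dar.sum(axis=0)
                dh_prev += dar @ Ur.T
                daz = dz * z * (1.0 - z)
                g[f"Wz{layer}"] += x.T @ daz
                g[f"Uz{layer}"] += h_prev.T @ daz
                g[f"bz{layer}"] += daz.sum(axis=0)
                dh_prev += daz @ Uz.T
                dX[:, t] = dan @ Wn.T + dar @ Wr.T + daz @ Wz.T
                dh_next = dh_prev
            dH = dX
        # dH is now [B, T, embedding_dim]: scatter into the embedding table
        np.add.at(g["E"], X, dH)
        return g

    # ------------------------------------------------------------------ #
    def save(self, path) -> None:
        meta = json.dumps(
            {
                "format": "molbias-gru-v1",
                "vocab_size": self.vocab_size,
                "embedding_dim": self.embedding_dim,
                "hidden_units": self.hidden_units,
                "num_layers": self.num_layers,
            }
        )
        np.savez(path, __meta__=np.array(meta), **self.params)

    @classmethod
    def load(cls, path) -> "GRUNetwork":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            if meta.get("format") != "molbias-gru-v1":
                raise ValueError(f"unrecognised checkpoint format in {path}")
            net = object.__new__(cls)
            net.vocab_size = meta["vocab_size"]
            net.embedding_dim = meta["embedding_dim"]
            net.hidden_units = meta["hidden_units"]
            net.num_layers = meta["num_layers"]
            net.params = {k: data[k].copy() for k in data.files if k != "__meta__"}
        return net


def weighted_nll(
    net: GRUNetwork,
    X: np.ndarray,
    Y: np.ndarray,
    weights: np.ndarray,
    grad_scale: float = 1.0,
):
    """Weighted negative log-likelihood of targets Y given inputs X.

    loss  = sum_{b,t} weights[b,t] * (-log p(Y[b,t] | X[b,:t+1]))
    grads = d(grad_scale * loss)/d(params)

    ``grad_scale`` lets callers backpropagate a scaled loss (the CRLV
    mechanism) while the *reported* loss stays on the unscaled scale.
    Weights may be negative (REINFORCE uses per-sequence rewards as weights).
    Returns (loss, grads); grads is None when every effective weight is zero,
    signalling the caller that no optimizer step is needed.
    """
    B, T = X.shape
    logits, cache = net.forward(X)
    logp = log_softmax(logits)
    rows = np.arange(B)[:, None]
    cols = np.arange(T)[None, :]
    nll = -logp[rows, cols, Y]
    loss = float((weights * nll).sum())
    w = weights * grad_scale
    if not np.any(w):
        return loss, None
    P = np.exp(logp)
    dlogits = P * w[..., None]
    dlogits[rows, cols, Y] -= w
    return loss, net.backward(cache, dlogits)


class Adam:
    """Adam optimizer over a GRUNetwork's parameter dict."""

    def __init__(self, lr: float = 5e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for key, grad in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(grad)
                self.v[key] = np.zeros_like(grad)
            m = self.m[key]
            v = self.v[key]
            m *= b1
            m += (1.0 - b1) * grad
            v *= b2
            v += (1.0 - b2) * grad * grad
            params[key] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def copy(self) -> "Adam":
        return copy.deepcopy(self)
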