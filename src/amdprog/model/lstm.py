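"""Two-layer stacked unidirectional LSTM with a per-timestep sigmoid head.

Implemented directly in numpy (forward + backprop through time + Adam) so
the package has no deep-learning framework dependency.  The network is
many-to-many: input (B, l, D) -> LSTM(h1, sequences) -> LSTM(h2, sequences)
-> affine + sigmoid -> (B, l) per-timestep risk.  State is carried across
timesteps within a sequence and reset between sequences, so predictions at
timestep t depend only on inputs 1..t (causality by construction).

Gate order in the fused weight matrices is (input, forget, cell, output).
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lstm_param_count(input_dim: int, hidden: tuple[int, ...], head: bool = True) -> int:
    """Closed-form parameter count: 4*(h*(h+d) + h) per layer, plus the
    per-timestep affine head (h_last + 1)."""
    total = 0
    d = input_dim
    for h in hidden:
        total += 4 * (h * (h + d) + h)
        d = h
    if head:
        total += d + 1
    return total


class _LSTMLayer:
    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        d, h = input_dim, hidden
        scale_x = np.sqrt(6.0 / (d + 4 * h))
        scale_h = np.sqrt(6.0 / (h + 4 * h))
        self.Wx = rng.uniform(-scale_x, scale_x, size=(d, 4 * h))
        self.Wh = rng.uniform(-scale_h, scale_h, size=(h, 4 * h))
        self.b = np.zeros(4 * h)
        self.b[h:2 * h] = 1.0  # forget-gate bias
        self.hidden = h
        self.input_dim = d

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        """X: (B, L, d) -> hidden sequence (B, L, h) plus caches for BPTT."""
        B, L, _ = X.shape
        h = self.hidden
        h_t = np.zeros((B, h))
        c_t = np.zeros((B, h))
        H = np.empty((B, L, h))
        caches = []
        for t in range(L):
            x_t = X[:, t, :]
            z = x_t @ self.Wx + h_t @ self.Wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            c_prev = c_t
            c_t = f * c_prev + i * g
            tc = np.tanh(c_t)
            h_prev = h_t
            h_t = o * tc
            H[:, t, :] = h_t
            caches.append((x_t, h_prev, c_prev, i, f, g, o, tc))
        return H, caches

    def backward(
        self, dH: np.ndarray, caches: list
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        """dH: (B, L, h) gradient on the hidden sequence.

        Returns the gradient w.r.t. the layer input (B, L, d) and gradients
        for [Wx, Wh, b].
        """
        B, L, h = dH.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.empty((B, L, self.input_dim))
        dh_rec = np.zeros((B, h))
        dc_rec = np.zeros((B, h))
        for t in range(L - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc = caches[t]
            dh = dH[:, t, :] + dh_rec
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_rec
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_rec = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t, :] = dz @ self.Wx.T
            dh_rec = dz @ self.Wh.T
        return dX, [dWx, dWh, db]


class StackedLSTM:
    """Stacked two-layer LSTM with a per-timestep scalar sigmoid output."""

    def __init__(
        self,
        input_dim: int,
        hidden: tuple[int, int] = (50, 20),
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.hidden = tuple(hidden)
        self.input_dim = input_dim
        self.layers = []
        d = input_dim
        for h in hidden:
            self.layers.append(_LSTMLayer(d, h, rng))
            d = h
        scale = np.sqrt(6.0 / (d + 1))
        self.w_out = rng.uniform(-scale, scale, size=(d, 1))
        self.b_out = np.zeros(1)

    # -- parameter plumbing --------------------------------------------------

    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        out.extend([self.w_out, self.b_out])
        return out

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w

    # -- forward / backward --------------------------------------------------

    def forward(
        self, X: np.ndarray, return_cache: bool = False
    ) -> np.ndarray | tuple[np.ndarray, dict]:
        """X: (B, l, D) -> per-timestep risks (B, l) in (0, 1)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        H = X
        layer_caches = []
        hidden_seqs = []
        for layer in self.layers:
            H, caches = layer.forward(H)
            layer_caches.append(caches)
            hidden_seqs.append(H)
        logits = H @ self.w_out + self.b_out  # (B, l, 1)
        yhat = _sigmoid(logits[..., 0])
        if return_cache:
            return yhat, {"layer_caches": layer_caches, "top_hidden": H}
        return yhat

    def backward(self, dlogits: np.ndarray, cache: dict) -> list[np.ndarray]:
        """dlogits: (B, l) gradient w.r.t. the pre-sigmoid output.

        Returns gradients aligned with :attr:`params`.
        """
        H_top = cache["top_hidden"]  # (B, l, h2)
        B, L, _ = H_top.shape
        dw_out = np.einsum("blh,bl->h", H_top, dlogits)[:, None]
        db_out = np.array([dlogits.sum()])
        dH = dlogits[..., None] * self.w_out[None, None, :, 0]
        grads_per_layer: list[list[np.ndarray]] = [None] * len(self.layers)
        for idx in range(len(self.layers) - 1, -1, -1):
            dH, layer_grads = self.layers[idx].backward(dH, cache["layer_caches"][idx])
            grads_per_layer[idx] = layer_grads
        grads: list[np.ndarray] = []
        for layer_grads in grads_per_layer:
            grads.extend(layer_grads)
        grads.extend([dw_out, db_out])
        return grads


class Adam:
    """Adaptive-moment optimizer over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v, strict=True):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
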