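"""Minimal numpy neural-network primitives.

Implements exactly what the package needs — uniform parameter
initialization, sigmoid/softplus, an Adam optimizer over named parameter
dicts, and GRU/LSTM recurrent layers with masked backpropagation through
time.  Gradients are analytic and are verified against central finite
differences in the test suite.

Masking convention: ``mask[i, t] = 0`` means visit ``t`` of sequence ``i``
is padding; the recurrent state is carried through unchanged, so the final
hidden state equals the state after the last real visit regardless of how
much padding follows.
"""

from __future__ import annotations

import numpy as np

Params = dict[str, np.ndarray]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def softplus_inverse(y: float) -> float:
    # u with softplus(u) = y;  u = log(e^y - 1)
    return float(np.log(np.expm1(y)))


def uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    a = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-a, a, size=shape)


class Adam:
    """Adam over a dict of named parameter arrays (updates in place)."""

    def __init__(self, params: Params, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Params) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class GRULayer:
    """Single GRU layer, batch-first, with padding-carry masking."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        D, H = input_dim, hidden_dim
        self.D, self.H = D, H
        self.params: Params = {
            "W": uniform_init(rng, (D, 3 * H), H),   # input -> [z, r, c]
            "U": uniform_init(rng, (H, 3 * H), H),   # hidden -> [z, r, c]
            "b": uniform_init(rng, (3 * H,), H),
        }

    def forward(self, x: np.ndarray, mask: np.ndarray):
        """x: (n, T, D), mask: (n, T) -> h_seq (n, T, H) + cache."""
        n, T, _ = x.shape
        H = self.H
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((n, H))
        h_seq = np.zeros((n, T, H))
        cache = []
        for t in range(T):
            xt = x[:, t, :]
            m = mask[:, t][:, None]
            pre_x = xt @ W + b
            z = sigmoid(pre_x[:, :H] + h @ U[:, :H])
            r = sigmoid(pre_x[:, H:2 * H] + h @ U[:, H:2 * H])
            c = np.tanh(pre_x[:, 2 * H:] + (r * h) @ U[:, 2 * H:])
            h_new = (1 - z) * h + z * c
            h_next = m * h_new + (1 - m) * h
            cache.append((xt, h, z, r, c, m))
            h = h_next
            h_seq[:, t, :] = h
        return h_seq, cache

    def backward(self, dh_seq: np.ndarray, cache) -> tuple[np.ndarray, Params]:
        """dh_seq: (n, T, H) gradients w.r.t. each output state."""
        n, T, H = dh_seq.shape
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx_seq = np.zeros((n, T, self.D))
        dh = np.zeros((n, H))
        for t in range(T - 1, -1, -1):
            xt, h_prev, z, r, c, m = cache[t]
            dh = dh + dh_seq[:, t, :]
            dh_masked = dh * m
            dh_prev = dh * (1 - m) + dh_masked * (1 - z)
            dz = dh_masked * (c - h_prev)
            dc = dh_masked * z
            dc_pre = dc * (1 - c * c)
            dz_pre = dz * z * (1 - z)
            dUc = dc_pre @ U[:, 2 * H:].T
            dr = dUc * h_prev
            dh_prev = dh_prev + dUc * r
            dr_pre = dr * r * (1 - r)
            gates = np.concatenate([dz_pre, dr_pre, dc_pre], axis=1)
            dW += xt.T @ gates
            db += gates.sum(axis=0)
            dU[:, :2 * H] += h_prev.T @ np.concatenate([dz_pre, dr_pre], axis=1)
            dU[:, 2 * H:] += (r * h_prev).T @ dc_pre
            dh_prev = dh_prev + np.concatenate([dz_pre, dr_pre], axis=1) @ U[:, :2 * H].T
            dx_seq[:, t, :] = gates @ W.T
            dh = dh_prev
        return dx_seq, {"W": dW, "U": dU, "b": db}


class LSTMLayer:
    """Single LSTM layer, batch-first, with padding-carry masking."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        D, H = input_dim, hidden_dim
        self.D, self.H = D, H
        self.params: Params = {
            "W": uniform_init(rng, (D, 4 * H), H),   # input -> [i, f, o, g]
            "U": uniform_init(rng, (H, 4 * H), H),
            "b": uniform_init(rng, (4 * H,), H),
        }

    def forward(self, x: np.ndarray, mask: np.ndarray):
        n, T, _ = x.shape
        H = self.H
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        h_seq = np.zeros((n, T, H))
        cache = []
        for t in range(T):
            xt = x[:, t, :]
            m = mask[:, t][:, None]
            pre = xt @ W + h @ U + b
            i = sigmoid(pre[:, :H])
            f = sigmoid(pre[:, H:2 * H])
            o = sigmoid(pre[:, 2 * H:3 * H])
            g = np.tanh(pre[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((xt, h, c, i, f, o, g, c_new, tanh_c, m))
            c = m * c_new + (1 - m) * c
            h = m * h_new + (1 - m) * h
            h_seq[:, t, :] = h
        return h_seq, cache

    def backward(self, dh_seq: np.ndarray, cache) -> tuple[np.ndarray, Params]:
        n, T, H = dh_seq.shape
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx_seq = np.zeros((n, T, self.D))
        dh = np.zeros((n, H))
        dc = np.zeros((n, H))
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, o, g, c_new, tanh_c, m = cache[t]
            dh = dh + dh_seq[:, t, :]
            dh_m = dh * m
            dc_m = dc * m
            dh_prev = dh * (1 - m)
            dc_prev = dc * (1 - m)
            do = dh_m * tanh_c
            dc_new = dh_m * o * (1 - tanh_c * tanh_c) + dc_m
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            dc_prev = dc_prev + dc_new * f
            di_pre = di * i * (1 - i)
            df_pre = df * f * (1 - f)
            do_pre = do * o * (1 - o)
            dg_pre = dg * (1 - g * g)
            gates = np.concatenate([di_pre, df_pre, do_pre, dg_pre], axis=1)
            dW += xt.T @ gates
            dU += h_prev.T @ gates
            db += gates.sum(axis=0)
            dh_prev = dh_prev + gates @ U.T
            dx_seq[:, t, :] = gates @ W.T
            dh = dh_prev
            dc = dc_prev
        return dx_seq, {"W": dW, "U": dU, "b": db}
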