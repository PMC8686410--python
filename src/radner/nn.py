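"""Minimal numpy neural-network primitives: LSTM with exact backprop, Adam.

Only what the tagger needs.  Sequences are processed one at a time with
exact (non-truncated) backpropagation through time; a training batch groups
sequences for a single optimizer step, so batched and single-sequence
computations agree to the last bit.
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


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class LSTM:
    """A single-direction LSTM layer (input D -> hidden H).

    Gate order in the stacked weight matrices is input, forget, cell, output.
    The forget-gate bias starts at 1.0 (standard long-memory initialization).
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_in, self.d_hidden = d_in, d_hidden
        H = d_hidden
        self.Wx = glorot(rng, (d_in, 4 * H))
        self.Wh = glorot(rng, (H, 4 * H))
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def forward(self, xs: np.ndarray) -> tuple[np.ndarray, dict]:
        """Run over a (T, D) sequence; returns hidden states (T, H) + cache."""
        T, H = xs.shape[0], self.d_hidden
        hs = np.zeros((T, H))
        cache = {
            "xs": xs,
            "i": np.zeros((T, H)), "f": np.zeros((T, H)),
            "g": np.zeros((T, H)), "o": np.zeros((T, H)),
            "c": np.zeros((T, H)), "tanh_c": np.zeros((T, H)),
        }
        h = np.zeros(H)
        c = np.zeros(H)
        for t in range(T):
            z = xs[t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:H])
            f = _sigmoid(z[H : 2 * H])
            g = np.tanh(z[2 * H : 3 * H])
            o = _sigmoid(z[3 * H :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[t] = h
            for k, v in (("i", i), ("f", f), ("g", g), ("o", o), ("c", c), ("tanh_c", tc)):
                cache[k][t] = v
        cache["hs"] = hs
        return hs, cache

    def backward(
        self, d_hs: np.ndarray, cache: dict
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Backprop through time given d(loss)/d(hidden states).

        Returns d(loss)/d(inputs) and parameter gradients.
        """
        xs = cache["xs"]
        T, H = xs.shape[0], self.d_hidden
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dxs = np.zeros_like(xs)
        dh_next = np.zeros(H)
        dc_next = np.zeros(H)
        for t in range(T - 1, -1, -1):
            i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
            tc = cache["tanh_c"][t]
            c_prev = cache["c"][t - 1] if t > 0 else np.zeros(H)
            h_prev = cache["hs"][t - 1] if t > 0 else np.zeros(H)
            dh = d_hs[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ]
            )
            dWx += np.outer(xs[t], dz)
            dWh += np.outer(h_prev, dz)
            db += dz
            dxs[t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dxs, {"Wx": dWx, "Wh": dWh, "b": db}


class BiLSTM:
    """Forward and backward LSTMs over the same inputs; states concatenated."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.fwd = LSTM(d_in, d_hidden, rng)
        self.bwd = LSTM(d_in, d_hidden, rng)
        self.d_out = 2 * d_hidden

    def forward(self, xs: np.ndarray) -> tuple[np.ndarray, dict]:
        hf, cf = self.fwd.forward(xs)
        hb_rev, cb = self.bwd.forward(xs[::-1])
        hs = np.concatenate([hf, hb_rev[::-1]], axis=1)
        return hs, {"cf": cf, "cb": cb}

    def backward(self, d_hs: np.ndarray, cache: dict) -> tuple[np.ndarray, dict]:
        H = self.fwd.d_hidden
        dxs_f, gf = self.fwd.backward(d_hs[:, :H], cache["cf"])
        dxs_b_rev, gb = self.bwd.backward(d_hs[::-1, H:], cache["cb"])
        dxs = dxs_f + dxs_b_rev[::-1]
        return dxs, {"fwd": gf, "bwd": gb}


class Adam:
    """Adam over a flat dict name -> array, with global-norm gradient clipping."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float | None = 5.0,
    ):
        self.params = params
        self.lr, self.eps, self.clip_norm = lr, eps, clip_norm
        self.b1, self.b2 = betas
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
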