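"""Minimal seeded numpy CNN: three conv-pool blocks, pooled feature vector,
affine sigmoid head, Adam. Sized for desk-scale CPU training on small
phantom images; everything is plain float64 numpy, so runs are bit-deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallCNN", "Adam", "sigmoid", "bce_with_logits"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    n = z.shape[0]
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    dz = (sigmoid(z) - y) / n
    return loss, dz


def _conv3x3(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded 3x3 convolution. x: (N,C,H,W), W: (O,C,3,3) -> (N,O,H,W)."""
    N, C, H, Wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.broadcast_to(b[None, :, None, None], (N, W.shape[0], H, Wd)).copy()
    for di in range(3):
        for dj in range(3):
            sl = xp[:, :, di : di + H, dj : dj + Wd]
            out += np.tensordot(sl, W[:, :, di, dj], axes=([1], [1])).transpose(0, 3, 1, 2)
    return out, xp


def _conv3x3_backward(dout: np.ndarray, xp: np.ndarray, W: np.ndarray):
    N, O, H, Wd = dout.shape
    dW = np.zeros_like(W)
    db = dout.sum(axis=(0, 2, 3))
    dxp = np.zeros_like(xp)
    for di in range(3):
        for dj in range(3):
            sl = xp[:, :, di : di + H, dj : dj + Wd]
            dW[:, :, di, dj] = np.tensordot(dout, sl, axes=([0, 2, 3], [0, 2, 3]))
            dxp[:, :, di : di + H, dj : dj + Wd] += np.tensordot(
                dout, W[:, :, di, dj], axes=([1], [0])
            ).transpose(0, 3, 1, 2)
    return dW, db, dxp[:, :, 1:-1, 1:-1]


def _avgpool(x: np.ndarray, f: int) -> np.ndarray:
    N, C, H, W = x.shape
    return x.reshape(N, C, H // f, f, W // f, f).mean(axis=(3, 5))


def _avgpool_backward(dout: np.ndarray, f: int) -> np.ndarray:
    return np.repeat(np.repeat(dout, f, axis=2), f, axis=3) / (f * f)


class SmallCNN:
    """conv(8)-pool2 / conv(16)-pool2 / conv(16)-pool-to-4x4 / fc(d_feat) / head(1).

    Input height/width must be divisible by 16 (two 2x pools plus the
    adaptive pool down to a 4x4 grid).
    """

    def __init__(self, in_shape: tuple[int, int, int], d_feat: int = 32,
                 conv_channels: tuple[int, int, int] = (8, 16, 16),
                 rng: np.random.Generator | None = None):
        C, H, W = in_shape
        if H % 16 or W % 16:
            raise ValueError("image height/width must be multiples of 16")
        self.in_shape = (C, H, W)
        self.d_feat = int(d_feat)
        self.conv_channels = tuple(conv_channels)
        self._pool3 = (H // 4) // 4  # factor taking the conv3 map to 4x4
        rng = np.random.default_rng() if rng is None else rng
        c1, c2, c3 = conv_channels

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "W1": he((c1, C, 3, 3), C * 9), "b1": np.zeros(c1),
            "W2": he((c2, c1, 3, 3), c1 * 9), "b2": np.zeros(c2),
            "W3": he((c3, c2, 3, 3), c2 * 9), "b3": np.zeros(c3),
            "Wf": he((d_feat, c3 * 16), c3 * 16), "bf": np.zeros(d_feat),
            "Wh": he((1, d_feat), d_feat), "bh": np.zeros(1),
        }

    # ---- forward -----------------------------------------------------------
    def _forward(self, x: np.ndarray):
        p = self.params
        cache = {}
        a1, cache["xp1"] = _conv3x3(x, p["W1"], p["b1"])
        r1 = np.maximum(a1, 0.0)
        h1 = _avgpool(r1, 2)
        a2, cache["xp2"] = _conv3x3(h1, p["W2"], p["b2"])
        r2 = np.maximum(a2, 0.0)
        h2 = _avgpool(r2, 2)
        a3, cache["xp3"] = _conv3x3(h2, p["W3"], p["b3"])
        r3 = np.maximum(a3, 0.0)
        h3 = _avgpool(r3, self._pool3) if self._pool3 > 1 else r3
        flat = h3.reshape(x.shape[0], -1)
        af = flat @ p["Wf"].T + p["bf"]
        feat = np.maximum(af, 0.0)
        cache.update(a1=a1, a2=a2, a3=a3, af=af, flat=flat, feat=feat, h3shape=h3.shape)
        return feat, cache

    def features(self, x: np.ndarray) -> np.ndarray:
        """Pooled encoder output (N, d_feat) — the input to the head."""
        feat, _ = self._forward(x)
        return feat

    def head_logits(self, feat: np.ndarray) -> np.ndarray:
        p = self.params
        return (feat @ p["Wh"].T + p["bh"]).ravel()

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.head_logits(self.features(x))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.logits(x))

    # ---- backward ----------------------------------------------------------
    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        p = self.params
        feat, c = self._forward(x)
        z = self.head_logits(feat)
        loss, dz = bce_with_logits(z, y)
        g = {}
        dz2 = dz[:, None]
        g["Wh"] = dz2.T @ feat
        g["bh"] = dz2.sum(axis=0)
        dfeat = dz2 @ p["Wh"]
        daf = dfeat * (c["af"] > 0)
        g["Wf"] = daf.T @ c["flat"]
        g["bf"] = daf.sum(axis=0)
        dflat = daf @ p["Wf"]
        dh3 = dflat.reshape(c["h3shape"])
        dr3 = _avgpool_backward(dh3, self._pool3) if self._pool3 > 1 else dh3
        da3 = dr3 * (c["a3"] > 0)
        g["W3"], g["b3"], dh2 = _conv3x3_backward(da3, c["xp3"], p["W3"])
        dr2 = _avgpool_backward(dh2, 2)
        da2 = dr2 * (c["a2"] > 0)
        g["W2"], g["b2"], dh1 = _conv3x3_backward(da2, c["xp2"], p["W2"])
        dr1 = _avgpool_backward(dh1, 2)
        da1 = dr1 * (c["a1"] > 0)
        g["W1"], g["b1"], _ = _conv3x3_backward(da1, c["xp1"], p["W1"])
        return loss, g

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


class Adam:
    def __init__(self, keys, lr=3e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
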