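"""Convolutional backbone with multi-task heads, implemented in numpy.

The MIL engine only needs a per-tile scorer with sigmoid task heads and
SGD (momentum + weight decay) training, so the backbone is a compact
three-conv-layer network written directly against numpy: im2col
convolutions, 2x2 max pooling, global average pooling and one dense head
per task (hard parameter sharing — all layers shared except the heads).
It trains in minutes on one CPU, which is what the synthetic-cohort test
loop requires.  The class is registered behind a name so heavier
backbones can be plugged in through the same interface.

Input convention: RGB tiles scaled to [0, 1], channel-first, square, with
side ``input_size`` (224-px tiles are block-averaged down before entry).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallConvNet", "build_backbone", "BACKBONES"]


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float64)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 same-padding convolution via im2col.

    x: (N, C, H, W); w: (C*9, F); b: (F,).  Returns (out, cols) with
    out (N, F, H, W) and the column matrix cached for backprop.
    """
    n, c, h, ww = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    # (N, C, H, W, 3, 3) -> (N, H, W, C*9)
    windows = sliding_window_view(xp, (3, 3), axis=(2, 3))
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * ww, c * 9)
    out = cols @ w + b
    out = out.reshape(n, h, ww, -1).transpose(0, 3, 1, 2)
    return out, cols


def _conv_backward(dout: np.ndarray, cols: np.ndarray, w: np.ndarray, x_shape):
    """Gradients of the same-padding 3x3 convolution."""
    n, c, h, ww = x_shape
    f = dout.shape[1]
    dflat = dout.transpose(0, 2, 3, 1).reshape(-1, f)
    dw = cols.T @ dflat
    db = dflat.sum(axis=0)
    dcols = dflat @ w.T  # (N*H*W, C*9)
    dcols = dcols.reshape(n, h, ww, c, 3, 3)
    dxp = np.zeros((n, c, h + 2, ww + 2))
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di:di + h, dj:dj + ww] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return dxp[:, :, 1:-1, 1:-1], dw, db


def _maxpool_forward_(x: np.ndarray):
    """2x2 max pooling; returns output and argmax mask for backprop."""
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_backward(dout: np.ndarray, idx: np.ndarray, x_shape):
    n, c, h, w = x_shape
    dflat = np.zeros((n, c, h // 2, w // 2, 4))
    np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
    dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dx.reshape(n, c, h, w)


@dataclass
class _SGDState:
    velocity: dict[str, np.ndarray]


class SmallConvNet:
    """3-conv-layer CNN with per-task sigmoid heads.

    Architecture (input 32x32x3): [conv3x3 -> ReLU -> maxpool2] x 2,
    conv3x3 -> ReLU -> global average pool -> one linear head per task.
    """

    input_size = 32
    #: fixed input standardization (the backbone's normalization
    #: convention, applied to [0,1]-scaled RGB): typical H&E tiles are
    #: bright and low-contrast, so centering keeps early gradients healthy
    input_mean = 0.76
    input_std = 0.2

    def __init__(self, tasks: tuple[str, ...], rng: np.random.Generator,
                 channels: tuple[int, int, int] = (8, 16, 32)):
        if len(tasks) == 0:
            raise ValueError("at least one task required")
        self.tasks = tuple(tasks)
        self.channels = tuple(channels)
        c1, c2, c3 = channels
        self.params: dict[str, np.ndarray] = {
            "w1": _he_normal(rng, (3 * 9, c1), 3 * 9),
            "b1": np.zeros(c1),
            "w2": _he_normal(rng, (c1 * 9, c2), c1 * 9),
            "b2": np.zeros(c2),
            "w3": _he_normal(rng, (c2 * 9, c3), c2 * 9),
            "b3": np.zeros(c3),
        }
        # heads start at zero so the untrained scorer is unbiased: every
        # tile gets probability 0.5 and the first top-k selection carries
        # no systematic preference for or against any tile appearance
        # (a randomly signed head can rank discriminative tiles last and
        # lock the MIL loop out of ever selecting them)
        for t in self.tasks:
            self.params[f"head_w_{t}"] = np.zeros(c3)
            self.params[f"head_b_{t}"] = np.zeros(1)
        self._sgd = _SGDState({k: np.zeros_like(v) for k, v in self.params.items()})

    # ------------------------------------------------------------------ fwd

    def _features(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        p = self.params
        x = (x - self.input_mean) / self.input_std
        a1, cols1 = _conv_forward(x, p["w1"], p["b1"])
        r1 = np.maximum(a1, 0.0)
        p1, idx1 = _maxpool_forward_(r1)
        a2, cols2 = _conv_forward(p1, p["w2"], p["b2"])
        r2 = np.maximum(a2, 0.0)
        p2, idx2 = _maxpool_forward_(r2)
        a3, cols3 = _conv_forward(p2, p["w3"], p["b3"])
        r3 = np.maximum(a3, 0.0)
        feats = r3.mean(axis=(2, 3))
        if cache is not None:
            cache.update(
                x=x, a1=a1, cols1=cols1, r1=r1, idx1=idx1, p1=p1,
                a2=a2, cols2=cols2, r2=r2, idx2=idx2, p2=p2,
                a3=a3, cols3=cols3, r3=r3, feats=feats,
            )
        return feats

    def forward_logits(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Logits per task; x is (N, C, S, S) float in [0, 1]."""
        feats = self._features(x, cache)
        logits = np.stack(
            [feats @ self.params[f"head_w_{t}"] + self.params[f"head_b_{t}"][0]
             for t in self.tasks],
            axis=1,
        )
        if not np.isfinite(logits).all():
            raise FloatingPointError("non-finite network output")
        return logits

    def forward_probs(self, x: np.ndarray) -> np.ndarray:
        """Per-task probabilities, shape (N, n_tasks)."""
        return _sigmoid(self.forward_logits(x))

    # ------------------------------------------------------------------ bwd

    def train_batch(
        self,
        x: np.ndarray,
        labels: np.ndarray,
        mask: np.ndarray,
        lr: float,
        momentum: float,
        weight_decay: float,
    ) -> dict[str, float]:
        """One SGD step on a mini-batch.

        labels/mask are (N, n_tasks); masked-out entries (mask 0, e.g.
        missing auxiliary labels) contribute zero loss and gradient.  The
        loss is the unweighted sum over tasks of mean BCE over the
        batch's labelled samples.  Returns per-task mean losses.
        """
        n = x.shape[0]
        cache: dict = {}
        logits = self.forward_logits(x, cache)
        probs = _sigmoid(logits)

        losses: dict[str, float] = {}
        dlogits = np.zeros_like(logits)
        for j, t in enumerate(self.tasks):
            m = mask[:, j].astype(bool)
            if not m.any():
                losses[t] = 0.0
                continue
            p = np.clip(probs[m, j], 1e-7, 1.0 - 1e-7)
            y = labels[m, j]
            losses[t] = float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
            dlogits[m, j] = (probs[m, j] - y) / m.sum()

        grads = self._backward(cache, dlogits)
        self._sgd_step(grads, lr, momentum, weight_decay)
        return losses

    def _backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        feats = cache["feats"]
        grads: dict[str, np.ndarray] = {}
        dfeats = np.zeros_like(feats)
        for j, t in enumerate(self.tasks):
            grads[f"head_w_{t}"] = feats.T @ dlogits[:, j]
            grads[f"head_b_{t}"] = np.array([dlogits[:, j].sum()])
            dfeats += np.outer(dlogits[:, j], p[f"head_w_{t}"])

        r3 = cache["r3"]
        n, c3, h3, w3 = r3.shape
        dr3 = np.broadcast_to(dfeats[:, :, None, None] / (h3 * w3), r3.shape).copy()
        da3 = dr3 * (cache["a3"] > 0)
        dp2, grads["w3"], grads["b3"] = _conv_backward(da3, cache["cols3"], p["w3"], cache["p2"].shape)
        dr2 = _maxpool_backward(dp2, cache["idx2"], cache["r2"].shape)
        da2 = dr2 * (cache["a2"] > 0)
        dp1, grads["w2"], grads["b2"] = _conv_backward(da2, cache["cols2"], p["w2"], cache["p1"].shape)
        dr1 = _maxpool_backward(dp1, cache["idx1"], cache["r1"].shape)
        da1 = dr1 * (cache["a1"] > 0)
        _, grads["w1"], grads["b1"] = _conv_backward(da1, cache["cols1"], p["w1"], cache["x"].shape)
        return grads

    def _sgd_step(self, grads, lr, momentum, weight_decay):
        for k, g in grads.items():
            g = g + weight_decay * self.params[k]
            v = self._sgd.velocity[k]
            v *= momentum
            v -= lr * g
            self.params[k] += v

    # ------------------------------------------------------------- serialize

    def state_snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_snapshot(self, snapshot: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = snapshot[k].copy()

    def save(self, path: str | Path) -> None:
        meta = json.dumps({"kind": "smallcnn", "tasks": list(self.tasks),
                           "channels": list(self.channels), "format_version": 1})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "SmallConvNet":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("kind") != "smallcnn":
            raise ValueError(f"unknown backbone kind {meta.get('kind')!r}")
        net = cls(tuple(meta["tasks"]), np.random.default_rng(0), tuple(meta["channels"]))
        for k in net.params:
            net.params[k] = data[k]
        return net


BACKBONES = {"smallcnn": SmallConvNet}


def build_backbone(name: str, tasks: tuple[str, ...], rng: np.random.Generator):
    try:
        factory = BACKBONES[name]
    except KeyError:
        raise ValueError(f"unknown backbone {name!r}; available: {sorted(BACKBONES)}") from None
    return factory(tasks, rng)
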