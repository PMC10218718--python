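"""A compact convolutional network in pure numpy.

This is the default desk-scale backbone for the 3-class patch classifier:
two 3x3 convolution + ReLU + 2x2 max-pool blocks over a 32x32x3 downsampled
patch, followed by a linear softmax head (~4.5k parameters). Being pure
single-threaded numpy it is bit-reproducible for a fixed seed, trains on a
few thousand patches in seconds on one CPU, and has no dependencies beyond
the scientific stack. Published large architectures can be plugged in
through the same ``fit`` / ``predict_proba`` surface when their framework is
available; nothing else in the pipeline assumes this particular network.

Convolutions are stride-1, pad-1 ("same"), implemented with
``sliding_window_view`` (im2col) forward and a 9-offset scatter-add
backward. Max-pool routes gradients to the first maximum. Cross-entropy
loss; SGD-with-momentum and Adam optimizers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallCNN", "TrainHistory"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H, W, k*k*C) patches for stride-1 same convolution."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N, H, W, C, k, k)
    n, h, w = x.shape[0], x.shape[1], x.shape[2]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n, h, w, -1)


def _col2im(dcol: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add column gradients back to pixels."""
    n, h, w, c = x_shape
    pad = k // 2
    dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c))
    dcol = dcol.reshape(n, h, w, k, k, c)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + h, j : j + w, :] += dcol[:, :, :, i, j, :]
    return dxp[:, pad : pad + h, pad : pad + w, :]


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, c, 4)
    idx = np.argmax(xr, axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool2_backward(dout: np.ndarray, idx: np.ndarray, x_shape: tuple) -> np.ndarray:
    n, h, w, c = x_shape
    dxr = np.zeros((n, h // 2, w // 2, c, 4))
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dxr = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return np.ascontiguousarray(dxr).reshape(n, h, w, c)


@dataclass
class TrainHistory:
    """Per-epoch training log."""

    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    epochs_run: int = 0


class SmallCNN:
    """Two-block CNN with a softmax head over ``n_classes``.

    Parameters are held in ``self.params`` (a name -> array dict), so cloning
    and serialization are trivial.
    """

    KERNEL = 3

    def __init__(
        self,
        input_hw: int = 32,
        in_channels: int = 3,
        channels: tuple[int, int] = (8, 16),
        n_classes: int = 3,
        seed: int = 0,
    ) -> None:
        if input_hw % 4 != 0:
            raise ValueError("input_hw must be divisible by 4 (two 2x2 pools)")
        self.input_hw = input_hw
        self.in_channels = in_channels
        self.channels = channels
        self.n_classes = n_classes
        self.flat_dim = (input_hw // 4) * (input_hw // 4) * channels[1]
        self.params = self._init_params(np.random.default_rng(seed))

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        k = self.KERNEL
        c0, (c1, c2) = self.in_channels, self.channels

        def he(fan_in: int, shape: tuple) -> np.ndarray:
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)

        return {
            "W1": he(k * k * c0, (k * k * c0, c1)),
            "b1": np.zeros(c1),
            "W2": he(k * k * c1, (k * k * c1, c2)),
            "b2": np.zeros(c2),
            "W3": he(self.flat_dim, (self.flat_dim, self.n_classes)),
            "b3": np.zeros(self.n_classes),
        }

    def reinit(self, seed: int) -> None:
        """Re-draw all parameters from the given seed."""
        self.params = self._init_params(np.random.default_rng(seed))

    def clone(self) -> "SmallCNN":
        other = SmallCNN(
            self.input_hw, self.in_channels, self.channels, self.n_classes
        )
        other.params = {k: v.copy() for k, v in self.params.items()}
        return other

    # ------------------------------------------------------------------ core

    def _forward(self, x: np.ndarray, want_cache: bool = False):
        p = self.params
        col1 = _im2col(x, self.KERNEL)
        z1 = col1 @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        p1, idx1 = _maxpool2(a1)

        col2 = _im2col(p1, self.KERNEL)
        z2 = col2 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        p2, idx2 = _maxpool2(a2)

        flat = p2.reshape(x.shape[0], -1)
        logits = flat @ p["W3"] + p["b3"]
        if not want_cache:
            return logits, None
        cache = (x, col1, z1, a1, p1, idx1, col2, z2, a2, p2, idx2, flat)
        return logits, cache

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities, shape (N, n_classes); rows sum to 1."""
        out = np.empty((x.shape[0], self.n_classes))
        for i in range(0, x.shape[0], batch_size):
            logits, _ = self._forward(x[i : i + batch_size])
            out[i : i + batch_size] = self._softmax(logits)
        return out

    def loss_and_grads(
        self, x: np.ndarray, y: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean cross-entropy and parameter gradients for a batch."""
        p = self.params
        n = x.shape[0]
        logits, cache = self._forward(x, want_cache=True)
        (_, col1, z1, a1, p1, idx1, col2, z2, a2, p2, idx2, flat) = cache

        probs = self._softmax(logits)
        loss = float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())

        dlogits = probs
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n

        grads = {
            "W3": flat.T @ dlogits,
            "b3": dlogits.sum(axis=0),
        }
        dflat = dlogits @ p["W3"].T
        dp2 = dflat.reshape(p2.shape)
        da2 = _maxpool2_backward(dp2, idx2, a2.shape)
        dz2 = da2 * (z2 > 0)
        grads["W2"] = np.tensordot(col2, dz2, axes=([0, 1, 2], [0, 1, 2]))
        grads["b2"] = dz2.sum(axis=(0, 1, 2))
        dcol2 = dz2 @ p["W2"].T
        dp1 = _col2im(dcol2, p1.shape, self.KERNEL)
        da1 = _maxpool2_backward(dp1, idx1, a1.shape)
        dz1 = da1 * (z1 > 0)
        grads["W1"] = np.tensordot(col1, dz1, axes=([0, 1, 2], [0, 1, 2]))
        grads["b1"] = dz1.sum(axis=(0, 1, 2))
        return loss, grads

    # ------------------------------------------------------------- training

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        lr: float = 0.005,
        optimizer: str = "adam",
        batch_size: int = 32,
        seed: int = 0,
        val: Optional[tuple[np.ndarray, np.ndarray]] = None,
        stop_callback: Optional[Callable[[int, TrainHistory], bool]] = None,
    ) -> TrainHistory:
        """Mini-batch training; deterministic for fixed inputs and seed.

        ``stop_callback(epoch, history)`` returning True halts training after
        that epoch (used by early stopping).
        """
        if optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {optimizer!r}")
        rng = np.random.default_rng(seed)
        state = {k: {"m": np.zeros_like(v), "v": np.zeros_like(v)} for k, v in self.params.items()}
        t = 0
        history = TrainHistory()
        n = x.shape[0]
        for epoch in range(1, epochs + 1):
            order = rng.permutation(n)
            losses = []
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                loss, grads = self.loss_and_grads(x[idx], y[idx])
                losses.append(loss)
                t += 1
                for k, g in grads.items():
                    if optimizer == "adam":
                        s = state[k]
                        s["m"] = 0.9 * s["m"] + 0.1 * g
                        s["v"] = 0.999 * s["v"] + 0.001 * g * g
                        mhat = s["m"] / (1 - 0.9**t)
                        vhat = s["v"] / (1 - 0.999**t)
                        self.params[k] -= lr * mhat / (np.sqrt(vhat) + 1e-8)
                    else:
                        s = state[k]
                        s["m"] = 0.9 * s["m"] - lr * g
                        self.params[k] += s["m"]
            history.train_loss.append(float(np.mean(losses)) if losses else float("nan"))
            if val is not None:
                history.val_accuracy.append(self.accuracy(val[0], val[1]))
            history.epochs_run = epoch
            if stop_callback is not None and stop_callback(epoch, history):
                break
        return history

    def accuracy(self, x: np.ndarray, y: np.ndarray) -> float:
        return float((self.predict_proba(x).argmax(axis=1) == y).mean())
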