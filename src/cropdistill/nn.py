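"""Compact NumPy engine for the convolutional yield surrogate.

Implements exactly the network family the distiller needs — two 3×3
stride-1 convolutions (padding 2) with ReLU, a flatten, one ReLU dense
hidden layer and a scalar linear head — with explicit reverse-mode
gradients for all parameters and, for saliency analysis, for the input
itself.  Convolutions are evaluated as im2col + GEMM in channels-last
layout so the heavy lifting stays in BLAS.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np


class DivergenceError(RuntimeError):
    """Raised when the training loss stops being finite."""


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, H, W, C) -> (B * Ho * Wo, k * k * C) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    b, h, w, c = x.shape
    ho, wo = h - k + 1, w - k + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (b, ho, wo, k, k, c), (s0, s1, s2, s1, s2, s3))
    return np.ascontiguousarray(view).reshape(b * ho * wo, k * k * c)


def _conv_out_hw(h: int, w: int, k: int, pad: int) -> tuple[int, int]:
    return h + 2 * pad - k + 1, w + 2 * pad - k + 1


class CNNRegressor:
    """Two-conv CNN mapping a single-channel (H, W) matrix to one scalar.

    Weight layout: conv kernels are stored flattened as
    ``(k*k*c_in, c_out)`` matching the im2col patch order; dense layers as
    ``(fan_in, fan_out)``.  Glorot-uniform initialization for all layers
    except the scalar head, which starts near zero so initial predictions
    are small regardless of input scale (the CO2 column is deliberately
    left un-standardized); Adam's per-parameter scaling then makes the
    early optimization well conditioned.
    """

    def __init__(
        self,
        input_shape: tuple[int, int] = (184, 5),
        conv1_maps: int = 32,
        conv2_maps: int = 64,
        kernel: int = 3,
        padding: int = 2,
        hidden: int = 64,
        seed: int = 0,
        dtype: type = np.float32,
    ) -> None:
        if padding != kernel - 1:
            # the input-gradient pass below relies on pad == k - 1
            raise ValueError("this engine supports padding == kernel - 1 only")
        self.input_shape = tuple(input_shape)
        self.kernel = kernel
        self.padding = padding
        self.conv1_maps = conv1_maps
        self.conv2_maps = conv2_maps
        self.hidden = hidden
        self.dtype = dtype
        self.seed = seed

        h, w = input_shape
        self.h1, self.w1 = _conv_out_hw(h, w, kernel, padding)
        self.h2, self.w2 = _conv_out_hw(self.h1, self.w1, kernel, padding)
        self.flat = self.h2 * self.w2 * conv2_maps

        rng = np.random.default_rng(seed)

        def glorot(fan_in: int, fan_out: int, shape: tuple[int, ...]) -> np.ndarray:
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape).astype(dtype)

        kk = kernel * kernel
        self.params: dict[str, np.ndarray] = {
            "W1": glorot(kk * 1, conv1_maps, (kk * 1, conv1_maps)),
            "b1": np.zeros(conv1_maps, dtype=dtype),
            "W2": glorot(kk * conv1_maps, conv2_maps, (kk * conv1_maps, conv2_maps)),
            "b2": np.zeros(conv2_maps, dtype=dtype),
            "W3": glorot(self.flat, hidden, (self.flat, hidden)),
            "b3": np.zeros(hidden, dtype=dtype),
            "W4": (1e-3 * rng.standard_normal((hidden, 1))).astype(dtype),
            "b4": np.zeros(1, dtype=dtype),
        }
        self._cache: dict[str, np.ndarray] | None = None
        # target scaling set by the trainer; identity by default
        self.y_center = 0.0
        self.y_scale = 1.0

    # -- parameter bookkeeping --------------------------------------------

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: Mapping[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(params[k], dtype=self.dtype).copy()

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        """Scaled-target predictions for ``x`` of shape (B, H, W)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected input shape (*, {self.input_shape[0]}, "
                f"{self.input_shape[1]}), got {x.shape}")
        b = x.shape[0]
        p = self.params
        k, pad = self.kernel, self.padding

        cols1 = _im2col(x[..., None], k, pad)
        z1 = (cols1 @ p["W1"] + p["b1"]).reshape(b, self.h1, self.w1, -1)
        np.maximum(z1, 0, out=z1)  # ReLU in place; mask recovered as z1 > 0

        cols2 = _im2col(z1, k, pad)
        z2 = (cols2 @ p["W2"] + p["b2"]).reshape(b, self.h2, self.w2, -1)
        np.maximum(z2, 0, out=z2)

        flat = z2.reshape(b, self.flat)
        z3 = flat @ p["W3"] + p["b3"]
        np.maximum(z3, 0, out=z3)
        y = (z3 @ p["W4"] + p["b4"])[:, 0]

        if cache:
            self._cache = {
                "cols1": cols1, "z1": z1, "cols2": cols2, "z2": z2,
                "flat": flat, "z3": z3, "a3": z3, "batch": b,
            }
        return y.astype(np.float64)

    def backward(self, dy: np.ndarray, need_input_grad: bool = False):
        """Gradients of ``sum(dy * y)`` from the last cached forward.

        Returns ``grads`` (dict keyed like ``params``) and, if requested,
        the gradient with respect to the input, shape (B, H, W).
        """
        if self._cache is None:
            raise RuntimeError("backward() requires a cached forward pass")
        c = self._cache
        p = self.params
        b = c["batch"]
        k = self.kernel
        dy = np.asarray(dy, dtype=self.dtype).reshape(b, 1)

        grads: dict[str, np.ndarray] = {}
        grads["W4"] = c["a3"].T @ dy
        grads["b4"] = dy.sum(axis=0)
        da3 = dy @ p["W4"].T
        dz3 = da3 * (c["z3"] > 0)
        grads["W3"] = c["flat"].T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["W3"].T

        dz2 = dflat.reshape(b, self.h2, self.w2, -1) * (c["z2"] > 0)
        dz2f = dz2.reshape(b * self.h2 * self.w2, -1)
        grads["W2"] = c["cols2"].T @ dz2f
        grads["b2"] = dz2f.sum(axis=0)
        # input gradient of a pad = k-1 convolution: valid cross-correlation
        # of the output gradient with the spatially flipped kernel
        w2k = p["W2"].reshape(k, k, self.conv1_maps, self.conv2_maps)
        w2fl = w2k[::-1, ::-1].transpose(0, 1, 3, 2).reshape(
            k * k * self.conv2_maps, self.conv1_maps)
        da1 = (_im2col(dz2, k, 0) @ w2fl).reshape(b, self.h1, self.w1, -1)

        dz1 = da1 * (c["z1"] > 0)
        dz1f = dz1.reshape(b * self.h1 * self.w1, -1)
        grads["W1"] = c["cols1"].T @ dz1f
        grads["b1"] = dz1f.sum(axis=0)

        if not need_input_grad:
            return grads
        w1k = p["W1"].reshape(k, k, 1, self.conv1_maps)
        w1fl = w1k[::-1, ::-1].transpose(0, 1, 3, 2).reshape(
            k * k * self.conv1_maps, 1)
        h, w = self.input_shape
        dx = (_im2col(dz1, k, 0) @ w1fl).reshape(b, h, w)
        return grads, dx.astype(np.float64)

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(output)/d(input) per sample, shape like ``x``."""
        x = np.asarray(x)
        squeeze = x.ndim == 2
        y = self.forward(x if not squeeze else x[None], cache=True)
        _, dx = self.backward(np.ones(len(y)), need_input_grad=True)
        self._cache = None
        return dx[0] if squeeze else dx


def calibrate_init(model: CNNRegressor, x_sample: np.ndarray) -> None:
    """Layer-sequential unit-variance rescaling of the initial weights.

    Runs a sample batch through the network and divides each layer's
    weights by its pre-activation standard deviation, so every layer
    starts with unit-scale activations regardless of the input's column
    scales (the CO2 column is deliberately not standardized).  Deterministic
    given the sample batch; a no-op on zero-variance layers.
    """
    for key, zname in (("W1", "z1"), ("W2", "z2"), ("W3", "z3")):
        model.forward(x_sample, cache=True)
        z = model._cache[zname]
        s = float(np.std(z))
        if s > 1e-12:
            model.params[key] /= np.asarray(s, dtype=model.dtype)
    model._cache = None


class Adam:
    """Adaptive-moment gradient descent with bias correction."""

    def __init__(self, params: Mapping[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            g = g.astype(np.float32, copy=False)
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * np.square(g)
            update = (self.lr * (m / b1c)
                      / (np.sqrt(v / b2c) + self.eps))
            params[k] -= update.astype(params[k].dtype, copy=False)
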