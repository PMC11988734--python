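"""Compact CNN engine: NHWC layers with explicit forward/backward passes.

Implements exactly the pieces the desk-scale classifier needs — 2D
convolution (im2col), max pooling, batch normalization with running
statistics, ReLU, global average pooling, a dense head, sigmoid /
binary-cross-entropy, and Adam — with hand-written gradients.  The
explicit backward pass is also what lets class-activation mapping obtain
d(score)/d(feature map) at any convolutional layer.

All arrays are float64 NHWC; batches are small, so clarity is preferred
over micro-optimization (convolutions go through a single matmul per
batch).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "MaxPool2D",
    "GlobalAvgPool",
    "Dense",
    "Network",
    "Adam",
    "sigmoid",
    "bce_loss_and_grad",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss_and_grad(logits: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    z = logits.ravel()
    y = y.ravel().astype(np.float64)
    p = sigmoid(z)
    eps = 1e-12
    loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    dz = (p - y) / z.size
    return loss, dz.reshape(logits.shape)


class Layer:
    """Base layer: holds params/grads dicts and a forward cache."""

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


class Conv2D(Layer):
    """Same-padded 2D convolution (square kernel) via im2col."""

    def __init__(self, cin, cout, k=3, stride=1, name="conv", rng=None, bias=True):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (k * k * cin))  # He initialization
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout
        self.params["W"] = rng.normal(0.0, scale, size=(k, k, cin, cout))
        if bias:
            self.params["b"] = np.zeros(cout)

    def _im2col(self, x):
        B, H, W, C = x.shape
        k, s = self.k, self.stride
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]  # (B, Ho, Wo, C, k, k)
        Ho, Wo = win.shape[1], win.shape[2]
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(B, Ho, Wo, k * k * C)
        return cols, (B, H, W, C, Ho, Wo, pad)

    def forward(self, x, training=False):
        cols, geom = self._im2col(x)
        Wm = self.params["W"].reshape(-1, self.cout)
        out = cols @ Wm
        if "b" in self.params:
            out += self.params["b"]
        self.cache = (cols, geom)
        return out

    def backward(self, dout):
        cols, (B, H, W, C, Ho, Wo, pad) = self.cache
        k, s = self.k, self.stride
        Wm = self.params["W"].reshape(-1, self.cout)
        dcols_flat = dout.reshape(-1, self.cout) @ Wm.T
        self.grads["W"] = (
            cols.reshape(-1, k * k * C).T @ dout.reshape(-1, self.cout)
        ).reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] = dout.sum(axis=(0, 1, 2))
        # col2im scatter-add
        dxp = np.zeros((B, H + 2 * pad, W + 2 * pad, C))
        dcols = dcols_flat.reshape(B, Ho, Wo, k, k, C)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + Ho * s : s, j : j + Wo * s : s, :] += dcols[:, :, :, i, j, :]
        return dxp[:, pad : pad + H, pad : pad + W, :]


class BatchNorm(Layer):
    """Per-channel normalization with running statistics.

    When ``frozen`` (the transfer-learning default here) the layer always
    normalizes with its stored running mean/variance and neither the
    statistics nor gamma/beta are ever updated.
    """

    def __init__(self, c, name="bn", momentum=0.9, eps=1e-5, frozen=True):
        super().__init__(name)
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps
        self.frozen = frozen

    def forward(self, x, training=False):
        use_batch = training and not self.frozen
        if use_batch:
            axes = tuple(range(x.ndim - 1))
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self.cache = (xhat, inv_std, use_batch, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv_std, use_batch, shape = self.cache
        axes = tuple(range(dout.ndim - 1))
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        if not use_batch:
            return dout * self.params["gamma"] * inv_std
        m = np.prod([shape[a] for a in axes])
        dxhat = dout * self.params["gamma"]
        return (
            inv_std
            / m
            * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        )


class ReLU(Layer):
    def __init__(self, name="relu"):
        super().__init__(name)

    def forward(self, x, training=False):
        self.cache = x > 0
        return np.where(self.cache, x, 0.0)

    def backward(self, dout):
        return np.where(self.cache, dout, 0.0)


class MaxPool2D(Layer):
    def __init__(self, size=2, name="pool"):
        super().__init__(name)
        self.size = size

    def forward(self, x, training=False):
        B, H, W, C = x.shape
        s = self.size
        Ho, Wo = H // s, W // s
        xr = x[:, : Ho * s, : Wo * s, :].reshape(B, Ho, s, Wo, s, C)
        out = xr.max(axis=(2, 4))
        self.cache = (x.shape, xr, out)
        return out

    def backward(self, dout):
        shape, xr, out = self.cache
        B, H, W, C = shape
        s = self.size
        Ho, Wo = H // s, W // s
        mask = xr == out[:, :, None, :, None, :]
        # split ties evenly so the gradient is conserved
        mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        dx = np.zeros(shape)
        dx[:, : Ho * s, : Wo * s, :] = (mask * dout[:, :, None, :, None, :]).reshape(
            B, Ho * s, Wo * s, C
        )
        return dx


class GlobalAvgPool(Layer):
    def __init__(self, name="gap"):
        super().__init__(name)

    def forward(self, x, training=False):
        self.cache = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        B, H, W, C = self.cache
        return np.broadcast_to(dout[:, None, None, :], (B, H, W, C)) / (H * W)


class Dense(Layer):
    def __init__(self, cin, cout, name="dense", rng=None):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(0.0, np.sqrt(1.0 / cin), size=(cin, cout))
        self.params["b"] = np.zeros(cout)

    def forward(self, x, training=False):
        self.cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        x = self.cache
        self.grads["W"] = x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Network:
    """Sequential layer stack; the last layer is the classification head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def head(self) -> Dense:
        return self.layers[-1]

    @property
    def base_layers(self) -> list[Layer]:
        return self.layers[:-1]

    def forward(self, x, training=False, start: int = 0):
        for layer in self.layers[start:]:
            x = layer.forward(x, training=training)
        return x

    def features(self, x) -> np.ndarray:
        """Global-average-pooled feature vector (input to the head)."""
        for layer in self.base_layers:
            x = layer.forward(x, training=False)
        return x

    def predict_proba(self, x) -> np.ndarray:
        return sigmoid(self.forward(x, training=False)).ravel()

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def grad_wrt_layer_output(self, x, layer_index: int, sign: float = 1.0):
        """Forward a batch, then d(logit)/d(output of layers[layer_index]).

        ``sign=+1`` differentiates the positive-class logit; ``-1`` its
        negation (the logit of the complementary class of a single sigmoid
        unit).  Returns (activation, gradient), both shaped like the
        layer's output.
        """
        acts = [x]
        h = x
        for layer in self.layers:
            h = layer.forward(h, training=False)
            acts.append(h)
        dout = np.full_like(h, sign)
        for i in range(len(self.layers) - 1, layer_index, -1):
            dout = self.layers[i].backward(dout)
        return acts[layer_index + 1], dout

    # --- parameter bookkeeping -------------------------------------------

    def named_params(self):
        for li, layer in enumerate(self.layers):
            for key, val in layer.params.items():
                yield f"{li}:{layer.name}:{key}", layer, key, val

    def get_state(self) -> dict[str, np.ndarray]:
        state = {name: val.copy() for name, _, _, val in self.named_params()}
        for li, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                state[f"{li}:{layer.name}:running_mean"] = layer.running_mean.copy()
                state[f"{li}:{layer.name}:running_var"] = layer.running_var.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, key, _ in self.named_params():
            layer.params[key] = state[name].copy()
        for li, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[f"{li}:{layer.name}:running_mean"].copy()
                layer.running_var = state[f"{li}:{layer.name}:running_var"].copy()

    def trainable_refs(self, phase: str):
        """(layer, key) pairs receiving gradient updates in a phase.

        retrain   : head only (the base stays frozen);
        fine_tune : everything except normalization-layer parameters.
        """
        refs = []
        if phase == "retrain":
            for key in self.head.params:
                refs.append((self.head, key))
        elif phase == "fine_tune":
            for layer in self.layers:
                if isinstance(layer, BatchNorm):
                    continue
                for key in layer.params:
                    refs.append((layer, key))
        else:
            raise ValueError(f"unknown phase {phase!r}")
        return refs


class Adam:
    """Adaptive-moment optimizer over an explicit list of (layer, key) refs."""

    def __init__(self, refs, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.refs = refs
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[k]) for layer, k in refs]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in refs]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (layer, key) in enumerate(self.refs):
            g = layer.grads[key]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            layer.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
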