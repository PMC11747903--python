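"""A compact CPU neural-network engine for the patch classifiers.

Implements exactly the pieces the OCT patch CNNs need — 3x3 same-padding
convolution (im2col + GEMM), ReLU, 2x2 max pooling, inverted dropout, dense
layers, Adam, and class-weighted binary cross-entropy with logits — with
explicit reverse-mode gradients, so the models are fully introspectable
(layer shapes, activations, and activation gradients for Grad-CAM).

All arrays are float32; convolution is chunked over the batch axis to keep
the im2col buffers small. Every source of randomness (init, dropout,
shuffling) is a `numpy.random.Generator` passed in explicitly.
"""

from __future__ import annotations

import numpy as np

class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data.astype(np.float32)
        self.grad = np.zeros_like(self.data)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """NHWC (N,H,W,C) -> (N*H*W, k*k*C) with same padding (k odd).

    The channel axis stays innermost, so the gather copies contiguous
    C-length blocks.
    """
    n, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # (N, H, W, C, k, k) -> (N, H, W, k, k, C)
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, k * k * c)


class Conv2d:
    """3x3 stride-1 same-padding convolution, He-initialized.

    Activations are NHWC; the convolution is one im2col + GEMM. The kernel
    is stored (k, k, cin, cout), matching the im2col column order when
    flattened to (k*k*cin, cout).
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 3):
        self.cin, self.cout, self.k = cin, cout, k
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.standard_normal((k, k, cin, cout)).astype(np.float32) * scale)
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        self._x = x
        cols = _im2col(x, self.k)
        self._cols = cols if train else None  # reused for dW in backward
        out = cols @ self.W.data.reshape(-1, self.cout) + self.b.data
        return out.reshape(n, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        x = self._x
        n, h, w, c = x.shape
        k = self.k
        p = k // 2
        dy2d = dy.reshape(-1, self.cout)
        cols = self._cols if self._cols is not None else _im2col(x, k)
        self.W.grad[...] = (cols.T @ dy2d).reshape(k, k, c, self.cout)
        self.b.grad[...] = dy2d.sum(axis=0)
        self._x = None
        self._cols = None
        if getattr(self, "is_input_layer", False):
            return None  # dx unused at the input
        # dx by col2im: column gradients scattered back to their taps
        dcols = (dy2d @ self.W.data.reshape(-1, self.cout).T
                 ).reshape(n, h, w, k, k, self.cin)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.cin), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p:p + h, p:p + w, :]


class ReLU:
    def params(self):
        return []

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2, NHWC (input H, W must be even).

    Ties are broken toward the first window position (row-major), matching
    a single-argmax implementation.
    """

    def params(self):
        return []

    def forward(self, x, train=False):
        self._shape = x.shape
        v = [x[:, i::2, j::2, :] for i in (0, 1) for j in (0, 1)]
        out = np.maximum.reduce(v)
        taken = np.zeros(out.shape, dtype=bool)
        self._masks = []
        for vk in v:
            m = (vk == out) & ~taken
            taken |= m
            self._masks.append(m)
        return out

    def backward(self, dy):
        dx = np.zeros(self._shape, dtype=dy.dtype)
        for (i, j), m in zip(((0, 0), (0, 1), (1, 0), (1, 1)), self._masks):
            dx[:, i::2, j::2, :] += dy * m
        return dx


class Dropout:
    """Inverted dropout: scaling at train time, identity at eval."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def params(self):
        return []

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten:
    def params(self):
        return []

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.d_in, self.d_out = d_in, d_out
        scale = np.sqrt(2.0 / d_in)
        self.W = Param(rng.standard_normal((d_out, d_in)).astype(np.float32) * scale)
        self.b = Param(np.zeros(d_out, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.data.T + self.b.data

    def backward(self, dy):
        self.W.grad[...] = dy.T @ self._x
        self.b.grad[...] = dy.sum(axis=0)
        dx = dy @ self.W.data
        self._x = None
        return dx


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def weighted_bce_with_logits(logits: np.ndarray, y: np.ndarray,
                             weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Class-weighted binary cross-entropy on logits.

    Returns (mean loss, d loss / d logits). Stable via softplus.
    """
    z = logits.astype(np.float64)
    y = y.astype(np.float64)
    w = weights.astype(np.float64)
    # log(1 + e^z) - y z, computed stably
    softplus = np.where(z > 0, z + np.log1p(np.exp(-z)), np.log1p(np.exp(z)))
    loss = float(np.mean(w * (softplus - y * z)))
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    dz = (w * (sig - y) / z.size).astype(np.float32)
    return loss, dz


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class CNNClassifier:
    """The patch CNN and its two feature-fusion variants.

    Convolutional stack (shared by all variants), input 1x64x128:

        conv3x3(1->32)   + ReLU + maxpool2          -> 32 x 32 x 64
        conv3x3(32->64)  + ReLU + maxpool2 + drop   -> 64 x 16 x 32
        conv3x3(64->128) + ReLU + maxpool2          -> 128 x 8 x 16
        conv3x3(128->256)+ ReLU + maxpool2 + drop   -> 256 x 4 x 8
        flatten                                     -> 8192

    Heads: ``plain`` maps the 8192-long embedding straight to the class
    logit; ``v1`` inserts a dense bottleneck to 12 units, concatenates the 4
    engineered features (16 inputs to the last dense layer); ``v2``
    concatenates the 4 features directly onto the embedding (8196 inputs to
    the last dense layer). P(PV) = sigmoid(logit).
    """

    VARIANTS = ("plain", "v1", "v2")
    INPUT_SHAPE = (1, 64, 128)
    CONV_CHANNELS = (32, 64, 128, 256)

    def __init__(self, variant: str = "plain", n_features: int = 4,
                 dropout_p: float = 0.15, seed: int = 0):
        if variant not in self.VARIANTS:
            raise ValueError(f"variant must be one of {self.VARIANTS}")
        self.variant = variant
        self.n_features = n_features if variant != "plain" else 0
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        ch = self.CONV_CHANNELS
        self.conv_stack = [
            Conv2d(1, ch[0], rng), ReLU(), MaxPool2(),
            Conv2d(ch[0], ch[1], rng), ReLU(), MaxPool2(), Dropout(dropout_p, self.dropout_rng),
            Conv2d(ch[1], ch[2], rng), ReLU(), MaxPool2(),
            Conv2d(ch[2], ch[3], rng), ReLU(), MaxPool2(), Dropout(dropout_p, self.dropout_rng),
            Flatten(),
        ]
        self.conv_stack[0].is_input_layer = True
        #: index (within conv_stack) of the last conv layer's ReLU output,
        #: i.e. the activation map Grad-CAM attends to
        self._gradcam_layer = 11

        self.embedding_dim = self._trace_embedding_dim()
        c, h, w = self.INPUT_SHAPE
        if variant == "plain":
            self.head = [Dense(self.embedding_dim, 1, rng)]
        elif variant == "v1":
            self.head = [Dense(self.embedding_dim, 12, rng), ReLU(),
                         Dense(12 + self.n_features, 1, rng)]
        else:  # v2
            self.head = [Dense(self.embedding_dim + self.n_features, 1, rng)]

    # -- introspection -----------------------------------------------------
    def _trace_embedding_dim(self) -> int:
        c, h, w = self.INPUT_SHAPE
        x = np.zeros((1, h, w, c), dtype=np.float32)
        for layer in self.conv_stack:
            x = layer.forward(x, train=False)
        return int(x.shape[1])

    @property
    def final_dense_in(self) -> int:
        """Input width of the last dense layer (8192 plain / 16 v1 / 8196 v2)."""
        return self.head[-1].d_in

    @property
    def bottleneck_out(self) -> int | None:
        """Width of the v1 intermediate dense layer (12), else None."""
        return self.head[0].d_out if self.variant == "v1" else None

    def params(self) -> list[Param]:
        out = []
        for layer in self.conv_stack + self.head:
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, feats: np.ndarray | None = None,
                train: bool = False, capture: bool = False) -> np.ndarray:
        """Logit per item. ``x`` is (N, 1, 64, 128) in [0, 1]; ``feats`` is
        (N, n_features) standardized engineered features (v1/v2 only)."""
        if x.ndim != 4 or x.shape[1:] != self.INPUT_SHAPE:
            raise ValueError(f"expected input of shape (N, {self.INPUT_SHAPE}), got {x.shape}")
        if self.variant != "plain":
            if feats is None or feats.shape != (x.shape[0], self.n_features):
                raise ValueError(f"variant {self.variant} needs (N, {self.n_features}) features")
        # activations run NHWC internally
        x = np.ascontiguousarray(x.astype(np.float32, copy=False).transpose(0, 2, 3, 1))
        self._capture = capture
        for i, layer in enumerate(self.conv_stack):
            x = layer.forward(x, train=train)
            if capture and i == self._gradcam_layer:
                self.captured_activation = x
        if self.variant == "plain":
            h = x
            for layer in self.head:
                h = layer.forward(h, train=train)
        elif self.variant == "v1":
            h = self.head[1].forward(self.head[0].forward(x, train=train), train=train)
            h = np.concatenate([h, feats.astype(np.float32)], axis=1)
            self._concat_split = self.head[0].d_out
            h = self.head[2].forward(h, train=train)
        else:
            h = np.concatenate([x, feats.astype(np.float32)], axis=1)
            h = self.head[0].forward(h, train=train)
        return h[:, 0]

    def backward(self, dlogit: np.ndarray) -> np.ndarray | None:
        """Backpropagate d loss / d logit; fills every Param's ``.grad``.

        Returns the gradient at the last conv activation (Grad-CAM's
        attention target), also stored in ``captured_grad``.
        """
        dy = dlogit[:, None].astype(np.float32)
        if self.variant == "plain":
            for layer in reversed(self.head):
                dy = layer.backward(dy)
        elif self.variant == "v1":
            dy = self.head[2].backward(dy)
            dy = dy[:, : self._concat_split]
            dy = self.head[0].backward(self.head[1].backward(dy))
        else:
            dy = self.head[0].backward(dy)
            dy = dy[:, : self.embedding_dim]
        captured = None
        for i in range(len(self.conv_stack) - 1, -1, -1):
            if i == self._gradcam_layer:
                captured = dy.copy()
            dy = self.conv_stack[i].backward(dy)
        self.captured_grad = captured
        return captured

    def predict_proba(self, x: np.ndarray, feats: np.ndarray | None = None,
                      batch: int = 256) -> np.ndarray:
        """P(PV) per item, evaluation mode, batched for memory."""
        out = np.empty(x.shape[0], dtype=np.float64)
        for s in range(0, x.shape[0], batch):
            e = min(s + batch, x.shape[0])
            f = feats[s:e] if feats is not None else None
            out[s:e] = sigmoid(self.forward(x[s:e], f, train=False))
        return out

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state, strict=True):
            p.data[...] = s
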