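"""A compact differentiable network stack on numpy.

Provides exactly what the spectral probe needs from a classifier: logits,
penultimate-layer features, and gradients of the classification loss with
respect to the *input* (for white-box attacks) and the weights (for SGD
training).  Layers are deliberately few — strided convolution, ReLU, global
average pooling, flatten, linear — mirroring the conv-trunk /
average-pool / linear-head shape of standard image backbones at a scale
that trains in CPU-seconds.

Public images are (N, H, W, 3) floats in [0, 1]; the internal layout is
NCHW.  All randomness flows through explicit ``numpy.random.Generator``s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Conv2d",
    "Normalize",
    "ReLU",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "NumpyNet",
    "Classifier",
    "LinearClassifier",
    "softmax_cross_entropy",
    "sgd_train",
    "TrainingLog",
]


class Layer:
    """Base layer: forward caches what backward needs; grads mirror params."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution (cross-correlation), stride s, symmetric zero pad."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k * k
        # He-normal init for ReLU trunks
        self.W = rng.standard_normal((out_channels, in_channels, k, k)) * np.sqrt(
            2.0 / fan_in
        )
        self.b = np.zeros(out_channels)
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        k = self.W.shape[2]
        return (
            (h + 2 * self.pad - k) // self.stride + 1,
            (w + 2 * self.pad - k) // self.stride + 1,
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.W.shape[2]
        s = self.stride
        ho, wo = self._out_hw(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        y = np.tile(self.b[None, :, None, None], (n, 1, ho, wo))
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s]
                # (N,C,ho,wo) x (O,C) -> (N,O,ho,wo)
                y += np.einsum("ncij,oc->noij", xs, self.W[:, :, ki, kj], optimize=True)
        self._cache = (xp, x.shape)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, xshape = self._cache
        n, c, h, w = xshape
        k = self.W.shape[2]
        s = self.stride
        ho, wo = dout.shape[2:]
        dxp = np.zeros_like(xp)
        self.db += dout.sum(axis=(0, 2, 3))
        for ki in range(k):
            for kj in range(k):
                xs = xp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s]
                self.dW[:, :, ki, kj] += np.einsum(
                    "noij,ncij->oc", dout, xs, optimize=True
                )
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += np.einsum(
                    "noij,oc->ncij", dout, self.W[:, :, ki, kj], optimize=True
                )
        p = self.pad
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class Normalize(Layer):
    """Fixed affine preprocessing ``(x - shift) * scale`` (not trainable).

    Part of the model's preprocessing chain, so white-box attacks
    differentiate through it like any other layer.
    """

    def __init__(self, shift: float = 0.5, scale: float = 4.0) -> None:
        self.shift = shift
        self.scale = scale

    def forward(self, x: np.ndarray) -> np.ndarray:
        return (x - self.shift) * self.scale

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.scale


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) mean over space; the usual penultimate pool."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(
        self, in_features: int, out_features: int, rng: np.random.Generator | None = None
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.W = rng.standard_normal((in_features, out_features)) * np.sqrt(
            1.0 / in_features
        )
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T


class NumpyNet:
    """A plain layer stack; ``feature_index`` marks the penultimate output."""

    def __init__(self, layers: list[Layer], feature_index: int = -1) -> None:
        self.layers = layers
        self.feature_index = feature_index % len(layers)

    def forward(self, x: np.ndarray, collect_features: bool = False):
        feats = None
        for i, layer in enumerate(self.layers):
            x = layer.forward(x)
            if collect_features and i == self.feature_index:
                feats = x
        return (x, feats) if collect_features else x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def zero_grad(self) -> None:
        for g in self.grads():
            g[...] = 0.0

    def n_params(self) -> int:
        return sum(p.size for p in self.params())


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, label_smoothing: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-example smoothed CE loss and its gradient w.r.t. the logits.

    With smoothing ``ls`` the target distribution is
    ``(1 - ls) * onehot + ls / K``; the gradient is ``softmax - target``.
    """
    n, k = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    p = np.exp(logp)
    target = np.full_like(p, label_smoothing / k)
    target[np.arange(n), labels] += 1.0 - label_smoothing
    loss = -(target * logp).sum(axis=1)
    return loss, p - target


class Classifier:
    """User-facing wrapper: HWC images in, logits / features / grads out.

    This is the contract the attack and RSA modules rely on:
    ``logits``, ``predict``, ``features`` (penultimate representation) and
    ``loss_and_input_grad`` (sum-of-per-example CE, so the returned input
    gradient is exact per example).
    """

    def __init__(self, net: NumpyNet, n_classes: int, label_smoothing: float = 0.0):
        self.net = net
        self.n_classes = n_classes
        self.label_smoothing = label_smoothing

    @staticmethod
    def _to_nchw(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        return np.transpose(x, (0, 3, 1, 2))

    def logits(self, images: np.ndarray) -> np.ndarray:
        return self.net.forward(self._to_nchw(images))

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.logits(images).argmax(axis=1)

    def features(self, images: np.ndarray) -> np.ndarray:
        _, feats = self.net.forward(self._to_nchw(images), collect_features=True)
        return feats

    def accuracy(self, images: np.ndarray, labels: np.ndarray, batch_size: int = 256) -> float:
        hits = 0
        for i in range(0, len(images), batch_size):
            hits += int((self.predict(images[i : i + batch_size]) == labels[i : i + batch_size]).sum())
        return hits / len(images)

    def loss_and_input_grad(
        self, images: np.ndarray, labels: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-example CE loss and d(loss_i)/d(image_i), shape (N, H, W, 3)."""
        x = self._to_nchw(images)
        logits = self.net.forward(x)
        loss, dlogits = softmax_cross_entropy(logits, labels, self.label_smoothing)
        self.net.zero_grad()
        dx = self.net.backward(dlogits)
        return loss, np.transpose(dx, (0, 2, 3, 1))


class LinearClassifier(Classifier):
    """Multinomial logistic model on flattened pixels; closed-form oracle.

    The input gradient of the CE loss is ``(softmax(z) - target) @ W.T``
    reshaped to the image — a constant direction field for fixed softmax
    weights, which makes the worst-case l-inf perturbation analytic.
    """

    def __init__(self, image_shape: tuple[int, int, int], n_classes: int,
                 rng: np.random.Generator | None = None, scale: float = 1.0):
        h, w, c = image_shape
        rng = rng or np.random.default_rng(0)
        lin = Linear(h * w * c, n_classes, rng=rng)
        lin.W *= scale
        net = NumpyNet([Flatten(), lin], feature_index=0)
        super().__init__(net, n_classes)
        self.image_shape = image_shape

    @property
    def weight(self) -> np.ndarray:
        """(H*W*C, K) weight matrix in NCHW-flattened pixel order."""
        return self.net.layers[1].W


@dataclass
class TrainingLog:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


def sgd_train(
    clf: Classifier,
    images: np.ndarray,
    labels: np.ndarray,
    epochs: int,
    lr: float,
    momentum: float = 0.9,
    weight_decay: float = 1e-4,
    batch_size: int = 64,
    lr_decay_epochs: tuple[int, ...] = (),
    lr_decay_factor: float = 0.1,
    rng: np.random.Generator | None = None,
    augment_fn=None,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> TrainingLog:
    """SGD with momentum, weight decay, step lr decay and label smoothing.

    ``augment_fn(batch_images, rng) -> batch_images`` is applied to training
    batches only (this is where the phase-scrambling policy plugs in).
    Raises ``FloatingPointError`` on NaN loss (divergence).
    """
    rng = rng or np.random.default_rng(0)
    net = clf.net
    velocity = [np.zeros_like(p) for p in net.params()]
    log = TrainingLog()
    n = len(images)
    cur_lr = lr
    for epoch in range(epochs):
        if epoch in lr_decay_epochs:
            cur_lr *= lr_decay_factor
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_hits = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = images[idx]
            yb = labels[idx]
            if augment_fn is not None:
                xb = augment_fn(xb, rng)
            x = clf._to_nchw(xb)
            logits = net.forward(x)
            loss, dlogits = softmax_cross_entropy(logits, yb, clf.label_smoothing)
            mean_loss = float(loss.mean())
            if not np.isfinite(mean_loss):
                raise FloatingPointError(
                    f"training diverged (loss={mean_loss}) at epoch {epoch}"
                )
            epoch_loss += mean_loss * len(idx)
            epoch_hits += int((logits.argmax(axis=1) == yb).sum())
            net.zero_grad()
            net.backward(dlogits / len(idx))
            for p, g, v in zip(net.params(), net.grads(), velocity):
                g += weight_decay * p
                v *= momentum
                v -= cur_lr * g
                p += v
        log.epochs.append(epoch)
        log.train_loss.append(epoch_loss / n)
        log.train_acc.append(epoch_hits / n)
        log.lr.append(cur_lr)
        if val_images is not None:
            log.val_acc.append(clf.accuracy(val_images, val_labels))
    return log
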