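"""Convolutional feature encoder and synthetic feature-bank fixtures.

The encoder maps single-channel (grayscale) images to a 64-dimensional
nonnegative feature vector: two convolution stages (each followed by 2x2
stride-2 max pooling), a fully connected stage, the rectified 64-unit
feature layer, and a linear class-score layer trained with softmax
cross-entropy under plain SGD. It is implemented directly on NumPy arrays
(im2col convolutions) so the whole pipeline runs without a deep-learning
framework.

``synthetic_feature_bank`` produces sparse nonnegative stimulus vectors
with a controllable pairwise overlap and fully replaces the trained-encoder
path in tests and desk-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "EncoderConfig",
    "FeatureBank",
    "ConvEncoder",
    "train_encoder",
    "extract_features",
    "synthetic_feature_bank",
]


@dataclass(frozen=True)
class FeatureBank:
    """Stimulus feature vectors: shape ``(n_images, dim)``, nonnegative.

    ``provenance`` records whether the rows came from a trained encoder or
    the synthetic generator.
    """

    vectors: np.ndarray
    provenance: str = "synthetic"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "vectors", vectors)
        if vectors.ndim != 2:
            raise ValueError("feature bank must be a 2-D array")
        if np.any(vectors < 0):
            raise ValueError("feature vectors must be nonnegative")
        if np.any(~vectors.any(axis=1)):
            raise ValueError("every feature vector needs at least one nonzero entry")

    @property
    def n_images(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def to_csv(self, path) -> None:
        np.savetxt(path, self.vectors, delimiter=",")

    @classmethod
    def from_csv(cls, path, provenance: str = "file") -> "FeatureBank":
        return cls(vectors=np.loadtxt(path, delimiter=",", ndmin=2), provenance=provenance)


def synthetic_feature_bank(
    n_images: int,
    dim: int = 64,
    sparsity: float = 0.8,
    overlap: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> FeatureBank:
    """Sparse nonnegative stimulus vectors with tunable similarity.

    Each entry is drawn independently: with probability ``overlap`` it is
    copied from a shared template row, otherwise it is image-specific. In
    either case the entry is zero with probability ``sparsity`` and
    otherwise uniform on ``[0.2, 2.0)``, so the expected zero fraction of
    every row equals ``sparsity`` and ``overlap = 1`` makes all rows
    identical.

    Raises
    ------
    ValueError
        On out-of-range ``sparsity``/``overlap`` or when a degenerate
        (all-zero) row cannot be avoided.
    """
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must lie in [0, 1)")
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)

    def draw_row() -> np.ndarray:
        mask = rng.random(dim) >= sparsity
        return mask * rng.uniform(0.2, 2.0, size=dim)

    for _ in range(100):  # retry on the (rare) all-zero row
        template = draw_row()
        rows = np.empty((n_images, dim))
        for i in range(n_images):
            own = draw_row()
            take_template = rng.random(dim) < overlap
            rows[i] = np.where(take_template, template, own)
        if rows.any(axis=1).all():
            return FeatureBank(vectors=rows, provenance="synthetic", seed=seed)
    raise ValueError(
        f"could not draw nonzero rows (n_images={n_images}, dim={dim}, "
        f"sparsity={sparsity}); lower the sparsity"
    )


# ---------------------------------------------------------------------------
# NumPy CNN
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture and training settings of the convolutional encoder."""

    image_size: int = 32
    conv_channels: Tuple[int, int] = (6, 16)
    kernel_size: int = 5
    fc_width: int = 120
    feature_dim: int = 64
    n_classes: int = 10
    n_epochs: int = 5
    batch_size: int = 32
    learning_rate: float = 0.05
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_dim != 64:
            raise ValueError("feature layer width is fixed to 64")
        if self.n_epochs < 1 or self.batch_size < 1:
            raise ValueError("n_epochs and batch_size must be positive")
        size = self.image_size
        for _ in self.conv_channels:
            size = size - self.kernel_size + 1
            if size < 2:
                raise ValueError("image too small for this conv stack")
            size //= 2
        if size < 1:
            raise ValueError("image too small for this conv stack")


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H', W', C*k*k) patches for a valid convolution."""
    B, C, H, W = x.shape
    Ho, Wo = H - k + 1, W - k + 1
    s = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(B, C, Ho, Wo, k, k), strides=(s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return patches.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho, Wo, C * k * k)


class _Conv:
    """Valid convolution, kernel ``k``, via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self.k = k
        self.c_in = c_in

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cols = _im2col(x, self.k)  # (B, Ho, Wo, C*k*k)
        self._in_shape = x.shape
        out = self._cols @ self.W.T + self.b  # (B, Ho, Wo, c_out)
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad.transpose(0, 2, 3, 1)  # (B, Ho, Wo, c_out)
        self.dW = np.tensordot(g, self._cols, axes=([0, 1, 2], [0, 1, 2]))
        self.db = g.sum(axis=(0, 1, 2))
        gcols = g @ self.W  # (B, Ho, Wo, C*k*k)
        B, C, H, W = self._in_shape
        k = self.k
        Ho, Wo = H - k + 1, W - k + 1
        gx = np.zeros(self._in_shape)
        gcols = gcols.reshape(B, Ho, Wo, C, k, k)
        for di in range(k):
            for dj in range(k):
                gx[:, :, di : di + Ho, dj : dj + Wo] += gcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return gx


class _MaxPool2:
    """2x2 max pooling with stride 2 (truncating odd edges)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        Ho, Wo = H // 2, W // 2
        x = x[:, :, : Ho * 2, : Wo * 2]
        patches = x.reshape(B, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, Ho, Wo, 4
        )
        self._argmax = patches.argmax(axis=-1)
        self._in_shape = x.shape
        return patches.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        Ho, Wo = H // 2, W // 2
        gx = np.zeros((B, C, Ho, Wo, 4))
        np.put_along_axis(gx, self._argmax[..., None], grad[..., None], axis=-1)
        return gx.reshape(B, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, H, W
        )


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T


class ConvEncoder:
    """Small grayscale-image encoder with a rectified 64-unit feature layer.

    Use :func:`train_encoder` to fit it and :func:`extract_features` to read
    the feature bank off a set of images.
    """

    def __init__(self, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2 = config.conv_channels
        k = config.kernel_size
        self.conv1 = _Conv(1, c1, k, rng)
        self.pool1 = _MaxPool2()
        self.conv2 = _Conv(c1, c2, k, rng)
        self.pool2 = _MaxPool2()
        size = config.image_size
        size = (size - k + 1) // 2
        size = (size - k + 1) // 2
        self.flat_dim = c2 * size * size
        self.fc1 = _Dense(self.flat_dim, config.fc_width, rng)
        self.fc2 = _Dense(config.fc_width, config.feature_dim, rng)
        self.head = _Dense(config.feature_dim, config.n_classes, rng)
        self.trained = False

    # -- forward -----------------------------------------------------------

    def _check_images(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.ndim == 3:  # (B, H, W) grayscale
            images = images[:, None, :, :]
        if images.ndim != 4 or images.shape[1] != 1:
            raise ValueError("expected single-channel images (B, H, W) or (B, 1, H, W)")
        if images.shape[2] != self.config.image_size or images.shape[3] != self.config.image_size:
            raise ValueError(
                f"expected {self.config.image_size}x{self.config.image_size} images, "
                f"got {images.shape[2]}x{images.shape[3]}"
            )
        return images

    def features(self, images: np.ndarray) -> np.ndarray:
        """Rectified FC-64 activations, shape ``(B, 64)``."""
        x = self._check_images(images)
        h = self.conv1.forward(x)
        self._m1 = h > 0
        h = self.pool1.forward(h * self._m1)
        h = self.conv2.forward(h)
        self._m2 = h > 0
        h = self.pool2.forward(h * self._m2)
        h = h.reshape(h.shape[0], self.flat_dim)
        h = self.fc1.forward(h)
        self._m3 = h > 0
        h = self.fc2.forward(h * self._m3)
        self._m4 = h > 0
        return h * self._m4

    def class_probabilities(self, images: np.ndarray) -> np.ndarray:
        """Softmax class scores, rows summing to 1."""
        logits = self.head.forward(self.features(images))
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    # -- training ----------------------------------------------------------

    def _layers(self):
        return [self.conv1, self.conv2, self.fc1, self.fc2, self.head]

    def _backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        g = self.fc2.backward(g * self._m4)
        g = self.fc1.backward(g * self._m3)
        B = dlogits.shape[0]
        c2 = self.config.conv_channels[1]
        side = int(np.sqrt(self.flat_dim // c2))
        g = g.reshape(B, c2, side, side)
        g = self.pool2.backward(g)
        g = self.conv2.backward(g * self._m2)
        g = self.pool1.backward(g)
        self.conv1.backward(g * self._m1)

    def fit(self, images: np.ndarray, labels: np.ndarray) -> list:
        """SGD training with softmax cross-entropy; returns per-epoch losses."""
        cfg = self.config
        images = self._check_images(images)
        labels = np.asarray(labels, dtype=int)
        if labels.shape[0] != images.shape[0]:
            raise ValueError("one label per image required")
        rng = np.random.default_rng(cfg.seed + 1)
        velocity = {id(l): (np.zeros_like(l.W), np.zeros_like(l.b)) for l in self._layers()}
        losses = []
        n = images.shape[0]
        for _ in range(cfg.n_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                probs = self.class_probabilities(images[idx])
                B = len(idx)
                epoch_loss += -np.log(probs[np.arange(B), labels[idx]] + 1e-12).sum()
                dlogits = probs.copy()
                dlogits[np.arange(B), labels[idx]] -= 1.0
                dlogits /= B
                self._backward(dlogits)
                for layer in self._layers():
                    vW, vb = velocity[id(layer)]
                    vW *= cfg.momentum
                    vW -= cfg.learning_rate * layer.dW.reshape(vW.shape)
                    vb *= cfg.momentum
                    vb -= cfg.learning_rate * layer.db
                    layer.W += vW.reshape(layer.W.shape)
                    layer.b += vb
            losses.append(epoch_loss / n)
        self.trained = True
        return losses

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        arrays: Dict[str, np.ndarray] = {}
        for name, layer in zip(["conv1", "conv2", "fc1", "fc2", "head"], self._layers()):
            arrays[f"{name}_W"] = layer.W
            arrays[f"{name}_b"] = layer.b
        np.savez(path, trained=np.array(self.trained), **arrays)

    def load(self, path) -> "ConvEncoder":
        data = np.load(path)
        for name, layer in zip(["conv1", "conv2", "fc1", "fc2", "head"], self._layers()):
            layer.W = data[f"{name}_W"]
            layer.b = data[f"{name}_b"]
        self.trained = bool(data["trained"])
        return self


def train_encoder(
    images: np.ndarray, labels: np.ndarray, config: EncoderConfig
) -> ConvEncoder:
    """Fit a :class:`ConvEncoder` on labelled grayscale images."""
    encoder = ConvEncoder(config)
    encoder.fit(images, labels)
    return encoder


def extract_features(encoder: ConvEncoder, images: np.ndarray) -> FeatureBank:
    """Read the FC-64 activations of ``images`` off a trained encoder.

    Raises
    ------
    RuntimeError
        If the encoder has not been trained (or loaded) yet.
    """
    if not encoder.trained:
        raise RuntimeError("encoder must be trained (or loaded) before feature extraction")
    return FeatureBank(
        vectors=encoder.features(images),
        provenance="trained-encoder",
        seed=encoder.config.seed,
    )
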