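"""Forward-only 3D fully-convolutional feature extractor and softmax head.

Five same-padded 3D convolution layers (8/16/32/64/128 output channels,
3x3x3 kernels), each followed by a one-parameter ReLU and a stride-2 max
pool (layers 1-4); a global average pool after layer 5 collapses whatever
spatial extent remains into a fixed 128-element feature vector.  There is
no backpropagation anywhere: every kernel coefficient comes from the fuzzy
generator and every remaining scalar (ReLU slopes, head weights) from the
metaheuristic optimizer, so the network only ever runs forward.

Convolutions use true convolution semantics (kernel flipped, zero-padded
borders) via :func:`scipy.ndimage.convolve`.  Because a filter's kernel is
replicated across its input channels, summing over channels commutes with
the convolution; the forward pass exploits this (and deduplicates
identical kernels in layer-tied mode) so that desk-scale fitness
evaluations stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage

from .fuzzy_weights import KernelBank

__all__ = [
    "NetworkSpec",
    "ReLUParams",
    "HeadParams",
    "parametric_relu",
    "forward_features",
    "forward_features_batch",
    "softmax_probs",
]

FEATURE_LENGTH = 128


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture constants of the 5-layer extractor."""

    channels: Tuple[int, ...] = (8, 16, 32, 64, 128)
    kernel_shape: Tuple[int, int, int] = (3, 3, 3)
    in_channels: int = 4

    def __post_init__(self) -> None:
        if len(self.channels) != 5:
            raise ValueError("the extractor has exactly 5 convolutional layers")
        if self.channels[-1] != FEATURE_LENGTH:
            raise ValueError(
                f"last layer must have {FEATURE_LENGTH} channels (feature length)"
            )

    @property
    def kernel_elements(self) -> int:
        return int(np.prod(self.kernel_shape))


@dataclass(frozen=True)
class ReLUParams:
    """Per-layer parametric ReLU slopes.

    The activation is max(a*x + b, c*x + d) with a = b = d = 0 frozen, so
    only the positive slope c (one per layer) is ever optimized.
    """

    slopes: Tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    a: float = 0.0
    b: float = 0.0
    d: float = 0.0

    def __post_init__(self) -> None:
        if self.a != 0.0 or self.b != 0.0 or self.d != 0.0:
            raise ValueError("a, b and d are fixed at 0 in this architecture")
        if len(self.slopes) != 5:
            raise ValueError("need one ReLU slope per convolutional layer (5)")
        for c in self.slopes:
            if not (0.0 < c <= 2.0):
                raise ValueError(f"ReLU slope must lie in (0, 2], got {c}")


@dataclass(frozen=True)
class HeadParams:
    """Fully-connected softmax head: 128x2 weights plus 2 biases."""

    fc_weights: np.ndarray
    fc_bias: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.fc_weights, dtype=float)
        b = np.asarray(self.fc_bias, dtype=float)
        if w.shape != (FEATURE_LENGTH, 2) or b.shape != (2,):
            raise ValueError(
                f"head must be ({FEATURE_LENGTH}, 2) weights and (2,) bias, "
                f"got {w.shape} and {b.shape}"
            )
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
            raise ValueError("head parameters must be finite")
        object.__setattr__(self, "fc_weights", w)
        object.__setattr__(self, "fc_bias", b)


def parametric_relu(x: np.ndarray, c: float) -> np.ndarray:
    """Elementwise max(0, c*x); equals c * max(0, x) for c > 0."""
    if not c > 0:
        raise ValueError(f"ReLU slope must be positive, got {c}")
    return np.maximum(0.0, c * np.asarray(x))


def _pad_to_even(x: np.ndarray) -> np.ndarray:
    # replicate-pad odd spatial dims so the stride-2 pool halves exactly
    pads = [(0, dim % 2) for dim in x.shape]
    if any(p[1] for p in pads):
        x = np.pad(x, pads, mode="edge")
    return x


def _maxpool2(x: np.ndarray) -> np.ndarray:
    x = _pad_to_even(x)
    a, b, c = x.shape
    return x.reshape(a // 2, 2, b // 2, 2, c // 2, 2).max(axis=(1, 3, 5))


def _conv_same(volume: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(volume, kernel, mode="constant", cval=0.0)


def forward_features(
    volume: np.ndarray, bank: KernelBank, relu: ReLUParams
) -> np.ndarray:
    """Extract the 128-element feature vector from one 4-channel volume.

    ``volume`` has shape (4, X, Y, Z) with every spatial dim >= 16 so the
    four stride-2 pools are well defined.  Per layer: same-padded 3D
    convolution summing over input channels (kernels replicated across
    input channels, so the channel sum is taken first), parametric ReLU,
    then max pool (layers 1-4) or global average pool (layer 5).
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4 or volume.shape[0] != 4:
        raise ValueError(
            f"expected a 4-channel volume of shape (4, X, Y, Z), got {volume.shape}"
        )
    if min(volume.shape[1:]) < 16:
        raise ValueError(
            f"spatial dims must be >= 16 to survive four stride-2 pools, "
            f"got {volume.shape[1:]}"
        )

    # Kernels are replicated across a filter's input channels, so each
    # layer only ever consumes the SUM over its input channels; propagate
    # that sum and deduplicate identical kernels (layer-tied mode) with
    # multiplicities instead of materializing every channel.
    summed = volume.sum(axis=0)
    n_layers = len(bank.layers)
    features = None
    for layer_idx, kernels in enumerate(bank.layers):
        unique: Dict[bytes, np.ndarray] = {}
        keys = []
        counts: Dict[bytes, int] = {}
        for kernel in kernels:
            key = kernel.tobytes()
            if key not in unique:
                unique[key] = _conv_same(summed, kernel)
            counts[key] = counts.get(key, 0) + 1
            keys.append(key)
        c = relu.slopes[layer_idx]
        if layer_idx < n_layers - 1:
            pooled = {k: _maxpool2(parametric_relu(v, c)) for k, v in unique.items()}
            summed = sum(counts[k] * v for k, v in pooled.items())
        else:
            means = {k: parametric_relu(v, c).mean() for k, v in unique.items()}
            features = np.array([means[k] for k in keys])
    if features.shape != (FEATURE_LENGTH,):  # pragma: no cover - spec guard
        raise AssertionError(f"feature length {features.shape} != {FEATURE_LENGTH}")
    return features


def forward_features_batch(
    volumes, bank: KernelBank, relu: ReLUParams
) -> np.ndarray:
    """Stack :func:`forward_features` over an iterable of volumes."""
    return np.stack([forward_features(v, bank, relu) for v in volumes])


def softmax_probs(features: np.ndarray, head: HeadParams) -> np.ndarray:
    """Class probabilities from the FC + softmax head (max-logit shifted)."""
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    logits = features @ head.fc_weights + head.fc_bias
    return softmax(logits)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    logits = np.asarray(logits, dtype=float)
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)
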