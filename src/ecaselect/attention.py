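"""Efficient channel attention (ECA) primitives.

An ECA module squeezes each channel of a feature block to a scalar by global
average pooling, maps the pooled vector through a small shared transform, and
gates the channels with the resulting sigmoid weights.  Two transforms are
supported:

* a shared 1-D convolution whose kernel size adapts to the channel dimension
  (the inter-layer ECA module), and
* a full square linear map (the input-facing "CA layer"), which captures
  global cross-channel interaction — appropriate when the attention dimension
  is EEG electrodes, whose informative couplings are not spatially local.

Layout convention
-----------------
A feature block is an array of shape ``(W, H, C)`` — width, height, channels —
with the channel axis LAST.  For the CA layer acting on an EEG sample the
block is ``(1, T, C)``: width 1, T time samples, C electrodes.  EEG samples
elsewhere in this package use the ``(C, T)`` layout; :func:`sample_to_block`
and :func:`block_to_sample` convert between the two.  Indexing is 0-based
throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "EcaConvParams",
    "CaLayerParams",
    "adaptive_kernel_size",
    "global_average_pool",
    "eca_attention",
    "ca_attention",
    "recalibrate",
    "sample_to_block",
    "block_to_sample",
]


def adaptive_kernel_size(c: int) -> int:
    """Adaptive 1-D convolution kernel size for channel dimension ``c``.

    The kernel size is the odd integer nearest to ``log2(c)/2 + 1/2``, so the
    interaction range grows logarithmically with the channel dimension.  When
    the value falls exactly between two odd integers the larger one is taken
    (e.g. ``c=128`` gives 4.0, resolved to 5).  The result is never below 1.
    """
    if not isinstance(c, (int, np.integer)) or c < 1:
        raise ValueError(f"channel dimension must be a positive integer, got {c!r}")
    v = math.log2(c) / 2.0 + 0.5
    f = math.floor(v)
    lo = f if f % 2 == 1 else f - 1  # largest odd <= v (may be negative)
    hi = lo + 2
    k = lo if (v - lo) < (hi - v) else hi
    return max(k, 1)


@dataclass
class EcaConvParams:
    """Shared 1-D convolution taps plus a single bias term.

    ``kernel`` has odd length ``k = adaptive_kernel_size(C)`` for the hosting
    layer's channel dimension; every channel shares the same taps, replacing a
    band matrix of per-channel local weights.  Trainable scalars: ``k + 1``.
    """

    kernel: np.ndarray
    bias: float = 0.0

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.ndim != 1 or self.kernel.size % 2 == 0:
            raise ValueError("ECA kernel must be a 1-D array of odd length")

    @property
    def k(self) -> int:
        return int(self.kernel.size)

    @property
    def n_parameters(self) -> int:
        return self.k + 1


@dataclass
class CaLayerParams:
    """Full square linear map for the CA layer: weight matrix plus bias vector.

    For C channels the trainable parameter count is ``C**2 + C``.
    """

    weight_matrix: np.ndarray
    bias: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weight_matrix = np.asarray(self.weight_matrix, dtype=float)
        if self.weight_matrix.ndim != 2 or (
            self.weight_matrix.shape[0] != self.weight_matrix.shape[1]
        ):
            raise ValueError("CA weight matrix must be square")
        if self.bias is None:
            self.bias = np.zeros(self.weight_matrix.shape[0])
        self.bias = np.asarray(self.bias, dtype=float)
        if self.bias.shape != (self.weight_matrix.shape[0],):
            raise ValueError("CA bias length must equal the channel count")

    @property
    def n_channels(self) -> int:
        return int(self.weight_matrix.shape[0])

    @property
    def n_parameters(self) -> int:
        return self.n_channels**2 + self.n_channels


def _check_block(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"feature block must be 3-D (W, H, C), got shape {x.shape}")
    if min(x.shape) < 1:
        raise ValueError(f"feature block has an empty axis: shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature block contains non-finite entries")
    return x


def global_average_pool(x: np.ndarray) -> np.ndarray:
    """Channel-wise global average pooling of a ``(W, H, C)`` block.

    Returns a length-C vector whose entry c is the mean of channel c over the
    W x H plane.
    """
    x = _check_block(x)
    return x.mean(axis=(0, 1))


def eca_attention(y: np.ndarray, params: EcaConvParams) -> np.ndarray:
    """Attention weights from the shared 1-D convolution: ``w = sigmoid(conv(y))``.

    The convolution is a cross-correlation with zero padding of ``(k-1)/2`` on
    each side, so the output length equals ``len(y)``; the single bias is
    added to every position.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("aggregated descriptor must be 1-D")
    c = y.size
    if params.k > 2 * c:
        raise ValueError(
            f"ECA kernel size {params.k} exceeds twice the channel dimension {c}"
        )
    pad = (params.k - 1) // 2
    yp = np.pad(y, pad)
    windows = np.lib.stride_tricks.sliding_window_view(yp, params.k)
    z = windows @ params.kernel + params.bias
    return expit(z)


def ca_attention(y: np.ndarray, params: CaLayerParams) -> np.ndarray:
    """Attention weights from the full linear map: ``w = sigmoid(W y + b)``.

    No dimensionality reduction: output length equals the channel count.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (params.n_channels,):
        raise ValueError(
            f"descriptor length {y.shape} does not match CA layer "
            f"channel count {params.n_channels}"
        )
    return expit(params.weight_matrix @ y + params.bias)


def recalibrate(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Scale each channel of a ``(W, H, C)`` block by its attention weight."""
    x = _check_block(x)
    w = np.asarray(w, dtype=float)
    if w.shape != (x.shape[2],):
        raise ValueError(
            f"attention length {w.shape} does not match channel count {x.shape[2]}"
        )
    return x * w


def sample_to_block(sample: np.ndarray) -> np.ndarray:
    """Adapt an EEG sample ``(C, T)`` to the block layout ``(1, T, C)``."""
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 2:
        raise ValueError("EEG sample must be 2-D (channels, time)")
    return sample.T[np.newaxis, :, :]


def block_to_sample(block: np.ndarray) -> np.ndarray:
    """Adapt a ``(1, T, C)`` block back to the EEG sample layout ``(C, T)``."""
    block = np.asarray(block, dtype=float)
    if block.ndim != 3 or block.shape[0] != 1:
        raise ValueError("block must have shape (1, T, C)")
    return block[0].T
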